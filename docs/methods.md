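# Methods

## Kinetic model

Each enzyme/DP assay is modeled by the single-substrate Michaelis–Menten
law on the velocity scale,

    v = Vmax [S] / (KM + [S]),    Vmax = kcat [E]0,

with v in M/s, [S] and KM in M and kcat in 1/s. The assay is an endpoint
measurement: product released over a fixed incubation t (default 30 min)
divided by t. This is a valid initial-rate estimate only while substrate
depletion stays small; `initial_rate_fraction` computes the linear upper
bound v₀·t/[S]₀ and flags anything above 10%. At the reference enzyme
loadings (~30 nM) the bound is ≈10% at the lowest grid point (50 µM) and
<2% at the highest, so the endpoint design is taken at face value and no
depletion correction is applied (progress-curve integration is out of
scope).

Assumptions: single active site, 100% active enzyme (no active-site
titration), no substrate or product inhibition, no transglycosylation.

## Fitting

`fit_mm` estimates (Vmax, KM) by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, positivity
bounds) and derives kcat = Vmax/[E]0. Details that matter:

* **Initialization** — Hanes–Woolf linearization (S/v regressed on S;
  Vmax = 1/slope, KM = intercept/slope), falling back to
  (max v, median S) when the linearization is degenerate (non-positive
  slope or intercept, or <2 positive velocities). The linearization is
  never the final estimator.
* **Residual scaling** — velocities are ~1e-8 M/s, so raw residuals are
  far below the optimizer's absolute ftol/gtol and it would stop at the
  first iterate. Residuals are divided by the largest (weighted)
  velocity and parameters are scaled by their initial values; the
  reported covariance is invariant to this normalization.
* **Weighting** — default is unweighted least squares on the velocity
  scale. A `relative` mode (1/v² weights) is the generalized
  least-squares choice when the error is multiplicative (constant CV),
  which is exactly the synthetic generator's noise model; the recovery
  studies therefore fit with `weighting="relative"`. For real data whose
  error structure is unknown the unweighted default stands.
* **Uncertainties** — Gauss–Newton covariance s²(JᵀJ)⁻¹ at the optimum
  with s² = RSS/(n−2); kcat/KM standard error by the first-order delta
  method, value·sqrt((se_kcat/kcat)² + (se_KM/KM)²), treating the two
  errors as uncorrelated. For the reference X₂ parameters of PcBxl3 this
  gives 0.145 mM⁻¹s⁻¹, which is smaller than the ±0.2 quoted alongside
  the published table; the published propagation method is not stated,
  and no attempt is made to match it.
* Non-convergence is reported via `converged=False` with NaN standard
  errors rather than an exception; fewer than three distinct substrate
  concentrations raises `InsufficientDataError` (two points cannot
  separate Vmax from KM in the presence of noise).

Reported tables round to 2–3 significant figures, ties to even
(`round_report`).

## Subsite theory

For an exo-acting glycosidase whose substrate of DP n fills subsites
−1, +1, …, +(n−1), the specificity constant factorizes as

    (kcat/KM)_n = c_w · k_int · exp[(A₋₁ + A₊₁ + Σ_{i=2}^{n-1} A₊ᵢ) / RT]

with k_int the DP-independent hydrolysis rate constant of the productive
complex and A_i the binding free-energy contribution of subsite i
(kcal/mol, favorable positive). Consequences implemented here:

* **k_int** is approximated by the maximum kcat across the DP series
  (2.05 s⁻¹ for PcBxl3, 0.82 s⁻¹ for TrXyl3A on the reference panel).
* **Plus-subsites**: A₊ₙ = RT ln[(kcat/KM)ₙ₊₁/(kcat/KM)ₙ] — a pure
  ratio, so the unit the specificity constants are carried in cancels.
* **Active center**: A₋₁+A₊₁ = RT ln[(kcat/KM)₂/(c_w·k_int)], with
  (kcat/KM)₂ in M⁻¹s⁻¹ and c_w = 0.018 L/mol (reciprocal molarity of
  water, Hiromi's convention making the argument dimensionless). The
  absolute sum shifts by RT·ln(c_w'/c_w) under a different convention —
  output JSON flags it as convention-dependent — but any between-enzyme
  difference is convention-free, and the comparison report verifies and
  reports only differences at headline level. Separate A₋₁ estimation
  would require a productive/nonproductive binding decomposition that is
  not defensible for a pocket-shaped two-subsite enzyme, so only the sum
  is ever reported.
* **Constants**: R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹ and T = 303.15 K (the
  30 °C assay temperature), so RT ≈ 0.6024 kcal/mol. All three are
  configurable through `ThermoContext`.
* **Subsite counting**: subsites −1 and +1 always count (an active
  exo-enzyme must span the scissile bond); plus-subsites count outward
  from +2 while their affinity is ≥ 0.4 kcal/mol, stopping at the first
  failure. The 0.4 kcal/mol default separates the ~1 kcal/mol affinities
  typical of genuine glycosidase subsites from the sub-RT fluctuations
  seen at nonexistent ones; it is configurable.
* **Printed vs fitted inputs**: when the analysis runs on a published
  parameter table, ratio analyses use the table's own (rounded) kcat/KM
  column (`specificity_printed`), so results are traceable to the
  printed numbers; fits from data use full precision. The telescoping
  identity — rebuilding every (kcat/KM)ₙ from the profile — holds
  exactly in either mode and is asserted to 1e-10 relative.
* **Uncertainty on affinities** (`affinity_uncertainty`): parametric
  bootstrap resampling (kcat, KM) at both DPs from independent normals
  truncated at zero with the stored standard errors; the sample SD of
  the recomputed affinity is validated against a first-order delta
  oracle within 10%. Truncation matters only when se/mean is large
  (≥ ~4σ from zero everywhere on the reference panel).

## Synthetic data generator

Emulates the reference assay design: 8 log-spaced substrate
concentrations from 50 µM to 5 mM (geometric spacing covers the two
decades evenly; the count and spacing are this package's choice, the
range is the assay's), 3 replicates per concentration, true velocities
from the Michaelis–Menten law at the configured [E]0, product accumulated
over 30 min and converted back to a rate, and multiplicative Gaussian
noise with CV 3% on the quantified product (typical HPLC quantification
repeatability; replicate count and noise magnitude are generator choices,
not measured properties). Negative noisy velocities are clipped to zero —
a bias only at extreme noise, documented rather than resampled away.
Seeding uses `numpy.random.default_rng`; identical (parameters, grid,
noise model) give bit-identical datasets, and the pipeline spawns
independent child seeds per enzyme/DP from one base seed.

What the generator does **not** emulate: substrate depletion feedback
(rates are sampled at t=0 velocity), product inhibition,
transglycosylation, pipetting/series correlations, or heteroscedasticity
beyond the constant-CV model. Passing recovery tests therefore show the
estimator chain is correct and unbiased under the stated noise model —
not that real chromatographic data meet that model.

Recovery study sizes: 200 seeded datasets per enzyme/DP parameter set
(8 sets), 3 replicates each; mean fitted kcat and KM agree with the
generating values within 3% (observed: within 0.2% with matched
weighting). With unweighted fitting the KM of the one parameter set lying
below the grid floor (24 µM vs 50 µM) shows a heavy right tail whose mean
is not a reliable summary — one reason the recovery study uses the
variance-matched weights.

## Pipeline and formats

Rate tables, fit tables and subsite profiles are plain CSV with explicit
unit columns (closed unit sets; unknown units fail with the row number).
Rate CSVs default to internal units (M, M/s) so write→read round trips
are bit-exact; the re-fit equivalence test relies on this. The comparison
report is versioned JSON echoing every constant (R, T, c_w, threshold,
k_int) so any number in it can be recomputed from the inputs plus the
echo. CLI exit codes: 0 success, 2 usage/configuration, 3 data/parse,
4 numerical.

## Known limitations

* kcat/KM uncertainties assume independent kcat and KM errors; the fit
  covariance is available internally but published tables do not carry
  it, so the delta method and bootstrap both drop the cross term.
* k_int = max kcat is an approximation inherited from the theory; if no
  DP saturates the productive mode, all active-center sums shift
  together (differences between enzymes computed at matching DP ranges
  are more robust).
* The subsite count threshold is a reporting convention, not an
  estimator; affinities near 0.4 kcal/mol should be judged with their
  bootstrap SEs.
* Absolute active-center sums are c_w-convention-dependent; only
  differences should be compared across studies.
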