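# bxlkinetics

Kinetic comparison and subsite-energetics mapping for exo-acting
β-xylosidases (GH3 family) degrading xylooligosaccharides of increasing
chain length.

β-Xylosidases (Bxls) release xylose from the nonreducing end of the
xylooligosaccharides produced by xylanases. How fast an enzyme handles
xylobiose (X₂) through xylopentaose (X₅) is summarized by the
Michaelis–Menten parameters per substrate DP (degree of polymerization),
and the DP dependence of the specificity constant k_cat/K_M can be
decomposed into per-subsite binding free energies. This package implements
that full analysis chain for a two-enzyme comparison (the reference panel
is the basidiomycete enzyme *Pc*Bxl3 vs the ascomycete enzyme *Tr*Xyl3A):

* **Michaelis–Menten fitting** of initial-rate data,
  v = k_cat·[E]₀·[S]/(K_M + [S]), by nonlinear least squares on the
  velocity scale, with Gauss–Newton standard errors and delta-method
  errors on k_cat/K_M.
* **Subsite-affinity mapping** (Hiromi's theory for exo-enzymes): the
  intrinsic rate constant k_int is the maximum k_cat over the DP series;
  the affinity of plus-subsite +n is A₊ₙ = RT·ln[(k_cat/K_M)ₙ₊₁ /
  (k_cat/K_M)ₙ]; the active-center sum A₋₁+A₊₁ is
  RT·ln[(k_cat/K_M)₂ / (c_w·k_int)] with c_w = 0.018 L/mol.
* **DP and two-enzyme comparison**: normalized specificity profiles,
  per-DP efficiency ratios, parameter ranges, subsite counts, and the
  convention-free active-center affinity difference.
* **A synthetic assay generator** (endpoint rates over a 50 µM–5 mM
  substrate grid with multiplicative measurement noise) so the whole
  pipeline runs and is tested without instrument data.

## Worked example

```python
from bxlkinetics import (
    ThermoContext, load_table2_fixture, build_profile, count_subsites,
    plus_subsite_affinity,
)

series = load_table2_fixture()          # packaged reference parameters, DP 2-5
ctx = ThermoContext()                   # 303.15 K, R = 1.9872e-3 kcal/(mol K)

tr = build_profile(series["TrXyl3A"], ctx)
pc = build_profile(series["PcBxl3"], ctx)

print(f"k_int:            PcBxl3 {pc.k_int} 1/s, TrXyl3A {tr.k_int} 1/s")
print(f"subsite +2:       TrXyl3A {tr.plus_affinities[2]:.3f} kcal/mol, "
      f"PcBxl3 {pc.plus_affinities[2]:.3f} kcal/mol")
print(f"active center:    TrXyl3A {tr.active_center_affinity:.3f}, "
      f"PcBxl3 {pc.active_center_affinity:.3f} kcal/mol")
print(f"difference:       {tr.active_center_affinity - pc.active_center_affinity:.3f}")
print(f"subsite counts:   PcBxl3 {count_subsites(pc)}, TrXyl3A {count_subsites(tr)}")
```

prints

```
k_int:            PcBxl3 2.05 1/s, TrXyl3A 0.82 1/s
subsite +2:       TrXyl3A 0.882 kcal/mol, PcBxl3 -0.134 kcal/mol
active center:    TrXyl3A 7.489, PcBxl3 6.567 kcal/mol
difference:       0.923
subsite counts:   PcBxl3 2, TrXyl3A 3
```

Reading: *Tr*Xyl3A has a genuine third binding subsite (+2, ~1 kcal/mol,
the typical magnitude for glycosidase subsites) and binds the −1/+1
active-center pair about 1 kcal/mol more tightly than *Pc*Bxl3, whereas
*Pc*Bxl3 shows no meaningful affinity beyond the active center — it is a
two-subsite enzyme. The absolute −1/+1 sums depend on the c_w convention
constant; the difference between enzymes does not.

The same analysis is available from the shell:

```sh
bxlkin compare --fixture table2 --out-dir out/     # published parameters
bxlkin run --simulate --seed 1 --out-dir out/      # full synthetic pipeline
bxlkin run path/to/rates.csv --config assay.yaml --out-dir out/
```

`run --simulate` generates the synthetic assay panel, fits every
enzyme/DP dataset, maps subsites and writes `rates.csv`, `fits.csv`,
`profiles.csv`, `profiles.json` and `report.json`; identical seeds give
byte-identical outputs.

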