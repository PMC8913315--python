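"""Subsite-affinity mapping for exo-acting glycoside hydrolases.

For an exo-enzyme hydrolysing a homo-oligosaccharide of DP n, subsite
theory (Hiromi's treatment) decomposes the specificity constant into a
DP-independent intrinsic rate constant k_int and additive subsite binding
free energies A_i:

    (kcat/KM)_n = c_w * k_int * exp[(A_-1 + A_+1 + sum_{i=2}^{n-1} A_+i) / RT]

with c_w = 0.018 L/mol (the reciprocal molarity of water) making the
left-hand side, in 1/(M s), dimensionally consistent. Two consequences
drive everything here:

* the ratio (kcat/KM)_{n+1} / (kcat/KM)_n isolates the affinity of
  subsite +n:  A_+n = RT ln[(kcat/KM)_{n+1} / (kcat/KM)_n];
* at n = 2 the bracket holds only the active-center sum A_-1 + A_+1,
  which is therefore RT ln[(kcat/KM)_2 / (c_w k_int)].

k_int is approximated by the maximum kcat across the DP series. Separate
A_-1 estimation would require a productive/nonproductive binding
decomposition that does not hold for pocket-shaped exo-xylosidases, so
only the -1/+1 sum is ever reported; its absolute value depends on the
c_w convention, but differences between enzymes do not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .assay import DEFAULT_TEMPERATURE_K
from .errors import InvalidArgumentError, MissingDataError
from .kinetics import KineticSeries

__all__ = [
    "GAS_CONSTANT_KCAL",
    "WATER_MOLARITY_CONSTANT",
    "DEFAULT_SUBSITE_THRESHOLD",
    "ThermoContext",
    "SubsiteProfile",
    "select_k_int",
    "affinity_from_ratio",
    "plus_subsite_affinity",
    "active_center_affinity",
    "build_profile",
    "reconstruct_specificity",
    "count_subsites",
    "affinity_uncertainty",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.9872e-3

#: Reciprocal molarity of water, L/mol (1/55.5): Hiromi's convention
#: constant making c_w * k_int commensurate with kcat/KM in 1/(M s).
WATER_MOLARITY_CONSTANT = 0.018

#: A plus-subsite with affinity >= this (kcal/mol) counts as a real
#: binding subsite; below it, thermal noise.
DEFAULT_SUBSITE_THRESHOLD = 0.4


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic constants for affinity calculations.

    Temperature defaults to the assay temperature (303.15 K, i.e. 30 C).
    """

    temperature: float = DEFAULT_TEMPERATURE_K
    gas_constant: float = GAS_CONSTANT_KCAL
    water_molarity_constant: float = WATER_MOLARITY_CONSTANT

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.gas_constant <= 0:
            raise InvalidArgumentError("temperature and gas_constant must be > 0")
        if self.water_molarity_constant <= 0:
            raise InvalidArgumentError("water_molarity_constant must be > 0")

    @property
    def rt(self) -> float:
        """RT in kcal/mol."""
        return self.gas_constant * self.temperature


@dataclass
class SubsiteProfile:
    """Subsite map of one enzyme.

    ``plus_affinities`` maps the positive subsite index n (2, 3, ...)
    to A_+n in kcal/mol; ``active_center_affinity`` is the summed
    A_-1 + A_+1 (convention-dependent through c_w, see module docstring).
    """

    enzyme_label: str
    k_int: float
    active_center_affinity: float
    plus_affinities: dict[int, float] = field(default_factory=dict)
    context: ThermoContext = field(default_factory=ThermoContext)

    def __post_init__(self) -> None:
        if self.k_int <= 0:
            raise InvalidArgumentError(f"k_int must be > 0, got {self.k_int}")
        keys = sorted(self.plus_affinities)
        if keys and keys != list(range(2, 2 + len(keys))):
            raise InvalidArgumentError(
                f"plus subsite indices must be contiguous from +2, got {keys}"
            )
        self.plus_affinities = {k: self.plus_affinities[k] for k in keys}

    @property
    def max_dp(self) -> int:
        return 2 + len(self.plus_affinities)


def select_k_int(series: KineticSeries) -> float:
    """Intrinsic rate constant: the maximum kcat across the DP series."""
    return max(series.kcat(dp) for dp in series.dps)


def affinity_from_ratio(ratio: float, context: ThermoContext) -> float:
    """RT ln(ratio) in kcal/mol for a dimensionless specificity ratio."""
    if ratio <= 0 or not math.isfinite(ratio):
        raise InvalidArgumentError(f"specificity ratio must be finite and > 0, got {ratio}")
    return context.rt * math.log(ratio)


def plus_subsite_affinity(series: KineticSeries, n: int, context: ThermoContext) -> float:
    """Affinity of subsite +n: RT ln[(kcat/KM)_{n+1} / (kcat/KM)_n].

    Only the ratio enters, so the unit the specificity constants are
    carried in cancels.
    """
    for dp in (n, n + 1):
        if dp not in series.fits:
            raise MissingDataError(f"{series.enzyme_label}: series lacks DP {dp}")
    return affinity_from_ratio(series.specificity(n + 1) / series.specificity(n), context)


def active_center_affinity(series: KineticSeries, k_int: float, context: ThermoContext) -> float:
    """Summed -1/+1 affinity: RT ln[(kcat/KM)_2 / (c_w k_int)].

    (kcat/KM)_2 is taken in 1/(M s) and c_w in L/mol, so the log argument
    is dimensionless up to the c_w convention.
    """
    if k_int <= 0:
        raise InvalidArgumentError(f"k_int must be > 0, got {k_int}")
    if 2 not in series.fits:
        raise MissingDataError(f"{series.enzyme_label}: series lacks DP 2")
    spec2 = series.specificity(2)
    if spec2 <= 0:
        raise InvalidArgumentError("specificity at DP 2 must be > 0")
    return context.rt * math.log(spec2 / (context.water_molarity_constant * k_int))


def build_profile(series: KineticSeries, context: ThermoContext | None = None) -> SubsiteProfile:
    """Assemble the full subsite profile of one enzyme.

    Requires a consecutive DP series starting at 2 (enforced by
    :class:`KineticSeries`); yields A_+n for every adjacent DP pair
    (DP 2-5 gives +2, +3, +4).
    """
    if context is None:
        context = ThermoContext()
    k_int = select_k_int(series)
    plus = {
        n: plus_subsite_affinity(series, n, context)
        for n in series.dps
        if n + 1 in series.fits
    }
    return SubsiteProfile(
        enzyme_label=series.enzyme_label,
        k_int=k_int,
        active_center_affinity=active_center_affinity(series, k_int, context),
        plus_affinities=plus,
        context=context,
    )


def reconstruct_specificity(profile: SubsiteProfile, n: int) -> float:
    """Invert the subsite map: (kcat/KM)_n in 1/(M s) from the profile.

    Telescoping of the ratio definition guarantees this reproduces every
    input specificity constant exactly (to floating-point round-off).
    """
    if n < 2 or n > profile.max_dp:
        raise InvalidArgumentError(
            f"n={n} outside profile DP range [2, {profile.max_dp}]"
        )
    ctx = profile.context
    total = profile.active_center_affinity + sum(
        profile.plus_affinities[i] for i in range(2, n)
    )
    return ctx.water_molarity_constant * profile.k_int * math.exp(total / ctx.rt)


def count_subsites(profile: SubsiteProfile, threshold: float = DEFAULT_SUBSITE_THRESHOLD) -> int:
    """Number of substrate-binding subsites.

    Subsites -1 and +1 always exist for an active exo-enzyme (count 2);
    plus-subsites are counted outward from +2 while contiguous and with
    affinity >= threshold, stopping at the first failure.
    """
    if threshold <= 0:
        raise InvalidArgumentError(f"threshold must be > 0, got {threshold}")
    count = 2
    for i in sorted(profile.plus_affinities):
        if profile.plus_affinities[i] >= threshold:
            count += 1
        else:
            break
    return count


def _truncated_normal(rng: np.random.Generator, mean: float, se: float, size: int) -> np.ndarray:
    if se == 0:
        return np.full(size, mean)
    a = (0.0 - mean) / se  # truncate at zero: parameters are positive
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=se, size=size, random_state=rng)


def affinity_uncertainty(
    series: KineticSeries,
    n: int,
    context: ThermoContext,
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Parametric-bootstrap SE (kcal/mol) of the subsite +n affinity.

    Resamples (kcat, KM) at DP n and n+1 from independent normal
    distributions truncated at zero, using the stored fit SEs, and
    returns the sample standard deviation of the recomputed affinity.
    Independence of the kcat and KM errors is assumed (their covariance
    is not available from a published table).
    """
    if n_boot < 100:
        raise InvalidArgumentError(f"n_boot must be >= 100, got {n_boot}")
    for dp in (n, n + 1):
        if dp not in series.fits:
            raise MissingDataError(f"{series.enzyme_label}: series lacks DP {dp}")
        fit = series.fits[dp]
        if not (math.isfinite(fit.kcat_se) and math.isfinite(fit.km_se)):
            raise MissingDataError(f"DP {dp} carries no standard errors")
    lo, hi = series.fits[n], series.fits[n + 1]
    if lo.kcat_se == lo.km_se == hi.kcat_se == hi.km_se == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    kcat_lo = _truncated_normal(rng, lo.kcat, lo.kcat_se, n_boot)
    km_lo = _truncated_normal(rng, lo.km, lo.km_se, n_boot)
    kcat_hi = _truncated_normal(rng, hi.kcat, hi.kcat_se, n_boot)
    km_hi = _truncated_normal(rng, hi.km, hi.km_se, n_boot)
    a = context.rt * np.log((kcat_hi / km_hi) / (kcat_lo / km_lo))
    return float(np.std(a, ddof=1))
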