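"""DP-dependence profiles and two-enzyme comparison report.

Quantifies how catalytic efficiency (kcat/KM) changes with substrate
degree of polymerization for each enzyme, and how the two enzymes differ:
per-DP efficiency ratios, kinetic-parameter ranges, the active-center
affinity difference (convention-free, since the c_w constant cancels in
the difference) and subsite counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import ConfigurationError, InvalidArgumentError, MissingDataError
from .kinetics import KineticSeries
from .subsites import DEFAULT_SUBSITE_THRESHOLD, SubsiteProfile, count_subsites

__all__ = [
    "SpecificityProfile",
    "ParameterRange",
    "ComparisonReport",
    "dp_specificity_profile",
    "efficiency_ratio",
    "parameter_range",
    "build_report",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


@dataclass
class SpecificityProfile:
    """Per-enzyme map DP -> (kcat/KM)_n / (kcat/KM)_2 (dimensionless)."""

    enzyme_label: str
    ratios: dict[int, float]

    def __post_init__(self) -> None:
        if self.ratios.get(2) != 1.0:
            raise InvalidArgumentError("ratio at DP 2 must be exactly 1")
        if any(r <= 0 for r in self.ratios.values()):
            raise InvalidArgumentError("all specificity ratios must be > 0")


class ParameterRange(NamedTuple):
    min: float
    max: float
    unit: str


def dp_specificity_profile(series: KineticSeries) -> SpecificityProfile:
    """Specificity constants normalized to the DP 2 (xylobiose) value."""
    if 2 not in series.fits:
        raise MissingDataError(f"{series.enzyme_label}: series lacks DP 2")
    spec2 = series.specificity(2)
    ratios = {dp: series.specificity(dp) / spec2 for dp in series.dps}
    ratios[2] = 1.0
    return SpecificityProfile(enzyme_label=series.enzyme_label, ratios=ratios)


def efficiency_ratio(series_a: KineticSeries, series_b: KineticSeries) -> dict[int, float]:
    """Per-DP (kcat/KM)_a / (kcat/KM)_b over the shared DP range."""
    shared = [dp for dp in series_a.dps if dp in series_b.fits]
    if not shared:
        raise MissingDataError("series share no DP")
    return {dp: series_a.specificity(dp) / series_b.specificity(dp) for dp in shared}


def parameter_range(series: KineticSeries, which: str) -> ParameterRange:
    """(min, max) of kcat (1/s) or KM (reported in mM) across the series."""
    if which == "kcat":
        values = [series.kcat(dp) for dp in series.dps]
        unit = "s^-1"
    elif which == "km":
        values = [series.km(dp) * 1e3 for dp in series.dps]  # M -> mM
        unit = "mM"
    else:
        raise InvalidArgumentError(f"which must be 'kcat' or 'km', got {which!r}")
    return ParameterRange(min(values), max(values), unit)


@dataclass
class ComparisonReport:
    """Machine-readable two-enzyme comparison (serializes to JSON)."""

    enzyme_labels: tuple[str, str]
    specificity_profiles: dict[str, SpecificityProfile]
    efficiency_ratios: dict[int, float]
    kcat_ranges: dict[str, ParameterRange]
    km_ranges: dict[str, ParameterRange]
    active_center_difference: float
    subsite_counts: dict[str, int]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.efficiency_ratios.values()):
            raise InvalidArgumentError("efficiency ratios must be > 0")
        for ranges in (self.kcat_ranges, self.km_ranges):
            for r in ranges.values():
                if r.min > r.max:
                    raise InvalidArgumentError("range min must be <= max")

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "enzyme_labels": list(self.enzyme_labels),
            "specificity_profiles": {
                label: {str(dp): r for dp, r in prof.ratios.items()}
                for label, prof in self.specificity_profiles.items()
            },
            "efficiency_ratios": {str(dp): r for dp, r in self.efficiency_ratios.items()},
            "kcat_ranges": {k: list(v) for k, v in self.kcat_ranges.items()},
            "km_ranges": {k: list(v) for k, v in self.km_ranges.items()},
            "active_center_difference_kcal_mol": self.active_center_difference,
            "subsite_counts": dict(self.subsite_counts),
            "provenance": dict(self.provenance),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "ComparisonReport":
        if data.get("schema_version") != SCHEMA_VERSION:
            raise ConfigurationError(
                f"unsupported report schema version {data.get('schema_version')!r}"
            )
        labels = tuple(data["enzyme_labels"])
        profiles = {
            label: SpecificityProfile(
                enzyme_label=label,
                ratios={int(dp): r for dp, r in prof.items()},
            )
            for label, prof in data["specificity_profiles"].items()
        }
        return cls(
            enzyme_labels=labels,  # type: ignore[arg-type]
            specificity_profiles=profiles,
            efficiency_ratios={int(dp): r for dp, r in data["efficiency_ratios"].items()},
            kcat_ranges={
                k: ParameterRange(v[0], v[1], v[2]) for k, v in data["kcat_ranges"].items()
            },
            km_ranges={
                k: ParameterRange(v[0], v[1], v[2]) for k, v in data["km_ranges"].items()
            },
            active_center_difference=data["active_center_difference_kcal_mol"],
            subsite_counts=dict(data["subsite_counts"]),
            provenance=dict(data.get("provenance", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        return cls.from_dict(json.loads(text))


def build_report(
    series_a: KineticSeries,
    series_b: KineticSeries,
    profile_a: SubsiteProfile,
    profile_b: SubsiteProfile,
    threshold: float = DEFAULT_SUBSITE_THRESHOLD,
) -> ComparisonReport:
    """Assemble the full comparison of enzyme a against enzyme b.

    ``active_center_difference`` is profile_a minus profile_b, in
    kcal/mol; both profiles must have been built with the same
    :class:`~bxlkinetics.subsites.ThermoContext`.
    """
    if profile_a.context != profile_b.context:
        raise ConfigurationError("subsite profiles were built with different ThermoContexts")
    la, lb = series_a.enzyme_label, series_b.enzyme_label
    ctx = profile_a.context
    return ComparisonReport(
        enzyme_labels=(la, lb),
        specificity_profiles={
            la: dp_specificity_profile(series_a),
            lb: dp_specificity_profile(series_b),
        },
        efficiency_ratios=efficiency_ratio(series_a, series_b),
        kcat_ranges={la: parameter_range(series_a, "kcat"), lb: parameter_range(series_b, "kcat")},
        km_ranges={la: parameter_range(series_a, "km"), lb: parameter_range(series_b, "km")},
        active_center_difference=(
            profile_a.active_center_affinity - profile_b.active_center_affinity
        ),
        subsite_counts={
            la: count_subsites(profile_a, threshold),
            lb: count_subsites(profile_b, threshold),
        },
        provenance={
            "gas_constant_kcal_mol_K": ctx.gas_constant,
            "temperature_K": ctx.temperature,
            "water_molarity_constant_L_mol": ctx.water_molarity_constant,
            "subsite_threshold_kcal_mol": threshold,
            "k_int_per_s": {la: profile_a.k_int, lb: profile_b.k_int},
        },
    )
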