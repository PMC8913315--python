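"""File formats: rate tables, fit tables, subsite profiles, fixtures.

All CSVs are comma-separated UTF-8 with a required header and "." as the
decimal mark. Concentrations and velocities in rate tables carry explicit
unit columns drawn from closed sets; everything is converted to internal
molar units (M, M/s) on read and back on write.
"""

from __future__ import annotations

import csv
import json
import math
from importlib import resources
from pathlib import Path

import pandas as pd

from .assay import AssayConfig
from .errors import ConfigurationError, ParseError, SchemaError
from .kinetics import KineticSeries, MMFit, RateDataset, RatePoint
from .subsites import SubsiteProfile

__all__ = [
    "CONC_UNITS",
    "VELOCITY_UNITS",
    "read_rate_csv",
    "write_rate_csv",
    "write_fit_csv",
    "read_fit_csv",
    "load_table2_fixture",
    "write_profile_csv",
    "profiles_to_json",
]

#: Multiplicative factors to M and M/s.
CONC_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6}
VELOCITY_UNITS = {"M/s": 1.0, "nM/s": 1e-9, "uM/min": 1e-6 / 60.0}

RATE_COLUMNS = [
    "enzyme_label",
    "dp",
    "substrate_conc",
    "conc_unit",
    "velocity",
    "velocity_unit",
    "replicate",
]

FIT_COLUMNS = [
    "enzyme_label",
    "dp",
    "kcat_per_s",
    "kcat_se",
    "km_mM",
    "km_se",
    "spec_mM_s",
    "spec_se",
]

TABLE2_FIXTURE = "table2_kinetics.csv"


def _require_columns(fieldnames, required, path) -> None:
    missing = set(required) - set(fieldnames or [])
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")


def read_rate_csv(
    path: str | Path,
    assay_configs: dict[str, AssayConfig] | None = None,
) -> list[RateDataset]:
    """Read a rate table, grouped by (enzyme_label, dp) preserving row order.

    ``assay_configs`` maps enzyme label to the assay conditions (above all
    [E]0, without which kcat cannot be derived later); labels absent from
    the map get datasets with ``config=None``.
    """
    path = Path(path)
    groups: dict[tuple[str, int], list[RatePoint]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _require_columns(reader.fieldnames, RATE_COLUMNS, path)
        for i, row in enumerate(reader, start=2):  # header is row 1
            try:
                label = row["enzyme_label"]
                dp = int(row["dp"])
                conc_unit = row["conc_unit"]
                vel_unit = row["velocity_unit"]
                if conc_unit not in CONC_UNITS:
                    raise ParseError(f"{path} row {i}: unknown concentration unit {conc_unit!r}")
                if vel_unit not in VELOCITY_UNITS:
                    raise ParseError(f"{path} row {i}: unknown velocity unit {vel_unit!r}")
                conc = float(row["substrate_conc"]) * CONC_UNITS[conc_unit]
                vel = float(row["velocity"]) * VELOCITY_UNITS[vel_unit]
                if not (math.isfinite(conc) and math.isfinite(vel)):
                    raise ParseError(f"{path} row {i}: non-finite value")
                point = RatePoint(
                    substrate_conc=conc, velocity=vel, replicate=int(row["replicate"])
                )
            except ParseError:
                raise
            except (KeyError, TypeError, ValueError) as exc:
                raise ParseError(f"{path} row {i}: {exc}") from exc
            groups.setdefault((label, dp), []).append(point)

    datasets = []
    for (label, dp), points in groups.items():
        config = None
        if assay_configs and label in assay_configs:
            base = assay_configs[label]
            config = AssayConfig(
                enzyme_conc=base.enzyme_conc,
                temperature=base.temperature,
                reaction_time=base.reaction_time,
                substrate_dp=dp,
            )
        datasets.append(RateDataset(enzyme_label=label, dp=dp, config=config, points=points))
    return datasets


def write_rate_csv(
    datasets: list[RateDataset],
    path: str | Path,
    conc_unit: str = "M",
    velocity_unit: str = "M/s",
) -> None:
    """Write rate datasets to the standard rate table.

    The default units are the internal ones (M, M/s), for which the
    write/read round trip is bit-exact; pick mM or nM/s for tables meant
    to be eyeballed.
    """
    if conc_unit not in CONC_UNITS or velocity_unit not in VELOCITY_UNITS:
        raise ParseError(f"unknown unit {conc_unit!r}/{velocity_unit!r}")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RATE_COLUMNS)
        for ds in datasets:
            for p in ds.points:
                writer.writerow(
                    [
                        ds.enzyme_label,
                        ds.dp,
                        repr(p.substrate_conc / CONC_UNITS[conc_unit]),
                        conc_unit,
                        repr(p.velocity / VELOCITY_UNITS[velocity_unit]),
                        velocity_unit,
                        p.replicate,
                    ]
                )


def write_fit_csv(series_map: dict[str, KineticSeries], path: str | Path) -> None:
    """Write fitted parameters as a fit table (KM reported in mM)."""
    rows = []
    for label, series in series_map.items():
        for dp in series.dps:
            fit = series.fits[dp]
            rows.append(
                {
                    "enzyme_label": label,
                    "dp": dp,
                    "kcat_per_s": repr(fit.kcat),
                    "kcat_se": repr(fit.kcat_se),
                    "km_mM": repr(fit.km * 1e3),
                    "km_se": repr(fit.km_se * 1e3),
                    "spec_mM_s": repr(fit.reported_specificity / 1e3),
                    "spec_se": repr(
                        fit.specificity_printed_se / 1e3
                        if fit.specificity_printed_se is not None
                        else fit.specificity_se / 1e3
                    ),
                }
            )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=FIT_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)


def _series_from_fit_frame(df: pd.DataFrame, source: str) -> dict[str, KineticSeries]:
    missing = set(FIT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{source}: missing required columns {sorted(missing)}")
    out: dict[str, KineticSeries] = {}
    for label, sub in df.groupby("enzyme_label", sort=False):
        fits = {}
        for _, row in sub.iterrows():
            spec_printed = float(row["spec_mM_s"]) * 1e3  # mM^-1 s^-1 -> M^-1 s^-1
            spec_se = float(row["spec_se"]) * 1e3
            fits[int(row["dp"])] = MMFit(
                kcat=float(row["kcat_per_s"]),
                km=float(row["km_mM"]) * 1e-3,
                kcat_se=float(row["kcat_se"]),
                km_se=float(row["km_se"]) * 1e-3,
                specificity_printed=spec_printed,
                specificity_printed_se=spec_se if math.isfinite(spec_se) else None,
            )
        out[str(label)] = KineticSeries(enzyme_label=str(label), fits=fits)
    return out


def read_fit_csv(path: str | Path) -> dict[str, KineticSeries]:
    """Read a fit table back into per-enzyme kinetic series.

    The ``spec_mM_s`` column is retained as the reported specificity
    constant, so a table holding published (rounded) values drives all
    downstream ratio analyses with exactly the printed numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _series_from_fit_frame(df, str(path))


def load_table2_fixture() -> dict[str, KineticSeries]:
    """Packaged reference kinetic parameters for PcBxl3 and TrXyl3A, DP 2-5."""
    ref = resources.files("bxlkinetics").joinpath("fixtures", TABLE2_FIXTURE)
    with resources.as_file(ref) as fspath:
        df = pd.read_csv(fspath)
    return _series_from_fit_frame(df, TABLE2_FIXTURE)


def write_profile_csv(profiles: dict[str, SubsiteProfile], path: str | Path,
                      uncertainties: dict[str, dict[int, float]] | None = None) -> None:
    """Write subsite profiles: one row per enzyme/subsite.

    The active center appears as subsite ``-1/+1`` (a summed quantity);
    plus-subsites as ``+2``, ``+3``, ... ``uncertainties`` optionally maps
    enzyme label -> subsite index -> bootstrap SE.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["enzyme_label", "subsite", "affinity_kcal_mol", "se"])
        for label, profile in profiles.items():
            writer.writerow([label, "-1/+1", repr(profile.active_center_affinity), ""])
            for idx in sorted(profile.plus_affinities):
                se = (uncertainties or {}).get(label, {}).get(idx)
                writer.writerow(
                    [
                        label,
                        f"+{idx}",
                        repr(profile.plus_affinities[idx]),
                        "" if se is None else repr(se),
                    ]
                )


def profiles_to_json(profiles: dict[str, SubsiteProfile]) -> str:
    """JSON record of subsite profiles including the convention constants."""
    payload = {}
    for label, p in profiles.items():
        payload[label] = {
            "k_int_per_s": p.k_int,
            "active_center_affinity_kcal_mol": p.active_center_affinity,
            "active_center_convention_dependent": True,
            "plus_affinities_kcal_mol": {f"+{i}": a for i, a in p.plus_affinities.items()},
            "context": {
                "temperature_K": p.context.temperature,
                "gas_constant_kcal_mol_K": p.context.gas_constant,
                "water_molarity_constant_L_mol": p.context.water_molarity_constant,
            },
        }
    return json.dumps(payload, indent=2, sort_keys=True)


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    import yaml

    text = Path(path).read_text(encoding="utf-8")
    try:
        data = yaml.safe_load(text)  # JSON is a YAML subset: either accepted
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse config ({exc})") from exc
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data
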