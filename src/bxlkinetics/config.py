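"""Pipeline configuration: validated, unknown keys rejected."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .assay import (
    DEFAULT_ENZYME_CONC_M,
    DEFAULT_REACTION_TIME_S,
    DEFAULT_TEMPERATURE_K,
    AssayConfig,
)
from .errors import ConfigurationError
from .io import CONC_UNITS
from .subsites import (
    DEFAULT_SUBSITE_THRESHOLD,
    GAS_CONSTANT_KCAL,
    WATER_MOLARITY_CONSTANT,
    ThermoContext,
)
from .synthetic import (
    DEFAULT_GRID_MAX_M,
    DEFAULT_GRID_MIN_M,
    DEFAULT_GRID_POINTS,
    DEFAULT_NOISE_CV,
    DEFAULT_REPLICATES,
    NoiseModel,
)

__all__ = ["PipelineConfig", "default_config"]


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in {section}: {sorted(unknown)}")


@dataclass
class PipelineConfig:
    """Everything the pipeline driver needs, with assay defaults.

    ``enzymes`` maps label -> enzyme concentration in M. Temperature and
    reaction time are shared by all assays. The noise block only matters
    in simulation mode.
    """

    enzymes: dict[str, float] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE_K
    reaction_time: float = DEFAULT_REACTION_TIME_S
    weighting: str = "none"
    init: str = "hanes"
    gas_constant: float = GAS_CONSTANT_KCAL
    water_molarity_constant: float = WATER_MOLARITY_CONSTANT
    subsite_threshold: float = DEFAULT_SUBSITE_THRESHOLD
    noise_kind: str = "multiplicative"
    noise_scale: float = DEFAULT_NOISE_CV
    replicates: int = DEFAULT_REPLICATES
    grid_min: float = DEFAULT_GRID_MIN_M
    grid_max: float = DEFAULT_GRID_MAX_M
    grid_points: int = DEFAULT_GRID_POINTS
    grid_spacing: str = "log"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.enzymes:
            raise ConfigurationError("config must name at least one enzyme concentration")
        for label, conc in self.enzymes.items():
            if not isinstance(conc, (int, float)) or conc <= 0:
                raise ConfigurationError(
                    f"enzyme concentration for {label!r} must be > 0, got {conc!r}"
                )

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested config mapping (YAML/JSON layout).

        Layout::

            enzymes:
              PcBxl3: {conc: 30.2, unit: nM}
            temperature_K: 303.15
            reaction_time_s: 1800
            fitting: {weighting: none, init: hanes}
            thermo: {gas_constant: 1.9872e-3, c_w: 0.018}
            subsite_threshold: 0.4
            noise: {kind: multiplicative, scale: 0.03}
            replicates: 3
            grid: {min_M: 5.0e-5, max_M: 5.0e-3, n: 8, spacing: log}
            seed: 0
        """
        _check_keys(
            "config",
            data,
            {
                "enzymes",
                "temperature_K",
                "reaction_time_s",
                "fitting",
                "thermo",
                "subsite_threshold",
                "noise",
                "replicates",
                "grid",
                "seed",
            },
        )
        if "enzymes" not in data or not isinstance(data["enzymes"], dict) or not data["enzymes"]:
            raise ConfigurationError("config must contain a non-empty 'enzymes' mapping")
        enzymes: dict[str, float] = {}
        for label, spec in data["enzymes"].items():
            if not isinstance(spec, dict):
                raise ConfigurationError(f"enzymes.{label} must be a mapping with conc/unit")
            _check_keys(f"enzymes.{label}", spec, {"conc", "unit"})
            if "conc" not in spec:
                raise ConfigurationError(f"enzymes.{label} is missing 'conc'")
            unit = spec.get("unit", "M")
            factor = {"nM": 1e-9, **CONC_UNITS}.get(unit)
            if factor is None:
                raise ConfigurationError(f"enzymes.{label}: unknown unit {unit!r}")
            enzymes[label] = float(spec["conc"]) * factor

        fitting = data.get("fitting", {})
        _check_keys("fitting", fitting, {"weighting", "init"})
        thermo = data.get("thermo", {})
        _check_keys("thermo", thermo, {"gas_constant", "c_w", "temperature_K"})
        noise = data.get("noise", {})
        _check_keys("noise", noise, {"kind", "scale", "seed"})
        grid = data.get("grid", {})
        _check_keys("grid", grid, {"min_M", "max_M", "n", "spacing"})

        temperature = float(data.get("temperature_K", DEFAULT_TEMPERATURE_K))
        return cls(
            enzymes=enzymes,
            temperature=float(thermo.get("temperature_K", temperature)),
            reaction_time=float(data.get("reaction_time_s", DEFAULT_REACTION_TIME_S)),
            weighting=fitting.get("weighting", "none"),
            init=fitting.get("init", "hanes"),
            gas_constant=float(thermo.get("gas_constant", GAS_CONSTANT_KCAL)),
            water_molarity_constant=float(thermo.get("c_w", WATER_MOLARITY_CONSTANT)),
            subsite_threshold=float(data.get("subsite_threshold", DEFAULT_SUBSITE_THRESHOLD)),
            noise_kind=noise.get("kind", "multiplicative"),
            noise_scale=float(noise.get("scale", DEFAULT_NOISE_CV)),
            replicates=int(data.get("replicates", DEFAULT_REPLICATES)),
            grid_min=float(grid.get("min_M", DEFAULT_GRID_MIN_M)),
            grid_max=float(grid.get("max_M", DEFAULT_GRID_MAX_M)),
            grid_points=int(grid.get("n", DEFAULT_GRID_POINTS)),
            grid_spacing=grid.get("spacing", "log"),
            seed=int(noise.get("seed", data.get("seed", 0))),
        )

    def assay_config(self, label: str, dp: int) -> AssayConfig:
        if label not in self.enzymes:
            raise ConfigurationError(f"no enzyme concentration configured for {label!r}")
        return AssayConfig(
            enzyme_conc=self.enzymes[label],
            temperature=self.temperature,
            reaction_time=self.reaction_time,
            substrate_dp=dp,
        )

    def thermo_context(self) -> ThermoContext:
        return ThermoContext(
            temperature=self.temperature,
            gas_constant=self.gas_constant,
            water_molarity_constant=self.water_molarity_constant,
        )

    def noise_model(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            kind=self.noise_kind,
            scale=self.noise_scale,
            seed=self.seed if seed is None else seed,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def default_config() -> PipelineConfig:
    """Reference-assay defaults: both enzymes at their published [E]0."""
    return PipelineConfig(enzymes=dict(DEFAULT_ENZYME_CONC_M))
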