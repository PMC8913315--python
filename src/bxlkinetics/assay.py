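"""Assay metadata shared by the simulator and the fitting layer.

All quantities are carried internally in SI-flavoured molar units:
concentrations in M, time in seconds, temperature in kelvin. The I/O
layer (:mod:`bxlkinetics.io`) converts to and from reporting units.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidArgumentError

CELSIUS_OFFSET = 273.15

#: Assay temperature used throughout: 30 degrees C.
DEFAULT_TEMPERATURE_K = 30.0 + CELSIUS_OFFSET

#: Endpoint incubation time: 30 min.
DEFAULT_REACTION_TIME_S = 30.0 * 60.0

#: Final enzyme concentrations in the reference assay (M).
DEFAULT_ENZYME_CONC_M = {
    "PcBxl3": 30.2e-9,
    "TrXyl3A": 26.6e-9,
}


@dataclass(frozen=True)
class AssayConfig:
    """Conditions of one endpoint initial-rate assay.

    Parameters
    ----------
    enzyme_conc
        Total enzyme concentration [E]0 in M (active-site titre assumed
        100%).
    temperature
        Assay temperature in K.
    reaction_time
        Endpoint incubation time in s over which released product is
        accumulated.
    substrate_dp
        Degree of polymerization of the xylooligosaccharide substrate
        (2 = xylobiose ... 5 = xylopentaose).
    """

    enzyme_conc: float
    temperature: float = DEFAULT_TEMPERATURE_K
    reaction_time: float = DEFAULT_REACTION_TIME_S
    substrate_dp: int = 2

    def __post_init__(self) -> None:
        if self.enzyme_conc <= 0:
            raise InvalidArgumentError(f"enzyme_conc must be > 0, got {self.enzyme_conc}")
        if self.temperature <= 0:
            raise InvalidArgumentError(f"temperature must be > 0 K, got {self.temperature}")
        if self.reaction_time <= 0:
            raise InvalidArgumentError(f"reaction_time must be > 0 s, got {self.reaction_time}")
        if self.substrate_dp < 2:
            raise InvalidArgumentError(f"substrate_dp must be >= 2, got {self.substrate_dp}")
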