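"""Synthetic initial-rate assay generator.

Emulates an endpoint beta-xylosidase assay: Michaelis-Menten true
velocities on a substrate grid spanning 50 uM - 5 mM, product accumulated
over a fixed incubation (30 min) and converted back to a rate, with
multiplicative measurement noise on the quantified product. The generator
exists so that the fitting, subsite and comparison stages can be exercised
end to end without instrument data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .assay import AssayConfig
from .errors import InvalidArgumentError, SubstrateDepletionWarning
from .kinetics import RateDataset, RatePoint, mm_velocity

__all__ = [
    "TrueParameters",
    "NoiseModel",
    "make_concentration_grid",
    "simulate_rates",
    "endpoint_to_rate",
    "initial_rate_fraction",
    "DEFAULT_GRID_MIN_M",
    "DEFAULT_GRID_MAX_M",
    "DEFAULT_GRID_POINTS",
    "DEFAULT_NOISE_CV",
    "DEFAULT_REPLICATES",
]

#: Substrate grid bounds of the reference assay (M): 50 uM - 5 mM.
DEFAULT_GRID_MIN_M = 5e-5
DEFAULT_GRID_MAX_M = 5e-3
DEFAULT_GRID_POINTS = 8
#: Default multiplicative noise, typical HPLC quantification repeatability.
DEFAULT_NOISE_CV = 0.03
DEFAULT_REPLICATES = 3

#: Above this estimated consumed-substrate fraction the endpoint rate is
#: flagged as a questionable initial-rate estimate.
DEPLETION_WARN_FRACTION = 0.10


@dataclass(frozen=True)
class TrueParameters:
    """Generating Michaelis-Menten parameters: kcat in 1/s, km in M."""

    kcat: float
    km: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise InvalidArgumentError(f"kcat must be > 0, got {self.kcat}")
        if self.km <= 0:
            raise InvalidArgumentError(f"km must be > 0, got {self.km}")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise specification.

    ``multiplicative``: v -> v * (1 + eps), eps ~ N(0, scale); ``scale``
    is a dimensionless CV. ``additive``: v -> v + eps with scale in M/s.
    ``none`` ignores scale and seed. Negative noisy velocities are clipped
    to zero.
    """

    kind: str = "multiplicative"
    scale: float = DEFAULT_NOISE_CV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative", "additive", "none"):
            raise InvalidArgumentError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise InvalidArgumentError(f"noise scale must be >= 0, got {self.scale}")


def make_concentration_grid(
    min_conc: float = DEFAULT_GRID_MIN_M,
    max_conc: float = DEFAULT_GRID_MAX_M,
    n_points: int = DEFAULT_GRID_POINTS,
    spacing: str = "log",
) -> np.ndarray:
    """Ordered substrate concentration grid (M), endpoints exact.

    ``spacing="log"`` gives geometric spacing, the natural choice for a
    two-decade Michaelis-Menten design; ``"linear"`` is uniform.
    """
    if min_conc <= 0 or max_conc <= 0:
        raise InvalidArgumentError("concentrations must be > 0")
    if min_conc > max_conc:
        raise InvalidArgumentError("min_conc must be <= max_conc")
    if n_points < 1:
        raise InvalidArgumentError(f"n_points must be >= 1, got {n_points}")
    if n_points == 1:
        if min_conc != max_conc:
            raise InvalidArgumentError("a single-point grid requires min_conc == max_conc")
        return np.array([min_conc], dtype=float)
    if min_conc == max_conc:
        raise InvalidArgumentError("a strictly increasing grid requires min_conc < max_conc")
    if spacing == "linear":
        grid = np.linspace(min_conc, max_conc, n_points)
    elif spacing == "log":
        grid = np.geomspace(min_conc, max_conc, n_points)
    else:
        raise InvalidArgumentError(f"unknown spacing {spacing!r}")
    grid[0], grid[-1] = min_conc, max_conc
    return grid


def endpoint_to_rate(product_conc: float, reaction_time: float) -> float:
    """Convert accumulated product (M) over a fixed time (s) to M/s."""
    if reaction_time <= 0:
        raise InvalidArgumentError(f"reaction_time must be > 0, got {reaction_time}")
    if np.any(np.asarray(product_conc) < 0):
        raise InvalidArgumentError("product_conc must be >= 0")
    out = np.asarray(product_conc, dtype=float) / reaction_time
    return float(out) if out.ndim == 0 else out


def simulate_rates(
    params: TrueParameters,
    config: AssayConfig,
    grid: np.ndarray | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise: NoiseModel = NoiseModel(),
) -> RateDataset:
    """Simulate one enzyme/DP endpoint assay.

    Noise-free velocities follow kcat*[E]0*[S]/(KM+[S]); noise perturbs
    the quantified endpoint product, which is then divided by the
    incubation time, so the recorded rates inherit the noise unchanged.
    Identical (params, config, grid, replicates, noise) always produce an
    identical dataset.
    """
    if replicates < 1:
        raise InvalidArgumentError(f"replicates must be >= 1, got {replicates}")
    if grid is None:
        grid = make_concentration_grid()
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(noise.seed)
    v_true = mm_velocity(params.kcat, config.enzyme_conc, params.km, grid)

    points: list[RatePoint] = []
    for rep in range(replicates):
        if noise.kind == "multiplicative":
            v_noisy = v_true * (1.0 + rng.normal(0.0, noise.scale, size=grid.shape))
        elif noise.kind == "additive":
            v_noisy = v_true + rng.normal(0.0, noise.scale, size=grid.shape)
        else:
            v_noisy = v_true.copy()
        v_noisy = np.clip(v_noisy, 0.0, None)
        product = v_noisy * config.reaction_time
        v_meas = endpoint_to_rate(product, config.reaction_time)
        for s, v in zip(grid, np.atleast_1d(v_meas)):
            points.append(RatePoint(substrate_conc=float(s), velocity=float(v), replicate=rep))
    return RateDataset(
        enzyme_label=params.label,
        dp=config.substrate_dp,
        config=config,
        points=points,
    )


def initial_rate_fraction(params: TrueParameters, config: AssayConfig, s0: float) -> float:
    """Linear upper bound on the substrate fraction consumed at endpoint.

    Uses the t=0 Michaelis-Menten velocity held constant over the
    incubation: fraction = min(1, v0*t/s0). Emits a
    :class:`SubstrateDepletionWarning` when the fraction exceeds 10%,
    the usual validity ceiling for an initial-rate endpoint assay.
    """
    if s0 <= 0:
        raise InvalidArgumentError(f"s0 must be > 0, got {s0}")
    v0 = mm_velocity(params.kcat, config.enzyme_conc, params.km, s0)
    fraction = min(1.0, v0 * config.reaction_time / s0)
    if fraction > DEPLETION_WARN_FRACTION:
        warnings.warn(
            f"estimated {fraction:.1%} of substrate consumed at [S]0={s0:g} M; "
            "endpoint rate may not be a valid initial rate",
            SubstrateDepletionWarning,
            stacklevel=2,
        )
    return fraction
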