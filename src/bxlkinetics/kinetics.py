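"""Michaelis-Menten model evaluation and nonlinear least-squares fitting.

The velocity law for an exo-glycosidase acting on a single substrate is

    v = kcat * [E]0 * [S] / (KM + [S])

with v in M/s, [E]0 and [S] in M, kcat in 1/s and KM in M. Fitting is
performed on the direct velocity scale (Vmax, KM) with optional relative
(1/v^2) weighting; kcat is recovered as Vmax/[E]0. Standard errors come
from the Gauss-Newton covariance s^2 (J^T J)^-1 at the optimum, and the
specificity constant kcat/KM carries a first-order delta-method error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import least_squares

from .assay import AssayConfig
from .errors import InsufficientDataError, InvalidArgumentError

__all__ = [
    "RatePoint",
    "RateDataset",
    "MMFit",
    "KineticSeries",
    "mm_velocity",
    "fit_mm",
    "specificity_constant",
    "round_report",
]


@dataclass(frozen=True)
class RatePoint:
    """One (substrate concentration, velocity) observation.

    ``substrate_conc`` in M, ``velocity`` in M/s. Replicates at the same
    concentration are independent observations.
    """

    substrate_conc: float
    velocity: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.substrate_conc <= 0:
            raise InvalidArgumentError(
                f"substrate_conc must be > 0, got {self.substrate_conc}"
            )
        if self.velocity < 0 or not math.isfinite(self.velocity):
            raise InvalidArgumentError(f"velocity must be finite and >= 0, got {self.velocity}")


@dataclass
class RateDataset:
    """All rate observations for one (enzyme, substrate DP) assay."""

    enzyme_label: str
    dp: int
    config: AssayConfig | None
    points: list[RatePoint]

    def __post_init__(self) -> None:
        if not self.points:
            raise InvalidArgumentError("RateDataset needs at least one point")

    @property
    def substrate_concs(self) -> np.ndarray:
        return np.array([p.substrate_conc for p in self.points], dtype=float)

    @property
    def velocities(self) -> np.ndarray:
        return np.array([p.velocity for p in self.points], dtype=float)


def mm_velocity(kcat: float, enzyme_conc: float, km: float, s) -> float | np.ndarray:
    """Michaelis-Menten velocity kcat*[E]0*[S]/(KM+[S]) in M/s.

    ``s`` may be a scalar or an array of substrate concentrations (M).
    """
    if km <= 0:
        raise InvalidArgumentError(f"km must be > 0, got {km}")
    if kcat < 0 or enzyme_conc < 0:
        raise InvalidArgumentError("kcat and enzyme_conc must be >= 0")
    s = np.asarray(s, dtype=float)
    if np.any(s < 0):
        raise InvalidArgumentError("substrate concentration must be >= 0")
    v = kcat * enzyme_conc * s / (km + s)
    return float(v) if v.ndim == 0 else v


def _delta_specificity(kcat: float, kcat_se: float, km: float, km_se: float) -> tuple[float, float]:
    value = kcat / km
    if (
        kcat_se is None
        or km_se is None
        or not (math.isfinite(kcat_se) and math.isfinite(km_se))
    ):
        return value, float("nan")
    se = value * math.sqrt((kcat_se / kcat) ** 2 + (km_se / km) ** 2)
    return value, se


@dataclass
class MMFit:
    """Fitted Michaelis-Menten parameters for one enzyme/DP pair.

    ``kcat`` in 1/s, ``km`` in M, ``specificity`` (= kcat/KM) in 1/(M s).
    ``specificity`` is always the full-precision ratio of the stored kcat
    and KM. When the fit was loaded from a published table,
    ``specificity_printed`` additionally carries the table's own (rounded)
    kcat/KM value, which downstream ratio analyses prefer so that results
    are traceable to the printed numbers.
    """

    kcat: float
    km: float
    kcat_se: float = float("nan")
    km_se: float = float("nan")
    specificity: float = field(default=None)  # type: ignore[assignment]
    specificity_se: float = field(default=None)  # type: ignore[assignment]
    rss: float = 0.0
    n_points: int = 0
    converged: bool = True
    specificity_printed: float | None = None
    specificity_printed_se: float | None = None

    def __post_init__(self) -> None:
        if self.kcat <= 0:
            raise InvalidArgumentError(f"kcat must be > 0, got {self.kcat}")
        if self.km <= 0:
            raise InvalidArgumentError(f"km must be > 0, got {self.km}")
        value, se = _delta_specificity(self.kcat, self.kcat_se, self.km, self.km_se)
        if self.specificity is None:
            self.specificity = value
        elif abs(self.specificity - value) > 1e-12 * value:
            raise InvalidArgumentError(
                "specificity must equal kcat/km; use specificity_printed for "
                "rounded published values"
            )
        if self.specificity_se is None:
            self.specificity_se = se

    @property
    def reported_specificity(self) -> float:
        """Specificity constant in 1/(M s), preferring the printed value."""
        if self.specificity_printed is not None:
            return self.specificity_printed
        return self.specificity


@dataclass
class KineticSeries:
    """Per-enzyme map DP -> MMFit over a consecutive DP range starting at 2."""

    enzyme_label: str
    fits: Mapping[int, MMFit]

    def __post_init__(self) -> None:
        dps = sorted(self.fits)
        if not dps:
            raise InvalidArgumentError("KineticSeries needs at least one fit")
        if dps != list(range(2, 2 + len(dps))):
            raise InvalidArgumentError(
                f"DPs must be consecutive integers starting at 2, got {dps}"
            )
        self.fits = {dp: self.fits[dp] for dp in dps}

    @property
    def dps(self) -> list[int]:
        return list(self.fits)

    def specificity(self, dp: int, prefer_printed: bool = True) -> float:
        """kcat/KM at the given DP in 1/(M s)."""
        fit = self.fits[dp]
        return fit.reported_specificity if prefer_printed else fit.specificity

    def kcat(self, dp: int) -> float:
        return self.fits[dp].kcat

    def km(self, dp: int) -> float:
        return self.fits[dp].km


def _hanes_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # Hanes-Woolf: s/v = s/Vmax + KM/Vmax, linear in s.
    mask = v > 0
    if int(mask.sum()) >= 2:
        slope, intercept = np.polyfit(s[mask], s[mask] / v[mask], 1)
        if slope > 0 and intercept > 0:
            return 1.0 / slope, intercept / slope
    # degenerate linearization: crude but safe starting point
    return float(np.max(v)), float(np.median(s))


def fit_mm(
    dataset: RateDataset,
    weighting: str = "none",
    init: str = "hanes",
    init_params: tuple[float, float] | None = None,
) -> MMFit:
    """Fit (kcat, KM) to one rate dataset by nonlinear least squares.

    Parameters
    ----------
    dataset
        Observations plus the assay config carrying [E]0.
    weighting
        ``"none"`` for unweighted residuals on the velocity scale,
        ``"relative"`` for 1/v^2 weighting (constant relative error).
    init
        ``"hanes"`` (Hanes-Woolf linearization, with a max-v/median-S
        fallback when degenerate) or ``"explicit"`` with ``init_params``
        = (Vmax0, KM0) on the velocity scale.

    Raises
    ------
    InsufficientDataError
        Fewer than three distinct substrate concentrations.
    """
    if weighting not in ("none", "relative"):
        raise InvalidArgumentError(f"unknown weighting {weighting!r}")
    if dataset.config is None:
        raise InvalidArgumentError("dataset has no assay config (enzyme_conc unknown)")
    s = dataset.substrate_concs
    v = dataset.velocities
    if len(np.unique(s)) < 3:
        raise InsufficientDataError(
            f"need >= 3 distinct substrate concentrations, got {len(np.unique(s))}"
        )
    e0 = dataset.config.enzyme_conc

    if init == "explicit":
        if init_params is None:
            raise InvalidArgumentError("init='explicit' requires init_params")
        x0 = np.array(init_params, dtype=float)
    elif init == "hanes":
        x0 = np.array(_hanes_init(s, v), dtype=float)
    else:
        raise InvalidArgumentError(f"unknown init {init!r}")
    tiny = 1e-30
    x0 = np.clip(x0, tiny, None)

    if float(np.max(v)) <= 0:
        raise InsufficientDataError("all velocities are zero; parameters unidentifiable")
    if weighting == "relative":
        w = 1.0 / np.maximum(v, 1e-9 * float(np.max(v)))
    else:
        w = np.ones_like(v)
    # normalize residuals to O(1): velocities are ~1e-8 M/s and absolute
    # ftol/gtol thresholds would otherwise fire immediately
    norm = float(np.max(np.abs(v * w)))

    def resid(p: np.ndarray) -> np.ndarray:
        return (p[0] * s / (p[1] + s) - v) * w / norm

    res = least_squares(
        resid,
        x0,
        bounds=(np.array([tiny, tiny]), np.array([np.inf, np.inf])),
        method="trf",
        x_scale=x0,
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
        max_nfev=2000,
    )
    vmax, km = float(res.x[0]), float(res.x[1])
    converged = bool(res.success)

    n = len(v)
    dof = n - 2
    if converged and dof > 0:
        jtj = res.jac.T @ res.jac
        s2 = 2.0 * res.cost / dof
        try:
            cov = s2 * np.linalg.pinv(jtj)
            vmax_se = math.sqrt(max(cov[0, 0], 0.0))
            km_se = math.sqrt(max(cov[1, 1], 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
            vmax_se = km_se = float("nan")
    else:
        vmax_se = km_se = float("nan")

    model = vmax * s / (km + s)
    rss = float(np.sum((model - v) ** 2))
    return MMFit(
        kcat=vmax / e0,
        km=km,
        kcat_se=vmax_se / e0,
        km_se=km_se,
        rss=rss,
        n_points=n,
        converged=converged,
    )


def specificity_constant(fit: MMFit) -> tuple[float, float]:
    """(kcat/KM, SE) in 1/(M s); SE by the first-order delta method."""
    if fit.km <= 0:
        raise InvalidArgumentError("km must be > 0")
    return _delta_specificity(fit.kcat, fit.kcat_se, fit.km, fit.km_se)


def round_report(value: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures, ties to even."""
    if sig_figs < 1:
        raise InvalidArgumentError(f"sig_figs must be >= 1, got {sig_figs}")
    if value == 0 or not math.isfinite(value):
        return float(value)
    d = Decimal(repr(float(value)))
    exp = d.adjusted()
    mantissa = d.scaleb(-exp).quantize(
        Decimal(1).scaleb(1 - sig_figs), rounding=ROUND_HALF_EVEN
    )
    return float(mantissa.scaleb(exp))
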