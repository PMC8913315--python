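"""Michaelis-Menten fitting: exact recovery, scale invariance, errors."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bxlkinetics import (
    AssayConfig,
    InsufficientDataError,
    InvalidArgumentError,
    KineticSeries,
    MMFit,
    NoiseModel,
    RateDataset,
    RatePoint,
    TrueParameters,
    fit_mm,
    make_concentration_grid,
    mm_velocity,
    round_report,
    simulate_rates,
    specificity_constant,
)


class TestMMVelocity:
    def test_zero_substrate_gives_zero(self):
        assert mm_velocity(1.0, 1e-8, 1e-4, 0.0) == 0.0

    def test_half_vmax_at_km(self):
        assert mm_velocity(2.0, 1e-8, 1e-4, 1e-4) == pytest.approx(1e-8, rel=1e-12)

    def test_reference_value(self):
        assert mm_velocity(1.81, 30.2e-9, 0.90e-3, 5e-3) == pytest.approx(4.632e-8, rel=1e-3)

    def test_nonpositive_km_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mm_velocity(1.0, 1e-8, 0.0, 1e-4)


def _noiseless_dataset(kcat, km, e0=30e-9, n=8):
    config = AssayConfig(enzyme_conc=e0, substrate_dp=2)
    grid = make_concentration_grid(5e-5, 5e-3, n)
    points = [
        RatePoint(substrate_conc=float(s), velocity=float(mm_velocity(kcat, e0, km, s)))
        for s in grid
    ]
    return RateDataset(enzyme_label="X", dp=2, config=config, points=points)


class TestFitMM:
    @given(
        kcat=st.floats(min_value=0.1, max_value=10.0),
        km=st.floats(min_value=1e-5, max_value=1e-2),
    )
    def test_noiseless_exact_recovery(self, kcat, km):
        fit = fit_mm(_noiseless_dataset(kcat, km))
        assert fit.converged
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.km == pytest.approx(km, rel=1e-6)

    def test_two_distinct_concentrations_insufficient(self):
        config = AssayConfig(enzyme_conc=30e-9)
        points = [
            RatePoint(1e-4, 1e-9, 0),
            RatePoint(1e-4, 1.1e-9, 1),
            RatePoint(1e-3, 5e-9, 0),
        ]
        with pytest.raises(InsufficientDataError):
            fit_mm(RateDataset("X", 2, config, points))

    def test_scale_invariance_of_kcat_and_km(self):
        # multiplying all velocities and [E]0 by c leaves (kcat, KM) fixed
        base = _noiseless_dataset(1.5, 3e-4, e0=30e-9)
        fit0 = fit_mm(base)
        c = 37.0
        scaled = RateDataset(
            "X",
            2,
            AssayConfig(enzyme_conc=30e-9 * c, substrate_dp=2),
            [
                RatePoint(p.substrate_conc, p.velocity * c, p.replicate)
                for p in base.points
            ],
        )
        fit1 = fit_mm(scaled)
        assert fit1.kcat == pytest.approx(fit0.kcat, rel=1e-9)
        assert fit1.km == pytest.approx(fit0.km, rel=1e-9)

    def test_duplicated_concentrations_are_independent_observations(self):
        ds = _noiseless_dataset(1.0, 1e-4)
        ds.points = ds.points + ds.points
        fit = fit_mm(ds)
        assert fit.n_points == 16
        assert fit.kcat == pytest.approx(1.0, rel=1e-6)

    def test_explicit_init(self):
        fit = fit_mm(
            _noiseless_dataset(2.0, 5e-4), init="explicit", init_params=(1e-8, 1e-3)
        )
        assert fit.kcat == pytest.approx(2.0, rel=1e-6)

    def test_relative_weighting_noiseless_equivalent(self):
        ds = _noiseless_dataset(0.8, 2e-4)
        fit = fit_mm(ds, weighting="relative")
        assert fit.kcat == pytest.approx(0.8, rel=1e-6)
        assert fit.km == pytest.approx(2e-4, rel=1e-6)

    @pytest.mark.parametrize("cvs", [(0.10, 0.03, 0.005)])
    def test_error_shrinks_with_noise(self, cvs):
        """Mean absolute estimation error decreases as noise CV drops."""
        kcat, km = 1.81, 0.90e-3
        params = TrueParameters(kcat=kcat, km=km)
        config = AssayConfig(enzyme_conc=30.2e-9, substrate_dp=2)
        grid = make_concentration_grid()
        errs = []
        for cv in cvs:
            devs = []
            for seed in range(60):
                ds = simulate_rates(params, config, grid, 3, NoiseModel(scale=cv, seed=seed))
                fit = fit_mm(ds, weighting="relative")
                devs.append(abs(fit.kcat - kcat) / kcat + abs(fit.km - km) / km)
            errs.append(np.mean(devs))
        assert errs[0] > errs[1] > errs[2]


class TestSpecificityConstant:
    def test_value_and_delta_method_se(self):
        fit = MMFit(kcat=1.81, km=0.90e-3, kcat_se=0.05, km_se=0.06e-3)
        value, se = specificity_constant(fit)
        assert value == pytest.approx(2011.1, rel=1e-4)  # 2.0 mM^-1 s^-1
        assert se == pytest.approx(145.1, rel=1e-3)  # 0.145 mM^-1 s^-1

    def test_unit_carried_in_m_vs_mm_is_consistent(self):
        # same parameters expressed with km in M: value scales by exactly 1e3
        fit_m = MMFit(kcat=0.39, km=24e-6)
        assert fit_m.specificity * 1e-3 == pytest.approx(16.25, rel=1e-12)

    def test_specificity_field_always_consistent(self):
        with pytest.raises(InvalidArgumentError):
            MMFit(kcat=1.0, km=1e-4, specificity=123.0)


class TestKineticSeries:
    def test_requires_consecutive_dps_from_two(self):
        fit = MMFit(kcat=1.0, km=1e-4)
        with pytest.raises(InvalidArgumentError):
            KineticSeries("X", {3: fit, 4: fit})
        with pytest.raises(InvalidArgumentError):
            KineticSeries("X", {2: fit, 4: fit})
        series = KineticSeries("X", {3: fit, 2: fit})
        assert series.dps == [2, 3]


@pytest.mark.parametrize(
    "value, sig, expected",
    [
        (16.25, 2, 16.0),
        (2.011, 2, 2.0),
        (0.8821, 1, 0.9),
        (0.135, 2, 0.14),
        (-2.85, 2, -2.8),
        (0.0, 3, 0.0),
    ],
)
def test_round_report_half_even(value, sig, expected):
    assert round_report(value, sig) == expected


def test_round_report_requires_positive_sig_figs():
    with pytest.raises(InvalidArgumentError):
        round_report(1.0, 0)
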