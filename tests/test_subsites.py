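"""Subsite theory: k_int rule, affinities, telescoping, bootstrap SEs."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from bxlkinetics import (
    InvalidArgumentError,
    KineticSeries,
    MMFit,
    MissingDataError,
    SubsiteProfile,
    ThermoContext,
    active_center_affinity,
    affinity_uncertainty,
    build_profile,
    count_subsites,
    plus_subsite_affinity,
    reconstruct_specificity,
    select_k_int,
)
from bxlkinetics.subsites import affinity_from_ratio


def _single_dp_series(kcat=1.0, km=1e-4, label="X"):
    return KineticSeries(label, {2: MMFit(kcat=kcat, km=km)})


class TestSelectKInt:
    def test_reference_values(self, table2):
        assert select_k_int(table2["PcBxl3"]) == 2.05
        assert select_k_int(table2["TrXyl3A"]) == 0.82

    def test_single_entry(self):
        assert select_k_int(_single_dp_series(kcat=1.0)) == 1.0


class TestPlusSubsiteAffinity:
    def test_trxyl3a_plus2(self, table2, ctx):
        # RT ln(16/3.7) at 303.15 K
        assert plus_subsite_affinity(table2["TrXyl3A"], 2, ctx) == pytest.approx(
            0.882, abs=1e-3
        )

    def test_pcbxl3_plus2_weak(self, table2, ctx):
        assert plus_subsite_affinity(table2["PcBxl3"], 2, ctx) == pytest.approx(
            -0.134, abs=1e-3
        )

    def test_equal_specificities_give_zero(self, ctx):
        fit = MMFit(kcat=1.0, km=1e-4)
        series = KineticSeries("X", {2: fit, 3: MMFit(kcat=1.0, km=1e-4)})
        assert plus_subsite_affinity(series, 2, ctx) == 0.0

    def test_missing_dp_raises(self, table2, ctx):
        with pytest.raises(MissingDataError):
            plus_subsite_affinity(table2["PcBxl3"], 5, ctx)

    @given(ratio=st.floats(min_value=1e-6, max_value=1e6))
    def test_antisymmetry_in_ratio(self, ratio):
        ctx = ThermoContext()
        assert affinity_from_ratio(ratio, ctx) == pytest.approx(
            -affinity_from_ratio(1.0 / ratio, ctx), abs=1e-12
        )

    @given(t1=st.floats(min_value=250.0, max_value=400.0))
    def test_linear_in_temperature_for_favorable_ratio(self, t1):
        ratio = 4.0
        a1 = affinity_from_ratio(ratio, ThermoContext(temperature=t1))
        a2 = affinity_from_ratio(ratio, ThermoContext(temperature=2.0 * t1))
        assert a2 == pytest.approx(2.0 * a1, rel=1e-12)
        assert a1 > 0

    def test_unit_invariance_of_affinity(self, table2, ctx):
        """Scaling every specificity constant (M vs mM carriage) cancels."""
        tr = table2["TrXyl3A"]
        scaled = KineticSeries(
            "TrXyl3A",
            {
                dp: MMFit(
                    kcat=f.kcat,
                    km=f.km,
                    specificity_printed=f.reported_specificity * 1e-3,
                )
                for dp, f in tr.fits.items()
            },
        )
        assert plus_subsite_affinity(scaled, 2, ctx) == pytest.approx(
            plus_subsite_affinity(tr, 2, ctx), rel=1e-12
        )


class TestActiveCenterAffinity:
    def test_reference_values(self, table2, ctx):
        tr = active_center_affinity(table2["TrXyl3A"], 0.82, ctx)
        pc = active_center_affinity(table2["PcBxl3"], 2.05, ctx)
        assert tr == pytest.approx(7.49, abs=0.01)
        assert pc == pytest.approx(6.57, abs=0.01)
        assert tr - pc == pytest.approx(0.92, abs=0.01)

    def test_difference_invariant_to_water_constant(self, table2):
        """c_w cancels in the two-enzyme difference."""
        diffs = []
        for c_w in (0.018, 1.0):
            ctx = ThermoContext(water_molarity_constant=c_w)
            diffs.append(
                active_center_affinity(table2["TrXyl3A"], 0.82, ctx)
                - active_center_affinity(table2["PcBxl3"], 2.05, ctx)
            )
        assert diffs[0] == pytest.approx(diffs[1], abs=1e-12)

    def test_invalid_k_int(self, table2, ctx):
        with pytest.raises(InvalidArgumentError):
            active_center_affinity(table2["PcBxl3"], 0.0, ctx)


class TestBuildProfile:
    def test_pcbxl3_plus_affinities(self, table2, ctx):
        prof = build_profile(table2["PcBxl3"], ctx)
        assert prof.plus_affinities == pytest.approx(
            {2: -0.134, 3: 0.337, 4: -0.418}, abs=1e-3
        )
        assert prof.k_int == 2.05

    def test_trxyl3a_plus_affinities(self, table2, ctx):
        prof = build_profile(table2["TrXyl3A"], ctx)
        assert prof.plus_affinities == pytest.approx(
            {2: 0.882, 3: -0.173, 4: -0.208}, abs=1e-3
        )

    def test_single_dp_profile(self, ctx):
        prof = build_profile(_single_dp_series(), ctx)
        assert prof.plus_affinities == {}
        assert math.isfinite(prof.active_center_affinity)

    def test_noncontiguous_plus_indices_rejected(self, ctx):
        with pytest.raises(InvalidArgumentError):
            SubsiteProfile("X", 1.0, 5.0, {3: 0.5}, ctx)


class TestReconstructSpecificity:
    def test_telescoping_reproduces_all_inputs(self, table2, ctx):
        for series in table2.values():
            prof = build_profile(series, ctx)
            for dp in series.dps:
                assert reconstruct_specificity(prof, dp) == pytest.approx(
                    series.specificity(dp), rel=1e-10
                )

    def test_out_of_range(self, table2, ctx):
        prof = build_profile(table2["PcBxl3"], ctx)
        for n in (1, 6):
            with pytest.raises(InvalidArgumentError):
                reconstruct_specificity(prof, n)


class TestCountSubsites:
    def test_reference_counts(self, table2, ctx):
        assert count_subsites(build_profile(table2["PcBxl3"], ctx)) == 2
        assert count_subsites(build_profile(table2["TrXyl3A"], ctx)) == 3

    def test_empty_plus_affinities(self, ctx):
        assert count_subsites(build_profile(_single_dp_series(), ctx)) == 2

    def test_counting_stops_at_first_subthreshold(self, ctx):
        prof = SubsiteProfile("X", 1.0, 5.0, {2: 1.0, 3: 0.1, 4: 1.0}, ctx)
        assert count_subsites(prof, 0.4) == 3


class TestAffinityUncertainty:
    def test_zero_ses_give_zero(self, ctx):
        fits = {
            dp: MMFit(kcat=1.0, km=1e-4, kcat_se=0.0, km_se=0.0) for dp in (2, 3)
        }
        series = KineticSeries("X", fits)
        assert affinity_uncertainty(series, 2, ctx, n_boot=200, seed=0) == 0.0

    def test_bootstrap_matches_delta_method(self, table2, ctx):
        """Independent first-order oracle: RT*sqrt(sum of relative variances)."""
        tr = table2["TrXyl3A"]
        se = affinity_uncertainty(tr, 2, ctx, n_boot=10_000, seed=42)
        f2, f3 = tr.fits[2], tr.fits[3]
        delta = ctx.rt * math.sqrt(
            (f2.kcat_se / f2.kcat) ** 2
            + (f2.km_se / f2.km) ** 2
            + (f3.kcat_se / f3.kcat) ** 2
            + (f3.km_se / f3.km) ** 2
        )
        assert se == pytest.approx(delta, rel=0.10)

    def test_seed_determinism(self, table2, ctx):
        a = affinity_uncertainty(table2["TrXyl3A"], 2, ctx, n_boot=500, seed=3)
        b = affinity_uncertainty(table2["TrXyl3A"], 2, ctx, n_boot=500, seed=3)
        assert a == b

    def test_missing_ses_raise(self, ctx):
        fits = {dp: MMFit(kcat=1.0, km=1e-4) for dp in (2, 3)}
        with pytest.raises(MissingDataError):
            affinity_uncertainty(KineticSeries("X", fits), 2, ctx, n_boot=200, seed=0)
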