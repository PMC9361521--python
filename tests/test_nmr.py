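import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from camdyn import nmr
from camdyn.nmr import RateEstimate, SolventModel, TractConstants


class TestFitDecay:
    def test_noiseless_rate_recovered_exactly(self):
        t = np.array([0.0, 0.02, 0.05, 0.1, 0.2, 0.4])
        y = 100.0 * np.exp(-10.0 * t)
        est = nmr.fit_decay(t, y, noise_sd=0.0, n_mc=0)
        assert est.rate == pytest.approx(10.0, rel=1e-9)
        assert est.amplitude == pytest.approx(100.0, rel=1e-9)

    def test_two_point_closed_form(self):
        est = nmr.fit_decay([0.0, 0.1], [100.0, 100.0 * math.exp(-1)], 0.0, n_mc=0)
        assert est.rate == pytest.approx(10.0, rel=1e-6)

    def test_mc_error_scales_with_noise(self):
        t = np.linspace(0.0, 0.4, 10)
        y = 100.0 * np.exp(-8.0 * t)
        errs = [
            nmr.fit_decay(t, y, noise_sd=s, n_mc=300, seed=1).err
            for s in (0.1, 1.0)
        ]
        assert errs[1] / errs[0] == pytest.approx(10.0, rel=0.3)

    def test_mc_error_vanishes_without_noise(self):
        t = np.linspace(0.0, 0.4, 8)
        est = nmr.fit_decay(t, 50 * np.exp(-5 * t), noise_sd=0.0, n_mc=100)
        assert est.err == 0.0

    def test_non_decaying_data_flagged(self):
        t = np.linspace(0.0, 0.4, 6)
        with pytest.raises(ValueError, match="non-decaying"):
            nmr.fit_decay(t, 10.0 * np.exp(+2.0 * t), 0.0, n_mc=0)


class TestTract:
    def test_round_trip_identity_over_range(self):
        # forward rates -> tau_c inversion must be the identity to 1e-3 ns
        for tc in np.linspace(1.0, 20.0, 12):
            ra, rb = nmr.tract_rates(tc, 600.0)
            res = nmr.tract_tauc(
                RateEstimate(ra, 100, 0, 0), RateEstimate(rb, 100, 0, 0),
                600.0, n_mc=0,
            )
            assert res.tau_c == pytest.approx(tc, abs=1e-3)

    def test_rate_difference_monotone_in_tauc(self):
        grid = np.linspace(1.0, 20.0, 40)
        diffs = [nmr.tract_rate_difference(tc, 600.0) for tc in grid]
        assert np.all(np.diff(diffs) > 0)
        assert all(d > 0 for d in diffs)  # R_beta always exceeds R_alpha

    def test_mc_ci_contains_estimate(self):
        ra, rb = nmr.tract_rates(5.2, 600.0)
        res = nmr.tract_tauc(
            RateEstimate(ra, 100, 0.1, 1000), RateEstimate(rb, 100, 0.15, 1000),
            600.0, n_mc=300, seed=0,
        )
        assert res.ci[0] <= res.tau_c <= res.ci[1]
        assert res.ci[1] - res.ci[0] < 1.0  # sub-ns interval at these errors

    def test_inverted_rates_rejected(self):
        with pytest.raises(ValueError):
            nmr.tract_tauc(
                RateEstimate(12.0, 100, 0, 0), RateEstimate(11.0, 100, 0, 0), 600.0
            )


class TestSedTauc:
    def test_compact_cam_sized_sphere_at_37C(self):
        # M = 16706 g/mol, vbar = 0.73 cm^3/g, water at 37 C, 2.8 A shell
        tc = nmr.sed_tauc(16706.0, 0.73, 310.15, 0.6913, 2.8)
        assert tc == pytest.approx(5.2, rel=0.05)

    def test_hydration_bracket_stays_near_5_2(self):
        vals = [nmr.sed_tauc(16706.0, 0.73, 310.15, 0.6913, h) for h in (2.8, 3.0, 3.2)]
        assert all(4.9 <= v <= 5.5 for v in vals)

    def test_linear_in_viscosity(self):
        a = nmr.sed_tauc(16706.0, 0.73, 310.15, 0.6913, 2.8)
        b = nmr.sed_tauc(16706.0, 0.73, 310.15, 2 * 0.6913, 2.8)
        assert b == pytest.approx(2 * a, rel=1e-12)

    def test_cube_law_in_dry_radius(self):
        a = nmr.sed_tauc(16706.0, 0.73, 310.15, 0.6913, 0.0)
        b = nmr.sed_tauc(8 * 16706.0, 0.73, 310.15, 0.6913, 0.0)
        assert b == pytest.approx(8 * a, rel=1e-9)


class TestViscosity:
    def test_pure_h2o_is_identity(self):
        s = SolventModel(temperature=298.15)
        assert nmr.viscosity_correct(5.0, s) == pytest.approx(5.0)

    def test_d2o_ratio_at_25C(self):
        s = SolventModel(temperature=298.15, d2o_fraction=1.0)
        corrected = nmr.viscosity_correct(5.0, s)
        assert 5.0 / corrected == pytest.approx(1.23, abs=0.02)

    def test_monotone_in_d2o_fraction(self):
        vals = [
            nmr.viscosity_correct(5.0, SolventModel(298.15, d2o_fraction=f))
            for f in (0.0, 0.2, 0.5, 1.0)
        ]
        assert np.all(np.diff(vals) < 0)  # more D2O -> larger downward correction

    def test_out_of_range_temperature(self):
        with pytest.raises(ValueError, match="table"):
            nmr.viscosity("h2o", 350.0)


def shift_table(residues, dH, dN):
    return pd.DataFrame({"residue": residues, "dH": dH, "dN": dN})


class TestCsp:
    @pytest.mark.parametrize(
        "ddn, ddh, expected",
        [
            (0.0, 0.0, 0.0),
            (1.0, 0.0, 0.159),
            (0.5, 0.06, 0.0996),  # sqrt(0.0795^2 + 0.06^2)
        ],
    )
    def test_formula(self, ddn, ddh, expected):
        free = shift_table([1], [8.0], [115.0])
        bound = shift_table([1], [8.0 + ddh], [115.0 + ddn])
        rec = nmr.csp(free, bound)[0]
        assert rec.csp == pytest.approx(expected, abs=1e-4)

    def test_symmetric_under_swap(self):
        free = shift_table([1, 2], [8.0, 8.5], [115.0, 120.0])
        bound = shift_table([1, 2], [8.2, 8.4], [116.0, 119.0])
        a = [r.csp for r in nmr.csp(free, bound)]
        b = [r.csp for r in nmr.csp(bound, free)]
        assert a == pytest.approx(b)

    def test_unmatched_residue_reported_missing(self):
        free = shift_table([1, 2], [8.0, 8.5], [115.0, 120.0])
        bound = shift_table([1], [8.0], [115.0])
        recs = nmr.csp(free, bound)
        assert len(recs) == 2
        assert recs[1].missing and math.isnan(recs[1].csp)

    def test_duplicate_residues_rejected(self):
        bad = shift_table([1, 1], [8.0, 8.1], [115.0, 115.5])
        with pytest.raises(ValueError, match="duplicate"):
            nmr.csp(bad, bad)

    @given(
        ddh=st.floats(-1, 1, allow_nan=False),
        ddn=st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_csp_nonnegative_and_exact(self, ddh, ddn):
        free = shift_table([1], [8.0], [115.0])
        bound = shift_table([1], [8.0 + ddh], [115.0 + ddn])
        rec = nmr.csp(free, bound)[0]
        assert rec.csp >= 0
        assert rec.csp == pytest.approx(
            math.sqrt((0.159 * ddn) ** 2 + ddh**2), rel=1e-9, abs=1e-12
        )


class TestClassifyCsp:
    @pytest.mark.parametrize(
        "value, category",
        [
            (0.14, "very_strong"),  # boundary inclusive
            (0.20, "very_strong"),
            (0.07, "strong"),  # lower boundary inclusive
            (0.1399, "strong"),
            (0.0699, "none"),
            (0.0, "none"),
        ],
    )
    def test_boundaries(self, value, category):
        rec = nmr.CSPRecord(1, value, 0.0, value)
        assert nmr.classify_csp([rec])[0].category == category

    def test_empty_input(self):
        assert nmr.classify_csp([]) == []


class TestRegionPartition:
    def test_unassigned_list_splits_8_5_18(self):
        from camdyn.protein import CAM_CDZ_UNASSIGNED

        assert len(CAM_CDZ_UNASSIGNED) == 31
        parts = nmr.partition_by_region(CAM_CDZ_UNASSIGNED)
        assert len(parts["n_lobe"]) == 8
        assert len(parts["linker"]) == 5
        assert len(parts["c_lobe"]) == 18


def intensity_table(residues, signals):
    return pd.DataFrame({"residue": residues, "signal": signals})


class TestNoe:
    def test_equal_intensities_give_one(self):
        recs = nmr.noe_analysis(
            intensity_table([1], [50.0]), intensity_table([1], [50.0]), 0.5
        )
        assert recs[0].noe == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "delta, band",
        [(0.18, "very_high"), (0.25, "very_high"), (0.10, "high"),
         (0.16, "high"), (0.17, "unclassified"), (0.05, "none"), (-0.1, "none")],
    )
    def test_delta_bands(self, delta, band):
        free = nmr.noe_analysis(
            intensity_table([1], [40.0]), intensity_table([1], [50.0]), 0.1
        )
        bound = nmr.noe_analysis(
            intensity_table([1], [(0.8 + delta) * 50.0]),
            intensity_table([1], [50.0]),
            0.1,
            reference=free,
        )
        assert bound[0].delta_noe == pytest.approx(delta, abs=1e-9)
        assert bound[0].band == band

    def test_propagated_error_matches_mc(self):
        # independent Monte-Carlo oracle at SNR >= 10
        rng = np.random.default_rng(0)
        isat, iunsat, sd = 40.0, 50.0, 2.0
        recs = nmr.noe_analysis(
            intensity_table([1], [isat]), intensity_table([1], [iunsat]), sd
        )
        mc = np.std(
            (isat + rng.normal(0, sd, 20000)) / (iunsat + rng.normal(0, sd, 20000))
        )
        assert recs[0].err == pytest.approx(mc, rel=0.1)

    def test_zero_unsaturated_flagged_unusable(self):
        recs = nmr.noe_analysis(
            intensity_table([1], [1.0]), intensity_table([1], [0.5]), 0.5
        )
        assert not recs[0].usable
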