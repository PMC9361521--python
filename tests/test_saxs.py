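import itertools

import numpy as np
import pytest

from camdyn import saxs, synth
from camdyn.io import ScatteringCurve

from conftest import make_guinier_curve, make_sphere_curve

SPHERE_RG = np.sqrt(3.0 / 5.0) * 20.0  # exact Rg of a solid sphere, R = 20 A


class TestGuinier:
    def test_exact_guinier_curve_recovered(self):
        c = make_guinier_curve(Rg=16.8, I0=1.0)
        g = saxs.guinier_fit(c)
        assert g.Rg == pytest.approx(16.8, rel=1e-6)
        assert g.I0 == pytest.approx(1.0, rel=1e-6)
        assert g.qRg_max <= 1.3 + 1e-9

    def test_sphere_curve_rg_within_2pc(self, sphere_curve):
        g = saxs.guinier_fit(sphere_curve)
        assert g.Rg == pytest.approx(SPHERE_RG, rel=0.02)

    def test_debye_sphere_matches_coordinate_rg(self):
        # Debye output of a bead sphere must carry the bead-coordinate Rg
        rng = np.random.default_rng(0)
        coords = synth._lobe_beads(300, 20.0, rng)
        rg_exact = np.sqrt(np.mean(np.sum((coords - coords.mean(0)) ** 2, axis=1)))
        q = np.linspace(1e-3, 0.4 / rg_exact, 60)  # qRg < 0.5
        curve = saxs.debye_scattering(coords, q)
        curve = ScatteringCurve(curve.q, curve.I, 1e-4 * curve.I)
        g = saxs.guinier_fit(curve, qRg_limit=0.5)
        assert g.Rg == pytest.approx(rg_exact, rel=0.01)

    def test_rising_curve_has_no_guinier_region(self):
        q = np.linspace(0.01, 0.1, 50)
        c = ScatteringCurve(q, 1.0 + q**2, np.full_like(q, 1e-3))
        with pytest.raises(ValueError, match="Guinier"):
            saxs.guinier_fit(c)


class TestKratky:
    def test_guinier_law_peaks_at_sqrt3_3_over_e(self, guinier_curve):
        g = saxs.guinier_fit(guinier_curve)
        x, y = saxs.kratky_peak(saxs.dimensionless_kratky(guinier_curve, g))
        assert x == pytest.approx(np.sqrt(3.0), abs=1e-4)
        assert y == pytest.approx(3.0 / np.e, abs=1e-4)
        assert y == pytest.approx(1.104, abs=5e-4)

    def test_flat_curve_monotone_no_interior_peak(self):
        q = np.linspace(0.01, 0.3, 100)
        c = ScatteringCurve(q, np.ones_like(q), np.full_like(q, 1e-3))
        g = saxs.GuinierResult(Rg=10.0, I0=1.0, Rg_err=0, I0_err=0,
                               fit_range=(0, 0), n_points=3, qRg_max=0)
        xy = saxs.dimensionless_kratky(c, g)
        assert np.all(np.diff(xy[:, 1]) > 0)  # y = x^2, strictly increasing

    def test_dumbbell_peak_above_globular_peak(self, extended_pool, compact_pool, qgrid):
        peaks = {}
        for label, pool in (("ext", extended_pool), ("comp", compact_pool)):
            curve, _ = synth.simulate_saxs(pool, qgrid, 0.0)
            g = saxs.guinier_fit(curve)
            peaks[label] = saxs.kratky_peak(saxs.dimensionless_kratky(curve, g))
        assert peaks["ext"][0] > peaks["comp"][0]
        assert peaks["ext"][1] > peaks["comp"][1]
        # the compact state shows the globular signature
        assert peaks["comp"][0] == pytest.approx(np.sqrt(3.0), abs=0.25)
        assert peaks["comp"][1] == pytest.approx(3.0 / np.e, abs=0.15)


class TestIft:
    def test_sphere_pr_recovered(self, sphere_curve):
        pr = saxs.ift_pr(sphere_curve, 40.0, alpha=1e-2)
        assert pr.Rg_real == pytest.approx(SPHERE_RG, rel=0.02)
        # analytic sphere p(r) ~ r^2 (1 - 3r/4R + r^3/16R^3)
        r = pr.r
        R = 20.0
        p_ref = r**2 * (1 - 3 * r / (4 * R) + r**3 / (16 * R**3))
        p_ref[r > 2 * R] = 0.0
        corr = np.corrcoef(pr.p, p_ref)[0, 1]
        assert corr > 0.99
        assert pr.p[0] == 0.0 and pr.p[-1] == 0.0

    def test_forward_transform_self_consistency(self, qgrid, compact_pool):
        curve, _ = synth.simulate_saxs(compact_pool, qgrid, 0.01, seed=3)
        pr = saxs.ift_pr(curve, 56.0)
        assert pr.chi2_red == pytest.approx(1.0, abs=0.5)

    def test_guinier_and_real_space_rg_agree(self, sphere_curve):
        g = saxs.guinier_fit(sphere_curve)
        pr = saxs.ift_pr(sphere_curve, 40.0, alpha=1e-2)
        assert pr.Rg_real == pytest.approx(g.Rg, rel=0.05)

    def test_small_dmax_warns_resolution(self):
        c = make_sphere_curve(qmax=0.05)
        with pytest.warns(UserWarning, match="resolution"):
            saxs.ift_pr(c, 20.0, alpha=1e-2)


class TestEstimateDmax:
    def test_sphere_diameter_recovered_within_grid_step(self, sphere_curve):
        grid = np.arange(24.0, 72.1, 4.0)
        d, profile = saxs.estimate_dmax(sphere_curve, grid)
        assert abs(d - 40.0) <= 4.0
        assert profile.shape == (len(grid), 2)

    def test_underestimated_dmax_raises_chi2(self, sphere_curve):
        small = saxs.ift_pr(sphere_curve, 24.0, alpha=1e-2)
        right = saxs.ift_pr(sphere_curve, 40.0, alpha=1e-2)
        assert small.chi2_red > 10 * right.chi2_red

    def test_compact_pool_smaller_than_extended(self, extended_pool, compact_pool, qgrid):
        grid = np.arange(30.0, 90.1, 4.0)
        dmax = {}
        for label, pool in (("ext", extended_pool), ("comp", compact_pool)):
            curve, _ = synth.simulate_saxs(pool, qgrid, 0.001, seed=5)
            dmax[label], _ = saxs.estimate_dmax(curve, grid)
        assert dmax["comp"] < dmax["ext"]


class TestDebye:
    def test_single_bead_flat(self):
        q = np.linspace(0.0, 0.5, 20)
        c = saxs.debye_scattering(np.zeros((1, 3)), q, weights=np.array([2.0]))
        np.testing.assert_allclose(c.I, 4.0)

    def test_two_beads_closed_form(self):
        d = 10.0
        q = np.linspace(1e-4, 0.5, 100)
        c = saxs.debye_scattering(np.array([[0, 0, 0], [0, 0, d]]), q)
        expected = 2.0 * (1.0 + np.sin(q * d) / (q * d))
        np.testing.assert_allclose(c.I, expected, rtol=1e-10)

    def test_forward_scattering_is_sum_f_squared(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(scale=10, size=(50, 3))
        w = rng.uniform(0.5, 2.0, 50)
        c = saxs.debye_scattering(coords, np.array([1e-8, 0.1]), weights=w)
        assert c.I[0] == pytest.approx(w.sum() ** 2, rel=1e-6)

    def test_histogram_acceleration_matches_exact(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(scale=15, size=(500, 3))
        q = np.linspace(1e-3, 0.4, 50)
        exact = saxs.debye_scattering(coords, q, use_histogram=False)
        fast = saxs.debye_scattering(coords, q, use_histogram=True)
        assert np.max(np.abs(fast.I - exact.I) / exact.I) < 1e-3

    def test_nan_coordinates_rejected(self):
        with pytest.raises(ValueError):
            saxs.debye_scattering(np.array([[0, 0, np.nan]]), np.array([0.1]))


class TestReducedChi2:
    def test_scaled_copy_gives_zero(self, sphere_curve):
        data = ScatteringCurve(
            sphere_curve.q, 7.3 * sphere_curve.I, sphere_curve.sigma
        )
        fq = saxs.reduced_chi2(sphere_curve, data)
        assert fq.chi2_red == pytest.approx(0.0, abs=1e-12)
        assert fq.scale == pytest.approx(7.3)

    def test_scale_invariance(self, sphere_curve):
        data = ScatteringCurve(
            sphere_curve.q,
            sphere_curve.I + 0.01 * sphere_curve.I.max(),
            sphere_curve.sigma,
        )
        a = saxs.reduced_chi2(sphere_curve, data).chi2_red
        model2 = ScatteringCurve(sphere_curve.q, 42.0 * sphere_curve.I, sphere_curve.sigma)
        b = saxs.reduced_chi2(model2, data).chi2_red
        assert a == pytest.approx(b, rel=1e-9)

    def test_noise_replicates_average_one(self, sphere_curve):
        rng = np.random.default_rng(0)
        sig = 0.02 * sphere_curve.I.max() * np.ones(len(sphere_curve))
        vals = []
        for _ in range(100):
            data = ScatteringCurve(
                sphere_curve.q, sphere_curve.I + rng.normal(0, sig), sig
            )
            vals.append(saxs.reduced_chi2(sphere_curve, data).chi2_red)
        assert np.mean(vals) == pytest.approx(1.0, abs=0.15)

    def test_offset_flag_absorbs_constant(self, sphere_curve):
        data = ScatteringCurve(
            sphere_curve.q, 2.0 * sphere_curve.I + 0.05, sphere_curve.sigma
        )
        fq = saxs.reduced_chi2(sphere_curve, data, fit_offset=True)
        assert fq.chi2_red == pytest.approx(0.0, abs=1e-9)
        assert fq.offset == pytest.approx(0.05, rel=1e-6)


class TestCormap:
    def test_all_positive_extreme(self):
        q = np.linspace(0.01, 0.3, 100)
        a = ScatteringCurve(q, np.full(100, 2.0), np.ones(100))
        b = ScatteringCurve(q, np.ones(100), np.ones(100))
        C, p = saxs.cormap_compare(a, b)
        assert C == 100
        assert p < 1e-20

    def test_survival_matches_exhaustive_n20(self):
        # enumerate all 2^20 sign sequences and count longest runs
        n = 20
        bits = np.arange(2**n, dtype=np.uint32)
        arr = ((bits[:, None] >> np.arange(n)) & 1).astype(np.int8)
        runs = np.ones(arr.shape[0], dtype=np.int16)
        cur = runs.copy()
        for j in range(1, n):
            same = arr[:, j] == arr[:, j - 1]
            cur = np.where(same, cur + 1, 1)
            runs = np.maximum(runs, cur)
        for C in (2, 3, 5, 8, 12, 20):
            exact = float((runs >= C).mean())
            assert saxs.longest_run_survival(n, C) == pytest.approx(exact, rel=1e-12)

    def test_null_rejection_rate_about_1pc(self):
        rng = np.random.default_rng(4)
        q = np.linspace(0.01, 0.3, 200)
        base = np.exp(-(q**2) * 40.0)
        sig = 0.05 * np.ones_like(q)
        rejections = 0
        trials = 100
        for _ in range(trials):
            a = ScatteringCurve(q, base + rng.normal(0, sig), sig)
            b = ScatteringCurve(q, base + rng.normal(0, sig), sig)
            _, p = saxs.cormap_compare(a, b)
            rejections += p < 0.01
        assert rejections <= 5  # ~1% of 100 within binomial slack

    def test_short_curves_refused(self):
        q = np.linspace(0.01, 0.05, 5)
        a = ScatteringCurve(q, np.ones(5), np.ones(5))
        with pytest.raises(ValueError):
            saxs.cormap_compare(a, a)


@pytest.fixture(scope="module")
def pool_curves(extended_pool, qgrid):
    return np.stack(
        [synth.simulate_saxs(c, qgrid, 0.0)[0].I for c in extended_pool.conformers]
    )


class TestEnsembleSelect:
    def test_planted_single_member_found(self, pool_curves, qgrid):
        target = pool_curves[7]
        sig = 1e-4 * np.sqrt(np.maximum(target, 0) * target[0])
        data = ScatteringCurve(qgrid, target, np.maximum(sig, 1e-8))
        fit = saxs.ensemble_select(pool_curves, data, ensemble_size=1,
                                   generations=50, seed=0)
        assert fit.member_indices == (7,)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_ga_equals_exhaustive_on_mixture(self, pool_curves, qgrid):
        mix = 0.5 * (pool_curves[3] + pool_curves[9])
        sig = 0.002 * np.sqrt(np.maximum(mix, 0) * mix[0])
        rng = np.random.default_rng(1)
        data = ScatteringCurve(qgrid, mix + rng.normal(0, sig), sig)
        fit = saxs.ensemble_select(pool_curves, data, ensemble_size=2,
                                   generations=100, seed=2)
        # independent oracle: exhaustive search over all multisets, scoring
        # each averaged curve with reduced_chi2
        best = None
        n = pool_curves.shape[0]
        for idx in itertools.combinations_with_replacement(range(n), 2):
            avg = pool_curves[list(idx)].mean(axis=0)
            model = ScatteringCurve(qgrid, avg, np.ones_like(avg))
            chi2 = saxs.reduced_chi2(model, data).chi2_red
            if best is None or chi2 < best[0]:
                best = (chi2, tuple(sorted(idx)))
        assert fit.member_indices == best[1]
        assert fit.chi2 == pytest.approx(best[0], rel=1e-9)

    def test_selected_rg_tracks_extended_mode(self, pool_curves, extended_pool, qgrid):
        rg = extended_pool.rg()
        mix = pool_curves.mean(axis=0)
        sig = 0.005 * np.sqrt(np.maximum(mix, 0) * mix[0])
        rng = np.random.default_rng(5)
        data = ScatteringCurve(qgrid, mix + rng.normal(0, sig), sig)
        fit = saxs.ensemble_select(pool_curves, data, ensemble_size=4,
                                   generations=80, n_runs=3, seed=3, pool_rg=rg)
        assert fit.rg_selected is not None
        assert fit.rg_selected.mean() == pytest.approx(rg.mean(), abs=3.0)
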