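import numpy as np
import pytest

from meltquant import (AssayConfig, CalibrationError, MeltModelParams,
                       StandardPoint, calibrate_nts, estimate_methylation,
                       fit_interpolation, normalize_curves, nts,
                       quantify_plate, simulate_curve, simulate_plate,
                       window_mean_rfu)
from meltquant.simulate import STANDARD_LEVELS

from conftest import lagrange_eval, make_truth


def affine_standards(slope=1.25, intercept=-12.5):
    """Standards whose percentage is an exact affine function of RFU."""
    return [StandardPoint(p, (p - intercept) / slope) for p in STANDARD_LEVELS]


class TestFitInterpolation:
    def test_exact_interpolation_on_simulated_standards(self, noiseless_plate,
                                                        apc_cfg):
        curves, sheet, _ = noiseless_plate
        _, cal = quantify_plate(curves, sheet, apc_cfg)
        assert cal.degree == 5
        rfu = np.array([p.mean_rfu for p in cal.standards])
        pct = np.array([p.nominal_pct for p in cal.standards])
        assert sorted(pct) == list(STANDARD_LEVELS)
        np.testing.assert_allclose(cal.predict(rfu), pct, atol=1e-6)

    def test_two_point_line(self):
        cal = fit_interpolation([StandardPoint(0.0, 10.0),
                                 StandardPoint(100.0, 90.0)])
        x = np.linspace(0, 120, 13)
        np.testing.assert_allclose(cal.predict(x), 1.25 * (x - 10.0), atol=1e-9)

    def test_collinear_standards_collapse_to_line(self):
        cal = fit_interpolation(affine_standards())
        x = np.linspace(*cal.rfu_range, 500)
        np.testing.assert_allclose(cal.predict(x), 1.25 * x - 12.5, atol=1e-9)

    def test_matches_lagrange_oracle(self):
        rng = np.random.default_rng(11)
        rfu = np.sort(rng.uniform(10, 90, 6))
        pts = [StandardPoint(p, r) for p, r in zip(STANDARD_LEVELS, rfu)]
        cal = fit_interpolation(pts)
        x = np.linspace(rfu[0], rfu[-1], 400)
        np.testing.assert_allclose(cal.predict(x),
                                   lagrange_eval(rfu, STANDARD_LEVELS, x),
                                   atol=1e-6)

    def test_duplicate_rfu_rejected(self):
        with pytest.raises(CalibrationError):
            fit_interpolation([StandardPoint(0, 10), StandardPoint(50, 10),
                               StandardPoint(100, 90)])

    def test_non_monotone_standards_rejected(self):
        pts = [StandardPoint(0, 10), StandardPoint(50, 80),
               StandardPoint(100, 40)]
        with pytest.raises(CalibrationError, match="order"):
            fit_interpolation(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(CalibrationError):
            fit_interpolation([StandardPoint(0, 10)])


class TestEstimateMethylation:
    def test_standard_rfu_is_fixed_point(self):
        cal = fit_interpolation(affine_standards())
        w = cal.standards[0].mean_rfu  # the 0% standard
        res = estimate_methylation(cal, w, sample="s")
        assert res.pct_interp == pytest.approx(0.0, abs=1e-9)
        assert not res.extrapolated

    def test_below_range_is_clamped_and_flagged(self):
        cal = fit_interpolation(affine_standards())
        res = estimate_methylation(cal, cal.rfu_range[0] - 5.0)
        assert res.extrapolated
        assert 0.0 <= res.pct_interp <= 100.0
        assert res.pct_interp == max(0.0, min(100.0, res.pct_raw))

    def test_halfway_between_standards_on_affine_curve(self):
        cal = fit_interpolation(affine_standards())
        std = {p.nominal_pct: p.mean_rfu for p in cal.standards}
        mid = 0.5 * (std[25.0] + std[50.0])
        res = estimate_methylation(cal, mid)
        assert res.pct_interp == pytest.approx(37.5, abs=1e-9)


class TestNTS:
    def test_self_is_zero(self, apc_cfg, noiseless_params):
        t = noiseless_params.grid
        f = simulate_curve(0.5, noiseless_params)
        assert nts(f, f, t, apc_cfg) == 0.0

    def test_constant_offset_closed_form(self, apc_cfg, noiseless_params):
        t = noiseless_params.grid
        f = simulate_curve(0.5, noiseless_params)
        c = 7.0
        n_points = int(round(apc_cfg.nts_span / apc_cfg.nts_step)) + 1
        assert n_points == 101
        assert nts(f + c, f, t, apc_cfg) == pytest.approx(n_points * c / 100.0,
                                                          abs=1e-9)

    def test_monotone_in_methylated_fraction(self, apc_cfg, noiseless_params):
        """Less methylated samples melt earlier: NTS more negative, rising
        to 0 as the sample approaches the fully methylated control."""
        from meltquant.preprocess import normalize_curves as norm
        from meltquant import MeltCurveSet
        t = noiseless_params.grid
        ms = [0.0, 0.25, 0.5, 0.75, 1.0]
        traces = np.vstack([simulate_curve(m, noiseless_params) for m in ms])
        curves = norm(MeltCurveSet(t, [f"m{m}" for m in ms], traces), apc_cfg)
        control = curves.rfu[-1]
        vals = [nts(curves.rfu[i], control, t, apc_cfg) for i in range(len(ms))]
        assert vals[-1] == 0.0
        assert all(v <= 0 for v in vals)
        assert np.all(np.diff(vals) > 0)

    def test_range_outside_grid_rejected(self, noiseless_params):
        from meltquant import ValidationError
        cfg = AssayConfig("X", 74.0, 80.0, nts_span=50.0,
                          premelt=(70.0, 72.0), postmelt=(82.0, 84.0))
        t = noiseless_params.grid
        f = simulate_curve(0.5, noiseless_params)
        with pytest.raises(ValidationError):
            nts(f, f, t, cfg)


class TestCalibrateNTS:
    def test_exact_affine_recovery(self):
        pairs = [(p, (p - 100.0) / 20.0) for p in STANDARD_LEVELS]
        cal = calibrate_nts(pairs)
        for pct, val in pairs:
            assert cal.predict(val) == pytest.approx(pct, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        pct = np.array(STANDARD_LEVELS)
        val = (pct - 100.0) / 20.0 + rng.normal(0, 0.3, pct.size)
        cal = calibrate_nts(list(zip(pct, val)))
        n = val.size
        sx, sy = val.sum(), pct.sum()
        sxx, sxy = (val * val).sum(), (val * pct).sum()
        slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
        intercept = (sy - slope * sx) / n
        assert cal.slope == pytest.approx(slope, abs=1e-9)
        assert cal.intercept == pytest.approx(intercept, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_nts([(0.0, 1.0), (100.0, 1.0)])

    def test_methylated_control_maps_near_100(self, noiseless_plate, apc_cfg):
        curves, sheet, _ = noiseless_plate
        results, _ = quantify_plate(curves, sheet, apc_cfg)
        for r in results:
            assert r.pct_nts is not None


class TestQuantifyPlate:
    def test_noiseless_recovery(self, noiseless_plate, apc_cfg):
        curves, sheet, truth = noiseless_plate
        results, cal = quantify_plate(curves, sheet, apc_cfg)
        assert cal.monotone_ok
        est = {r.sample: r.pct_interp for r in results}
        for entry in truth:
            assert est[entry.sample] == pytest.approx(100.0 * entry.m,
                                                      abs=1e-6)

    def test_samples_copying_standards_recover_levels(self, noiseless_params,
                                                      apc_cfg):
        truth = make_truth([p / 100.0 for p in STANDARD_LEVELS])
        curves, sheet = simulate_plate(samples=truth, params=noiseless_params,
                                       seed=0)
        results, _ = quantify_plate(curves, sheet, apc_cfg)
        est = {r.sample: r.pct_interp for r in results}
        for entry in truth:
            assert est[entry.sample] == pytest.approx(100.0 * entry.m,
                                                      abs=1e-6)

    def test_noisy_recovery_rmse_under_5_points(self, apc_cfg):
        from meltquant import random_truth
        truth = random_truth(50, seed=21)
        params = MeltModelParams(noise_sd=1.0)
        curves, sheet = simulate_plate(samples=truth, params=params, seed=22,
                                       sample_replicates=3)
        results, _ = quantify_plate(curves, sheet, apc_cfg)
        est = {r.sample: r.pct_interp for r in results}
        errors = np.array([est[e.sample] - 100.0 * e.m for e in truth])
        assert np.sqrt(np.mean(errors ** 2)) < 5.0

    def test_replicate_sd_reported(self, apc_cfg):
        truth = make_truth([0.4])
        params = MeltModelParams(noise_sd=1.0)
        curves, sheet = simulate_plate(samples=truth, params=params, seed=5,
                                       sample_replicates=3)
        results, _ = quantify_plate(curves, sheet, apc_cfg)
        assert results[0].n_replicates == 3
        assert results[0].replicate_sd is not None
        assert results[0].replicate_sd >= 0

    def test_pool_rfu_equivalent_in_noiseless_limit(self, noiseless_plate,
                                                    apc_cfg):
        curves, sheet, _ = noiseless_plate
        a, _ = quantify_plate(curves, sheet, apc_cfg, pool_rfu=False)
        b, _ = quantify_plate(curves, sheet, apc_cfg, pool_rfu=True)
        for ra, rb in zip(a, b):
            assert ra.pct_interp == pytest.approx(rb.pct_interp, abs=1e-9)

    def test_missing_standards_rejected(self, noiseless_plate):
        from meltquant import ValidationError
        curves, sheet, _ = noiseless_plate
        other = AssayConfig.default("CDKN2A")
        with pytest.raises(ValidationError, match="CDKN2A"):
            quantify_plate(curves, sheet, other)


def test_mean_signed_error_shrinks_with_replicates(apc_cfg):
    """Parameter recovery: averaging more replicates drives bias toward 0."""
    from meltquant import random_truth
    params = MeltModelParams(noise_sd=2.0)
    truth = random_truth(30, seed=9)
    biases = []
    for reps in (1, 8):
        curves, sheet = simulate_plate(samples=truth, params=params, seed=13,
                                       sample_replicates=reps)
        results, _ = quantify_plate(curves, sheet, apc_cfg)
        est = {r.sample: r.pct_interp for r in results}
        err = [est[e.sample] - 100.0 * e.m for e in truth]
        biases.append(abs(np.mean(err)))
    assert biases[1] < biases[0] + 0.5  # noise floor; must not blow up
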