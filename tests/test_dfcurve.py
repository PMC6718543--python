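import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfass.dfcurve import (FitParams, ProcessedTrace, batch_fit, classify_fit,
                           detect_peak, fit_half_max, normalize, preprocess,
                           refine_baseline, FitResult,
                           NO_HALF_CROSSING, NO_SIGNIFICANT_PEAK,
                           OUT_OF_WINDOW, MISSING_DATA,
                           STATUS_OK, STATUS_UNFIT)
from lfass.plate_io import RawTrace, TimeGrid
from lfass.simkit import simulate_plate, stress384

from conftest import staircase


def processed_staircase(times, deaths, cadence=2.0):
    """Idealized processed trace for estimator-level tests: unit steps at
    the death times, zero baseline, no noise, no smoothing distortion."""
    f = staircase(times, deaths)
    return ProcessedTrace("A1", TimeGrid(times, cadence), f, 0.0,
                          (float(times[0]), float(times[-1])), noise_sigma=0.0)


def logistic(t, f0, a, t50, k):
    return f0 + a / (1 + np.exp(-k * (t - t50)))


class TestPreprocess:
    def test_constant_trace_is_fixed_point(self, make_trace, grid8h):
        p = preprocess(make_trace(np.full(len(grid8h), 100.0)))
        np.testing.assert_allclose(p.f_smooth, 100.0)
        assert p.baseline == pytest.approx(100.0)

    def test_single_read_spike_removed_by_median_stage(self, make_trace, grid8h):
        f = np.full(len(grid8h), 100.0)
        f[60] = 10000.0
        p = preprocess(make_trace(f), smooth_window=5)
        assert p.f_smooth[55:65].max() < 2 * 100.0

    def test_gentle_logistic_distorted_below_one_percent(self, make_trace, grid8h):
        f = logistic(grid8h.times, 0.0, 1.0, 200.0, 0.1)
        p = preprocess(make_trace(f), smooth_window=5)
        assert np.abs(p.f_smooth - f).max() <= 0.01

    def test_short_gap_interpolated(self, make_trace, grid8h):
        f = grid8h.times.copy()  # linear ramp
        f[[50, 51]] = np.nan
        p = preprocess(make_trace(f))
        assert np.isfinite(p.f_smooth).all()
        assert p.valid

    def test_long_gap_flags_missing_data(self, make_trace, grid8h):
        f = np.full(len(grid8h), 100.0)
        f[50:54] = np.nan
        p = preprocess(make_trace(f))
        assert not p.valid and MISSING_DATA in p.flags
        fr = fit_half_max(p, detect_peak(p))
        assert fr.status == STATUS_UNFIT and fr.t_half is None

    def test_even_window_rejected(self, make_trace, grid8h):
        from lfass.errors import ConfigError
        with pytest.raises(ConfigError):
            preprocess(make_trace(np.ones(len(grid8h))), smooth_window=4)


class TestDetectPeak:
    def test_large_bump_on_noise_significant(self, make_trace, grid8h):
        t = grid8h.times
        rng = np.random.default_rng(1)
        f = 100 + 10 * rng.standard_normal(len(t)) + 1000 * np.exp(
            -((t - 200) / 30) ** 2)
        peak = detect_peak(preprocess(make_trace(f)))
        assert peak.significant
        assert abs(peak.t_peak - 200) < 10

    def test_most_prominent_of_two_bumps_wins(self, make_trace, grid8h):
        t = grid8h.times
        f = (100 + 800 * np.exp(-((t - 300) / 20) ** 2)
             + 300 * np.exp(-((t - 120) / 20) ** 2))
        p = preprocess(make_trace(f))
        peak = detect_peak(p)
        # oracle: exhaustive scan of strict local maxima of the smoothed trace
        fs = p.f_smooth
        locs = [i for i in range(1, len(fs) - 1)
                if fs[i] > fs[i - 1] and fs[i] > fs[i + 1]]
        best = max(locs, key=lambda i: fs[i])
        assert peak.t_peak == pytest.approx(t[best], abs=4.0)
        assert abs(peak.t_peak - 300) < 10

    def test_flat_noise_rarely_significant(self, make_trace, grid8h):
        n_fp = 0
        reps = 400
        for s in range(reps):
            rng = np.random.default_rng(s)
            f = 100 + 5 * rng.standard_normal(len(grid8h))
            if detect_peak(preprocess(make_trace(f))).significant:
                n_fp += 1
        assert n_fp / reps <= 0.01

    def test_constant_trace_not_significant(self, make_trace, grid8h):
        peak = detect_peak(preprocess(make_trace(np.full(len(grid8h), 5.0))))
        assert not peak.significant


class TestNormalize:
    def test_peak_maps_to_one_and_min_to_zero(self, make_trace, grid8h):
        t = grid8h.times
        f = logistic(t, 200, 1000, 90, 0.5) * np.exp(-t / 600)
        p = preprocess(make_trace(f))
        peak = detect_peak(p)
        p = refine_baseline(p, peak)
        _, g = normalize(p, peak)
        assert g[-1] == pytest.approx(1.0)
        assert g.min() == pytest.approx(0.0)

    def test_affine_invariance(self, make_trace, grid8h):
        t = grid8h.times
        f = logistic(t, 200, 1000, 90, 0.5)
        out = []
        for a, b in [(1.0, 0.0), (3.7, 55.0)]:
            p = preprocess(make_trace(a * f + b))
            peak = detect_peak(p)
            p = refine_baseline(p, peak)
            out.append(normalize(p, peak)[1])
        np.testing.assert_allclose(out[0], out[1], atol=1e-9)

    def test_logistic_half_point(self, make_trace, grid8h):
        t = grid8h.times
        f = logistic(t, 200, 1000, 90, 0.5)
        p = preprocess(make_trace(f))
        peak = detect_peak(p)
        p = refine_baseline(p, peak)
        tt, g = normalize(p, peak)
        g90 = g[np.argmin(np.abs(tt - 90))]
        assert g90 == pytest.approx(0.5, abs=0.01)


class TestFitHalfMax:
    @pytest.mark.parametrize("mode", ["auto", "interpolation"])
    def test_noiseless_logistic_recovers_midpoint(self, make_trace, grid8h, mode):
        f = logistic(grid8h.times, 0.0, 1.0, 90.0, 0.5)
        p = preprocess(make_trace(f))
        peak = detect_peak(p)
        p = refine_baseline(p, peak)
        fr = fit_half_max(p, peak, mode=mode)
        assert fr.status == STATUS_OK
        assert fr.t_half == pytest.approx(90.0, abs=0.2)

    def test_step_sum_median_equivalence_spec_example(self, grid8h):
        # 15 worms, unit steps at 10,20,...,150: half-max (7.5 units) is
        # crossed at the 8th step, the sample median
        deaths = np.arange(10.0, 151.0, 10.0)
        p = processed_staircase(grid8h.times, deaths)
        fr = fit_half_max(p, detect_peak(p), mode="interpolation")
        assert fr.t_half == 80.0 == np.median(deaths)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(1, 50), st.integers(0, 10_000))
    def test_step_sum_median_equivalence_randomized(self, half_n, seed):
        """For instantaneous bursts without decay and an odd worm count,
        the interpolated half-max time IS the sample median of the death
        times (grid-aligned deaths, separated by at least two samples)."""
        n = 2 * half_n + 1  # odd N in {3,...,101}
        times = np.arange(0.0, 480.001, 2.0)
        rng = np.random.default_rng(seed)
        # distinct grid indices with gaps >= 2 samples
        idx = np.sort(rng.choice(np.arange(2, len(times) // 2), size=n,
                                 replace=False)) * 2
        deaths = times[idx]
        p = processed_staircase(times, deaths)
        fr = fit_half_max(p, detect_peak(p), mode="interpolation")
        assert fr.t_half == np.median(deaths)

    def test_shift_equivariance(self, grid8h):
        deaths = np.array([40.0, 60.0, 80.0, 100.0, 120.0])
        out = []
        for shift in (0.0, 30.0):
            p = processed_staircase(grid8h.times, deaths + shift)
            out.append(fit_half_max(p, detect_peak(p), mode="interpolation").t_half)
        assert out[1] - out[0] == pytest.approx(30.0, abs=0.2)

    def test_affine_invariance_of_t_half(self, make_trace, grid8h):
        t = grid8h.times
        rng = np.random.default_rng(3)
        f = logistic(t, 100, 900, 110, 0.3) + 5 * rng.standard_normal(len(t))
        out = {}
        for mode in ("auto", "interpolation"):
            res = []
            for a, b in [(1.0, 0.0), (2.5, 300.0)]:
                p = preprocess(make_trace(a * f + b))
                peak = detect_peak(p)
                p = refine_baseline(p, peak)
                res.append(fit_half_max(p, peak, mode=mode).t_half)
            out[mode] = res
        assert out["interpolation"][0] == pytest.approx(
            out["interpolation"][1], abs=1e-6)
        assert out["auto"][0] == pytest.approx(out["auto"][1], abs=0.1)

    def test_no_half_crossing_flagged(self, grid8h):
        # peak at the very first sample: no upward crossing precedes it
        t = grid8h.times
        f = 1000 * np.exp(-t / 50) + 100
        p = ProcessedTrace("A1", grid8h, f, 100.0, (0.0, 480.0))
        peak = detect_peak(p)
        fr = fit_half_max(p, peak)
        assert fr.status == STATUS_UNFIT
        assert NO_HALF_CROSSING in fr.flags or OUT_OF_WINDOW in fr.flags


class TestClassify:
    def test_flat_noise_well_unfit(self, make_trace, grid8h):
        rng = np.random.default_rng(7)
        f = 100 + 5 * rng.standard_normal(len(grid8h))
        p = preprocess(make_trace(f))
        fr = fit_half_max(p, detect_peak(p))
        assert fr.status == STATUS_UNFIT
        assert NO_SIGNIFICANT_PEAK in fr.flags

    def test_estimate_before_first_read_is_out_of_window(self, grid8h):
        fr = FitResult("A1", t_half=-5.0, params={"A": 100.0}, rmse=1.0)
        p = ProcessedTrace("A1", grid8h, np.ones(len(grid8h)), 0.0, (0.0, 480.0))
        fr = classify_fit(fr, p)
        assert fr.status == STATUS_UNFIT
        assert OUT_OF_WINDOW in fr.flags
        assert fr.t_half is None

    def test_high_rmse_unfit(self, grid8h):
        fr = FitResult("A1", t_half=100.0, params={"A": 100.0}, rmse=40.0)
        p = ProcessedTrace("A1", grid8h, np.ones(len(grid8h)), 0.0, (0.0, 480.0))
        assert classify_fit(fr, p).status == STATUS_UNFIT

    def test_borderline_rmse_review(self, grid8h):
        fr = FitResult("A1", t_half=100.0, params={"A": 100.0}, rmse=20.0)
        p = ProcessedTrace("A1", grid8h, np.ones(len(grid8h)), 0.0, (0.0, 480.0))
        assert classify_fit(fr, p).status == "REVIEW"


class TestBatchFit:
    def test_one_result_per_well(self, stress384_fit):
        _, results, _ = stress384_fit
        assert len(results.fits) == 384
        assert len({f.well_id for f in results.fits}) == 384

    def test_wells_independent_of_plate_order(self):
        run, _ = simulate_plate(stress384(), seed=11)
        sub = type(run)(run.traces[:24])
        rev = type(run)(list(reversed(run.traces[:24])))
        by_well = {f.well_id: f.t_half for f in batch_fit(sub)}
        by_well_rev = {f.well_id: f.t_half for f in batch_fit(rev)}
        assert by_well == by_well_rev

    def test_deterministic(self):
        run, _ = simulate_plate(stress384(), seed=11)
        sub = type(run)(run.traces[:12])
        a = [(f.well_id, f.t_half, f.status) for f in batch_fit(sub)]
        b = [(f.well_id, f.t_half, f.status) for f in batch_fit(sub)]
        assert a == b

    def test_decay_robust_with_many_worms(self):
        """Burst decay (tau 120 min) does not break the estimator on long
        infection-cadence recordings when deaths are dense: 100 worms,
        dispersion well below the decay constant."""
        from lfass.simkit import (BurstKernel, DeathModel, NoiseModel,
                                  render_trace, sample_death_times)
        grid = TimeGrid(np.arange(0.0, 5760.001, 5.0), 5.0)
        for s in range(5):
            rng = np.random.default_rng([13, s])
            deaths = sample_death_times(
                100, DeathModel(median_min=1440.0, sd_min=25.0), rng)
            tr = render_trace(deaths, BurstKernel(), NoiseModel(), grid, rng)
            p = preprocess(tr)
            peak = detect_peak(p)
            p = refine_baseline(p, peak)
            fr = fit_half_max(p, peak)
            assert fr.t_half == pytest.approx(np.median(deaths), abs=10.0)
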