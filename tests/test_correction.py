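import itertools
import numpy as np
import pytest

from pupilstitch.correction import (
    correct_saccade,
    effective_bounds,
    end_value,
    estimate_step,
    optimize_windows,
    presaccadic_slope,
    stitch_trial,
    window_median,
)
from pupilstitch.simulate import SimScene, simulate_trial
from pupilstitch.types import (
    CorrectionConfig,
    InsufficientContextError,
    SaccadeEvent,
    Trial,
)

from conftest import FS, make_trace, step_trial


CFG = CorrectionConfig()


class TestEffectiveBounds:
    def test_one_sample_extension(self):
        s = SaccadeEvent(50, 70)
        assert effective_bounds(s, CFG, 200) == (49, 71)

    def test_zero_extension_identity(self):
        s = SaccadeEvent(50, 70)
        cfg = CorrectionConfig(extension=0)
        assert effective_bounds(s, cfg, 200) == (50, 70)

    def test_too_close_to_edge_is_skippable(self):
        with pytest.raises(InsufficientContextError):
            effective_bounds(SaccadeEvent(3, 20), CFG, 200)
        with pytest.raises(InsufficientContextError):
            effective_bounds(SaccadeEvent(150, 196), CFG, 200)


class TestWindowMedian:
    def test_even_window_averages_central_pair(self):
        tr = make_trace([3.0, 3.1, 3.2, 3.0])
        assert window_median(tr, 0, 4) == pytest.approx(3.05)

    def test_constant(self):
        tr = make_trace([2.9] * 4)
        assert window_median(tr, 0, 4) == 2.9

    def test_mostly_invalid_window_is_skippable(self):
        tr = make_trace([3.0, 3.1, 3.2, 3.0],
                        valid=np.array([True, False, False, False]))
        with pytest.raises(InsufficientContextError):
            window_median(tr, 0, 4)

    def test_matches_sort_based_oracle_on_random_windows(self, rng):
        pupil = rng.uniform(2.0, 5.0, size=5000)
        tr = make_trace(pupil)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            start = int(rng.integers(0, len(tr) - n))
            vals = sorted(pupil[start:start + n])
            m = len(vals)
            oracle = vals[m // 2] if m % 2 else (vals[m // 2 - 1] + vals[m // 2]) / 2
            assert window_median(tr, start, n) == oracle


class TestEstimateStep:
    def test_flat_trace_zero_step(self, flat_trace):
        step, pre, post = estimate_step(flat_trace, SaccadeEvent(100, 120), CFG)
        assert step == 0.0 and pre == post == 3.0

    def test_median_oracle_on_both_windows(self):
        # layout: pre window | ext | saccade | ext | post window, window=4
        pupil = np.concatenate([
            [3.0] * 10, [3.0, 3.1, 3.2, 3.0], [3.0],          # pre, ext
            [2.5] * 10,                                        # in flight
            [2.8], [2.8, 2.9, 2.7, 2.85], [2.8] * 10])         # ext, post
        tr = make_trace(pupil)
        s = SaccadeEvent(15, 24)  # eff bounds (14, 25) with ext=1
        step, pre, post = estimate_step(tr, s, CFG)
        assert pre == pytest.approx(3.05)
        assert post == pytest.approx(2.825)
        assert step == pytest.approx(2.825 - 3.05)

    def test_simulated_step_recovered_exactly(self):
        sc = SimScene(noise_sd_mm=0.0, step_mm=0.07)
        trial, truth = simulate_trial(sc)
        step, _, _ = estimate_step(trial.trace, trial.saccades[0], CFG)
        assert step == pytest.approx(truth.true_steps[0], abs=1e-12)
        assert step == pytest.approx(-0.07, abs=1e-12)


class TestPresaccadicSlope:
    def test_flat_window_zero_slope(self, flat_trace):
        slope = presaccadic_slope(flat_trace, SaccadeEvent(150, 170), CFG)
        assert slope == pytest.approx(0.0, abs=1e-14)

    def test_exact_ramp_recovered(self):
        tr = make_trace(3.0 + 0.001 * np.arange(300) * (1000.0 / FS))
        slope = presaccadic_slope(tr, SaccadeEvent(150, 170), CFG)
        assert slope == pytest.approx(0.001, abs=1e-12)

    def test_too_few_valid_samples_falls_back_to_zero(self, flat_trace):
        valid = flat_trace.valid.copy()
        valid[:148] = False  # leave 2 valid samples in the 100-ms window
        tr = make_trace(flat_trace.pupil, valid=valid)
        with pytest.warns(UserWarning, match="slope set to 0"):
            assert presaccadic_slope(tr, SaccadeEvent(150, 170), CFG) == 0.0


class TestCorrectSaccade:
    def test_flat_trace_zero_correction(self, flat_trace):
        for method in ("simple", "slope"):
            cfg = CorrectionConfig(method=method)
            corr = correct_saccade(flat_trace, SaccadeEvent(100, 120), cfg)
            assert corr.applied_correction == pytest.approx(0.0, abs=1e-12)
            assert corr.intrasaccadic_change == pytest.approx(0.0, abs=1e-12)

    def test_zero_slope_reduces_to_simple(self):
        trial = step_trial(steps=(-0.225, 0.225))
        cfg = CorrectionConfig(method="slope")
        corr = correct_saccade(trial.trace, trial.saccades[0], cfg)
        assert corr.slope == pytest.approx(0.0, abs=1e-15)
        assert corr.applied_correction == pytest.approx(-0.225, abs=1e-9)

    def test_simple_invariant_applied_equals_raw_step(self):
        trial = step_trial()
        corr = correct_saccade(trial.trace, trial.saccades[0], CFG)
        assert corr.slope == 0.0
        assert corr.applied_correction == corr.raw_step

    def test_slope_variant_recovers_injected_step_on_ramp(self):
        r = 0.0005
        trial = step_trial(ramp=r, steps=(-0.1, 0.1))
        cfg = CorrectionConfig(method="slope")
        corr = correct_saccade(trial.trace, trial.saccades[0], cfg)
        assert corr.slope == pytest.approx(r, abs=1e-12)
        assert corr.applied_correction == pytest.approx(-0.1, abs=1e-9)
        assert corr.applied_correction == pytest.approx(
            corr.raw_step - corr.intrasaccadic_change, abs=1e-12)


class TestStitchTrial:
    def test_zero_saccades_identity(self, flat_trace):
        trial = Trial(trace=flat_trace, saccades=[], meta={"participant": "p"})
        res = stitch_trial(trial, CFG)
        np.testing.assert_array_equal(res.corrected.pupil, flat_trace.pupil)
        assert res.per_saccade == [] and not res.interpolated.any()

    def test_single_step_restored_to_presaccadic_level(self):
        trial = step_trial(onsets=((100, 110),), steps=(-0.08,))
        res = stitch_trial(trial, CFG)
        assert res.corrected.pupil[-1] == pytest.approx(3.0, abs=1e-9)

    def test_opposite_steps_cancel(self):
        trial = step_trial(steps=(-0.05, 0.05))
        res = stitch_trial(trial, CFG)
        assert res.corrected.pupil[-1] == pytest.approx(
            trial.trace.pupil[-1], abs=1e-9)
        assert res.total_correction == pytest.approx(0.0, abs=1e-12)

    def test_offset_additivity_invariant(self):
        """corrected - raw is a step function changing only at effective
        saccade offsets, by exactly -applied_correction."""
        trial = step_trial(steps=(-0.06, 0.11))
        res = stitch_trial(trial, CFG)
        diff = res.corrected.pupil - trial.trace.pupil
        expected = np.zeros(len(diff))
        for c in res.per_saccade:
            expected[c.eff_offset + 1:] -= c.applied_correction
        outside = ~res.interpolated
        np.testing.assert_allclose(diff[outside], expected[outside], atol=1e-12)

    def test_windows_on_corrected_trace_equal_raw_trace_evaluation(self):
        trial = step_trial(steps=(-0.06, 0.11), ramp=3e-4)
        cfg = CorrectionConfig(method="slope")
        res = stitch_trial(trial, cfg)
        for c in res.per_saccade:
            standalone = correct_saccade(trial.trace, c.saccade, cfg)
            assert c.applied_correction == pytest.approx(
                standalone.applied_correction, abs=1e-12)

    def test_interpolation_is_linear_within_anchor_hull(self):
        trial = step_trial(onsets=((100, 110),), steps=(-0.08,))
        res = stitch_trial(trial, CFG)
        (c,) = res.per_saccade
        lo, hi = c.eff_onset, c.eff_offset
        assert res.interpolated[lo:hi + 1].all()
        assert not res.interpolated[lo - 1] and not res.interpolated[hi + 1]
        seg = res.corrected.pupil[lo - 1:hi + 2]
        np.testing.assert_allclose(np.diff(seg, 2), 0.0, atol=1e-9)
        low, high = min(seg[0], seg[-1]), max(seg[0], seg[-1])
        assert np.all(seg >= low - 1e-12) and np.all(seg <= high + 1e-12)

    def test_edge_saccade_skipped_not_fatal(self):
        trial = step_trial(onsets=((2, 12), (250, 260)), steps=(-0.05, 0.05))
        res = stitch_trial(trial, CFG)
        assert len(res.per_saccade) == 1
        assert res.skipped and res.skipped[0][0].onset == 2
        # the skipped span is untouched
        np.testing.assert_array_equal(res.corrected.pupil[:3],
                                      trial.trace.pupil[:3])

    def test_close_saccades_merged_into_one_snip(self):
        trial = step_trial(onsets=((100, 110), (113, 123)), steps=(-0.05, -0.05))
        res = stitch_trial(trial, CFG)
        assert len(res.per_saccade) == 1
        (c,) = res.per_saccade
        assert c.merged_from and len(c.merged_from) == 2
        assert c.applied_correction == pytest.approx(-0.10, abs=1e-9)


def _grid_objective(trials, cfg0, w, e):
    from dataclasses import replace
    cfg = replace(cfg0, window=w, extension=e)
    losses = []
    for trial in trials:
        res = stitch_trial(trial, cfg)
        if res.skipped:
            continue
        losses.append(abs((end_value(res.corrected, w) - end_value(res.raw, w)) / 2))
    return float(np.mean(losses)) if losses else float("inf")


class TestOptimizeWindows:
    def _bracketing_trials(self, n=12):
        """Forward-saccade markers mis-placed 5 samples inward: with
        extension 0 at least half of every candidate median window (width
        <= 8) is in-flight contamination, while extension >= 1 admits a
        clean window. The return saccade is marked exactly so its (zero)
        error cannot cancel the forward one at trial end."""
        trials = []
        for i in range(n):
            t = step_trial(onsets=((100, 121), (250, 271)), steps=(-0.05, 0.05),
                           trial_id=f"t{i}")
            fwd = t.saccades[0]
            marked = [SaccadeEvent(fwd.onset + 5, fwd.offset - 5, is_return=False),
                      t.saccades[1]]
            trials.append(Trial(trace=t.trace, saccades=marked, meta=t.meta))
        return trials

    def test_finds_bracketing_extension(self):
        trials = self._bracketing_trials()
        best = optimize_windows(trials, CFG)
        # exhaustive grid oracle with the documented tie-break
        grid = {(w, e): _grid_objective(trials, CFG, w, e)
                for w, e in itertools.product(range(1, 9), range(0, 5))}
        (ow, oe) = min(grid, key=lambda k: (grid[k], k[1], k[0]))
        assert oe == 1
        assert (best.window, best.extension) == (ow, oe)
        # extension 0 never reaches the optimum: the step bleeds outside
        # the marked saccade
        assert min(v for (w, e), v in grid.items() if e == 0) > \
            min(grid.values()) + 1e-6

    def test_constant_objective_tie_break(self, flat_trace):
        trials = [Trial(trace=make_trace(np.full(300, 3.0), trial_id=f"t{i}"),
                        saccades=[SaccadeEvent(100, 110), SaccadeEvent(200, 210)],
                        meta={}) for i in range(12)]
        best = optimize_windows(trials, CFG)
        assert (best.window, best.extension) == (1, 0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            optimize_windows(self._bracketing_trials(5), CFG)
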