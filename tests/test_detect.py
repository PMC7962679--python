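import numpy as np
import pytest

from msaccade.detect import (DetectionParams, SaccadeEvent, VelocityThreshold,
                             compute_velocity, detect_monocular,
                             detect_saccades, estimate_threshold,
                             measure_and_classify, pair_binocular)
from msaccade.preprocess import screen_recording
from msaccade.reference import reference_detect
from msaccade.simulate import SimConfig, simulate_trial

PARAMS = DetectionParams()


def _vel(vx, vy=None):
    vx = np.asarray(vx, float)
    vy = np.zeros_like(vx) if vy is None else np.asarray(vy, float)
    return np.column_stack([vx, vy])


class TestComputeVelocity:
    def test_constant_position_zero_velocity(self):
        pos = np.zeros((50, 2))
        v = compute_velocity(pos, 1000.0)
        assert np.nanmax(np.abs(v)) == 0.0
        assert np.isnan(v[:2]).all() and np.isnan(v[-2:]).all()

    def test_linear_motion_exact(self):
        # x(t) = 3 t deg at 1000 Hz: the stencil is exact for linear motion
        t = np.arange(100) / 1000.0
        pos = np.column_stack([3.0 * t, np.zeros(100)])
        v = compute_velocity(pos, 1000.0)
        np.testing.assert_allclose(v[2:-2, 0], 3.0, atol=1e-9)

    def test_stencil_arithmetic(self):
        # direct stencil evaluation: v_c = (x_{c+2} + x_{c+1} - x_{c-1} - x_{c-2}) * rate / 6
        pos = np.column_stack([[0, 0, 0, 1, 1], np.zeros(5)]).astype(float)
        v = compute_velocity(pos, 1000.0)
        assert v[2, 0] == pytest.approx((1 + 1 - 0 - 0) * 1000.0 / 6.0)
        pos = np.column_stack([[0, 0, 0, 0, 1], np.zeros(5)]).astype(float)
        v = compute_velocity(pos, 1000.0)
        assert v[2, 0] == pytest.approx((1 + 0 - 0 - 0) * 1000.0 / 6.0)

    def test_masked_samples_cut_the_stencil(self):
        pos = np.zeros((20, 2))
        usable = np.ones(20, bool)
        usable[10] = False
        v = compute_velocity(pos, 1000.0, usable)
        assert np.isnan(v[8:13]).all()
        assert np.isfinite(v[2:8]).all()

    def test_short_segment_all_nan(self):
        v = compute_velocity(np.zeros((3, 2)), 1000.0)
        assert np.isnan(v).all()


class TestEstimateThreshold:
    def test_alternating_velocities_give_unit_sigma(self):
        # median(v)=0, median(v^2)=1 => sigma=1, eta=lambda=6
        vx = np.tile([1.0, -1.0], 50)
        thr = estimate_threshold(_vel(vx, np.zeros(100)))
        assert thr.sigma_x == pytest.approx(1.0)
        assert thr.eta_x == pytest.approx(6.0)

    def test_degenerate_distribution_floored(self):
        thr = estimate_threshold(_vel(np.ones(100)))
        assert thr.degenerate
        assert thr.sigma_x == PARAMS.sigma_floor

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="usable"):
            estimate_threshold(_vel(np.ones(10)))

    def test_default_lambda_is_six(self):
        assert DetectionParams().lambda_ == 6.0


class TestDetectMonocular:
    def _thr(self):
        return VelocityThreshold(eta_x=10.0, eta_y=10.0, sigma_x=10 / 6, sigma_y=10 / 6)

    def test_no_suprathreshold_empty(self):
        v = _vel(np.full(100, 1.0))
        assert detect_monocular(v, self._thr(), PARAMS, 1000.0) == []

    def test_six_sample_run_is_kept_five_dropped(self):
        vx = np.zeros(100)
        vx[20:26] = 50.0  # exactly 6 ms at 1000 Hz
        assert detect_monocular(_vel(vx), self._thr(), PARAMS, 1000.0) == [(20, 26)]
        vx[25] = 0.0      # now 5 ms: below the minimum duration
        assert detect_monocular(_vel(vx), self._thr(), PARAMS, 1000.0) == []

    def test_runs_within_isi_merge_before_duration_test(self):
        vx = np.zeros(100)
        vx[20:26] = 50.0
        vx[36:42] = 50.0  # 10 ms gap < 20 ms minimum ISI
        events = detect_monocular(_vel(vx), self._thr(), PARAMS, 1000.0)
        assert events == [(20, 42)]
        assert events[0][1] - events[0][0] == 22

    def test_gap_at_isi_not_merged(self):
        vx = np.zeros(100)
        vx[20:26] = 50.0
        vx[46:52] = 50.0  # exactly 20 ms gap
        events = detect_monocular(_vel(vx), self._thr(), PARAMS, 1000.0)
        assert events == [(20, 26), (46, 52)]

    def test_elliptic_criterion_combines_components(self):
        # each component at 0.8 eta: radial 2*(0.8^2) = 1.28 > 1
        v = _vel(np.full(100, 8.0), np.full(100, 8.0))
        events = detect_monocular(v, self._thr(), PARAMS, 1000.0)
        assert events == [(0, 100)]


class TestPairBinocular:
    def test_identical_events_pair(self):
        events = pair_binocular([(100, 120)], [(100, 120)])
        assert len(events) == 1
        assert (events[0].onset_sample, events[0].offset_sample) == (100, 120)

    def test_monocular_event_discarded(self):
        assert pair_binocular([(100, 120)], []) == []
        assert pair_binocular([(100, 120)], [(300, 320)]) == []

    def test_single_sample_overlap_pairs_with_union(self):
        events = pair_binocular([(100, 120)], [(119, 140)])
        assert len(events) == 1
        assert (events[0].onset_sample, events[0].offset_sample) == (100, 140)

    def test_greedy_largest_overlap(self):
        # one right event overlaps two left events; the larger overlap wins
        events = pair_binocular([(100, 120), (118, 140)], [(116, 138)])
        assert len(events) == 1
        assert events[0].left_interval == (118, 140)
        assert events[0].right_interval == (116, 138)
        assert (events[0].onset_sample, events[0].offset_sample) == (116, 140)

    def test_each_event_pairs_at_most_once(self):
        events = pair_binocular([(100, 120)], [(105, 110), (112, 118)])
        assert len(events) == 1


class TestMeasureAndClassify:
    def _measure(self, disp_l, disp_r):
        n = 40
        pos_l = np.zeros((n, 2)); pos_l[20:, 0] = disp_l
        pos_r = np.zeros((n, 2)); pos_r[20:, 0] = disp_r
        vel = np.zeros((n, 2))
        ev = SaccadeEvent(10, 30, left_interval=(10, 30), right_interval=(10, 30))
        return measure_and_classify([ev], pos_l, pos_r, vel, vel)[0]

    def test_mean_is_arithmetic_average(self):
        ev = self._measure(0.4, 0.6)
        assert ev.amp_l == pytest.approx(0.4)
        assert ev.amp_r == pytest.approx(0.6)
        assert ev.mean_amplitude == pytest.approx(0.5)
        assert ev.is_microsaccade

    def test_both_eyes_must_be_below_two_degrees(self):
        ev = self._measure(1.9, 2.1)
        assert not ev.is_microsaccade
        ev = self._measure(1.9, 1.99)
        assert ev.is_microsaccade

    def test_horizontal_unit_displacement(self):
        ev = self._measure(1.0, 1.0)
        assert ev.amp_l == pytest.approx(1.0)


class TestDetectSaccades:
    def test_scaling_invariance(self, quiet_trial):
        rec, _ = quiet_trial
        events = detect_saccades(rec)
        rec2 = rec
        for ch in ("x_l", "y_l", "x_r", "y_r"):
            setattr(rec2, ch, getattr(rec, ch) * 7.0)
        events2 = detect_saccades(rec2)
        assert [(e.onset_sample, e.offset_sample) for e in events] \
            == [(e.onset_sample, e.offset_sample) for e in events2]

    def test_no_event_on_invalid_samples_and_min_duration(self, default_trial):
        rec, _ = default_trial
        mask = screen_recording(rec)
        for ev in detect_saccades(rec, mask):
            assert mask.valid[ev.onset_sample:ev.offset_sample].all()
            assert ev.duration_samples >= 6

    def test_main_sequence_of_detected_events(self):
        cfg = SimConfig(ms_rate=2.0, blink_rate=0.0, semiblink_rate=0.0)
        amps, pvs = [], []
        for seed in range(2):
            rec, _ = simulate_trial(cfg, seed)
            for e in detect_saccades(rec):
                amps.append(e.mean_amplitude)
                pvs.append(e.mean_peak_velocity)
        assert len(amps) >= 200
        r = np.corrcoef(np.log(amps), np.log(pvs))[0, 1]
        assert r > 0.9


class TestReferenceEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_short_segments(self, seed):
        rng = np.random.default_rng(seed)
        cfg = SimConfig(trial_duration_s=2.0,
                        ms_rate=float(rng.uniform(0.5, 3.0)),
                        ms_amplitude_log_mean=float(np.log(rng.uniform(0.2, 0.8))),
                        blink_rate=0.0, semiblink_rate=0.0)
        rec, _ = simulate_trial(cfg, seed=900 + seed)
        mask = screen_recording(rec)
        fast = detect_saccades(rec, mask)
        ref = reference_detect(rec, mask)
        assert len(fast) == len(ref)
        for a, b in zip(fast, ref):
            assert (a.onset_sample, a.offset_sample) == (b.onset_sample, b.offset_sample)
            assert a.left_interval == b.left_interval
            assert a.right_interval == b.right_interval
            assert a.amp_l == pytest.approx(b.amp_l, abs=1e-12)
            assert a.pv_l == pytest.approx(b.pv_l, abs=1e-9)
            assert a.is_microsaccade == b.is_microsaccade
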