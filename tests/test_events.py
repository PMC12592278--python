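"""Gaze cleaning chain and event detection on constructed traces."""

import numpy as np
import pytest

import jointgaze as jg
from jointgaze.events import (SaccadeThresholds, _runs,
                              adaptive_saccade_threshold, correct_blinks,
                              compute_velocity, detect_fixations,
                              detect_saccades, drop_implausible, smooth_gaze,
                              trial_quality)
from jointgaze.io import (STATUS_BLINK, STATUS_EXCLUDED, STATUS_IMPLAUSIBLE,
                          STATUS_MISSING, STATUS_VALID)

from conftest import make_segment


def _status(n, missing=()):
    s = np.full(n, STATUS_VALID, dtype=object)
    for lo, hi in missing:
        s[lo:hi] = STATUS_MISSING
    return s


class TestBlinkCorrection:
    def test_blink_band_run_and_pads(self, paradigm, cleaning_cfg):
        # 150 ms gap (45 samples) -> blink, plus 25 ms (7-8 samples) pads
        seg = make_segment(paradigm, status=_status(600, [(300, 345)]))
        out = correct_blinks(seg, cleaning_cfg).data["status"].to_numpy()
        assert (out[300:345] == STATUS_BLINK).all()
        n_pad = int(round(0.025 * paradigm.sampling_rate))
        assert (out[300 - n_pad:300] == STATUS_EXCLUDED).all()
        assert (out[345:345 + n_pad] == STATUS_EXCLUDED).all()
        assert (out[:300 - n_pad] == STATUS_VALID).all()

    def test_short_gap_untouched(self, paradigm, cleaning_cfg):
        # 50 ms gap is below the 75 ms blink band
        seg = make_segment(paradigm, status=_status(600, [(300, 315)]))
        out = correct_blinks(seg, cleaning_cfg).data["status"].to_numpy()
        assert (out[300:315] == STATUS_MISSING).all()
        assert (out[:300] == STATUS_VALID).all()

    def test_long_gap_untouched(self, paradigm, cleaning_cfg):
        # 300 ms gap exceeds the 250 ms blink band
        seg = make_segment(paradigm, status=_status(600, [(200, 290)]))
        out = correct_blinks(seg, cleaning_cfg).data["status"].to_numpy()
        assert (out[200:290] == STATUS_MISSING).all()

    def test_fully_valid_identity(self, paradigm, cleaning_cfg):
        seg = make_segment(paradigm, status=_status(600))
        out = correct_blinks(seg, cleaning_cfg)
        assert (out.data["status"] == STATUS_VALID).all()


class TestImplausibleFilter:
    def test_stationary_nothing_dropped(self, paradigm, geometry,
                                        cleaning_cfg):
        seg = make_segment(paradigm, n=900)
        out = drop_implausible(seg, geometry, cleaning_cfg)
        assert (out.data["status"] == STATUS_VALID).all()

    def test_single_sample_jump_flagged(self, paradigm, geometry,
                                        cleaning_cfg):
        # 10 degrees in one 300 Hz step is 3000 deg/s > 1000 deg/s
        x = np.full(900, 960.0)
        jump_px = jg.deg_to_px(10.0, geometry)
        x[450] += jump_px
        seg = make_segment(paradigm, x=x, n=900)
        out = drop_implausible(seg, geometry, cleaning_cfg)
        status = out.data["status"].to_numpy()
        assert status[450] == STATUS_IMPLAUSIBLE
        assert (status[:450] == STATUS_VALID).all()
        assert (status[451:] == STATUS_VALID).all()

    def test_smooth_drift_survives(self, paradigm, geometry, cleaning_cfg):
        # ~20 deg/s pursuit-like drift
        t = np.arange(900) / paradigm.sampling_rate
        x = 500.0 + jg.deg_to_px(20.0, geometry) * t
        seg = make_segment(paradigm, x=x, n=900)
        out = drop_implausible(seg, geometry, cleaning_cfg)
        assert (out.data["status"] == STATUS_VALID).all()


class TestSmoothing:
    def test_constant_unchanged(self, paradigm, cleaning_cfg):
        seg = make_segment(paradigm, n=600)
        out = smooth_gaze(seg, cleaning_cfg)
        np.testing.assert_allclose(out.data["x_sm"], 960.0, atol=1e-9)

    def test_linear_ramp_preserved(self, paradigm, cleaning_cfg):
        x = np.linspace(500.0, 900.0, 600)
        seg = make_segment(paradigm, x=x, n=600)
        out = smooth_gaze(seg, cleaning_cfg)
        np.testing.assert_allclose(out.data["x_sm"], x, atol=1e-9)

    def test_spike_attenuated(self, paradigm, cleaning_cfg):
        x = np.full(600, 960.0)
        x[300] += 30.0
        seg = make_segment(paradigm, x=x, n=600)
        out = smooth_gaze(seg, cleaning_cfg)
        assert abs(out.data["x_sm"][300] - 960.0) < 30.0

    def test_short_run_left_unsmoothed(self, paradigm, cleaning_cfg):
        x = np.full(60, 960.0)
        x[30] += 30.0
        status = _status(60, [(0, 45)])  # valid run of only 15 samples
        seg = make_segment(paradigm, x=x, status=status, n=60)
        out = smooth_gaze(seg, cleaning_cfg)
        np.testing.assert_array_equal(out.data["x_sm"][45:],
                                      seg.data["x"][45:])


class TestVelocity:
    def test_stationary_zero(self, paradigm, geometry, cleaning_cfg):
        seg = smooth_gaze(make_segment(paradigm, n=600), cleaning_cfg)
        vel = compute_velocity(seg, geometry).data["vel_deg"]
        defined = vel.dropna()
        assert len(defined) > 0
        np.testing.assert_allclose(defined, 0.0, atol=1e-9)

    def test_uniform_motion(self, paradigm, geometry, cleaning_cfg):
        # 1 degree per 10 ms -> 100 deg/s; small-angle regime near centre
        t = np.arange(600) / paradigm.sampling_rate
        x = 960.0 + jg.deg_to_px(1.0, geometry) * (t * 100.0)
        seg = smooth_gaze(make_segment(paradigm, x=x, n=600), cleaning_cfg)
        vel = compute_velocity(seg, geometry).data["vel_deg"].dropna()
        np.testing.assert_allclose(vel, 100.0, rtol=0.02)

    def test_undefined_at_run_edges(self, paradigm, geometry, cleaning_cfg):
        seg = smooth_gaze(make_segment(paradigm, n=600), cleaning_cfg)
        vel = compute_velocity(seg, geometry).data["vel_deg"]
        assert np.isnan(vel.iloc[0]) and np.isnan(vel.iloc[-1])


class TestAdaptiveThreshold:
    def test_gaussian_noise_closed_form(self, cleaning_cfg):
        # with no sample above the initial threshold the scheme converges
        # to mean + 6 SD of the full distribution
        rng = np.random.default_rng(0)
        v = rng.normal(5.0, 2.0, 3000)
        v = np.abs(v)
        thr = adaptive_saccade_threshold(v, cleaning_cfg)
        assert thr.peak == pytest.approx(np.mean(v) + 6 * np.std(v), abs=1.0)
        assert thr.onset == pytest.approx(np.mean(v) + 3 * np.std(v), abs=1.0)

    def test_all_zero_returns_floor(self, cleaning_cfg):
        thr = adaptive_saccade_threshold(np.zeros(3000), cleaning_cfg)
        assert thr.peak == cleaning_cfg.pt_floor

    def test_embedded_saccades_excluded(self, cleaning_cfg):
        rng = np.random.default_rng(1)
        v = np.abs(rng.normal(5.0, 2.0, 3000))
        v[1000:1020] = 300.0  # saccade samples
        thr = adaptive_saccade_threshold(v, cleaning_cfg)
        noise = np.abs(rng.normal(5.0, 2.0, 3000))
        assert thr.peak < 300.0
        assert thr.peak > np.mean(noise)
        # saccade samples did not contaminate the final statistics
        assert thr.peak == pytest.approx(
            np.mean(v[v < 100]) + 6 * np.std(v[v < 100]), abs=2.0)

    def test_too_few_samples_falls_back(self, cleaning_cfg):
        thr = adaptive_saccade_threshold(np.full(50, 5.0), cleaning_cfg)
        assert thr.fallback and thr.peak == cleaning_cfg.pt_initial


class TestSaccadeFixationDetection:
    def _prep(self, paradigm, geometry, cfg, x):
        seg = make_segment(paradigm, x=x, n=len(x))
        seg = smooth_gaze(seg, cfg)
        return compute_velocity(seg, geometry)

    def test_no_suprathreshold_no_saccades(self, paradigm, geometry,
                                           cleaning_cfg):
        seg = self._prep(paradigm, geometry, cleaning_cfg, np.full(900, 960.0))
        thr = SaccadeThresholds(peak=100.0, onset=50.0)
        assert detect_saccades(seg, thr, geometry, cleaning_cfg) == []

    def test_two_saccades_with_50ms_gap_not_merged(self, paradigm, geometry,
                                                   cleaning_cfg):
        # two 40 ms velocity bumps separated by a 50 ms (15-sample) still
        # interval; positions give each bump a 5-degree amplitude
        step = jg.deg_to_px(5.0, geometry)
        x = np.full(900, 600.0)
        x[300:312] += step * np.linspace(0.0, 1.0, 12)
        x[312:327] += step
        x[327:339] += step * (1.0 + np.linspace(0.0, 1.0, 12))
        x[339:] += 2 * step
        seg = make_segment(paradigm, x=x, n=900)
        seg.data["x_sm"] = x
        seg.data["y_sm"] = seg.data["y"]
        vel = np.zeros(900)
        vel[300:312] = 150.0
        vel[327:339] = 150.0
        seg.data["vel_deg"] = vel
        thr = SaccadeThresholds(peak=80.0, onset=20.0)
        saccades = detect_saccades(seg, thr, geometry, cleaning_cfg)
        assert len(saccades) == 2

    def test_constant_run_one_fixation(self, paradigm, geometry,
                                       cleaning_cfg):
        seg = self._prep(paradigm, geometry, cleaning_cfg, np.full(900, 700.0))
        fixations = detect_fixations(seg, [], geometry, cleaning_cfg)
        assert len(fixations) == 1
        assert fixations[0].centroid_x == pytest.approx(700.0)

    def test_80ms_run_too_short(self, paradigm, geometry, cleaning_cfg):
        # valid run of 24 samples (80 ms) < 100 ms minimum
        status = _status(300)
        status[:100] = STATUS_MISSING
        status[124:] = STATUS_MISSING
        seg = make_segment(paradigm, status=status, n=300)
        seg = smooth_gaze(seg, cleaning_cfg)
        seg = compute_velocity(seg, geometry)
        assert detect_fixations(seg, [], geometry, cleaning_cfg) == []


class TestTrialQuality:
    def test_fully_valid_retained(self, paradigm, cleaning_cfg):
        frac, dropped = trial_quality(make_segment(paradigm), cleaning_cfg)
        assert frac == 0.0 and not dropped

    def test_sixty_percent_missing_dropped(self, paradigm, cleaning_cfg):
        n = paradigm.samples_per_trial
        seg = make_segment(paradigm, status=_status(n, [(0, int(0.6 * n))]))
        frac, dropped = trial_quality(seg, cleaning_cfg)
        assert dropped and frac == pytest.approx(0.6, abs=1e-3)

    def test_exactly_half_valid_retained(self, paradigm, cleaning_cfg):
        n = 600
        seg = make_segment(paradigm, status=_status(n, [(0, n // 2)]), n=n)
        frac, dropped = trial_quality(seg, cleaning_cfg)
        assert frac == 0.5 and not dropped


def test_cleaning_is_monotone(paradigm, geometry, cleaning_cfg):
    """No cleaning step ever returns a non-valid sample to valid."""
    rng = np.random.default_rng(3)
    n = paradigm.samples_per_trial
    x = 960.0 + rng.normal(0, 15.0, n)
    status = _status(n, [(500, 540), (2000, 2030)])
    seg = make_segment(paradigm, x=x, status=status)
    valid_sets = [set(np.flatnonzero(seg.data["status"] == STATUS_VALID))]
    seg = correct_blinks(seg, cleaning_cfg)
    valid_sets.append(set(np.flatnonzero(seg.data["status"] == STATUS_VALID)))
    seg = drop_implausible(seg, geometry, cleaning_cfg)
    valid_sets.append(set(np.flatnonzero(seg.data["status"] == STATUS_VALID)))
    seg = smooth_gaze(seg, cleaning_cfg)
    valid_sets.append(set(np.flatnonzero(seg.data["status"] == STATUS_VALID)))
    for before, after in zip(valid_sets, valid_sets[1:]):
        assert after <= before


def test_runs_helper():
    mask = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1], dtype=bool)
    assert _runs(mask) == [(1, 3), (4, 5), (7, 10)]
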