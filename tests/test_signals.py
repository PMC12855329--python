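"""Gaze/pupil pipelines: filtering, windows, angular error, surprisal peaks."""
import numpy as np
import pytest

from pbac.signals import (
    TrialTimeseries,
    filter_gaze,
    min_gaze_ball_error,
    predictive_gaze,
    preprocess_pupil,
    pupil_surprisal_peak,
    recode_toward_likely,
)
from pbac.task_engine import derive_viewer_distance

FS = 90.0


def make_trial(
    n=540,
    gaze_x=None,
    gaze_dir=None,
    ball_dir=None,
    pupil_left=None,
    pupil_right=None,
    valid=None,
    release=2.0,
    arrival=2.5,
):
    t = np.arange(n) / FS
    if gaze_x is None:
        gaze_x = np.zeros(n)
    if gaze_dir is None:
        gaze_dir = np.tile([0.0, 0.0, 1.0], (n, 1))
    if ball_dir is None:
        ball_dir = np.full((n, 3), np.nan)
    if pupil_left is None:
        pupil_left = np.full(n, 3.0)
    if pupil_right is None:
        pupil_right = np.full(n, 3.0)
    if valid is None:
        valid = np.ones(n, dtype=bool)
    return TrialTimeseries(
        t=t, gaze_x=gaze_x, gaze_dir=gaze_dir, ball_pos=np.full((n, 3), np.nan),
        ball_dir=ball_dir, pupil_left=pupil_left, pupil_right=pupil_right,
        valid_left=valid.copy(), valid_right=valid.copy(),
        release_time=release, arrival_time=arrival, fs=FS,
    )


class TestGazeFilter:
    def test_constant_series_unchanged(self):
        x = np.full(300, 0.7)
        np.testing.assert_allclose(filter_gaze(x), x, atol=1e-9)

    def test_single_sample_spike_removed_by_median(self):
        x = np.zeros(300)
        x[150] = 1e6
        out = filter_gaze(x)
        assert np.max(np.abs(out)) < 1e-3

    def test_30hz_sinusoid_strongly_attenuated(self):
        # 2nd-order Butterworth at 2x cutoff: |H| ~ 0.243, squared by the
        # forward-backward pass -> ~0.06 of input amplitude
        t = np.arange(900) / FS
        x = np.sin(2 * np.pi * 30.0 * t)
        out = filter_gaze(x)
        interior = out[200:-200]
        assert np.max(np.abs(interior)) < 0.25

    def test_missing_samples_restored_as_missing(self):
        x = np.sin(np.arange(300) / 20.0)
        x[100:110] = np.nan
        out = filter_gaze(x)
        assert np.isnan(out[100:110]).all()
        assert np.isfinite(out[:100]).all()

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            filter_gaze(np.full(100, np.nan))


class TestPredictiveGaze:
    def test_constant_positive_classifies_right(self):
        trial = make_trial(gaze_x=np.full(540, 1.0))
        mean, side = predictive_gaze(trial, prefiltered=trial.gaze_x)
        assert mean == pytest.approx(1.0) and side == "right"

    def test_constant_negative_classifies_left(self):
        trial = make_trial(gaze_x=np.full(540, -0.2))
        mean, side = predictive_gaze(trial, prefiltered=trial.gaze_x)
        assert mean == pytest.approx(-0.2) and side == "left"

    def test_window_mean_is_arithmetic(self):
        gx = np.zeros(540)
        release = 2.0
        # the half-open 50 ms window at 90 Hz covers samples 176..179
        idx = [176, 177, 178, 179]
        vals = [-0.1, 0.3, 0.4, 0.2]
        for i, v in zip(idx, vals):
            gx[i] = v
        trial = make_trial(gaze_x=gx, release=release)
        mean, side = predictive_gaze(trial, prefiltered=gx)
        assert mean == pytest.approx(0.2, abs=1e-12)
        assert side == "right"

    def test_empty_window_returns_missing(self):
        gx = np.full(540, np.nan)
        gx[:100] = 0.5
        trial = make_trial(gaze_x=gx)
        mean, side = predictive_gaze(trial, prefiltered=gx)
        assert np.isnan(mean) and side is None


class TestRecodeTowardLikely:
    def test_gaze_at_likely_hole_is_half_separation(self, geom):
        ang = recode_toward_likely(3.67, "right", geom)
        assert ang == pytest.approx(42.5, abs=1e-9)

    def test_midline_is_zero(self, geom):
        assert recode_toward_likely(0.0, "left", geom) == 0.0

    def test_offside_gaze_is_negative(self, geom):
        ang = recode_toward_likely(-0.4, "right", geom)
        assert ang == pytest.approx(-5.7034, abs=1e-3)


class TestMinGazeBallError:
    def test_identical_vectors_give_zero(self):
        n = 540
        d = np.tile([0.0, 0.0, 1.0], (n, 1))
        trial = make_trial(gaze_dir=d, ball_dir=d.copy())
        assert min_gaze_ball_error(trial) == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_vectors_give_ninety(self):
        n = 540
        g = np.tile([0.0, 0.0, 1.0], (n, 1))
        b = np.tile([1.0, 0.0, 0.0], (n, 1))
        trial = make_trial(gaze_dir=g, ball_dir=b)
        assert min_gaze_ball_error(trial) == pytest.approx(90.0, abs=1e-9)

    def test_minimum_over_hand_built_angles(self):
        n = 540
        g = np.tile([0.0, 0.0, 1.0], (n, 1))
        b = np.full((n, 3), np.nan)
        # exactly three valid frames inside the window at 40, 12 and 25 deg
        for i, ang in zip([185, 195, 205], [40.0, 12.0, 25.0]):
            r = np.radians(ang)
            b[i] = [np.sin(r), 0.0, np.cos(r)]
        trial = make_trial(gaze_dir=g, ball_dir=b)
        assert min_gaze_ball_error(trial) == pytest.approx(12.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        n = 540
        g = np.tile([0.0, 0.0, 1.0], (n, 1))
        r = np.radians(25.0)
        b = np.tile([np.sin(r), 0.0, np.cos(r)], (n, 1))
        base = min_gaze_ball_error(make_trial(gaze_dir=g, ball_dir=b))
        # random rotation applied to both streams
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rot = min_gaze_ball_error(make_trial(gaze_dir=g @ q.T, ball_dir=b @ q.T))
        assert rot == pytest.approx(base, abs=1e-9)

    def test_no_valid_frames_gives_missing(self):
        trial = make_trial()  # ball_dir all-NaN
        assert np.isnan(min_gaze_ball_error(trial))


class TestPupilPipeline:
    def test_binocular_average_of_constants(self):
        trial = make_trial(pupil_left=np.full(540, 3.0), pupil_right=np.full(540, 4.0))
        trace, missing = preprocess_pupil(trial)
        np.testing.assert_allclose(trace, 3.5, atol=1e-9)
        assert missing == 0.0

    def test_gap_on_ramp_restored_exactly(self):
        n = 540
        ramp = 3.0 + 0.001 * np.arange(n)
        valid = np.ones(n, dtype=bool)
        valid[250:268] = False  # 200 ms blink
        trial = make_trial(pupil_left=ramp.copy(), pupil_right=ramp.copy(), valid=valid)
        trace, missing = preprocess_pupil(trial)
        np.testing.assert_allclose(trace[240:280], ramp[240:280], atol=1e-6)
        assert missing > 0.0

    def test_flat_trace_has_zero_peak(self):
        trial = make_trial()
        assert pupil_surprisal_peak(trial) == pytest.approx(0.0, abs=1e-9)

    def test_constructed_bump_recovered(self):
        n = 720
        t = np.arange(n) / FS
        release, arrival = 2.0, 2.5
        bump = 3.0 + 0.4 * np.exp(-0.5 * ((t - (release + 1.0)) / 0.25) ** 2)
        trial = make_trial(n=n, pupil_left=bump.copy(), pupil_right=bump.copy(),
                           release=release, arrival=arrival)
        peak = pupil_surprisal_peak(trial)
        assert peak == pytest.approx(0.4, rel=0.02)

    def test_pre_release_bump_gives_nonpositive_peak(self):
        n = 720
        t = np.arange(n) / FS
        release = 3.0
        bump = 3.0 + 0.4 * np.exp(-0.5 * ((t - 1.0) / 0.15) ** 2)
        trial = make_trial(n=n, pupil_left=bump.copy(), pupil_right=bump.copy(),
                           release=release, arrival=release + 0.5)
        assert pupil_surprisal_peak(trial) <= 1e-9

    def test_uniform_sampling_enforced(self):
        trial = make_trial(n=100)
        with pytest.raises(ValueError):
            TrialTimeseries(
                t=np.array([0.0, 0.01, 0.5]), gaze_x=np.zeros(3),
                gaze_dir=np.tile([0, 0, 1.0], (3, 1)), ball_pos=np.full((3, 3), np.nan),
                ball_dir=np.full((3, 3), np.nan), pupil_left=np.ones(3),
                pupil_right=np.ones(3), valid_left=np.ones(3, bool),
                valid_right=np.ones(3, bool), release_time=0.1, arrival_time=0.2,
            )
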