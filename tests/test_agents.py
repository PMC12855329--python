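"""Closed-loop agent behaviour: determinism, gaze-contingent allocation,
interception statistics, pupil/gaze trace generation, ground truth."""
import numpy as np
import pandas as pd
import pytest

from pbac.agents import (
    AgentParams,
    pupil_kernel,
    simulate_binary_responses,
    simulate_session,
    synth_gaze_trace,
    synth_pupil_trace,
    volatile_binary_sequence,
)
from pbac.signals import min_gaze_ball_error, TrialTimeseries
from pbac.task_engine import CourtGeometry, ExperimentDesign, ball_flight


class TestDeterminism:
    def test_same_seed_gives_identical_sessions(self):
        a = simulate_session(AgentParams(seed=3), ExperimentDesign(), seed=3)
        b = simulate_session(AgentParams(seed=3), ExperimentDesign(), seed=3)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.ground_truth, b.ground_truth)
        key = ("pbac", 5)
        np.testing.assert_array_equal(a.timeseries[key].gaze_x, b.timeseries[key].gaze_x)
        np.testing.assert_array_equal(a.timeseries[key].pupil_left, b.timeseries[key].pupil_left)

    def test_volatile_sequence_reproducible(self):
        u1 = volatile_binary_sequence(n=150, seed=9)
        u2 = volatile_binary_sequence(n=150, seed=9)
        np.testing.assert_array_equal(u1, u2)
        assert set(np.unique(u1)) <= {0, 1} and len(u1) == 150


class TestClosedLoop:
    def test_decisive_left_gazer_yields_forty_left_releases(self):
        # a frozen belief pinned on the non-likely (left) side plus a nearly
        # deterministic response model makes the agent gaze left on every trial
        agent = AgentParams(
            generative_model="rw",
            model_params={"alpha": 0.0, "v0": 1e-6},
            response_zeta=50.0,
            gaze_noise_sd=0.01,
            blink_rate=0.0,
            seed=0,
        )
        sess = simulate_session(agent, ExperimentDesign(likely_side="right"), seed=1)
        pbac = sess.trials[sess.trials.block == "pbac"]
        assert (pbac.chosen_side == "left").all()
        assert (pbac.release_side == "left").sum() == 40
        assert (pbac.release_side == "right").sum() == 10
        # expected-labelled trials come from the gaze side, by construction
        exp = pbac[pbac.congruency_label == "expected"]
        assert (exp.release_side == "left").all()

    def test_matched_block_replays_pbac(self, default_session):
        tr = default_session.trials
        pbac = tr[tr.block == "pbac"].sort_values("trial_index")
        matched = tr[tr.block == "matched"].sort_values("trial_index")
        assert list(pbac.release_side) == list(matched.release_side)
        assert list(pbac.congruency_label) == list(matched.congruency_label)

    def test_congruent_hit_rate_within_binomial_error(self, default_session):
        tr = default_session.trials
        cong = tr[tr.congruent]
        p = default_session.agent.hit_prob_congruent
        n = len(cong)
        assert abs(cong.hit.mean() - p) < 3.0 * np.sqrt(p * (1 - p) / n)

    def test_unexpected_trials_carry_more_surprise(self, default_session):
        gt = default_session.ground_truth.merge(
            default_session.trials[["block", "trial_index", "congruency_label"]],
            on=["block", "trial_index"],
        )
        gt = gt[gt.block != "practice"]
        s = gt.groupby("congruency_label")["surprise"].mean()
        assert s["unexpected"] > s["expected"]


class TestTraces:
    def test_zero_surprise_noiseless_trace_is_flat(self):
        agent = AgentParams(pupil_noise_sd=0.0, blink_rate=0.0)
        t = np.arange(450) / 90.0
        out = synth_pupil_trace(0.0, agent, t, 2.0, np.random.default_rng(0))
        np.testing.assert_allclose(out["pupil_left"], agent.pupil_baseline, atol=1e-12)

    def test_noiseless_peak_equals_gain_times_surprise(self):
        agent = AgentParams(pupil_noise_sd=0.0, blink_rate=0.0, pupil_gain=1.0)
        t = np.arange(720) / 90.0
        out = synth_pupil_trace(0.69, agent, t, 2.0, np.random.default_rng(0))
        delta = np.nanmax(out["pupil_left"]) - agent.pupil_baseline
        assert delta == pytest.approx(0.69, rel=1e-3)

    def test_kernel_unit_peak_at_latency(self):
        t = np.linspace(0, 5, 20001)
        k = pupil_kernel(t, latency=1.0, width=0.5)
        assert np.max(k) == pytest.approx(1.0, abs=1e-6)
        assert t[np.argmax(k)] == pytest.approx(1.0, abs=1e-3)
        assert k[0] == 0.0

    def test_congruent_noiseless_zero_lag_pursuit_is_exact(self, geom):
        agent = AgentParams(gaze_noise_sd=0.0, pursuit_lag=0.0, blink_rate=0.0)
        flight = ball_flight("right", geom)
        release = 1.5
        n = int((release + flight.flight_time + 3.2) * 90) + 1
        t = np.arange(n) / 90.0
        out = synth_gaze_trace("right", flight, agent, geom, t, release,
                               np.random.default_rng(0))
        ball_pos = np.full((n, 3), np.nan)
        m = (t >= release) & (t <= release + flight.flight_time)
        ball_pos[m] = flight.position(t[m] - release)
        eye = np.array([0.0, agent.eye_height, 0.0])
        rel = ball_pos - eye
        with np.errstate(invalid="ignore"):
            ball_dir = rel / np.linalg.norm(rel, axis=1, keepdims=True)
        trial = TrialTimeseries(
            t=t, gaze_x=out["gaze_x"], gaze_dir=out["gaze_dir"], ball_pos=ball_pos,
            ball_dir=ball_dir, pupil_left=np.full(n, 3.0), pupil_right=np.full(n, 3.0),
            valid_left=np.ones(n, bool), valid_right=np.ones(n, bool),
            release_time=release, arrival_time=release + flight.flight_time,
        )
        assert min_gaze_ball_error(trial) == pytest.approx(0.0, abs=1e-6)

    def test_pre_release_fixation_near_hole(self, geom):
        agent = AgentParams(gaze_noise_sd=0.15, blink_rate=0.0, seed=0)
        flight = ball_flight("left", geom)
        t = np.arange(270) / 90.0
        out = synth_gaze_trace("left", flight, agent, geom, t, 2.5,
                               np.random.default_rng(1))
        pre = out["gaze_x"][t < 2.5]
        assert abs(np.mean(pre) - (-3.67)) < 3 * 0.15 / np.sqrt(len(pre))

    def test_incongruent_initial_error_near_hole_separation(self, geom):
        agent = AgentParams(gaze_noise_sd=0.0, pursuit_lag=0.2, blink_rate=0.0)
        flight = ball_flight("right", geom)
        release = 1.0
        n = int((release + flight.flight_time + 0.2) * 90)
        t = np.arange(n) / 90.0
        out = synth_gaze_trace("left", flight, agent, geom, t, release,
                               np.random.default_rng(0))
        i0 = int(np.searchsorted(t, release))
        gaze0 = out["gaze_dir"][i0]
        eye = np.array([0.0, agent.eye_height, 0.0])
        b = flight.position(t[i0] - release) - eye
        b = b / np.linalg.norm(b)
        ang = np.degrees(np.arccos(np.clip(np.dot(gaze0, b), -1, 1)))
        assert ang == pytest.approx(85.0, abs=2.0)


class TestValidation:
    def test_hit_probability_ordering_enforced(self):
        with pytest.raises(ValueError):
            AgentParams(hit_prob_congruent=0.3, hit_prob_incongruent=0.6)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            AgentParams(generative_model="kalman")

    def test_binary_response_path_reports_surprise(self):
        u = volatile_binary_sequence(n=40, seed=1)
        out = simulate_binary_responses(AgentParams(seed=2), u, seed=3)
        assert set(np.unique(out["y"])) <= {0, 1}
        assert np.all(out["surprise"] >= 0)
        assert np.all((out["muhat1"] > 0) & (out["muhat1"] < 1))


class TestRoundTrip:
    def test_save_load_round_trip(self, default_session, tmp_path):
        default_session.save(tmp_path / "P01")
        loaded = type(default_session).load(tmp_path / "P01")
        pd.testing.assert_frame_equal(
            loaded.trials, default_session.trials, check_dtype=False
        )
        key = ("probability", 1)
        np.testing.assert_allclose(
            loaded.timeseries[key].gaze_x,
            default_session.timeseries[key].gaze_x,
            atol=1e-9, equal_nan=True,
        )
        np.testing.assert_allclose(
            loaded.timeseries[key].ball_dir,
            default_session.timeseries[key].ball_dir,
            atol=1e-6, equal_nan=True,
        )
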