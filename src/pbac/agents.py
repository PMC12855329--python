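"""Closed-loop generative agents standing in for human participants.

An agent carries a trial-by-trial learning model (3-level HGF by default)
over the binary ball-side sequence, chooses a gaze side through the
unit-square sigmoid response model, fixates the corresponding release hole
with Gaussian positional noise, pursues the ball after release with a
configurable lag, intercepts with a congruency-dependent hit probability,
and emits a phasic pupil response scaled by the Shannon surprisal of the
observed side under its own pre-trial prediction.  Blinks appear as
contiguous missing runs in both gaze and pupil streams.

The generator exists so the whole pipeline - closed-loop allocation, signal
processing, model fitting, statistics - can be exercised end-to-end with
known ground truth and no hardware.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .learning.filters import HGFParams, HGFState, unitsq_sigmoid
from .signals import TrialTimeseries
from .task_engine import (
    BlockSchedule,
    CourtGeometry,
    ExperimentDesign,
    Side,
    TrialSpec,
    allocate_matched,
    allocate_pbac,
    ball_flight,
    build_block_schedule,
    other_side,
    schedule_to_frame,
)

__all__ = [
    "AgentParams",
    "SessionData",
    "simulate_session",
    "simulate_binary_responses",
    "volatile_binary_sequence",
    "synth_pupil_trace",
    "synth_gaze_trace",
    "pupil_kernel",
]

log = logging.getLogger(__name__)

_PRE_BUFFER = 1.0  # s of recording before the onset-delay countdown starts
_POST_ARRIVAL = 3.2  # s recorded after ball arrival (covers the 3 s peak window)


@dataclass(frozen=True)
class AgentParams:
    """Generative agent configuration.

    ``generative_model`` selects the internal learner (``hgf3``, ``hgf2`` or
    ``rw``); ``model_params`` overrides its defaults (HGF omegas / initial
    beliefs, or ``alpha``/``v0`` for Rescorla-Wagner).  ``response_zeta`` is
    the decisiveness of the side choice.  The pupil kernel is a gamma-shaped
    impulse ``(latency_to_peak_s, width_s)``; peak dilation above baseline is
    ``pupil_gain * surprisal`` for a noiseless trace.
    """

    generative_model: str = "hgf3"
    model_params: dict = field(default_factory=dict)
    response_zeta: float = 4.0
    hit_prob_congruent: float = 0.8
    hit_prob_incongruent: float = 0.4
    pursuit_lag: float = 0.12
    gaze_noise_sd: float = 0.15
    pupil_baseline: float = 3.5
    pupil_gain: float = 0.4
    pupil_kernel: tuple[float, float] = (1.0, 0.5)
    pupil_noise_sd: float = 0.02
    blink_rate: float = 10.0
    eye_height: float = 1.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hit_prob_congruent", "hit_prob_incongruent"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.hit_prob_congruent < self.hit_prob_incongruent:
            raise ValueError("hit_prob_congruent must be >= hit_prob_incongruent")
        for name in ("gaze_noise_sd", "pupil_noise_sd", "blink_rate", "pursuit_lag"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.response_zeta > 0:
            raise ValueError("response_zeta must be > 0")
        if self.generative_model not in ("hgf3", "hgf2", "rw"):
            raise ValueError(f"unsupported generative_model {self.generative_model!r}")


class _Belief:
    """Stateful wrapper unifying the agent's internal learners."""

    def __init__(self, params: AgentParams) -> None:
        self.kind = params.generative_model
        mp = dict(params.model_params)
        if self.kind in ("hgf2", "hgf3"):
            n = int(self.kind[-1])
            self.state = HGFState(HGFParams(n_levels=n, **mp))
        else:
            self.alpha = float(mp.get("alpha", 0.3))
            self.v = float(mp.get("v0", 0.5))

    def predict(self) -> float:
        """p(u = 1) before the next outcome."""
        if self.kind == "rw":
            return self.v
        return self.state.muhat1

    def update(self, u: int) -> dict:
        if self.kind == "rw":
            pred = self.v
            self.v = self.v + self.alpha * (u - self.v)
            return {
                "muhat1": pred,
                "alpha2": self.alpha,
                "eps2": self.v - pred,
                "eps3": np.nan,
            }
        rec = self.state.update(u)
        return {
            "muhat1": rec["muhat1"],
            "alpha2": rec["alpha2"],
            "eps2": rec["eps2"],
            "eps3": rec.get("eps3", np.nan),
        }


# ---------------------------------------------------------------------------
# Trace synthesis
# ---------------------------------------------------------------------------

def pupil_kernel(t: np.ndarray, latency: float, width: float) -> np.ndarray:
    """Gamma-shaped impulse with unit peak at ``t = latency``.

    ``k(t) = ((t / latency) * exp(1 - t / latency)) ** shape`` with
    ``shape = (latency / width) ** 2``; zero for ``t <= 0``.
    """
    t = np.asarray(t, dtype=float)
    shape = (latency / width) ** 2
    with np.errstate(invalid="ignore"):
        base = np.where(t > 0, (t / latency) * np.exp(1.0 - t / latency), 0.0)
    return np.where(t > 0, base**shape, 0.0)


def _blink_mask(t: np.ndarray, rate_per_min: float, rng: np.random.Generator) -> np.ndarray:
    """Contiguous missing runs of 100-300 ms at the given event rate."""
    mask = np.zeros(len(t), dtype=bool)
    if rate_per_min <= 0 or len(t) == 0:
        return mask
    duration = t[-1] - t[0]
    n_events = rng.poisson(rate_per_min * duration / 60.0)
    for _ in range(n_events):
        start = rng.uniform(t[0], t[-1])
        length = rng.uniform(0.100, 0.300)
        mask |= (t >= start) & (t < start + length)
    return mask


def synth_pupil_trace(
    surprise: float,
    params: AgentParams,
    t: np.ndarray,
    release_time: float,
    rng: np.random.Generator,
    blink: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Binocular pupil trace: baseline + gain * surprise * kernel + noise.

    Blinks (shared across eyes) become NaN samples with validity flags
    cleared.  ``surprise`` is the Shannon surprisal (nats) of the observed
    ball side under the agent's pre-trial prediction.
    """
    if surprise < 0:
        raise ValueError("surprise must be non-negative")
    latency, width = params.pupil_kernel
    signal = params.pupil_baseline + params.pupil_gain * surprise * pupil_kernel(
        t - release_time, latency, width
    )
    left = signal + params.pupil_noise_sd * rng.standard_normal(len(t))
    right = signal + params.pupil_noise_sd * rng.standard_normal(len(t))
    if blink is None:
        blink = _blink_mask(t, params.blink_rate, rng)
    left[blink] = np.nan
    right[blink] = np.nan
    valid = ~blink
    return {
        "pupil_left": left,
        "pupil_right": right,
        "valid_left": valid.copy(),
        "valid_right": valid.copy(),
        "blink": blink,
    }


def synth_gaze_trace(
    chosen_side: Side,
    flight,
    params: AgentParams,
    geom: CourtGeometry,
    t: np.ndarray,
    release_time: float,
    rng: np.random.Generator,
    blink: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Gaze streams: pre-release fixation on the chosen hole, lagged pursuit.

    Before release the gaze point sits on the chosen release hole with
    per-sample lateral noise.  From ``release + pursuit_lag`` onward the gaze
    point relaxes toward the current ball position with time constant
    ``pursuit_lag`` (instantaneous when the lag is 0), so incongruent trials
    begin with the full inter-hole angular error.  Blink samples are missing.
    """
    eye = np.array([0.0, params.eye_height, 0.0])
    D = geom.viewer_wall_distance
    fix = np.array([geom.hole_x(chosen_side), geom.hole_height, D])
    n = len(t)
    dt = float(t[1] - t[0]) if n >= 2 else 1.0 / 90.0

    points = np.empty((n, 3))
    g = fix.copy()
    relax = 1.0 if params.pursuit_lag == 0 else 1.0 - np.exp(-dt / params.pursuit_lag)
    for i, ti in enumerate(t):
        if ti < release_time + params.pursuit_lag:
            g = fix.copy()
        else:
            tau = min(ti - release_time, flight.flight_time)
            target = flight.position(tau)
            if params.pursuit_lag == 0:
                g = target.copy()
            else:
                g = g + (target - g) * relax
        points[i] = g
    noise = params.gaze_noise_sd * rng.standard_normal(n)
    points[:, 0] += noise

    # in-world x: intersection of the eye->gaze-point ray with the wall plane
    gaze_x = np.empty(n)
    prev = fix[0]
    for i in range(n):
        gz = points[i, 2]
        if gz > 0.2:
            prev = eye[0] + (points[i, 0] - eye[0]) * D / gz
        gaze_x[i] = prev

    rel = points - eye[None, :]
    gaze_dir = rel / np.linalg.norm(rel, axis=1, keepdims=True)

    if blink is None:
        blink = _blink_mask(t, params.blink_rate, rng)
    gaze_x = gaze_x.copy()
    gaze_x[blink] = np.nan
    gaze_dir[blink] = np.nan
    return {"gaze_x": gaze_x, "gaze_dir": gaze_dir, "gaze_point": points, "blink": blink}


# ---------------------------------------------------------------------------
# Fast path for recovery studies (no traces)
# ---------------------------------------------------------------------------

def volatile_binary_sequence(
    n: int = 150,
    seed: int = 0,
    p_major: float = 0.9,
    volatile_spans: tuple[tuple[int, int], ...] = ((50, 80), (130, 10**9)),
    switch_period: int = 10,
) -> np.ndarray:
    """Binary stimulus sequence with stable and volatile phases.

    Outside the volatile spans the majority side holds with probability
    ``p_major``; inside them the majority side flips every ``switch_period``
    trials.  Alternating stable and volatile regimes make the environmental
    volatility - and hence the hierarchy depth of a learner - identifiable,
    which a single stationary contingency does not; this is the input used by
    the parameter- and model-recovery studies.
    """
    rng = np.random.default_rng(seed)
    u = np.empty(n, dtype=int)
    state = 1
    for i in range(n):
        for start, stop in volatile_spans:
            if start <= i < stop and (i - start) % switch_period == 0:
                state = 1 - state
        prob = p_major if state == 1 else 1.0 - p_major
        u[i] = int(rng.random() < prob)
    return u


def simulate_binary_responses(
    params: AgentParams, u: np.ndarray, seed: int | None = None
) -> dict[str, np.ndarray]:
    """Simulate gaze-side responses to a fixed stimulus sequence.

    Runs only the learning and response models (no time series), for
    parameter- and model-recovery studies.  Returns ``y`` (binary responses),
    the prediction sequence ``muhat1`` and per-trial surprisal.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    belief = _Belief(params)
    u = np.asarray(u)
    y = np.empty(len(u), dtype=int)
    muhat1 = np.empty(len(u))
    surprise = np.empty(len(u))
    for i, ui in enumerate(u):
        m = belief.predict()
        muhat1[i] = m
        p1 = float(unitsq_sigmoid(m, params.response_zeta))
        y[i] = int(rng.random() < p1)
        p_obs = m if ui == 1 else 1.0 - m
        surprise[i] = -np.log(max(p_obs, 1e-12))
        belief.update(int(ui))
    return {"y": y, "muhat1": muhat1, "surprise": surprise}


# ---------------------------------------------------------------------------
# Full closed-loop session
# ---------------------------------------------------------------------------

@dataclass
class SessionData:
    """Everything produced by one simulated participant session.

    ``trials`` has one row per trial across all blocks; ``timeseries`` maps
    ``(block, trial_index)`` to the 90 Hz streams; ``ground_truth`` holds the
    agent's internal states and injected surprisal for recovery tests.
    """

    participant_id: str
    design: ExperimentDesign
    agent: AgentParams
    trials: pd.DataFrame
    timeseries: dict[tuple[str, int], TrialTimeseries]
    ground_truth: pd.DataFrame
    schedules: dict[str, BlockSchedule]

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(out / "trials.csv", index=False)
        frames = []
        for (block, idx), ts in self.timeseries.items():
            df = ts.to_frame(idx)
            df.insert(0, "block", block)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(out / "timeseries.csv", index=False)
        sidecar = {
            "participant_id": self.participant_id,
            "agent": asdict(self.agent),
            "likely_side": self.design.likely_side,
            "eye_height": self.agent.eye_height,
            "ground_truth": self.ground_truth.to_dict(orient="list"),
        }
        (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, in_dir: str | Path) -> "SessionData":
        src = Path(in_dir)
        trials = pd.read_csv(src / "trials.csv")
        long = pd.read_csv(src / "timeseries.csv")
        sidecar = json.loads((src / "ground_truth.json").read_text())
        agent_d = sidecar["agent"]
        agent_d["pupil_kernel"] = tuple(agent_d["pupil_kernel"])
        agent = AgentParams(**agent_d)
        design = ExperimentDesign(likely_side=sidecar["likely_side"])
        eye = np.array([0.0, sidecar["eye_height"], 0.0])
        timeseries = {}
        for (block, idx), df in long.groupby(["block", "trial_index"], sort=False):
            row = trials[(trials.block == block) & (trials.trial_index == idx)].iloc[0]
            timeseries[(block, int(idx))] = TrialTimeseries.from_frame(
                df.reset_index(drop=True),
                release_time=float(row.release_time_s),
                arrival_time=float(row.arrival_time_s),
                eye_origin=eye,
            )
        gt = pd.DataFrame(sidecar["ground_truth"])
        return cls(
            participant_id=sidecar["participant_id"],
            design=design,
            agent=agent,
            trials=trials,
            timeseries=timeseries,
            ground_truth=gt,
            schedules={},
        )


def _simulate_trial(
    spec: TrialSpec,
    belief: _Belief,
    agent: AgentParams,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> tuple[dict, TrialTimeseries, dict]:
    geom = design.geometry
    fs = design.sample_rate
    dt = 1.0 / fs
    likely = spec.likely_side

    muhat1 = belief.predict()  # p(ball on likely side)
    p_choose_likely = float(unitsq_sigmoid(muhat1, agent.response_zeta))
    chooses_likely = rng.random() < p_choose_likely
    chosen_side: Side = likely if chooses_likely else other_side(likely)

    release_time = _PRE_BUFFER + spec.onset_delay
    # flight duration is side-symmetric; solve once for the actual side later
    probe_flight = ball_flight("left", geom, dt=dt)
    duration = release_time + probe_flight.flight_time + _POST_ARRIVAL
    n = int(np.floor(duration * fs)) + 1
    t = np.arange(n) * dt
    blink = _blink_mask(t, agent.blink_rate, rng)

    # pre-release fixation samples decide the PbAC gate
    fix_x = geom.hole_x(chosen_side)
    pre_gaze = fix_x + agent.gaze_noise_sd * rng.standard_normal(n)

    if spec.release_side is not None:
        release_side = spec.release_side
        gate_gaze = np.nan
    else:
        gate_t = release_time - 0.05
        gate_idx = int(np.floor(gate_t * fs))
        idx = gate_idx
        while idx >= 0 and blink[idx]:
            idx -= 1
        if idx < 0:
            log.warning("no valid gate gaze sample; falling back to fixation target")
            gate_gaze = fix_x
        else:
            if idx != gate_idx:
                log.info("gate gaze sample missing; using last valid sample")
            gate_gaze = float(pre_gaze[idx])
        release_side = allocate_pbac(gate_gaze, spec.congruency_label)

    flight = ball_flight(release_side, geom, dt=dt)
    arrival_time = release_time + flight.flight_time

    congruent = chosen_side == release_side
    u = 1 if release_side == likely else 0
    p_obs = muhat1 if u == 1 else 1.0 - muhat1
    surprise = -float(np.log(max(p_obs, 1e-12)))
    hit = bool(
        rng.random() < (agent.hit_prob_congruent if congruent else agent.hit_prob_incongruent)
    )

    gaze = synth_gaze_trace(chosen_side, flight, agent, geom, t, release_time, rng, blink=blink)
    pupil = synth_pupil_trace(surprise, agent, t, release_time, rng, blink=blink)

    ball_pos = np.full((n, 3), np.nan)
    in_flight = (t >= release_time) & (t <= arrival_time)
    ball_pos[in_flight] = flight.position(t[in_flight] - release_time)
    eye = np.array([0.0, agent.eye_height, 0.0])
    rel = ball_pos - eye[None, :]
    with np.errstate(invalid="ignore"):
        ball_dir = rel / np.linalg.norm(rel, axis=1, keepdims=True)

    ts = TrialTimeseries(
        t=t,
        gaze_x=gaze["gaze_x"],
        gaze_dir=gaze["gaze_dir"],
        ball_pos=ball_pos,
        ball_dir=ball_dir,
        pupil_left=pupil["pupil_left"],
        pupil_right=pupil["pupil_right"],
        valid_left=pupil["valid_left"],
        valid_right=pupil["valid_right"],
        release_time=release_time,
        arrival_time=arrival_time,
        fs=fs,
    )

    rec = belief.update(u)
    y = 1 if chooses_likely else 0
    row = {
        "trial_index": spec.trial_index,
        "block": spec.block,
        "condition": spec.block,
        "congruency_label": spec.congruency_label,
        "release_side": release_side,
        "onset_delay_s": spec.onset_delay,
        "likely_side": likely,
        "chosen_side": chosen_side,
        "gate_gaze_x_m": gate_gaze,
        "u": u,
        "y": y,
        "hit": hit,
        "congruent": congruent,
        "release_time_s": release_time,
        "arrival_time_s": arrival_time,
    }
    truth = {
        "block": spec.block,
        "trial_index": spec.trial_index,
        "muhat1": rec["muhat1"],
        "surprise": surprise,
        "alpha2": rec["alpha2"],
        "eps2": rec["eps2"],
        "eps3": rec["eps3"],
        "p_choose_likely": p_choose_likely,
    }
    return row, ts, truth


def simulate_session(
    agent: AgentParams, design: ExperimentDesign, seed: int, participant_id: str = "P00"
) -> SessionData:
    """Run practice plus the three experimental blocks for one agent.

    Block order is fixed (practice, probability-controlled, gaze-contingent,
    matched-order).  The gaze-contingent block resolves each release side
    from the agent's own gate-time gaze sample; the matched block replays
    that block's sides and inherits its labels.  Identical ``(agent, design,
    seed)`` yield bit-identical output.
    """
    rng = np.random.default_rng(seed)
    block_seeds = design.block_seeds(seed)
    belief = _Belief(agent)

    schedules: dict[str, BlockSchedule] = {
        "practice": build_block_schedule(
            "practice", design.likely_side, block_seeds["practice"],
            n_trials=design.n_practice, n_unexpected=design.n_practice_unexpected,
        ),
        "probability": build_block_schedule(
            "probability", design.likely_side, block_seeds["probability"],
            n_trials=design.n_trials, n_unexpected=design.n_unexpected,
        ),
        "pbac": build_block_schedule(
            "pbac", design.likely_side, block_seeds["pbac"],
            n_trials=design.n_trials, n_unexpected=design.n_unexpected,
        ),
    }

    rows: list[dict] = []
    truths: list[dict] = []
    timeseries: dict[tuple[str, int], TrialTimeseries] = {}

    for block in ("practice", "probability", "pbac"):
        sched = schedules[block]
        for spec in sched.trials:
            row, ts, truth = _simulate_trial(spec, belief, agent, design, rng)
            spec.release_side = row["release_side"]
            rows.append(row)
            truths.append(truth)
            timeseries[(block, spec.trial_index)] = ts

    schedules["matched"] = allocate_matched(schedules["pbac"])
    for spec in schedules["matched"].trials:
        row, ts, truth = _simulate_trial(spec, belief, agent, design, rng)
        rows.append(row)
        truths.append(truth)
        timeseries[("matched", spec.trial_index)] = ts

    return SessionData(
        participant_id=participant_id,
        design=design,
        agent=agent,
        trials=pd.DataFrame(rows),
        timeseries=timeseries,
        ground_truth=pd.DataFrame(truths),
        schedules=schedules,
    )
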