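"""Virtual racquetball court: geometry, trial scheduling, allocation, ball flight.

The task environment is an indoor court in which a ball is projected from one
of two release holes on the front wall and must be intercepted with a virtual
racquet near the viewer.  The coordinate frame has its origin at the court
midline at floor level: x lateral (positive = right), y up, z toward the front
wall.  The viewer stands at z = 0; the wall sits at the distance implied by the
two printed hole/angle pairs (holes 3.67 m from the midline, ~85 degrees of
visual angle apart), which this module derives explicitly.

Three allocation rules decide the release side on each trial:

* ``probability``  - an 80/20 cue-outcome contingency toward a counterbalanced
  "likely" side (conventional associative-learning design),
* ``pbac``         - gaze-contingent: the side matches (expected trials) or
  opposes (unexpected trials) the participant's gaze side sampled 50 ms before
  ball release,
* ``matched``      - replays the pbac block's release sides and expectedness
  labels trial-by-trial, isolating sequence effects.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "Side",
    "BlockName",
    "CourtGeometry",
    "TrialSpec",
    "BlockSchedule",
    "ExperimentDesign",
    "derive_viewer_distance",
    "visual_angle",
    "make_congruency_schedule",
    "build_block_schedule",
    "allocate_probability_controlled",
    "allocate_pbac",
    "allocate_matched",
    "ball_flight",
    "BallFlight",
    "other_side",
    "schedule_to_frame",
]

log = logging.getLogger(__name__)

Side = Literal["left", "right"]
BlockName = Literal["practice", "probability", "pbac", "matched"]

_SIDE_SIGN = {"left": -1.0, "right": 1.0}


def other_side(side: Side) -> Side:
    return "left" if side == "right" else "right"


def side_sign(side: Side) -> float:
    return _SIDE_SIGN[side]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def derive_viewer_distance(hole_offset: float, separation: float) -> float:
    """Viewer-to-wall distance from hole offset and angular hole separation.

    Solves ``2 * atan(hole_offset / d) = separation`` for ``d`` in closed form.
    The wall distance is never stated directly by the design; it is forced by
    the lateral hole offset and the angular separation between the two holes.

    Parameters
    ----------
    hole_offset
        Lateral distance of each release hole from the court midline (m), > 0.
    separation
        Full angle between the sight lines to the two holes (degrees),
        strictly inside (0, 180).
    """
    if not (math.isfinite(hole_offset) and math.isfinite(separation)):
        raise ValueError("hole_offset and separation must be finite")
    if hole_offset <= 0:
        raise ValueError(f"hole_offset must be > 0, got {hole_offset}")
    if not 0.0 < separation < 180.0:
        raise ValueError(f"separation must lie in (0, 180) degrees, got {separation}")
    return hole_offset / math.tan(math.radians(separation) / 2.0)


def visual_angle(lateral_offset: float, distance: float) -> float:
    """Signed visual angle (degrees) of a lateral offset seen from ``distance``.

    ``atan(lateral_offset / distance)``; the sign of the offset is preserved so
    that left/right of the midline map to negative/positive angles.
    """
    if not distance > 0:
        raise ValueError(f"distance must be > 0, got {distance}")
    return math.degrees(math.atan(lateral_offset / distance))


@dataclass(frozen=True)
class CourtGeometry:
    """Dimensions of the virtual court and ball-flight constants.

    ``viewer_wall_distance`` defaults to the value derived from
    ``hole_lateral_offset`` and ``hole_separation_deg``; if supplied
    explicitly it must be consistent with that derivation to within 0.01 m.
    ``hole_height`` defaults to the interception height (chest height); the
    design leaves it unstated, so it is configurable.
    """

    hole_lateral_offset: float = 3.67
    hole_separation_deg: float = 85.0
    viewer_wall_distance: Optional[float] = None
    hole_height: float = 1.5
    interception_height: float = 1.5
    interception_lateral_offset: float = 0.75
    ball_diameter: float = 0.057
    racquet_half_axes: tuple[float, float] = (0.3, 0.15)
    ball_mean_speed: float = 10.0
    gravity: float = 9.81

    def __post_init__(self) -> None:
        for name in (
            "hole_lateral_offset",
            "hole_height",
            "interception_height",
            "interception_lateral_offset",
            "ball_diameter",
            "ball_mean_speed",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.gravity < 0:
            raise ValueError("gravity must be >= 0")
        if any(a <= 0 for a in self.racquet_half_axes):
            raise ValueError("racquet_half_axes must be strictly positive")
        derived = derive_viewer_distance(self.hole_lateral_offset, self.hole_separation_deg)
        if self.viewer_wall_distance is None:
            object.__setattr__(self, "viewer_wall_distance", derived)
        elif abs(self.viewer_wall_distance - derived) > 0.01:
            raise ValueError(
                f"viewer_wall_distance {self.viewer_wall_distance:.4f} m inconsistent "
                f"with hole geometry (derived {derived:.4f} m)"
            )

    def hole_x(self, side: Side) -> float:
        return side_sign(side) * self.hole_lateral_offset


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

@dataclass
class TrialSpec:
    """One scheduled trial.

    ``release_side`` is fixed at scheduling time for probability-controlled
    and matched blocks; for the gaze-contingent (pbac) block it is ``None``
    until the closed loop resolves it at run time.
    """

    trial_index: int
    block: BlockName
    congruency_label: Literal["expected", "unexpected"]
    release_side: Optional[Side]
    onset_delay: float
    likely_side: Side

    def __post_init__(self) -> None:
        if not 0.0 <= self.onset_delay <= 5.0:
            raise ValueError(f"onset_delay must lie in [0, 5] s, got {self.onset_delay}")


@dataclass
class BlockSchedule:
    """Ordered trial sequence for one block, reproducible from its seed."""

    block: BlockName
    trials: list[TrialSpec]
    seed: int

    @property
    def n_expected(self) -> int:
        return sum(t.congruency_label == "expected" for t in self.trials)

    @property
    def n_unexpected(self) -> int:
        return sum(t.congruency_label == "unexpected" for t in self.trials)

    def __len__(self) -> int:
        return len(self.trials)

    def is_complete(self) -> bool:
        return len(self.trials) > 0 and all(t.release_side is not None for t in self.trials)


def make_congruency_schedule(n_trials: int, n_unexpected: int, seed: int) -> list[str]:
    """Pseudo-random permutation of expected/unexpected labels.

    Exactly ``n_unexpected`` trials are labelled unexpected (a fixed-count
    design, not iid draws); the permutation is reproducible from ``seed``.
    """
    if n_trials < 0 or not 0 <= n_unexpected <= n_trials:
        raise ValueError(f"invalid counts: n_trials={n_trials}, n_unexpected={n_unexpected}")
    labels = np.array(
        ["unexpected"] * n_unexpected + ["expected"] * (n_trials - n_unexpected), dtype=object
    )
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return list(labels)


def allocate_probability_controlled(label: str, likely_side: Side) -> Side:
    """Block-1 rule: expected trials come from the likely side, unexpected from the other."""
    return likely_side if label == "expected" else other_side(likely_side)


def allocate_pbac(gaze_x_at_gate: float, label: str) -> Side:
    """Gaze-contingent rule from the gate-time horizontal in-world gaze position.

    Gaze side is right for ``gaze_x > 0`` and left for ``gaze_x < 0``; an exact
    0 resolves to left (and is logged, since the rule is stated only for strict
    inequalities).  Expected trials release from the gaze side, unexpected
    trials from the opposite side.
    """
    if not math.isfinite(gaze_x_at_gate):
        raise ValueError(f"gate gaze sample must be finite, got {gaze_x_at_gate}")
    if gaze_x_at_gate == 0.0:
        log.info("gate gaze exactly at midline; classifying as left")
    gaze_side: Side = "right" if gaze_x_at_gate > 0 else "left"
    return gaze_side if label == "expected" else other_side(gaze_side)


def allocate_matched(pbac_block: BlockSchedule) -> BlockSchedule:
    """Block-3 schedule: replay the pbac block's sides and inherit its labels."""
    if not pbac_block.is_complete():
        raise ValueError("source pbac block is empty or has unresolved release sides")
    trials = [
        replace(t, block="matched") for t in pbac_block.trials
    ]
    return BlockSchedule(block="matched", trials=trials, seed=pbac_block.seed)


def build_block_schedule(
    block: BlockName,
    likely_side: Side,
    seed: int,
    n_trials: int = 50,
    n_unexpected: int = 10,
) -> BlockSchedule:
    """Build a block schedule: labels, onset delays and (where fixed) sides.

    Onset delays are drawn uniformly on [0, 5] s.  Practice blocks default to
    10 trials with an 8/2 split when built via :class:`ExperimentDesign`.
    """
    labels = make_congruency_schedule(n_trials, n_unexpected, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xDE1A]))
    delays = rng.uniform(0.0, 5.0, size=n_trials)
    trials = []
    for i, (label, delay) in enumerate(zip(labels, delays), start=1):
        if block in ("practice", "probability"):
            side: Optional[Side] = allocate_probability_controlled(label, likely_side)
        else:
            side = None
        trials.append(
            TrialSpec(
                trial_index=i,
                block=block,
                congruency_label=label,
                release_side=side,
                onset_delay=float(delay),
                likely_side=likely_side,
            )
        )
    return BlockSchedule(block=block, trials=trials, seed=seed)


@dataclass(frozen=True)
class ExperimentDesign:
    """Session-level design: block sizes, counterbalance side, geometry."""

    geometry: CourtGeometry = field(default_factory=CourtGeometry)
    likely_side: Side = "right"
    n_trials: int = 50
    n_unexpected: int = 10
    n_practice: int = 10
    n_practice_unexpected: int = 2
    sample_rate: float = 90.0

    def block_seeds(self, seed: int) -> dict[str, int]:
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(4)
        names = ["practice", "probability", "pbac", "matched"]
        return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def schedule_to_frame(schedule: BlockSchedule, condition: Optional[str] = None) -> pd.DataFrame:
    """Columnar view of a schedule (one row per trial)."""
    cond = condition if condition is not None else schedule.block
    return pd.DataFrame(
        {
            "trial_index": [t.trial_index for t in schedule.trials],
            "block": [t.block for t in schedule.trials],
            "condition": [cond] * len(schedule.trials),
            "congruency_label": [t.congruency_label for t in schedule.trials],
            "release_side": [t.release_side for t in schedule.trials],
            "onset_delay_s": [t.onset_delay for t in schedule.trials],
            "likely_side": [t.likely_side for t in schedule.trials],
        }
    )


# ---------------------------------------------------------------------------
# Ball flight
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BallFlight:
    """A solved ballistic trajectory sampled on a uniform grid.

    The ball leaves the release hole and passes through the interception point
    (0.75 m lateral on the release side, 1.5 m high, at the viewer plane).
    Lateral and depth velocities are constant; height follows gravity, with
    the initial vertical velocity chosen so the end point is hit exactly.  The
    flight time solves ``arc_length / T = ball_mean_speed``.
    """

    release_pos: np.ndarray
    target_pos: np.ndarray
    flight_time: float
    mean_speed: float
    t: np.ndarray
    pos: np.ndarray
    gravity: float

    def position(self, t: float | np.ndarray) -> np.ndarray:
        """Position(s) at time(s) since release, valid on [0, flight_time]."""
        t = np.asarray(t, dtype=float)
        T = self.flight_time
        frac = t / T
        x = self.release_pos[0] + (self.target_pos[0] - self.release_pos[0]) * frac
        z = self.release_pos[2] + (self.target_pos[2] - self.release_pos[2]) * frac
        vy0 = (self.target_pos[1] - self.release_pos[1]) / T + self.gravity * T / 2.0
        y = self.release_pos[1] + vy0 * t - 0.5 * self.gravity * t**2
        return np.stack([x, y, z], axis=-1)


def _arc_length(T: float, dxz: float, dy: float, g: float) -> float:
    """Arc length of the parabola over [0, T]; dxz is in-plane horizontal distance."""
    vh = dxz / T
    vy0 = dy / T + g * T / 2.0

    def speed(t: float) -> float:
        return math.hypot(vh, vy0 - g * t)

    val, _ = quad(speed, 0.0, T, limit=200)
    return val


def ball_flight(
    release_side: Side | TrialSpec,
    geom: CourtGeometry,
    dt: float = 1.0 / 90.0,
) -> BallFlight:
    """Solve and sample one ball trajectory.

    Parameters
    ----------
    release_side
        ``"left"``/``"right"``, or a :class:`TrialSpec` whose ``release_side``
        is used.
    geom
        Court geometry (supplies end points, mean speed and gravity).
    dt
        Sampling interval (s), default one 90 Hz frame.

    Raises
    ------
    ValueError
        If the end point is unreachable at the configured mean speed, or the
        inputs are degenerate.
    """
    if isinstance(release_side, TrialSpec):
        if release_side.release_side is None:
            raise ValueError("trial has no resolved release side")
        side = release_side.release_side
    else:
        side = release_side
    if dt <= 0:
        raise ValueError("dt must be > 0")

    s = side_sign(side)
    p0 = np.array([s * geom.hole_lateral_offset, geom.hole_height, geom.viewer_wall_distance])
    p1 = np.array([s * geom.interception_lateral_offset, geom.interception_height, 0.0])
    dxz = math.hypot(p1[0] - p0[0], p1[2] - p0[2])
    dy = p1[1] - p0[1]
    chord = math.hypot(dxz, dy)
    v = geom.ball_mean_speed
    g = geom.gravity

    T0 = chord / v
    if g == 0.0:
        T = T0
    else:
        def f(T: float) -> float:
            return _arc_length(T, dxz, dy, g) / T - v

        # mean speed exceeds v at the chord time (arc > chord under gravity);
        # it dips below v on the flatter branch before the sag-dominated rise
        res = minimize_scalar(
            lambda T: _arc_length(T, dxz, dy, g) / T, bracket=None,
            bounds=(T0, 20.0 * T0), method="bounded",
            options={"xatol": 1e-10},
        )
        if not res.success or f(res.x) > 0.0:
            raise ValueError(
                f"interception point unreachable at mean speed {v} m/s under gravity {g}"
            )
        T = brentq(f, T0, res.x, xtol=1e-12, rtol=8.9e-16)

    arc = _arc_length(T, dxz, dy, g) if g > 0 else chord
    n = int(math.floor(T / dt))
    grid = np.unique(np.append(np.arange(n + 1) * dt, T))
    flight = BallFlight(
        release_pos=p0,
        target_pos=p1,
        flight_time=float(T),
        mean_speed=float(arc / T),
        t=grid,
        pos=np.empty((len(grid), 3)),
        gravity=g,
    )
    object.__setattr__(flight, "pos", flight.position(grid))
    return flight
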