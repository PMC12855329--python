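"""Offline gaze and pupillometry processing.

Gaze streams are denoised with a three-frame moving median followed by a
zero-phase second-order low-pass Butterworth filter (15 Hz cutoff); pupil
streams have blinks padded by 150 ms per side and bridged by a least-squares
line before a zero-phase 10 Hz low-pass and binocular averaging.  Data are
recorded at a constant 90 Hz and never resampled.

Derived per-trial measures:

* predictive gaze - the filtered horizontal in-world gaze coordinate averaged
  over the final 50 ms before ball release, classified left (< 0) / right
  (> 0), optionally recoded as a signed visual angle toward the likely side,
* minimum gaze-ball angular error between release and ball contact,
* the baseline-corrected peak pupil dilation after release (surprisal index).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt, medfilt

from .task_engine import CourtGeometry, Side, visual_angle

__all__ = [
    "TrialTimeseries",
    "TrialMetrics",
    "filter_gaze",
    "predictive_gaze",
    "recode_toward_likely",
    "min_gaze_ball_error",
    "preprocess_pupil",
    "pupil_surprisal_peak",
    "compute_trial_metrics",
]

log = logging.getLogger(__name__)


@dataclass
class TrialTimeseries:
    """90 Hz per-trial streams with validity flags and event times.

    ``gaze_dir`` and ``ball_dir`` are unit vectors from the headset origin
    (yaw/pitch frame); ``ball_pos``/``ball_dir`` are NaN outside the flight
    window.  ``valid_left``/``valid_right`` flag usable eye samples (False
    during blinks and dropouts).
    """

    t: np.ndarray
    gaze_x: np.ndarray
    gaze_dir: np.ndarray
    ball_pos: np.ndarray
    ball_dir: np.ndarray
    pupil_left: np.ndarray
    pupil_right: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray
    release_time: float
    arrival_time: float
    fs: float = 90.0

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("gaze_x", "pupil_left", "pupil_right", "valid_left", "valid_right"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length mismatch")
        if self.gaze_dir.shape != (n, 3) or self.ball_dir.shape != (n, 3):
            raise ValueError("direction arrays must be (n, 3)")
        dt = np.diff(self.t)
        if len(dt) and not np.allclose(dt, 1.0 / self.fs, atol=1e-6):
            raise ValueError("sampling must be uniform at fs (no resampling)")
        norms = np.linalg.norm(self.gaze_dir, axis=1)
        ok = np.isfinite(norms)
        if ok.any() and not np.allclose(norms[ok], 1.0, atol=1e-6):
            raise ValueError("gaze_dir must hold unit vectors")

    def to_frame(self, trial_index: int) -> pd.DataFrame:
        """Long-format row block for the session timeseries CSV."""
        yaw = np.degrees(np.arctan2(self.gaze_dir[:, 0], self.gaze_dir[:, 2]))
        pitch = np.degrees(np.arcsin(np.clip(self.gaze_dir[:, 1], -1, 1)))
        return pd.DataFrame(
            {
                "trial_index": trial_index,
                "t_s": self.t,
                "gaze_x_m": self.gaze_x,
                "gaze_yaw_deg": yaw,
                "gaze_pitch_deg": pitch,
                "ball_x_m": self.ball_pos[:, 0],
                "ball_y_m": self.ball_pos[:, 1],
                "ball_z_m": self.ball_pos[:, 2],
                "pupil_left_mm": self.pupil_left,
                "pupil_right_mm": self.pupil_right,
                "valid_left": self.valid_left.astype(int),
                "valid_right": self.valid_right.astype(int),
            }
        )

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        release_time: float,
        arrival_time: float,
        eye_origin: np.ndarray,
        fs: float = 90.0,
    ) -> "TrialTimeseries":
        yaw = np.radians(df["gaze_yaw_deg"].to_numpy())
        pitch = np.radians(df["gaze_pitch_deg"].to_numpy())
        gaze_dir = np.stack(
            [np.cos(pitch) * np.sin(yaw), np.sin(pitch), np.cos(pitch) * np.cos(yaw)], axis=1
        )
        ball_pos = df[["ball_x_m", "ball_y_m", "ball_z_m"]].to_numpy()
        rel = ball_pos - eye_origin[None, :]
        with np.errstate(invalid="ignore"):
            ball_dir = rel / np.linalg.norm(rel, axis=1, keepdims=True)
        return cls(
            t=df["t_s"].to_numpy(),
            gaze_x=df["gaze_x_m"].to_numpy(),
            gaze_dir=gaze_dir,
            ball_pos=ball_pos,
            ball_dir=ball_dir,
            pupil_left=df["pupil_left_mm"].to_numpy(),
            pupil_right=df["pupil_right_mm"].to_numpy(),
            valid_left=df["valid_left"].to_numpy().astype(bool),
            valid_right=df["valid_right"].to_numpy().astype(bool),
            release_time=release_time,
            arrival_time=arrival_time,
            fs=fs,
        )


@dataclass
class TrialMetrics:
    """Derived per-trial measures (missing metrics are NaN)."""

    predictive_gaze_x: float
    predicted_side: Optional[Side]
    predictive_gaze_toward_likely: float
    min_gaze_ball_error: float
    pupil_peak_delta: float
    missing_fraction: float
    hit: Optional[bool]


# ---------------------------------------------------------------------------
# Gaze
# ---------------------------------------------------------------------------

def _fill_nan_linear(x: np.ndarray) -> np.ndarray:
    """Linear interpolation over interior NaNs; edge NaNs take nearest valid."""
    x = x.astype(float).copy()
    ok = np.isfinite(x)
    if ok.all():
        return x
    idx = np.arange(len(x))
    x[~ok] = np.interp(idx[~ok], idx[ok], x[ok])
    return x


def filter_gaze(series: np.ndarray, fs: float = 90.0, cutoff: float = 15.0) -> np.ndarray:
    """Denoise a gaze coordinate stream.

    Three-frame moving median then a zero-phase (forward-backward)
    second-order low-pass Butterworth at ``cutoff``.  Missing samples are
    bridged for filtering and restored as missing afterwards.
    """
    x = np.asarray(series, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        raise ValueError("all samples missing")
    filled = _fill_nan_linear(x)
    med = medfilt(filled, kernel_size=3)
    b, a = butter(2, cutoff, btype="low", fs=fs)
    out = filtfilt(b, a, med)
    out[~ok] = np.nan
    return out


def predictive_gaze(
    trial: TrialTimeseries, window: float = 0.05, prefiltered: np.ndarray | None = None
) -> tuple[float, Optional[Side]]:
    """Mean filtered gaze_x over [release - window, release), with its side.

    A mean of exactly 0 classifies as left (and is logged).  Returns
    ``(nan, None)`` when no valid sample falls in the window.
    """
    gx = prefiltered if prefiltered is not None else filter_gaze(trial.gaze_x, fs=trial.fs)
    mask = (trial.t >= trial.release_time - window) & (trial.t < trial.release_time)
    vals = gx[mask]
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        log.info("predictive-gaze window empty; metric missing for trial")
        return float("nan"), None
    mean = float(np.mean(vals))
    if mean == 0.0:
        log.info("predictive gaze exactly at midline; classifying as left")
    side: Side = "right" if mean > 0 else "left"
    return mean, side


def recode_toward_likely(gaze_x: float, likely_side: Side, geom: CourtGeometry) -> float:
    """Signed visual angle of a gaze coordinate, positive toward the likely side."""
    if not math.isfinite(gaze_x):
        return float("nan")
    mag = visual_angle(abs(gaze_x), geom.viewer_wall_distance)
    gaze_side: Side = "right" if gaze_x > 0 else "left"
    return mag if gaze_side == likely_side or gaze_x == 0.0 else -mag


# ---------------------------------------------------------------------------
# Gaze-ball angular error
# ---------------------------------------------------------------------------

def min_gaze_ball_error(
    trial: TrialTimeseries, end_time: float | None = None
) -> float:
    """Minimum per-frame angle (degrees) between gaze and ball unit vectors.

    The window runs from release to ball contact (``arrival_time`` by
    default; pass ``end_time`` to stop where the ball first passed the
    racquet on misses).  Frames with an invalid vector are skipped; NaN is
    returned when no frame is valid.
    """
    end = trial.arrival_time if end_time is None else end_time
    mask = (trial.t >= trial.release_time) & (trial.t <= end)
    g = trial.gaze_dir[mask]
    b = trial.ball_dir[mask]
    ok = np.isfinite(g).all(axis=1) & np.isfinite(b).all(axis=1)
    if not ok.any():
        return float("nan")
    dots = np.clip(np.sum(g[ok] * b[ok], axis=1), -1.0, 1.0)
    return float(np.degrees(np.arccos(dots)).min())


# ---------------------------------------------------------------------------
# Pupil
# ---------------------------------------------------------------------------

def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    runs = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _interp_gap_lsq(x: np.ndarray, start: int, stop: int, flank: int) -> None:
    """Fill x[start:stop] with a least-squares line over flanking valid samples."""
    n = len(x)
    left = np.arange(max(0, start - flank), start)
    right = np.arange(stop, min(n, stop + flank))
    support = np.concatenate([left, right])
    support = support[np.isfinite(x[support])]
    gap = np.arange(start, stop)
    if len(support) == 0:
        return  # unfillable (edge gap with no flank); stays NaN
    if len(support) == 1 or np.ptp(support) == 0:
        x[gap] = x[support[0]]
        return
    coef = np.polyfit(support.astype(float), x[support], 1)
    x[gap] = np.polyval(coef, gap.astype(float))


def _preprocess_one_eye(
    pupil: np.ndarray,
    valid: np.ndarray,
    fs: float,
    pad_s: float = 0.150,
    flank_s: float = 0.100,
    cutoff: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pad blinks, bridge gaps with least-squares lines, low-pass filter.

    Returns the filtered trace and the post-padding missing mask.
    """
    x = np.asarray(pupil, dtype=float).copy()
    x[~np.asarray(valid, dtype=bool)] = np.nan
    missing = ~np.isfinite(x)
    pad = int(round(pad_s * fs))
    flank = int(round(flank_s * fs))
    padded = missing.copy()
    for start, stop in _nan_runs(missing):
        padded[max(0, start - pad):min(len(x), stop + pad)] = True
    x[padded] = np.nan
    for start, stop in _nan_runs(padded):
        _interp_gap_lsq(x, start, stop, flank)
    still = ~np.isfinite(x)
    if still.all():
        raise ValueError("pupil trace entirely missing after padding")
    if still.any():
        x = _fill_nan_linear(x)  # edge gaps: nearest-valid extension for filtering
    b, a = butter(2, cutoff, btype="low", fs=fs)
    out = filtfilt(b, a, x)
    out[still] = np.nan
    return out, padded


def preprocess_pupil(trial: TrialTimeseries) -> tuple[np.ndarray, float]:
    """Blink-pad, interpolate, low-pass and binocularly average pupil diameter.

    Returns the mean-of-eyes trace (mm) and the missing fraction (proportion
    of samples flagged missing after 150 ms padding, averaged over eyes) used
    by the trial-discard rule.
    """
    left, miss_l = _preprocess_one_eye(trial.pupil_left, trial.valid_left, trial.fs)
    right, miss_r = _preprocess_one_eye(trial.pupil_right, trial.valid_right, trial.fs)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.stack([left, right]), axis=0)
    missing_fraction = float((miss_l.mean() + miss_r.mean()) / 2.0)
    return mean, missing_fraction


def pupil_surprisal_peak(
    trial: TrialTimeseries,
    trace: np.ndarray | None = None,
    baseline_window: float = 0.200,
    post_arrival: float = 3.0,
) -> float:
    """Baseline-corrected peak dilation after ball release.

    Peak over [release, arrival + 3 s] minus the mean over the 200 ms before
    release.  NaN when either window has no valid coverage.
    """
    x = trace if trace is not None else preprocess_pupil(trial)[0]
    t = trial.t
    base_mask = (t >= trial.release_time - baseline_window) & (t < trial.release_time)
    peak_mask = (t >= trial.release_time) & (t <= trial.arrival_time + post_arrival)
    base = x[base_mask]
    base = base[np.isfinite(base)]
    peak = x[peak_mask]
    peak = peak[np.isfinite(peak)]
    if len(base) == 0 or len(peak) == 0:
        return float("nan")
    return float(np.max(peak) - np.mean(base))


# ---------------------------------------------------------------------------
# Per-trial metrics
# ---------------------------------------------------------------------------

def compute_trial_metrics(
    trial: TrialTimeseries,
    geom: CourtGeometry,
    likely_side: Side,
    hit: Optional[bool] = None,
) -> TrialMetrics:
    """All derived measures for one trial."""
    gx_filt = filter_gaze(trial.gaze_x, fs=trial.fs)
    pg, side = predictive_gaze(trial, prefiltered=gx_filt)
    recoded = recode_toward_likely(pg, likely_side, geom)
    err = min_gaze_ball_error(trial)
    try:
        trace, missing = preprocess_pupil(trial)
        peak = pupil_surprisal_peak(trial, trace=trace)
    except ValueError:
        trace, missing, peak = None, 1.0, float("nan")
    return TrialMetrics(
        predictive_gaze_x=pg,
        predicted_side=side,
        predictive_gaze_toward_likely=recoded,
        min_gaze_ball_error=err,
        pupil_peak_delta=peak,
        missing_fraction=missing,
        hit=hit,
    )
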