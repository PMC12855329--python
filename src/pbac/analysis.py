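"""Data cleaning, condition x expectedness aggregation, inferential statistics.

Cleaning follows three rules: trials with more than 25 % missing samples are
discarded; per-metric scores more than 3 sample SDs from the mean are
replaced with a Winsorized substitute (1 % beyond the next most extreme
retained score); participants losing more than a third of their trials are
excluded.  Summaries aggregate per participant x condition x expectedness,
with difference scores (expected minus unexpected, or the reverse where a
metric grows with surprise) feeding Bonferroni-corrected post-hoc tests.

Inferential tests (repeated-measures ANOVA with partial eta squared, paired
and one-sample t with Cohen's d and its 95 % CI, Pearson/Spearman
correlations) are delegated to pingouin.  Bayes factors are a BIC
approximation, exp((BIC_null - BIC_alt) / 2), and are flagged as a
substitute for fully Bayesian values computed under explicit priors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .learning.fitting import extract_condition_parameters
from .signals import compute_trial_metrics

__all__ = [
    "qc_filter",
    "winsorize",
    "exclude_participants",
    "summarize",
    "inferential_suite",
    "StatsResult",
    "bic_bayes_factor",
    "session_metrics",
]

log = logging.getLogger(__name__)

EXPERIMENTAL_BLOCKS = ("probability", "pbac", "matched")


# ---------------------------------------------------------------------------
# Cleaning
# ---------------------------------------------------------------------------

def qc_filter(trials: pd.DataFrame, threshold: float = 0.25) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop trials whose missing-data fraction strictly exceeds the threshold.

    Returns the retained trials and a per-participant log of dropped counts.
    """
    if "missing_fraction" not in trials:
        raise ValueError("trials must carry a missing_fraction column")
    dropped = trials["missing_fraction"] > threshold
    retained = trials.loc[~dropped].copy()
    if "participant_id" in trials:
        logdf = (
            trials.assign(dropped=dropped)
            .groupby("participant_id")["dropped"]
            .agg(n_dropped="sum", n_total="count")
            .reset_index()
        )
    else:
        logdf = pd.DataFrame(
            {"participant_id": ["all"], "n_dropped": [int(dropped.sum())], "n_total": [len(trials)]}
        )
    return retained, logdf


def winsorize(values: Sequence[float], z_threshold: float = 3.0) -> np.ndarray:
    """Replace > 3 SD outliers by 1 % beyond the next most extreme retained score.

    z-scores use the full-sample mean and SD (ddof = 1); replacement is
    sign-aware: on the upper tail the substitute is the next most extreme
    retained value times 1.01 if that value is positive (0.99 if negative),
    mirrored on the lower tail.  Single pass; zero-variance input is returned
    unchanged.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3:
        raise ValueError("winsorize requires at least 3 values")
    sd = np.std(x, ddof=1)
    if sd == 0 or not np.isfinite(sd):
        return x.copy()
    z = (x - np.mean(x)) / sd
    out = x.copy()
    upper = z > z_threshold
    lower = z < -z_threshold
    retained = x[~(upper | lower)]
    if len(retained) == 0:
        return out
    if upper.any():
        nxt = retained.max()
        out[upper] = nxt * (1.01 if nxt > 0 else 0.99)
    if lower.any():
        nxt = retained.min()
        out[lower] = nxt * (0.99 if nxt > 0 else 1.01)
    return out


def exclude_participants(
    removal_log: pd.DataFrame, max_fraction: float = 1.0 / 3.0
) -> tuple[list, pd.DataFrame]:
    """Exclude participants with strictly more than a third of trials removed.

    ``removal_log`` needs participant_id, n_dropped and n_total columns (the
    qc_filter log).  Returns retained participant ids and the annotated log.
    """
    logdf = removal_log.copy()
    logdf["removed_fraction"] = logdf["n_dropped"] / logdf["n_total"]
    logdf["excluded"] = logdf["removed_fraction"] > max_fraction
    logdf["reason"] = np.where(
        logdf["excluded"], "more than a third of trials removed", ""
    )
    retained = logdf.loc[~logdf["excluded"], "participant_id"].tolist()
    return retained, logdf


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

_METRIC_COLS = ("min_gaze_ball_error", "pupil_peak_delta", "alpha2", "abs_eps2", "abs_eps3")


def summarize(metrics: pd.DataFrame, apply_winsorize: bool = True) -> pd.DataFrame:
    """Cell means per participant x condition x expectedness, plus delta scores.

    Interception is expressed as a percentage.  Winsorization (optional)
    screens each metric within its condition x expectedness cell across
    participants.  Delta columns are expected minus unexpected for
    interception, and unexpected minus expected for the surprise-type metrics
    (tracking error, pupil dilation, learning rate, prediction errors), so a
    positive delta always means "more surprise-related change".
    """
    df = metrics[metrics["block"].isin(EXPERIMENTAL_BLOCKS)].copy()
    grouped = (
        df.groupby(["participant_id", "block", "congruency_label"])
        .agg(
            interception_rate=("hit", lambda h: 100.0 * np.mean(h)),
            min_gaze_ball_error=("min_gaze_ball_error", "mean"),
            pupil_peak_delta=("pupil_peak_delta", "mean"),
            alpha2=("alpha2", "mean") if "alpha2" in df else ("hit", "size"),
            abs_eps2=("abs_eps2", "mean") if "abs_eps2" in df else ("hit", "size"),
            abs_eps3=("abs_eps3", "mean") if "abs_eps3" in df else ("hit", "size"),
            n_trials=("hit", "size"),
        )
        .reset_index()
    )
    if "alpha2" not in df:
        grouped[["alpha2", "abs_eps2", "abs_eps3"]] = np.nan

    if apply_winsorize:
        for col in ("interception_rate",) + _METRIC_COLS:
            for (block, label), idx in grouped.groupby(["block", "congruency_label"]).groups.items():
                vals = grouped.loc[idx, col].to_numpy()
                ok = np.isfinite(vals)
                if ok.sum() >= 3:
                    screened = winsorize(vals[ok])
                    vals = vals.copy()
                    vals[ok] = screened
                    grouped.loc[idx, col] = vals

    wide = grouped.pivot_table(
        index=["participant_id", "block"],
        columns="congruency_label",
        values=["interception_rate"] + list(_METRIC_COLS),
    )
    deltas = pd.DataFrame(index=wide.index)
    if ("interception_rate", "expected") in wide and ("interception_rate", "unexpected") in wide:
        deltas["delta_interception"] = (
            wide[("interception_rate", "expected")] - wide[("interception_rate", "unexpected")]
        )
    for col in _METRIC_COLS:
        if (col, "unexpected") in wide and (col, "expected") in wide:
            deltas[f"delta_{col}"] = wide[(col, "unexpected")] - wide[(col, "expected")]
    out = grouped.merge(deltas.reset_index(), on=["participant_id", "block"], how="left")
    return out


def session_metrics(session, trajectories=None, labels=None) -> pd.DataFrame:
    """Per-trial metric table for one simulated session.

    Joins the signal-pipeline measures with the trial table; when a fitted
    belief trajectory over the experimental trials is supplied, per-trial
    alpha2 / |eps2| / |eps3| columns are attached as well.
    """
    geom = session.design.geometry
    rows = []
    for _, tr in session.trials.iterrows():
        ts = session.timeseries[(tr.block, int(tr.trial_index))]
        m = compute_trial_metrics(ts, geom, tr.likely_side, hit=bool(tr.hit))
        rows.append(
            {
                "participant_id": session.participant_id,
                "block": tr.block,
                "trial_index": int(tr.trial_index),
                "congruency_label": tr.congruency_label,
                "release_side": tr.release_side,
                "likely_side": tr.likely_side,
                "hit": bool(tr.hit),
                "predictive_gaze_x": m.predictive_gaze_x,
                "predicted_side": m.predicted_side,
                "predictive_gaze_toward_likely": m.predictive_gaze_toward_likely,
                "min_gaze_ball_error": m.min_gaze_ball_error,
                "pupil_peak_delta": m.pupil_peak_delta,
                "missing_fraction": m.missing_fraction,
            }
        )
    out = pd.DataFrame(rows)
    if trajectories is not None:
        exp_mask = session.trials["block"].isin(EXPERIMENTAL_BLOCKS).to_numpy()
        traj_df = pd.DataFrame(
            {
                "block": session.trials.loc[exp_mask, "block"].to_numpy(),
                "trial_index": session.trials.loc[exp_mask, "trial_index"].to_numpy(),
                "alpha2": np.abs(trajectories.alpha2),
                "abs_eps2": np.abs(trajectories.eps2),
                "abs_eps3": np.abs(trajectories.eps3)
                if trajectories.eps3 is not None
                else np.nan,
            }
        )
        out = out.merge(traj_df, on=["block", "trial_index"], how="left")
    return out


# ---------------------------------------------------------------------------
# Inferential statistics
# ---------------------------------------------------------------------------

@dataclass
class StatsResult:
    """One test: statistic, df, p, effect size, optional substitute BF."""

    name: str
    test: str
    statistic: float
    df: object
    p: float
    effect_size: Optional[float] = None
    effect_size_type: Optional[str] = None
    effect_size_ci: Optional[tuple[float, float]] = None
    bf10_bic_substitute: Optional[float] = None
    p_adjusted: Optional[float] = None
    note: str = ""

    def to_dict(self) -> dict:
        if self.df is None:
            df_out = None
        elif isinstance(self.df, (tuple, list)):
            df_out = [float(v) for v in self.df]
        else:
            df_out = float(self.df)
        d = {
            "name": self.name,
            "test": self.test,
            "statistic": _f(self.statistic),
            "df": df_out,
            "p": _f(self.p),
            "effect_size": _f(self.effect_size),
            "effect_size_type": self.effect_size_type,
            "effect_size_ci": [None if v is None else _f(v) for v in self.effect_size_ci]
            if self.effect_size_ci
            else None,
            "bf10_bic_substitute": _f(self.bf10_bic_substitute),
            "p_adjusted": _f(self.p_adjusted),
            "note": self.note,
        }
        return d


def _f(v):
    if v is None:
        return None
    v = float(v)
    return v if np.isfinite(v) else None


def bic_bayes_factor(x: np.ndarray, y: np.ndarray | None = None, mu0: float = 0.0) -> float:
    """BIC-approximation Bayes factor for a (paired or one-sample) t design.

    exp((BIC_null - BIC_alt) / 2) on the difference scores; a substitute for
    fully Bayesian factors computed under explicit priors, so magnitudes are
    comparable only in order.
    """
    d = np.asarray(x, dtype=float) - (0.0 if y is None else np.asarray(y, dtype=float))
    d = d[np.isfinite(d)] - mu0
    n = len(d)
    if n < 2:
        return np.nan
    rss_alt = float(np.sum((d - d.mean()) ** 2))
    rss_null = float(np.sum(d**2))
    if rss_alt == 0:
        return np.inf
    bic_alt = n * np.log(rss_alt / n) + np.log(n)
    bic_null = n * np.log(rss_null / n)
    return float(np.exp((bic_null - bic_alt) / 2.0))


def _ttest_result(
    name: str, x: np.ndarray, y: np.ndarray | None, paired: bool, mu0: float = 0.0
) -> StatsResult:
    x = np.asarray(x, dtype=float)
    if y is None:
        tt = pg.ttest(x[np.isfinite(x)], mu0)
        test = "one-sample t"
    else:
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if np.std(x - y, ddof=1) == 0:
            return StatsResult(
                name, "paired t", np.nan, len(x) - 1, np.nan,
                note="degenerate: zero variance of paired differences",
            )
        tt = pg.ttest(x, y, paired=paired)
        test = "paired t" if paired else "independent t"
    row = tt.iloc[0]
    if y is not None and paired:
        # dz convention: mean difference over the SD of the differences
        diff = x - y
        d = float(np.abs(diff.mean()) / diff.std(ddof=1))
    else:
        d = float(abs(row["cohen_d"]))
    # CI for Cohen's d itself
    n = len(x)
    d_ci = pg.compute_esci(stat=d, nx=n, ny=n,
                           paired=True if y is None else paired,
                           eftype="cohen", confidence=0.95)
    return StatsResult(
        name=name,
        test=test,
        statistic=float(row["T"]),
        df=row["dof"],
        p=float(row["p_val"]),
        effect_size=d,
        effect_size_type="cohen_d",
        effect_size_ci=(float(d_ci[0]), float(d_ci[1])),
        bf10_bic_substitute=bic_bayes_factor(x, y, mu0=mu0 if y is None else 0.0),
    )


def inferential_suite(
    summary: pd.DataFrame,
    predictive_gaze_block1: pd.DataFrame | None = None,
    correlations: bool = True,
) -> list[StatsResult]:
    """The manipulation checks and hypothesis tests on a session summary.

    Runs, where the necessary cells are complete:

    * one-sample t of median block-1 predictive gaze angles against zero,
    * paired t of interception on expected vs unexpected trials (pooled),
    * 3 x 2 repeated-measures ANOVAs (condition x expectedness) on
      interception rate, tracking error and learning rate,
    * one-way repeated-measures ANOVAs across conditions on unexpected-trial
      pupil dilation and precision-weighted prediction errors,
    * Bonferroni-corrected post-hoc paired t-tests on the delta scores,
    * Spearman correlations of unexpected-trial measures with interception.

    Tests whose cells are missing are skipped with a reason.
    """
    results: list[StatsResult] = []

    if predictive_gaze_block1 is not None and len(predictive_gaze_block1):
        med = predictive_gaze_block1.groupby("participant_id")[
            "predictive_gaze_toward_likely"
        ].median()
        results.append(
            _ttest_result("median predictive gaze angle vs 0 (block 1)", med.to_numpy(), None, False)
        )

    pooled = (
        summary.groupby(["participant_id", "congruency_label"])["interception_rate"]
        .mean()
        .unstack()
    )
    if {"expected", "unexpected"} <= set(pooled.columns):
        results.append(
            _ttest_result(
                "interception expected vs unexpected (pooled)",
                pooled["expected"].to_numpy(),
                pooled["unexpected"].to_numpy(),
                paired=True,
            )
        )

    long = summary.copy()
    n_sub = long["participant_id"].nunique()
    for dv, label in (
        ("interception_rate", "interception rate"),
        ("min_gaze_ball_error", "gaze tracking error"),
        ("alpha2", "learning rate alpha2"),
    ):
        sub = long.dropna(subset=[dv])
        cells = sub.groupby(["block", "congruency_label"]).size()
        if len(cells) < 6 or not sub[dv].notna().any() or n_sub < 3:
            results.append(
                StatsResult(f"3x2 ANOVA on {label}", "rm ANOVA", np.nan, None, np.nan,
                            note="skipped: incomplete cells")
            )
            continue
        aov = pg.rm_anova(
            data=sub, dv=dv, within=["block", "congruency_label"],
            subject="participant_id", effsize="np2", detailed=True,
        )
        for _, row in aov.iterrows():
            results.append(
                StatsResult(
                    name=f"3x2 ANOVA on {label}: {row['Source']}",
                    test="rm ANOVA",
                    statistic=float(row["F"]),
                    df=(float(row["ddof1"]), float(row["ddof2"])),
                    p=float(row["p_unc"]),
                    effect_size=float(row["np2"]),
                    effect_size_type="partial_eta_sq",
                )
            )

    unexp = long[long["congruency_label"] == "unexpected"]
    for dv, label in (
        ("pupil_peak_delta", "pupil surprisal peak"),
        ("abs_eps2", "|eps2|"),
        ("abs_eps3", "|eps3|"),
    ):
        sub = unexp.dropna(subset=[dv])
        if len(sub) and n_sub >= 3 and sub.groupby("block").size().min() >= 3:
            aov = pg.rm_anova(
                data=sub, dv=dv, within="block", subject="participant_id",
                effsize="np2",
            )
            row = aov.iloc[0]
            results.append(
                StatsResult(
                    name=f"one-way ANOVA on unexpected-trial {label}",
                    test="rm ANOVA",
                    statistic=float(row["F"]),
                    df=(float(row["ddof1"]), float(row["ddof2"])),
                    p=float(row["p_unc"]),
                    effect_size=float(row["np2"]),
                    effect_size_type="partial_eta_sq",
                )
            )
        else:
            results.append(
                StatsResult(f"one-way ANOVA on unexpected-trial {label}", "rm ANOVA",
                            np.nan, None, np.nan, note="skipped: incomplete cells")
            )

    # Bonferroni post-hocs on delta scores between conditions
    for delta_col, label in (
        ("delta_interception", "delta interception"),
        ("delta_min_gaze_ball_error", "delta tracking error"),
    ):
        if delta_col not in summary:
            continue
        wide = summary.pivot_table(index="participant_id", columns="block", values=delta_col)
        pairs = [(a, b) for i, a in enumerate(EXPERIMENTAL_BLOCKS) for b in EXPERIMENTAL_BLOCKS[i + 1:]]
        family = []
        for a, b in pairs:
            if a in wide and b in wide:
                r = _ttest_result(f"{label}: {a} vs {b}", wide[a].to_numpy(), wide[b].to_numpy(), True)
                family.append(r)
        m = len(family)
        for r in family:
            r.p_adjusted = min(1.0, r.p * m) if np.isfinite(r.p) else np.nan
            r.note = (r.note + " Bonferroni family of %d" % m).strip()
        results.extend(family)

    if correlations and {"pupil_peak_delta", "min_gaze_ball_error"} <= set(summary.columns):
        for block in EXPERIMENTAL_BLOCKS:
            sub = unexp[unexp["block"] == block]
            if len(sub) >= 4:
                for var, label in (
                    ("min_gaze_ball_error", "tracking error"),
                    ("pupil_peak_delta", "pupil peak"),
                ):
                    ok = sub[[var, "interception_rate"]].dropna()
                    if len(ok) >= 4:
                        corr = pg.corr(ok[var], ok["interception_rate"], method="spearman")
                        row = corr.iloc[0]
                        results.append(
                            StatsResult(
                                name=f"Spearman {label} vs interception ({block}, unexpected)",
                                test="spearman",
                                statistic=float(row["r"]),
                                df=int(row["n"]) - 2,
                                p=float(row["p_val"]),
                            )
                        )
    return results
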