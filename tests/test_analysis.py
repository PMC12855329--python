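"""Cleaning rules, aggregation, and the inferential statistics layer."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbac.analysis import (
    bic_bayes_factor,
    exclude_participants,
    inferential_suite,
    qc_filter,
    summarize,
    winsorize,
)


class TestQCFilter:
    def test_boundary_is_strict(self):
        df = pd.DataFrame(
            {"participant_id": ["a"] * 3, "missing_fraction": [0.30, 0.25, 0.0]}
        )
        kept, logdf = qc_filter(df)
        assert len(kept) == 2
        assert 0.30 not in kept.missing_fraction.values
        assert logdf.loc[0, "n_dropped"] == 1

    def test_complete_data_is_identity(self):
        df = pd.DataFrame({"participant_id": ["a"] * 4, "missing_fraction": [0.0] * 4})
        kept, _ = qc_filter(df)
        pd.testing.assert_frame_equal(kept, df)

    def test_idempotent(self):
        df = pd.DataFrame(
            {"participant_id": ["a"] * 5, "missing_fraction": [0.0, 0.1, 0.26, 0.5, 0.2]}
        )
        once, _ = qc_filter(df)
        twice, _ = qc_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestWinsorize:
    def test_all_equal_unchanged(self):
        x = np.full(10, 1.7)
        np.testing.assert_array_equal(winsorize(x), x)

    def test_outlier_replaced_one_percent_beyond_next(self):
        x = np.concatenate([np.linspace(0.1, 0.3, 30), [50.0]])
        out = winsorize(x)
        assert out[-1] == pytest.approx(0.3 * 1.01, abs=1e-12)
        np.testing.assert_array_equal(out[:-1], x[:-1])

    def test_mirrored_outliers_keep_symmetry(self):
        base = np.linspace(-0.3, 0.3, 30)
        x = np.concatenate([base, [-50.0, 50.0]])
        out = winsorize(x)
        assert out[-1] == pytest.approx(0.3 * 1.01)
        assert out[-2] == pytest.approx(-0.3 * 1.01)
        s = np.sort(out)
        np.testing.assert_allclose(s + s[::-1], 0.0, atol=1e-12)

    def test_negative_tail_rule_is_sign_aware(self):
        # all-negative sample: upper-tail replacement shrinks toward zero
        x = np.concatenate([np.linspace(-5.0, -4.0, 30), [-0.000001]])
        out = winsorize(x)
        if out[-1] != x[-1]:  # replaced only if its z exceeds 3
            assert out[-1] == pytest.approx(-4.0 * 0.99)

    def test_idempotent_on_replaced_sample(self):
        x = np.concatenate([np.linspace(0.1, 0.3, 30), [50.0]])
        once = winsorize(x)
        np.testing.assert_array_equal(winsorize(once), once)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=-10, max_value=10), min_size=5, max_size=40))
    def test_never_exceeds_original_extremes(self, xs):
        out = winsorize(np.array(xs))
        assert np.max(np.abs(out)) <= np.max(np.abs(xs)) * 1.01 + 1e-9

    def test_requires_three_values(self):
        with pytest.raises(ValueError):
            winsorize([1.0, 2.0])


class TestExclusion:
    @pytest.mark.parametrize(
        "dropped,total,excluded", [(51, 150, True), (50, 150, False), (0, 150, False)]
    )
    def test_one_third_rule_is_strict(self, dropped, total, excluded):
        logdf = pd.DataFrame(
            {"participant_id": ["p"], "n_dropped": [dropped], "n_total": [total]}
        )
        kept, annotated = exclude_participants(logdf)
        assert ("p" not in kept) == excluded
        assert annotated.loc[0, "excluded"] == excluded


def toy_metrics(n_participants=3, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for p in range(n_participants):
        for block in ("probability", "pbac", "matched"):
            for label, n, hitp in (("expected", 40, 0.8), ("unexpected", 10, 0.3)):
                for i in range(n):
                    rows.append(
                        {
                            "participant_id": f"P{p}",
                            "block": block,
                            "trial_index": i + 1,
                            "congruency_label": label,
                            "hit": bool(rng.random() < hitp),
                            "min_gaze_ball_error": rng.normal(
                                5 if label == "expected" else 15, 1
                            ),
                            "pupil_peak_delta": rng.normal(
                                0.1 if label == "expected" else 0.6, 0.05
                            ),
                            "missing_fraction": 0.0,
                        }
                    )
    return pd.DataFrame(rows)


class TestSummarize:
    def test_interception_percentage(self):
        df = toy_metrics(1)
        df["hit"] = False
        df.loc[
            (df.block == "probability") & (df.congruency_label == "expected"), "hit"
        ] = [True] * 32 + [False] * 8
        out = summarize(df, apply_winsorize=False)
        cell = out[
            (out.block == "probability") & (out.congruency_label == "expected")
        ].iloc[0]
        assert cell.interception_rate == pytest.approx(80.0)

    def test_identical_cells_give_zero_delta(self):
        df = toy_metrics(2, seed=1)
        df["hit"] = True
        out = summarize(df, apply_winsorize=False)
        np.testing.assert_allclose(out["delta_interception"].dropna(), 0.0, atol=1e-12)

    def test_congruency_gap_propagates_to_delta(self):
        out = summarize(toy_metrics(6, seed=2), apply_winsorize=False)
        # hit probabilities 0.8 vs 0.3 -> delta near 50 points
        assert abs(out.groupby("block")["delta_interception"].mean().mean() - 50) < 15


class TestInferentialSuite:
    def test_paired_t_matches_hand_formula(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([1.5, 2.1, 3.4, 3.9, 5.6])
        from pbac.analysis import _ttest_result

        res = _ttest_result("toy", x, y, paired=True)
        d = x - y
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.statistic == pytest.approx(t_hand, abs=1e-10)
        assert res.effect_size == pytest.approx(abs(d.mean()) / d.std(ddof=1), abs=1e-6)

    def test_constant_difference_flagged_degenerate(self):
        from pbac.analysis import _ttest_result

        res = _ttest_result("toy", np.arange(5.0), np.arange(5.0) + 1.0, paired=True)
        assert "degenerate" in res.note
        assert np.isnan(res.statistic)

    def test_identical_samples_give_zero_t(self):
        from pbac.analysis import _ttest_result

        x = np.array([1.0, 2, 3, 4, 8])
        res = _ttest_result("toy", x, x + np.array([0.1, -0.1, 0.2, -0.2, 0.0]), paired=True)
        assert np.isfinite(res.statistic)

    def test_anova_sums_of_squares_match_brute_force(self):
        out = summarize(toy_metrics(3, seed=3), apply_winsorize=False)
        import pingouin as pg

        aov = pg.rm_anova(
            data=out, dv="interception_rate", within=["block", "congruency_label"],
            subject="participant_id", effsize="np2", detailed=True,
        )
        y = out.pivot_table(
            index="participant_id", columns=["block", "congruency_label"],
            values="interception_rate",
        )
        grand = y.to_numpy().mean()
        n_s, a_lv, b_lv = y.shape[0], 3, 2
        mean_a = y.T.groupby(level=0).mean().T.mean(axis=0)
        ss_a = n_s * b_lv * ((mean_a - grand) ** 2).sum()
        mean_b = y.T.groupby(level=1).mean().T.mean(axis=0)
        ss_b = n_s * a_lv * ((mean_b - grand) ** 2).sum()
        cell = y.mean(axis=0)
        ss_cells = n_s * ((cell - grand) ** 2).sum()
        ss_ab = ss_cells - ss_a - ss_b
        got = {r["Source"]: r["SS"] for _, r in aov.iterrows()}
        assert got["block"] == pytest.approx(ss_a, rel=1e-8)
        assert got["congruency_label"] == pytest.approx(ss_b, rel=1e-8)
        assert got["block * congruency_label"] == pytest.approx(ss_ab, rel=1e-8)

    def test_suite_runs_on_toy_summary(self):
        out = summarize(toy_metrics(6, seed=4), apply_winsorize=False)
        results = inferential_suite(out)
        names = [r.name for r in results]
        assert any("3x2 ANOVA on interception rate" in n for n in names)
        assert any("delta interception" in n for n in names)
        for r in results:
            if np.isfinite(r.p):
                assert 0.0 <= r.p <= 1.0
            if r.p_adjusted is not None and np.isfinite(r.p_adjusted):
                assert r.p_adjusted >= r.p - 1e-12


class TestBicBayesFactor:
    def test_strong_effect_gives_large_bf(self):
        x = np.linspace(1.0, 1.4, 12)
        assert bic_bayes_factor(x) > 3.0

    def test_null_data_gives_small_bf(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=20)
        assert bic_bayes_factor(x) < 3.0
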