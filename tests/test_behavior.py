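"""Behavioral statistics: outlier rules, summaries, gating contrasts,
repeated-measures ANOVA and effect sizes."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatingnet.behavior import (
    effect_size_from_F,
    effect_size_from_t,
    filter_outliers,
    gating_contrast,
    paired_t,
    rm_anova,
    summarize,
)


def _trials(rts, subject=0):
    n = len(rts)
    return pd.DataFrame(
        {
            "subject": subject,
            "trial": np.arange(n),
            "trial_type": "reference",
            "switching": "switch",
            "matching": "match",
            "response": "match",
            "correct": 1,
            "rt_s": rts,
        }
    )


class TestOutliers:
    def test_constant_rts_nothing_removed(self):
        rep = filter_outliers(_trials([0.5] * 10))
        assert len(rep.trials) == 10
        assert rep.n_removed_per_subject[0] == 0

    def test_extreme_rt_removed(self):
        rng = np.random.default_rng(0)
        rts = list(rng.normal(0.5, 0.05, 100)) + [10.0]
        rep = filter_outliers(_trials(rts))
        assert rep.n_removed_per_subject[0] == 1
        assert 10.0 not in rep.trials["rt_s"].values

    def test_infinite_k_is_identity(self):
        df = _trials([0.4, 0.5, 0.6, 5.0])
        rep = filter_outliers(df, k=math.inf)
        pd.testing.assert_frame_equal(rep.trials, df)

    def test_group_level_flagging(self):
        frames = [_trials(list(np.full(20, 0.5 + 0.001 * s)), subject=s) for s in range(8)]
        frames.append(_trials([3.0] * 20, subject=8))  # aberrant subject mean
        rep = filter_outliers(pd.concat(frames, ignore_index=True))
        assert 8 in rep.flagged_subjects


class TestSummaries:
    def test_all_correct_zero_error(self):
        summ = summarize(_trials([0.4, 0.5, 0.6]))
        assert (summ["error_pct"] == 0).all()

    def test_error_percentage_arithmetic(self):
        df = _trials([0.5] * 10)
        df.loc[:1, "correct"] = 0
        summ = summarize(df)
        assert summ["error_pct"].iloc[0] == pytest.approx(20.0)

    def test_rt_mean_uses_correct_trials_only(self):
        df = _trials([0.4, 0.4, 2.0])
        df.loc[2, "correct"] = 0
        summ = summarize(df)
        assert summ["mean_rt_s"].iloc[0] == pytest.approx(0.4)


class TestGatingContrast:
    def test_equal_cells_zero(self):
        gs = gating_contrast({c: 1.0 for c in (
            "switch-reference", "nonswitch-reference",
            "switch-comparison", "nonswitch-comparison")})
        assert gs.opening == 0.0 and gs.closing == 0.0

    def test_worked_example(self):
        gs = gating_contrast(
            {
                "switch-reference": 1.0,
                "nonswitch-reference": 0.9,
                "switch-comparison": 1.2,
                "nonswitch-comparison": 0.8,
            }
        )
        assert gs.opening == pytest.approx(0.1)
        assert gs.closing == pytest.approx(0.4)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        keys = ["switch-reference", "nonswitch-reference",
                "switch-comparison", "nonswitch-comparison"]
        A = {k: rng.standard_normal() for k in keys}
        B = {k: rng.standard_normal() for k in keys}
        combo = {k: 2.0 * A[k] + 3.0 * B[k] for k in keys}
        ga, gb, gc = gating_contrast(A), gating_contrast(B), gating_contrast(combo)
        assert gc.opening == pytest.approx(2 * ga.opening + 3 * gb.opening)
        assert gc.closing == pytest.approx(2 * ga.closing + 3 * gb.closing)

    def test_missing_cell_rejected(self):
        with pytest.raises(KeyError):
            gating_contrast({"switch-reference": 1.0})


class TestRmAnova:
    def test_zero_contrast_gives_zero_F(self):
        X = np.tile(np.random.default_rng(0).standard_normal(10)[:, None], (1, 4))
        for row in rm_anova(X, ["A", "B"]):
            assert row.F == pytest.approx(0.0)
            assert row.eta_p2 == pytest.approx(0.0)

    def test_matches_reference_solver_on_random_data(self):
        """Contrast-based F agrees with a standard RM-ANOVA solver."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        for rep in range(20):
            n = rng.integers(8, 20)
            X = rng.standard_normal((n, 4)) + rng.standard_normal((n, 1))
            ours = {r.effect: r.F for r in rm_anova(X, ["A", "B"])}
            recs = []
            for s in range(n):
                for ci, (a, b) in enumerate(
                    [("a0", "b0"), ("a0", "b1"), ("a1", "b0"), ("a1", "b1")]
                ):
                    recs.append((s, a, b, X[s, ci]))
            long = pd.DataFrame(recs, columns=["subject", "A", "B", "y"])
            ref = pingouin.rm_anova(
                data=long, dv="y", within=["A", "B"], subject="subject", detailed=True
            )
            theirs = dict(zip(ref["Source"], ref["F"]))
            for k1, k2 in [("A", "A"), ("B", "B"), ("A x B", "A * B")]:
                assert ours[k1] == pytest.approx(theirs[k2], abs=1e-8)

    def test_three_way_equals_paired_t_squared(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 8))
        rows = {r.effect: r for r in rm_anova(X, ["A", "B", "C"])}
        # main effect A: first four columns (+) vs last four (-)
        scores = X[:, :4].mean(axis=1) - X[:, 4:].mean(axis=1)
        t, df, _, _ = paired_t(scores, np.zeros(12))
        assert rows["A"].F == pytest.approx(t * t, rel=1e-12)
        assert rows["A"].df_err == df

    def test_published_effect_size(self):
        assert effect_size_from_F(210.98, 1, 60) == pytest.approx(0.779, abs=5e-4)


class TestEffectSizes:
    @pytest.mark.parametrize(
        "F,df_num,df_err,expected",
        [
            (210.98, 1, 60, 0.779),
            (93.42, 1, 60, 0.609),
            (317.29, 1, 60, 0.841),
            (48.03, 1, 60, 0.445),
            (49.31, 1, 60, 0.451),
            (33.96, 1, 60, 0.361),
            (0.0, 1, 60, 0.0),
        ],
    )
    def test_partial_eta_squared_reproduces_published(self, F, df_num, df_err, expected):
        assert effect_size_from_F(F, df_num, df_err) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "t,n,expected",
        [(6.93, 61, 0.887), (3.340, 61, 0.428), (6.78, 63, 0.85), (-2.54, 61, -0.325)],
    )
    def test_cohens_dz_reproduces_published(self, t, n, expected):
        assert effect_size_from_t(t, n) == pytest.approx(expected, abs=5e-3)

    def test_eta_monotone_in_F_and_bounded(self):
        Fs = np.linspace(0, 500, 100)
        etas = [effect_size_from_F(F, 1, 60) for F in Fs]
        assert np.all(np.diff(etas) > 0)
        assert etas[0] == 0.0 and etas[-1] < 1.0

    @given(
        F=st.floats(0.0, 1e6),
        df_num=st.integers(1, 3),
        df_err=st.integers(1, 500),
    )
    @settings(deadline=None, max_examples=200)
    def test_eta_bounded_for_any_inputs(self, F, df_num, df_err):
        eta = effect_size_from_F(F, df_num, df_err)
        assert 0.0 <= eta < 1.0

    def test_negative_F_rejected(self):
        with pytest.raises(ValueError):
            effect_size_from_F(-1.0, 1, 60)


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(5.0)
        t, df, p, d = paired_t(x, x)
        assert t == 0.0 and d == 0.0 and p == 1.0 and df == 4

    def test_zero_variance_nonzero_mean(self):
        t, _, p, d = paired_t(np.ones(5), np.zeros(5))
        assert math.isinf(t) and p == 0.0

    def test_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(9)
        x, y = rng.standard_normal((2, 30))
        t, df, p, d = paired_t(x, y)
        ref = stats.ttest_rel(x, y)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)
        assert d == pytest.approx(t / math.sqrt(30))
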