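"""Behavioral statistics: condition summaries, gating contrasts, outlier
rules, repeated-measures ANOVA for 2-level within factors, and effect sizes.

The gating contrasts quantify switch costs separately for the two trial
types of the reference-back task:

    gate opening = cell(switch, reference)  - cell(nonswitch, reference)
    gate closing = cell(switch, comparison) - cell(nonswitch, comparison)

and apply to any per-cell measure (RT, error percentage, or a fitted DDM
parameter).  All ANOVA factors are 2-level and within-subject, so every
effect is exactly the squared one-sample t of its per-subject contrast
scores; no sphericity correction is needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GatingScore",
    "AnovaRow",
    "OutlierReport",
    "filter_outliers",
    "summarize",
    "gating_contrast",
    "rm_anova",
    "paired_t",
    "effect_size_from_F",
    "effect_size_from_t",
]


@dataclass(frozen=True)
class GatingScore:
    measure: str
    opening: float
    closing: float


@dataclass(frozen=True)
class AnovaRow:
    effect: str
    F: float
    df_num: int
    df_err: int
    p: float
    eta_p2: float


@dataclass
class OutlierReport:
    trials: pd.DataFrame
    n_removed_per_subject: dict
    flagged_subjects: list  # subjects outside group-level +/- k SD rules


def filter_outliers(trials: pd.DataFrame, k: float = 2.0) -> OutlierReport:
    """Trial- and subject-level outlier correction of reaction times.

    Within each subject, trials with RT outside mean +/- k*SD are removed
    (if the within-subject SD is 0 nothing is removed).  Afterwards,
    subjects whose mean RT or per-condition trial counts fall outside the
    group mean +/- k*SD are flagged (not removed) for the caller to exclude.
    """
    if math.isinf(k):
        return OutlierReport(trials.copy(), {s: 0 for s in trials["subject"].unique()}, [])

    kept = []
    removed = {}
    for subj, sub in trials.groupby("subject"):
        if len(sub) < 3:
            raise ValueError(f"subject {subj} has fewer than 3 trials")
        m, sd = sub["rt_s"].mean(), sub["rt_s"].std(ddof=1)
        if sd == 0:
            mask = np.ones(len(sub), dtype=bool)
        else:
            mask = (sub["rt_s"] - m).abs() <= k * sd
        removed[subj] = int((~mask).sum())
        kept.append(sub[mask])
    out = pd.concat(kept, ignore_index=True)

    flagged = set()
    means = out.groupby("subject")["rt_s"].mean()
    gm, gsd = means.mean(), means.std(ddof=1)
    if gsd > 0:
        flagged |= set(means.index[(means - gm).abs() > k * gsd])
    if {"switching", "trial_type"}.issubset(out.columns):
        counts = out.groupby(["subject", "switching", "trial_type"]).size().unstack(
            ["switching", "trial_type"], fill_value=0
        )
        for col in counts.columns:
            c = counts[col]
            cm, csd = c.mean(), c.std(ddof=1)
            if csd > 0:
                flagged |= set(c.index[(c - cm).abs() > k * csd])
    empty = set(trials["subject"].unique()) - set(out["subject"].unique())
    return OutlierReport(out, removed, sorted(flagged | empty))


def summarize(trials: pd.DataFrame) -> pd.DataFrame:
    """Per subject x condition cell: mean RT over correct trials and error %.

    Returns a tidy frame with columns subject, switching, trial_type,
    mean_rt_s, error_pct, n_trials.  Cells with no correct trials get a
    missing mean RT.
    """
    rows = []
    for (subj, sw, tt), sub in trials.groupby(["subject", "switching", "trial_type"]):
        correct = sub[sub["correct"] == 1]
        rows.append(
            {
                "subject": subj,
                "switching": sw,
                "trial_type": tt,
                "mean_rt_s": correct["rt_s"].mean() if len(correct) else np.nan,
                "error_pct": 100.0 * (1.0 - sub["correct"].mean()),
                "n_trials": len(sub),
            }
        )
    return pd.DataFrame(rows)


def gating_contrast(cells: dict, measure: str = "value") -> GatingScore:
    """Gate opening/closing switch costs from the four Switching x TrialType cells.

    ``cells`` maps condition labels ("switch-reference", ...) to scalars.
    """
    needed = {
        "switch-reference",
        "nonswitch-reference",
        "switch-comparison",
        "nonswitch-comparison",
    }
    missing = needed - set(cells)
    if missing:
        raise KeyError(f"missing condition cells: {sorted(missing)}")
    return GatingScore(
        measure=measure,
        opening=float(cells["switch-reference"] - cells["nonswitch-reference"]),
        closing=float(cells["switch-comparison"] - cells["nonswitch-comparison"]),
    )


def rm_anova(cell_matrix: np.ndarray, factors: list[str]) -> list[AnovaRow]:
    """Repeated-measures ANOVA for 2 or 3 two-level within-subject factors.

    ``cell_matrix`` is (n_subjects, 2**k) with cells ordered as
    ``itertools.product`` over factor levels (last factor fastest).  Each
    main effect and interaction is computed from its per-subject contrast
    score (mean of "+" cells minus mean of "-" cells); F is the squared
    one-sample t of those scores, which is exact for 2-level factors.
    Rows with missing cells are dropped.
    """
    X = np.asarray(cell_matrix, dtype=float)
    k = len(factors)
    if k not in (2, 3):
        raise ValueError("only 2 or 3 factors supported")
    if X.shape[1] != 2**k:
        raise ValueError(f"expected {2**k} cells for {k} factors")
    X = X[~np.isnan(X).any(axis=1)]
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete subjects")

    signs = np.array(list(itertools.product([1, -1], repeat=k)))  # (cells, k)
    rows = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            w = np.prod(signs[:, combo], axis=1).astype(float)
            # normalize so the score is a difference of cell means
            w_pos = w > 0
            w[w_pos] /= w_pos.sum()
            w[~w_pos] /= (~w_pos).sum()
            scores = X @ w
            t, df, p, _ = paired_t(scores, np.zeros(n))
            F = t * t
            rows.append(
                AnovaRow(
                    effect=" x ".join(factors[i] for i in combo),
                    F=float(F),
                    df_num=1,
                    df_err=n - 1,
                    p=float(stats.f.sf(F, 1, n - 1)),
                    eta_p2=effect_size_from_F(F, 1, n - 1),
                )
            )
    return rows


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float, float]:
    """Classical paired t-test with the paired effect size d_z = t / sqrt(n).

    Returns (t, df, p, d).  Zero-variance differences give t = 0 (and p = 1)
    when the mean difference is also 0, else an infinite t with p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        t = 0.0 if d.mean() == 0.0 else math.copysign(math.inf, d.mean())
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p), effect_size_from_t(t, n)


def effect_size_from_F(F: float, df_num: int, df_err: int) -> float:
    """Partial eta squared: F*df_num / (F*df_num + df_err)."""
    if F < 0:
        raise ValueError("F must be >= 0")
    if df_err < 1:
        raise ValueError("df_err must be >= 1")
    return float(F * df_num / (F * df_num + df_err))


def effect_size_from_t(t: float, n: int) -> float:
    """Paired Cohen's d_z = t / sqrt(n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if math.isinf(t):
        return math.copysign(math.inf, t)
    return float(t / math.sqrt(n))
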