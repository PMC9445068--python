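"""Emotion-specificity statistics on the per-scene feature table.

One-way ANOVA with eta-squared effect sizes and Bonferroni-corrected
pairwise post hoc t tests, plus one-sample tests of recognition accuracy
against the four-alternative chance level.  Correlation-valued features
(distance correlations and synchrony) are Fisher-Z transformed before
testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CORRELATION_FEATURES",
    "AnovaResult",
    "fisher_z",
    "one_way_anova",
    "anova_table",
    "recognition_vs_chance",
]

#: feature columns holding Pearson correlations (Fisher-Z before ANOVA)
CORRELATION_FEATURES = ("DC_VEL", "DC_ACC", "DC_VOL", "DC_LC", "SYNC_VEL", "SYNC_ACC")

CHANCE_LEVEL = 0.25


@dataclass
class AnovaResult:
    feature_name: str
    F: float
    df: tuple[int, int]
    p: float
    eta_sq: float
    group_means: dict[str, float]
    group_sems: dict[str, float]
    posthoc: pd.DataFrame  # columns: group_a, group_b, mean_diff, p_raw, p_corrected


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher Z transform, atanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    clip = 1.0 - 1e-12
    if np.any(np.abs(r[np.isfinite(r)]) >= 1.0):
        warnings.warn("correlation at or beyond +-1 clipped before Fisher Z")
    z = np.arctanh(np.clip(r, -clip, clip))
    return float(z) if z.ndim == 0 else z


def one_way_anova(
    values: Sequence[float] | np.ndarray,
    labels: Sequence[str],
    feature_name: str = "feature",
    welch_posthoc: bool = False,
) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA with all-pairs post hoc t tests.

    Post hoc tests default to pooled-variance two-sample t with Bonferroni
    correction by the number of pairs; ``welch_posthoc`` switches to Welch.
    Missing values are dropped pairwise with their labels.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    keep = np.isfinite(values)
    values, labels = values[keep], labels[keep]

    group_names = list(dict.fromkeys(labels))
    groups = [values[labels == g] for g in group_names]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(g) == 0 for g in groups):
        raise ValueError("zero within-group variance everywhere: ANOVA degenerate")

    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_total = float(np.sum((values - grand) ** 2))
    df_b = len(groups) - 1
    df_w = len(values) - len(groups)
    F, p = stats.f_oneway(*groups)

    n_pairs = len(group_names) * (len(group_names) - 1) // 2
    rows = []
    for (i, a), (j, b) in combinations(enumerate(group_names), 2):
        t_res = stats.ttest_ind(groups[i], groups[j], equal_var=not welch_posthoc)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": float(groups[i].mean() - groups[j].mean()),
                "p_raw": float(t_res.pvalue),
                "p_corrected": float(min(1.0, n_pairs * t_res.pvalue)),
            }
        )

    return AnovaResult(
        feature_name=feature_name,
        F=float(F),
        df=(df_b, df_w),
        p=float(p),
        eta_sq=float(ss_between / ss_total) if ss_total > 0 else 0.0,
        group_means={g: float(grp.mean()) for g, grp in zip(group_names, groups)},
        group_sems={
            g: float(grp.std(ddof=1) / np.sqrt(len(grp))) for g, grp in zip(group_names, groups)
        },
        posthoc=pd.DataFrame(rows),
    )


def anova_table(
    features: pd.DataFrame, labels: Sequence[str] | pd.Series, **kwargs
) -> dict[str, AnovaResult]:
    """Run :func:`one_way_anova` per feature column.

    Correlation-valued columns (:data:`CORRELATION_FEATURES`) are Fisher-Z
    transformed first; their reported group means/SEMs are on the Z scale.
    """
    labels = np.asarray(labels)
    out: dict[str, AnovaResult] = {}
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        if col in CORRELATION_FEATURES:
            finite = np.isfinite(vals)
            vals = vals.copy()
            vals[finite] = fisher_z(vals[finite])
        out[col] = one_way_anova(vals, labels, feature_name=col, **kwargs)
    return out


def recognition_vs_chance(
    ratings: pd.DataFrame, chance: float = CHANCE_LEVEL
) -> pd.DataFrame:
    """Per-emotion recognition accuracy tested against chance across raters.

    ``ratings`` is the tidy frame produced by ``simulate_ratings``.  Returns
    one row per emotion with the across-rater mean accuracy, SEM, t and df of
    a one-sample t test against ``chance``, and the Bonferroni-corrected p
    (x number of emotions).
    """
    if ratings["rater"].nunique() < 2:
        raise ValueError("need at least 2 raters to test against chance")
    correct = (ratings["response"] == ratings["true_emotion"]).astype(float)
    acc = (
        ratings.assign(correct=correct)
        .groupby(["rater", "true_emotion"], sort=False)["correct"]
        .mean()
        .unstack("true_emotion")
    )
    n_emotions = acc.shape[1]
    rows = []
    for emotion in acc.columns:
        a = acc[emotion].to_numpy()
        t_res = stats.ttest_1samp(a, chance)
        rows.append(
            {
                "emotion": emotion,
                "accuracy": float(a.mean()),
                "sem": float(a.std(ddof=1) / np.sqrt(len(a))),
                "t": float(t_res.statistic),
                "df": len(a) - 1,
                "p_raw": float(t_res.pvalue),
                "p_corrected": float(min(1.0, n_emotions * t_res.pvalue)),
            }
        )
    return pd.DataFrame(rows).set_index("emotion")
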