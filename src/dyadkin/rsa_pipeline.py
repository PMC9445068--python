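"""Representational similarity analysis over scenes, features and raters.

Builds dissimilarity matrices (RDMs) of four flavours — binary category
models, per-feature Euclidean-distance RDMs, per-subject behavioural RDMs
and normalized combination RDMs — and relates them with Kendall's tau-A
(ties counted in the denominator only) or Pearson correlation, with
permutation and signed-rank significance, Holm-Bonferroni / FDR correction,
a two-bound noise ceiling and classical MDS embeddings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RDM",
    "NoiseCeiling",
    "model_rdm",
    "feature_rdm",
    "feature_rdms",
    "behavioural_rdms",
    "tau_a",
    "tau_a_vectors",
    "rdm_correlation",
    "relate_models_to_features",
    "relate_features_to_behaviour",
    "pairwise_feature_tests",
    "combine_rdms",
    "classical_mds",
    "noise_ceiling",
]


@dataclass
class RDM:
    """A symmetric nonnegative dissimilarity matrix with zero diagonal."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    name: str = "rdm"
    flavour: str = "feature"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} does not match {n} labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("RDM must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("RDM diagonal must be zero")
        if np.any(m < -1e-12):
            raise ValueError("RDM entries must be nonnegative")
        self.matrix = np.clip(m, 0.0, None)
        self.labels = tuple(self.labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def vector(self) -> np.ndarray:
        """Strict upper triangle, row-major (n(n-1)/2 entries)."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def permuted(self, order: np.ndarray) -> "RDM":
        return RDM(
            self.matrix[np.ix_(order, order)],
            tuple(self.labels[i] for i in order),
            self.name,
            self.flavour,
        )


@dataclass
class NoiseCeiling:
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.lower > self.upper + 1e-12:
            raise ValueError("noise-ceiling lower bound exceeds upper bound")


def model_rdm(
    categories: Mapping[str, str], name: str = "model", flavour: str = "model_emotion"
) -> RDM:
    """Binary categorical RDM: 0 within a category, 1 across categories."""
    labels = tuple(categories)
    cats = np.array([categories[l] for l in labels])
    m = (cats[:, None] != cats[None, :]).astype(float)
    return RDM(m, labels, name, flavour)


def feature_rdm(values: Mapping[str, float] | pd.Series, name: str = "feature") -> RDM:
    """Absolute-difference RDM of one scalar feature across scenes.

    A constant (or all-missing) feature yields an all-zero RDM with a
    warning; missing values are imputed with the feature median first.
    """
    series = pd.Series(values, dtype=float)
    vals = series.to_numpy()
    if not np.isfinite(vals).all():
        med = np.nanmedian(vals) if np.isfinite(vals).any() else 0.0
        vals = np.where(np.isfinite(vals), vals, med)
    if np.ptp(vals) == 0:
        warnings.warn(f"feature '{name}' is constant: RDM is all zeros")
    m = np.abs(vals[:, None] - vals[None, :])
    return RDM(m, tuple(series.index.astype(str)), name, "feature")


def feature_rdms(features: pd.DataFrame) -> dict[str, RDM]:
    """One RDM per feature column of a scene-indexed table."""
    return {col: feature_rdm(features[col], name=col) for col in features.columns}


def behavioural_rdms(
    ratings: pd.DataFrame,
) -> tuple[dict[int, RDM], dict[int, RDM], RDM, RDM]:
    """Per-subject emotion and valence RDMs plus their group means.

    The emotion RDM of a subject is binary over that subject's own responses
    (0 if two scenes received the same emotion choice, 1 otherwise); the
    valence RDM holds pairwise absolute rating differences.  Group-mean RDMs
    are the entrywise means over subjects.  Raises if any subject misses any
    scene.
    """
    scene_ids = tuple(dict.fromkeys(ratings["scene_id"]))
    emotion_rdms: dict[int, RDM] = {}
    valence_rdms: dict[int, RDM] = {}
    for rater, sub in ratings.groupby("rater", sort=True):
        sub = sub.set_index("scene_id")
        missing = [s for s in scene_ids if s not in sub.index]
        if missing or len(sub) != len(scene_ids):
            raise ValueError(f"rater {rater} has incomplete ratings; missing {missing}")
        sub = sub.loc[list(scene_ids)]
        resp = sub["response"].to_numpy()
        emo = (resp[:, None] != resp[None, :]).astype(float)
        val = np.abs(
            sub["valence"].to_numpy(float)[:, None] - sub["valence"].to_numpy(float)[None, :]
        )
        emotion_rdms[rater] = RDM(emo, scene_ids, f"emotion_s{rater}", "behav_emotion")
        valence_rdms[rater] = RDM(val, scene_ids, f"valence_s{rater}", "behav_valence")
    mean_emo = RDM(
        np.mean([r.matrix for r in emotion_rdms.values()], axis=0),
        scene_ids,
        "emotion_group",
        "behav_emotion",
    )
    mean_val = RDM(
        np.mean([r.matrix for r in valence_rdms.values()], axis=0),
        scene_ids,
        "valence_group",
        "behav_valence",
    )
    return emotion_rdms, valence_rdms, mean_emo, mean_val


def _tie_adjust(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float(np.sum(counts * (counts - 1) / 2.0))


def tau_a_vectors(x: np.ndarray, y: np.ndarray) -> float:
    """Kendall's tau-A of two vectors: (C - D) / (m(m-1)/2).

    Ties contribute to the denominator but not to C or D, so tau-A of a
    tied vector with itself is below 1.  Constant input returns NaN with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("tau_a needs two equal-length vectors")
    m = len(x)
    n0 = m * (m - 1) / 2.0
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("tau_a undefined for a constant vector")
        return float("nan")
    tau_b = stats.kendalltau(x, y).statistic
    # recover C - D from tau-b and the tie counts of each vector
    denom_b = np.sqrt((n0 - _tie_adjust(x)) * (n0 - _tie_adjust(y)))
    return float(tau_b * denom_b / n0)


def tau_a(rdm_a: RDM, rdm_b: RDM) -> float:
    """Kendall's tau-A between the upper triangles of two aligned RDMs."""
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDMs must share labels and ordering")
    return tau_a_vectors(rdm_a.vector(), rdm_b.vector())


def rdm_correlation(rdm_a: RDM, rdm_b: RDM, statistic: str = "tau_a") -> float:
    """``tau_a`` or ``pearson`` correlation between two aligned RDMs."""
    if rdm_a.labels != rdm_b.labels:
        raise ValueError("RDMs must share labels and ordering")
    if statistic == "tau_a":
        return tau_a(rdm_a, rdm_b)
    if statistic == "pearson":
        x, y = rdm_a.vector(), rdm_b.vector()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn("pearson undefined for a constant RDM")
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])
    raise ValueError(f"unknown statistic {statistic!r}")


def _permutation_p(
    rdm_a: RDM, rdm_b: RDM, observed: float, n_permutations: int, rng: np.random.Generator
) -> float:
    """Two-sided scene-label permutation p for tau_a(rdm_a, rdm_b)."""
    if not np.isfinite(observed):
        return float("nan")
    count = 0
    vec_a = rdm_a.vector()
    for _ in range(n_permutations):
        order = rng.permutation(rdm_b.n)
        t = tau_a_vectors(vec_a, rdm_b.permuted(order).vector())
        if np.isfinite(t) and abs(t) >= abs(observed) - 1e-15:
            count += 1
    return (1 + count) / (1 + n_permutations)


def relate_models_to_features(
    model_rdms: Mapping[str, RDM],
    feat_rdms: Mapping[str, RDM],
    n_permutations: int = 10_000,
    seed: int = 0,
    mds_components: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise tau-A among model and feature RDMs, with permutation tests.

    Returns ``(tau_matrix, tests, mds_coords)``: the symmetric tau-A matrix
    over all RDMs, a table of model-vs-feature permutation tests with
    Bonferroni correction by the number of features, and a classical MDS
    embedding of the ``1 - tau`` distances.
    """
    all_rdms = {**model_rdms, **feat_rdms}
    names = list(all_rdms)
    n = len(names)
    if n < 2:
        raise ValueError("need at least 2 RDMs")
    taus = np.ones((n, n))
    for (i, a), (j, b) in combinations(enumerate(names), 2):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = tau_a(all_rdms[a], all_rdms[b])
        taus[i, j] = taus[j, i] = t
    tau_matrix = pd.DataFrame(taus, index=names, columns=names)

    rng = np.random.default_rng(seed)
    rows = []
    k = max(len(feat_rdms), 1)
    for m_name, m_rdm in model_rdms.items():
        for f_name, f_rdm in feat_rdms.items():
            obs = tau_matrix.loc[m_name, f_name]
            p = _permutation_p(m_rdm, f_rdm, obs, n_permutations, rng)
            rows.append(
                {
                    "model": m_name,
                    "feature": f_name,
                    "tau_a": float(obs),
                    "p": p,
                    "p_corrected": float(min(1.0, k * p)) if np.isfinite(p) else float("nan"),
                }
            )
    tests = pd.DataFrame(rows)

    dist = 1.0 - np.nan_to_num(taus, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    coords = classical_mds(dist, n_components=mds_components)
    mds = pd.DataFrame(coords, index=names, columns=[f"dim{i+1}" for i in range(coords.shape[1])])
    return tau_matrix, tests, mds


def noise_ceiling(
    subject_rdms: Sequence[RDM], statistic: str = "tau_a"
) -> NoiseCeiling:
    """Two-bound noise ceiling over a cohort of subject RDMs.

    Upper bound: mean correlation of each subject with the group-mean RDM
    (subject included); lower bound: with the leave-that-subject-out mean.
    """
    mats = np.stack([r.matrix for r in subject_rdms])
    labels = subject_rdms[0].labels
    n = len(subject_rdms)
    if n < 2:
        raise ValueError("noise ceiling needs >= 2 subjects")
    total = mats.sum(axis=0)
    uppers, lowers = [], []
    for i in range(n):
        own = subject_rdms[i]
        with_mean = RDM(total / n, labels, "group")
        loo_mean = RDM((total - mats[i]) / (n - 1), labels, "loo")
        uppers.append(rdm_correlation(own, with_mean, statistic))
        lowers.append(rdm_correlation(own, loo_mean, statistic))
    return NoiseCeiling(lower=float(np.nanmean(lowers)), upper=float(np.nanmean(uppers)))


def relate_features_to_behaviour(
    feat_rdms: Mapping[str, RDM],
    subject_rdms: Mapping[int, RDM],
    statistic: str = "tau_a",
    fdr_alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, NoiseCeiling]:
    """Correlate each feature RDM with every subject's behavioural RDM.

    Returns ``(summary, per_subject, ceiling)``.  ``summary`` has one row per
    feature with the across-subject mean correlation, a one-sided Wilcoxon
    signed-rank p across subjects, Holm-Bonferroni corrected p and a
    Benjamini-Hochberg FDR significance flag; ``per_subject`` is the feature
    x subject correlation table used for pairwise tests.
    """
    subjects = sorted(subject_rdms)
    if len(subjects) < 2:
        raise ValueError("need >= 2 subjects")
    corr = pd.DataFrame(index=list(feat_rdms), columns=subjects, dtype=float)
    for f_name, f_rdm in feat_rdms.items():
        for s in subjects:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                corr.loc[f_name, s] = rdm_correlation(f_rdm, subject_rdms[s], statistic)

    rows = []
    for f_name in feat_rdms:
        vals = corr.loc[f_name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < 2 or np.all(vals == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(vals, alternative="greater").pvalue)
        rows.append({"feature": f_name, "mean_corr": float(np.mean(vals)) if len(vals) else float("nan"), "p": p})
    summary = pd.DataFrame(rows).set_index("feature")
    summary["p_holm"] = multipletests(summary["p"], method="holm")[1]
    summary["significant_fdr"] = multipletests(summary["p"], alpha=fdr_alpha, method="fdr_bh")[0]

    ceiling = noise_ceiling([subject_rdms[s] for s in subjects], statistic)
    return summary, corr, ceiling


def pairwise_feature_tests(
    per_subject: pd.DataFrame, fdr_alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sided signed-rank tests on per-subject correlation differences.

    ``per_subject`` is the feature x subject table from
    :func:`relate_features_to_behaviour`.  Returns a tidy table of pairs
    (p, FDR flag) and the symmetric p-value matrix (NaN diagonal).
    """
    if per_subject.shape[1] < 6:
        raise ValueError("signed-rank pairwise tests need >= 6 subjects")
    features = list(per_subject.index)
    rows = []
    for a, b in combinations(features, 2):
        diff = per_subject.loc[a].to_numpy(float) - per_subject.loc[b].to_numpy(float)
        diff = diff[np.isfinite(diff)]
        if len(diff) == 0 or np.all(diff == 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff).pvalue)
        rows.append({"feature_a": a, "feature_b": b, "p": p})
    table = pd.DataFrame(rows)
    table["significant_fdr"] = multipletests(table["p"], alpha=fdr_alpha, method="fdr_bh")[0]

    mat = pd.DataFrame(np.nan, index=features, columns=features)
    for row in table.itertuples():
        mat.loc[row.feature_a, row.feature_b] = row.p
        mat.loc[row.feature_b, row.feature_a] = row.p
    return table, mat


def combine_rdms(
    rdms: Sequence[RDM], name: str = "combination", normalization: str = "minmax"
) -> RDM:
    """Average RDMs after normalizing each one's representational geometry.

    ``minmax`` rescales each upper triangle to [0, 1]; ``zscore`` then
    min-max is available behind the flag.  Constant RDMs are excluded with a
    warning; at least two usable inputs are required.
    """
    if len(rdms) < 2:
        raise ValueError("need at least 2 RDMs to combine")
    labels = rdms[0].labels
    usable = []
    for r in rdms:
        if r.labels != labels:
            raise ValueError("all RDMs must share labels")
        vec = r.vector()
        if np.ptp(vec) == 0:
            warnings.warn(f"constant RDM '{r.name}' excluded from combination")
            continue
        if normalization == "minmax":
            norm = (vec - vec.min()) / np.ptp(vec)
        elif normalization == "zscore":
            z = (vec - vec.mean()) / vec.std()
            norm = (z - z.min()) / np.ptp(z)
        else:
            raise ValueError(f"unknown normalization {normalization!r}")
        usable.append(norm)
    if len(usable) < 2:
        raise ValueError("fewer than 2 non-constant RDMs to combine")
    mean_vec = np.mean(usable, axis=0)
    n = len(labels)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = mean_vec
    m += m.T
    return RDM(m, labels, name, "combination")


def classical_mds(distances: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a square distance matrix.

    Double-centres the squared distances and embeds on the top eigenvectors;
    axes with non-positive eigenvalues come back as zeros.  Deterministic:
    each axis is sign-fixed so its largest-magnitude coordinate is positive.
    """
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n):
        raise ValueError("distance matrix must be square")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    coords = np.zeros((n, n_components))
    for k in range(min(n_components, n)):
        lam = vals[order[k]]
        if lam <= 0:
            continue
        axis = vecs[:, order[k]] * np.sqrt(lam)
        if axis[np.argmax(np.abs(axis))] < 0:
            axis = -axis
        coords[:, k] = axis
    return coords
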