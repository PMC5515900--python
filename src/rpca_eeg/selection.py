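"""F-score feature ranking.

The F-score of a feature is the one-way ANOVA ratio of between-class to
within-class variance over trials, with p-values from the upper tail of
the F(1, n-2) distribution for the two-class case.  Features with high
F and p below a significance level are the informative ones; no
multiple-testing correction is applied, mirroring the raw p < 0.05
usage this pipeline reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FeatureScore", "fscore", "ranked_indices", "significant_features", "scores_frame"]

#: replacement for an infinite variance ratio (zero within-class variance
#: with non-zero between-class variance); keeps the ranking total.
F_CAP = np.finfo(float).max


@dataclass(frozen=True)
class FeatureScore:
    feature_name: str
    F: float
    p: float
    rank: int  # 1-based position by descending F, ties broken by feature order


def fscore(
    X: np.ndarray, labels: np.ndarray, feature_names: list[str] | None = None
) -> list[FeatureScore]:
    """Per-feature one-way ANOVA F statistic and p-value.

    ``X`` is trials x features.  Requires at least two classes with at
    least two trials each.  Degenerate features are made deterministic:
    zero within- and between-class variance gives F = 0, p = 1; zero
    within-class variance alone gives the largest finite F with p = 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise ValueError("need at least two classes")
    counts = np.array([(labels == g).sum() for g in groups])
    if counts.min() < 2 or counts.sum() < 3:
        raise ValueError("need at least two trials per class")
    n = counts.sum()
    k = groups.size

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g, c in zip(groups, counts):
        xg = X[labels == g]
        mg = xg.mean(axis=0)
        ssb += c * (mg - grand) ** 2
        ssw += ((xg - mg) ** 2).sum(axis=0)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = stats.f.sf(F, k - 1, n - k)
    zero_w = np.isclose(msw, 0.0)
    zero_b = np.isclose(msb, 0.0)
    F = np.where(zero_w & ~zero_b, F_CAP, F)
    p = np.where(zero_w & ~zero_b, 0.0, p)
    F = np.where(zero_w & zero_b, 0.0, F)
    p = np.where(zero_w & zero_b, 1.0, p)

    if feature_names is None:
        feature_names = [f"f{i:03d}" for i in range(X.shape[1])]
    order = np.argsort(-F, kind="stable")  # ties broken by feature order
    rank = np.empty(X.shape[1], dtype=int)
    rank[order] = np.arange(1, X.shape[1] + 1)
    return [
        FeatureScore(feature_names[i], float(F[i]), float(p[i]), int(rank[i]))
        for i in range(X.shape[1])
    ]


def ranked_indices(scores: list[FeatureScore]) -> np.ndarray:
    """Feature indices sorted by rank (descending F, stable ties)."""
    return np.argsort([s.rank for s in scores], kind="stable")


def significant_features(scores: list[FeatureScore], alpha: float = 0.05) -> np.ndarray:
    """Boolean mask, true where p < alpha (no multiplicity correction)."""
    return np.array([s.p < alpha for s in scores])


def scores_frame(scores: list[FeatureScore]) -> pd.DataFrame:
    """Scores as a DataFrame (feature_name, F, p, rank) for CSV export."""
    return pd.DataFrame(
        {"feature_name": [s.feature_name for s in scores],
         "F": [s.F for s in scores],
         "p": [s.p for s in scores],
         "rank": [s.rank for s in scores]}
    )
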