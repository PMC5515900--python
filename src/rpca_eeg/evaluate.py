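"""Diagnostic analyses: class-distribution projection, importance maps,
and the paired Wilcoxon signed-rank test.

``discriminant_project`` reduces the 110-dimensional feature space to a
2-D view for visualizing cross-day class distributions.  For a
two-class problem the between-class scatter has rank one, so only one
discriminant direction exists; the second axis is defined here as the
leading residual-variance direction orthogonal to the first — a
deterministic substitute that preserves the intent (discriminant axis
plus spread axis).

``ImportanceMap`` holds one F-score-derived scalar per feature.  Maps
from different analytical manners within a day are min-max normalized
jointly so their magnitudes stay comparable; their dissimilarity is the
plain Euclidean distance (a longer distance means two more distinct
maps).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .selection import FeatureScore

__all__ = [
    "ProjectionResult",
    "discriminant_project",
    "importance_map",
    "joint_minmax",
    "map_distance",
    "wilcoxon_signed_rank",
]


@dataclass
class ProjectionResult:
    coords: np.ndarray  # (n_trials, 2)
    axes: np.ndarray  # (2, n_features), unit rows
    class_centroids: dict[str, np.ndarray]  # label -> 2-D centroid (boundary basis)
    day_class_centroids: dict[tuple[int, str], np.ndarray]
    boundary_point: np.ndarray  # midpoint of the two class centroids
    boundary_normal: np.ndarray  # difference of the two class centroids


def _fix_sign(v: np.ndarray) -> np.ndarray:
    nz = np.flatnonzero(np.abs(v) > 1e-12)
    if nz.size and v[nz[0]] < 0:
        return -v
    return v


def discriminant_project(
    X: np.ndarray,
    y: np.ndarray,
    days: np.ndarray | None = None,
    shrinkage: float = 0.1,
    boundary_mask: np.ndarray | None = None,
) -> ProjectionResult:
    """Two-axis discriminant view of trials x features data.

    Axis 1 is the leading generalized discriminant direction of
    between- vs within-class scatter, with the within-class scatter
    shrunk toward its diagonal (coefficient ``shrinkage``) because
    trials are typically far fewer than features.  Axis 2 is the top
    variance direction orthogonal to axis 1.  Both axes are unit-norm
    with the first non-zero loading positive, so projections are
    deterministic.

    The conceptual decision boundary is the line through the midpoint
    of the two class centroids, perpendicular to the centroid
    difference; with ``boundary_mask`` the centroids are computed on a
    subset (e.g. training days only).
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    if X.shape[0] <= 2:
        raise ValueError("need more than two trials")
    mu = {c: X[y == c].mean(axis=0) for c in classes}
    sw = np.zeros((X.shape[1], X.shape[1]))
    for c in classes:
        xc = X[y == c] - mu[c]
        sw += xc.T @ xc
    sw /= max(X.shape[0] - 2, 1)
    sw = (1 - shrinkage) * sw + shrinkage * np.diag(np.diag(sw))
    sw += 1e-12 * np.trace(sw) / X.shape[1] * np.eye(X.shape[1])
    w1 = np.linalg.solve(sw, mu[classes[1]] - mu[classes[0]])
    w1 = _fix_sign(w1 / np.linalg.norm(w1))

    xc = X - X.mean(axis=0)
    resid = xc - np.outer(xc @ w1, w1)
    _, _, vt = np.linalg.svd(resid, full_matrices=False)
    w2 = vt[0] - (vt[0] @ w1) * w1  # re-orthogonalize against axis 1
    w2 = _fix_sign(w2 / np.linalg.norm(w2))

    axes = np.vstack([w1, w2])
    coords = X @ axes.T
    if boundary_mask is None:
        boundary_mask = np.ones(X.shape[0], dtype=bool)
    cc = {str(c): coords[boundary_mask & (y == c)].mean(axis=0) for c in classes}
    day_cc: dict[tuple[int, str], np.ndarray] = {}
    if days is not None:
        days = np.asarray(days)
        for d in np.unique(days):
            for c in classes:
                sel = (days == d) & (y == c)
                if sel.any():
                    day_cc[(int(d), str(c))] = coords[sel].mean(axis=0)
    c0, c1 = cc[str(classes[0])], cc[str(classes[1])]
    return ProjectionResult(
        coords=coords, axes=axes, class_centroids=cc, day_class_centroids=day_cc,
        boundary_point=(c0 + c1) / 2, boundary_normal=c1 - c0,
    )


def importance_map(scores: list[FeatureScore]) -> np.ndarray:
    """Raw (unnormalized) per-feature importance: the F values."""
    return np.array([s.F for s in scores], dtype=float)


def joint_minmax(maps: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Min-max normalize several maps jointly to [0, 1].

    The scope is the concatenation of all maps (e.g. the four
    analytical manners within one day), so relative magnitudes between
    maps are preserved.  A fully constant concatenation maps to zeros.
    """
    stacked = np.concatenate([np.asarray(v, float) for v in maps.values()])
    lo, hi = stacked.min(), stacked.max()
    span = hi - lo
    if span == 0:
        return {k: np.zeros_like(np.asarray(v, float)) for k, v in maps.items()}
    return {k: (np.asarray(v, float) - lo) / span for k, v in maps.items()}


def map_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two vectorized feature maps."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"map length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped.  The null distribution is exact for
    up to 25 remaining pairs when there are no rank ties, and the
    normal approximation otherwise.
    """
    x = np.asarray(x, float)
    d = x if y is None else x - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all pairs are tied; the test is undefined")
    ranks = stats.rankdata(np.abs(d))
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
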