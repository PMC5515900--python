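"""Gaussian Naive Bayes over selected MESH features.

Per class and per feature a Gaussian is fitted by sample mean and
variance; prediction is the argmax over classes of the log prior plus
the summed per-feature log densities.  Variances are floored at
``1e-9`` times the largest per-feature variance of the training pool
(or ``1e-9`` absolute if everything is constant) so that constant
features after normalization cannot produce degenerate densities.  The
class list is kept lexicographically sorted and ties in the posterior
break to the first class.

This hand-rolled model exists (rather than delegating to an external
classifier) because the add-feature-in search needs per-feature log
likelihoods that can be accumulated across a feature ranking in one
vectorized pass; see ``per_feature_log_likelihood``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GnbModel", "fit_gnb", "predict", "per_feature_log_likelihood"]

VAR_FLOOR_REL = 1e-9


@dataclass
class GnbModel:
    classes: np.ndarray  # sorted labels
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), floored
    priors: np.ndarray  # (n_classes,), in (0,1), sums to 1
    feature_indices: np.ndarray | None = None  # selected subspace, optional

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "classes": [str(c) for c in self.classes],
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "priors": self.priors.tolist(),
            "feature_indices": None if self.feature_indices is None
            else [int(i) for i in self.feature_indices],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GnbModel":
        d = json.loads(Path(path).read_text())
        return cls(
            classes=np.array(d["classes"]),
            means=np.array(d["means"], float),
            variances=np.array(d["variances"], float),
            priors=np.array(d["priors"], float),
            feature_indices=None if d["feature_indices"] is None
            else np.array(d["feature_indices"], int),
        )


def _variance_floor(X: np.ndarray) -> float:
    pooled = X.var(axis=0)
    top = pooled.max() if pooled.size else 0.0
    return VAR_FLOOR_REL * top if top > 0 else VAR_FLOOR_REL


def fit_gnb(
    X: np.ndarray,
    y: np.ndarray,
    priors: np.ndarray | None = None,
    feature_indices: np.ndarray | None = None,
) -> GnbModel:
    """Fit per-class, per-feature Gaussians.

    ``priors`` defaults to the empirical class frequencies; pass
    ``(0.5, 0.5)`` to mimic training on balanced data without
    discarding trials.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y)
    classes = np.unique(y)  # sorted, hence lexicographic tie-break below
    if classes.size < 2:
        raise ValueError("need at least two classes")
    counts = np.array([(y == c).sum() for c in classes])
    if counts.min() < 2:
        raise ValueError("need at least two trials per class")
    floor = _variance_floor(X)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    variances = np.stack([np.maximum(X[y == c].var(axis=0), floor) for c in classes])
    if priors is None:
        priors = counts / counts.sum()
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (classes.size,) or not np.isclose(priors.sum(), 1.0) or np.any(priors <= 0):
        raise ValueError("priors must be positive and sum to 1, one per class")
    return GnbModel(classes=classes, means=means, variances=variances,
                    priors=priors, feature_indices=feature_indices)


def joint_log_likelihood(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """(n_trials, n_classes) log prior + summed log Gaussian densities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X has {X.shape[1]} features but the model expects {model.n_features}"
        )
    diff = X[:, None, :] - model.means[None, :, :]
    ll = -0.5 * (np.log(2 * np.pi * model.variances)[None] + diff**2 / model.variances[None])
    return ll.sum(axis=2) + np.log(model.priors)[None, :]


def predict(model: GnbModel, X: np.ndarray) -> np.ndarray:
    """Argmax-posterior labels; posterior ties go to the first (sorted) class."""
    jll = joint_log_likelihood(model, X)
    return model.classes[np.argmax(jll, axis=1)]


def per_feature_log_likelihood(
    means: np.ndarray, variances: np.ndarray, X: np.ndarray
) -> np.ndarray:
    """(n_trials, n_classes, n_features) per-feature log densities.

    Cumulative sums of this array over a ranked feature axis give the
    GNB joint log likelihood for every top-d feature subset at once,
    which is what makes the add-feature-in accuracy curve cheap.
    """
    diff = X[:, None, :] - means[None, :, :]
    return -0.5 * (np.log(2 * np.pi * variances)[None] + diff**2 / variances[None])
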