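"""MESH feature matrices.

MESH extends per-electrode band power with bi-directional power
asymmetries: six left-right (laterality) and four fronto-posterior
(caudality) electrode pairs.  With 12 electrodes that is 22 attributes
per band; over five bands the feature dimension is 110.

Row ordering is band-major and fixed: for each band in
delta/theta/alpha/beta/gamma order, first the 12 single-channel rows
(montage order), then the 6 laterality rows, then the 4 caudality
rows.  Feature names are ``"<attribute>:<band>"``, e.g. ``"F3:alpha"``
or ``"F3-F4:alpha"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import BAND_ORDER, CAUDALITY_PAIRS, CHANNELS, LATERALITY_PAIRS, N_MESH_FEATURES
from .spectral import BandPowerSeries

__all__ = ["MeshFeatureMatrix", "mesh_feature_names", "build_mesh", "trial_average"]


def mesh_feature_names(asymmetry: str = "difference") -> list[str]:
    """The fixed 110-entry row-name list, band-major."""
    sep = {"difference": "-", "ratio": "/", "log_ratio": "log/"}[asymmetry]
    names: list[str] = []
    for band in BAND_ORDER:
        names.extend(f"{ch}:{band}" for ch in CHANNELS)
        names.extend(f"{a}{sep}{b}:{band}" for a, b in LATERALITY_PAIRS)
        names.extend(f"{a}{sep}{b}:{band}" for a, b in CAUDALITY_PAIRS)
    return names


@dataclass
class MeshFeatureMatrix:
    """110 features x n windows, with trial metadata carried through."""

    values: np.ndarray
    feature_names: list[str]
    day: int = 0
    trial: int = 0
    label: str = "neutral"
    segment: str = "music"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.feature_names):
            raise ValueError("values must be (n_features, n_windows) matching feature_names")

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]


def _asymmetry(p_first: np.ndarray, p_second: np.ndarray, mode: str) -> np.ndarray:
    if mode == "difference":
        return p_first - p_second
    if mode == "ratio":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(p_second != 0, p_first / p_second, 0.0)
        return out
    if mode == "log_ratio":
        eps = np.finfo(float).tiny
        return np.log((p_first + eps) / (p_second + eps))
    raise ValueError(f"unknown asymmetry mode {mode!r}")


def build_mesh(bp: BandPowerSeries, asymmetry: str = "difference") -> MeshFeatureMatrix:
    """Assemble the 110 x n MESH matrix from a band-power series.

    The asymmetry operator defaults to the simple power difference of
    the ordered pair; ``ratio`` and ``log_ratio`` variants are provided
    behind this switch.  Asymmetries are computed on raw (pre-
    normalization) powers and may be negative.
    """
    for ch in CHANNELS:
        if ch not in bp.channel_labels:
            raise ValueError(f"band-power series is missing channel {ch!r}")
    for band in BAND_ORDER:
        if band not in bp.bands:
            raise ValueError(f"band-power series is missing band {band!r}")
    ch_idx = {ch: bp.channel_labels.index(ch) for ch in CHANNELS}
    b_idx = {b: bp.bands.index(b) for b in BAND_ORDER}

    rows: list[np.ndarray] = []
    for band in BAND_ORDER:
        p = bp.values[b_idx[band]]
        rows.extend(p[ch_idx[ch]] for ch in CHANNELS)
        rows.extend(
            _asymmetry(p[ch_idx[a]], p[ch_idx[b]], asymmetry)
            for a, b in LATERALITY_PAIRS
        )
        rows.extend(
            _asymmetry(p[ch_idx[a]], p[ch_idx[b]], asymmetry)
            for a, b in CAUDALITY_PAIRS
        )
    values = np.vstack(rows)
    assert values.shape[0] == N_MESH_FEATURES
    return MeshFeatureMatrix(
        values=values, feature_names=mesh_feature_names(asymmetry),
        day=bp.day, trial=bp.trial, label=bp.label, segment=bp.segment,
    )


def trial_average(mesh: MeshFeatureMatrix | np.ndarray) -> np.ndarray:
    """Collapse a trial's window series to one vector: per-feature mean."""
    values = mesh.values if isinstance(mesh, MeshFeatureMatrix) else np.asarray(mesh, float)
    if values.ndim != 2 or values.shape[1] == 0:
        raise ValueError("need a non-empty (n_features, n_windows) matrix")
    return values.mean(axis=1)
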