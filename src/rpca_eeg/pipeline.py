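"""End-to-end pipeline: manifest in, ADI report out.

Stage order follows the analysis this package reproduces:
extract (raw only) -> MESH -> min-max normalize -> optional RPCA
(keep L or S) -> trial-average -> add-day-in validation.  The
``original`` manner bypasses RPCA entirely and consumes the
(normalized) feature matrices directly.

All intermediates and a provenance record (config hash, seed, package
version) can be written to an output directory, so any artifact is
reproducible from the manifest plus the provenance JSON.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np

from . import __version__
from .adi import AdiReport, run_adi
from .config import PipelineConfig
from .io import Manifest, load_feature_trials, load_manifest, read_raw_record
from .mesh import build_mesh, mesh_feature_names, trial_average
from .rpca import rpca_decompose
from .spectral import highpass_filter, minmax_normalize, stft_bandpower

__all__ = ["extract_feature_matrices", "apply_manner", "run_pipeline"]


def extract_feature_matrices(
    manifest: Manifest, config: PipelineConfig, segment: str = "music"
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Trial feature matrices for one segment, normalized per config.

    Raw-level manifests go through high-pass filtering, STFT band
    power and MESH assembly; feature-level manifests are consumed as
    stored.  Day-scope normalization computes each feature's min/max
    over that day's music-listening windows and applies it to all of
    the day's trials, so no day borrows another day's scale.
    """
    if manifest.level == "feature":
        trials, days, labels = load_feature_trials(manifest, segment=segment)
        names = [f"f{i:03d}" for i in range(trials.shape[1])]
    else:
        recs = [r for r in manifest.records if not r.excluded]
        mats, day_list, label_list = [], [], []
        for r in recs:
            raw = read_raw_record(manifest, r)
            bp = stft_bandpower(
                highpass_filter(raw, cutoff=config.highpass_cutoff),
                window_seconds=config.window_seconds, overlap=config.overlap,
            )
            mesh = build_mesh(bp, asymmetry=config.asymmetry)
            mats.append(mesh.values)
            day_list.append(r.day)
            label_list.append(r.label)
        keep = [i for i, r in enumerate(recs) if r.segment == segment]
        trials = np.stack([mats[i] for i in keep])
        days = np.array([day_list[i] for i in keep])
        labels = np.array([label_list[i] for i in keep])
        names = mesh_feature_names(config.asymmetry)

    if config.normalization_scope == "trial":
        trials = np.stack([minmax_normalize(t) for t in trials])
    elif config.normalization_scope == "day":
        trials = trials.copy()
        for d in np.unique(days):
            sel = days == d
            concat = np.concatenate(list(trials[sel]), axis=1)
            lo = concat.min(axis=1, keepdims=True)
            span = concat.max(axis=1, keepdims=True) - lo
            for i in np.flatnonzero(sel):
                out = np.zeros_like(trials[i])
                np.divide(trials[i] - lo, span, out=out, where=span > 0)
                trials[i] = out
    elif config.normalization_scope != "none":
        raise ValueError(f"unknown normalization scope {config.normalization_scope!r}")
    return trials, days, labels, names


def apply_manner(
    trials: np.ndarray, days: np.ndarray, config: PipelineConfig
) -> np.ndarray:
    """Route matrices through the configured manner; return trial vectors."""
    if config.manner == "original":
        return np.stack([trial_average(t) for t in trials])
    if config.manner not in ("rpca_sparse", "rpca_low_rank"):
        raise ValueError(f"unknown manner {config.manner!r}")
    part = "S" if config.manner == "rpca_sparse" else "L"
    kw = dict(lam=config.lam, lambda_rule=config.lambda_rule,
              tol=config.rpca_tol, max_iter=config.rpca_max_iter)
    if config.rpca_scope == "trial":
        comps = [getattr(rpca_decompose(t, **kw), part) for t in trials]
    elif config.rpca_scope == "day":
        comps = [None] * len(trials)
        for d in np.unique(days):
            idx = np.flatnonzero(days == d)
            widths = [trials[i].shape[1] for i in idx]
            res = rpca_decompose(np.concatenate([trials[i] for i in idx], axis=1), **kw)
            for i, piece in zip(idx, np.split(getattr(res, part), np.cumsum(widths)[:-1], axis=1)):
                comps[i] = piece
    else:
        raise ValueError(f"unknown rpca scope {config.rpca_scope!r}")
    return np.stack([trial_average(c) for c in comps])


def run_pipeline(
    config: PipelineConfig,
    manifest: Manifest | str | Path,
    outdir: str | Path | None = None,
) -> AdiReport:
    """Full pipeline for one manner/segment; optionally persist artifacts."""
    if not isinstance(manifest, Manifest):
        manifest = load_manifest(manifest)
    trials, days, labels, names = extract_feature_matrices(
        manifest, config, segment=config.segment
    )
    vectors = apply_manner(trials, days, config)
    report = run_adi(
        vectors, days, labels, manner=config.manner, segment=config.segment,
        reps=config.reps, folds=config.folds, seed=config.seed, feature_names=names,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "adi_report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True)
        )
        report.summary().to_csv(outdir / "adi_summary.csv", index=False)
        np.savetxt(outdir / "trial_vectors.tsv", vectors, delimiter="\t")
        (outdir / "provenance.json").write_text(json.dumps({
            "config": config.to_dict(),
            "config_hash": config.hash,
            "seed": config.seed,
            "package_version": __version__,
            "python": platform.python_version(),
        }, indent=2, sort_keys=True))
    return report
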