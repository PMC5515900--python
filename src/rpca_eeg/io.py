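"""Manifests and on-disk formats.

A dataset directory holds one TSV per trial plus a ``manifest.json``.
Feature-level trial TSVs have rows = features and columns = windows,
with a header row of window indices and the feature name in the first
column; raw-level TSVs use rows = channels.  EDF input is supported for
raw trials when the optional ``mne`` dependency is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS, LABELS
from .spectral import RawTrial
from .synthetic import SyntheticDataset

__all__ = [
    "ManifestRecord",
    "Manifest",
    "load_manifest",
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_dataset",
    "load_feature_trials",
    "read_raw_record",
]


@dataclass(frozen=True)
class ManifestRecord:
    subject: str
    day: int
    trial: int
    label: str
    segment: str  # music | baseline
    path: str
    format: str = "tsv"  # tsv | edf
    ground_truth: str | None = None

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.subject, self.day, self.trial, self.segment)

    @property
    def excluded(self) -> bool:
        """Neutral-rated music trials are excluded from classification."""
        return self.label == "neutral" and self.segment == "music"


@dataclass
class Manifest:
    records: list[ManifestRecord]
    sampling_rate: float = 128.0
    montage: tuple[str, ...] = CHANNELS
    level: str = "feature"  # feature | raw
    root: Path = field(default_factory=Path)

    def resolve(self, record: ManifestRecord) -> Path:
        return self.root / record.path

    def included(self) -> list[ManifestRecord]:
        return [r for r in self.records if not r.excluded]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "metadata": {
                "sampling_rate": self.sampling_rate,
                "montage": list(self.montage),
                "level": self.level,
            },
            "records": [
                {k: v for k, v in asdict(r).items() if v is not None}
                for r in self.records
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def load_manifest(path: str | Path) -> Manifest:
    """Load and validate a manifest.

    Rejects empty record lists, unknown labels, duplicate
    (subject, day, trial, segment) keys and missing files, naming the
    offending record in each case.
    """
    path = Path(path)
    payload = json.loads(path.read_text())
    meta = payload.get("metadata", {})
    records = [ManifestRecord(**r) for r in payload.get("records", [])]
    if not records:
        raise ValueError(f"{path}: manifest contains no records")
    manifest = Manifest(
        records=records,
        sampling_rate=float(meta.get("sampling_rate", 128.0)),
        montage=tuple(meta.get("montage", CHANNELS)),
        level=meta.get("level", "feature"),
        root=path.parent,
    )
    seen: set[tuple] = set()
    for r in records:
        if r.label not in LABELS:
            raise ValueError(f"record {r.key}: unknown label {r.label!r}")
        if r.segment not in ("music", "baseline"):
            raise ValueError(f"record {r.key}: unknown segment {r.segment!r}")
        if r.key in seen:
            raise ValueError(f"duplicate record key {r.key}")
        seen.add(r.key)
        if not manifest.resolve(r).exists():
            raise ValueError(f"record {r.key}: file not found: {manifest.resolve(r)}")
    return manifest


def write_matrix_tsv(path: str | Path, values: np.ndarray, row_names: list[str]) -> None:
    """Rows = named features/channels, columns = window/sample indices."""
    values = np.asarray(values)
    df = pd.DataFrame(values, index=row_names, columns=np.arange(values.shape[1]))
    df.to_csv(path, sep="\t", index_label="name")


def read_matrix_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, subject: str = "s01") -> Path:
    """Write a synthetic feature-level dataset as TSVs plus manifest.

    Ground-truth components are written next to each trial
    (``*_background.tsv``, ``*_sparse.tsv``) together with a
    ``ground_truth.json`` holding the support indices and signs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    names = [f"f{i:03d}" for i in range(dataset.config.n_features)]
    records: list[ManifestRecord] = []
    for t in dataset.trials:
        stem = f"{subject}_d{t.day}_{t.segment}_{t.label}_{t.trial:02d}"
        write_matrix_tsv(outdir / f"{stem}.tsv", t.values, names)
        gt = None
        if t.background is not None:
            write_matrix_tsv(outdir / f"{stem}_background.tsv", t.background, names)
            write_matrix_tsv(outdir / f"{stem}_sparse.tsv", t.sparse, names)
            gt = f"{stem}_background.tsv"
        records.append(ManifestRecord(
            subject=subject, day=t.day, trial=t.trial, label=t.label,
            segment=t.segment, path=f"{stem}.tsv", format="tsv", ground_truth=gt,
        ))
    manifest = Manifest(records=records, level="feature", root=outdir)
    manifest.to_json(outdir / "manifest.json")
    (outdir / "ground_truth.json").write_text(json.dumps({
        "support": [int(i) for i in dataset.support],
        "support_signs": [float(s) for s in dataset.support_signs],
        "config": asdict(dataset.config),
    }, indent=2))
    return outdir / "manifest.json"


def load_feature_trials(
    manifest: Manifest, segment: str = "music", include_excluded: bool = False
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack feature-level trial matrices: (trials, days, labels) arrays."""
    if manifest.level != "feature":
        raise ValueError("manifest is not feature-level")
    recs = [
        r for r in manifest.records
        if r.segment == segment and (include_excluded or not r.excluded)
    ]
    if not recs:
        raise ValueError(f"no usable {segment!r} records in manifest")
    mats = [read_matrix_tsv(manifest.resolve(r))[0] for r in recs]
    return (np.stack(mats),
            np.array([r.day for r in recs]),
            np.array([r.label for r in recs]))


def read_raw_record(manifest: Manifest, record: ManifestRecord) -> RawTrial:
    """Read one raw trial (TSV, or EDF via the optional mne dependency)."""
    path = manifest.resolve(record)
    if record.format == "tsv":
        values, names = read_matrix_tsv(path)
        return RawTrial(
            samples=values, sampling_rate=manifest.sampling_rate,
            channel_labels=tuple(names), day=record.day, trial=record.trial,
            label=record.label, segment=record.segment,
        )
    if record.format == "edf":
        try:
            import mne
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading EDF requires the optional 'mne' dependency") from exc
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        picks = [ch for ch in raw.ch_names if ch in manifest.montage]
        raw.pick(picks)
        return RawTrial(
            samples=raw.get_data() * 1e6,  # volts -> microvolts
            sampling_rate=raw.info["sfreq"], channel_labels=tuple(raw.ch_names),
            day=record.day, trial=record.trial, label=record.label,
            segment=record.segment,
        )
    raise ValueError(f"unknown format {record.format!r}")
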