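"""Pipeline configuration.

Every default matches the published analysis settings where one exists:
1-s Hamming STFT window with 50% overlap, five canonical bands, lambda
= 1/max(m, n), 100 balanced repetitions, 5-fold cross-validation, and
a raw significance level of 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    # spectral extraction
    highpass_cutoff: float = 1.0  # Hz
    window_seconds: float = 1.0
    overlap: float = 0.5
    asymmetry: str = "difference"  # difference | ratio | log_ratio
    #: min-max normalization scope for extracted features:
    #: "day" (per feature, per day, over that day's music windows),
    #: "trial", or "none".  Test days always use their own min/max.
    normalization_scope: str = "day"
    # RPCA
    lambda_rule: str = "paper"  # paper: 1/max(m,n); sqrt: 1/sqrt(max(m,n))
    lam: float | None = None  # explicit override of the rule
    rpca_tol: float = 1e-7
    rpca_max_iter: int = 1000
    rpca_scope: str = "trial"  # trial | day (per-day concatenated matrices)
    # selection / classification / validation
    manner: str = "original"  # original | rpca_sparse | rpca_low_rank
    segment: str = "music"  # music | baseline
    reps: int = 100
    folds: int = 5
    alpha: float = 0.05
    seed: int = 0

    def replace(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    @property
    def hash(self) -> str:
        """Stable digest of the full configuration, for provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
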