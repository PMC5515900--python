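"""Synthetic multi-day EEG datasets with known ground truth.

The real five-day music-listening dataset the method was designed for
is not public, so this module emulates its statistical structure at two
levels:

* **feature level** — per-subject, per-day sets of labeled trials, each
  a ``n_features x windows_per_trial`` matrix composed of a day-varying
  low-rank background (shared subspace rotated per day, plus a per-day
  feature offset), a day-stable sparse class-discriminative component,
  and i.i.d. Gaussian noise.  These matrices stand in for MESH feature
  matrices at the point where the RPCA decomposition consumes them.
* **raw-signal level** — 12-channel band-limited sinusoid mixtures with
  class-modulated alpha/gamma amplitudes plus 1/f noise, to exercise
  the spectral feature-extraction chain end to end.

The class-discriminative component is sparse both across features
(``sparse_support`` rows) and across time: each support row carries
events at a small fraction of windows, with a class-dependent signed
amplitude scaled so the per-trial row mean differs between classes by
``effect_size``.  Temporal sparsity matters: a component constant
across windows is rank one, which a nuclear-norm/l1 decomposition
correctly assigns to the low-rank part, not the sparse part.

All randomness flows from ``config.seed`` through named substreams
("support", "basis", ("day", d), ("trial", d, segment, label, i)), so
datasets are bit-reproducible and any one trial can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import substream
from .montage import CHANNELS
from .spectral import RawTrial

__all__ = [
    "SyntheticConfig",
    "FeatureTrial",
    "SyntheticDataset",
    "generate_feature_dataset",
    "generate_raw_trial",
]

CLASSES = ("happiness", "sadness")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the feature-level generator.

    Defaults emulate one subject of the five-day music protocol: 5 days
    of 12 trials per class, 110 features, 73 one-second half-overlapped
    windows per ~37-s trial.  ``day_drift`` controls both the rotation
    of the background subspace and the per-day, per-feature offset of
    the background level; its default is calibrated so that the
    original (undecomposed) features test near chance across days while
    within-day structure stays intact (see docs/methods.md).
    """

    n_days: int = 5
    trials_per_day: int = 12  # per class
    n_features: int = 110
    background_rank: int = 4
    day_drift: float = 3.0
    sparse_support: int = 10
    effect_size: float = 0.6
    noise_sd: float = 1.0
    windows_per_trial: int = 73
    seed: int = 0
    #: fraction of windows on which a support row carries an event
    event_rate: float = 0.15
    #: scale of the rank-r background U_d V^T
    background_scale: float = 1.0

    def validate(self) -> None:
        if min(self.n_days, self.trials_per_day, self.n_features,
               self.background_rank, self.windows_per_trial) < 1:
            raise ValueError("all counts must be >= 1")
        if self.trials_per_day <= 0:
            raise ValueError("trials_per_day must be positive")
        if self.background_rank >= min(self.n_features, self.windows_per_trial):
            raise ValueError("background_rank must be < min(n_features, windows_per_trial)")
        if self.sparse_support > self.n_features:
            raise ValueError("sparse_support cannot exceed n_features")
        if self.day_drift < 0 or self.noise_sd < 0:
            raise ValueError("day_drift and noise_sd must be non-negative")
        if not 0 < self.event_rate <= 1:
            raise ValueError("event_rate must be in (0, 1]")


@dataclass
class FeatureTrial:
    """One feature-level trial with its ground-truth decomposition."""

    values: np.ndarray  # (n_features, n_windows) = background + sparse + noise
    label: str
    day: int  # 1-based
    trial: int
    segment: str = "music"
    background: np.ndarray | None = None
    sparse: np.ndarray | None = None
    noise: np.ndarray | None = None


@dataclass
class SyntheticDataset:
    """Per-day labeled feature trials plus generator ground truth."""

    config: SyntheticConfig
    trials: list[FeatureTrial]
    support: np.ndarray  # indices of class-discriminative features
    support_signs: np.ndarray  # +-1 per support feature, fixed across days
    day_bases: list[np.ndarray]  # U_d, one per day
    day_offsets: list[np.ndarray]  # b_d, one per day

    def day_trials(self, day: int, segment: str = "music") -> list[FeatureTrial]:
        return [t for t in self.trials if t.day == day and t.segment == segment]

    def as_arrays(self, segment: str = "music") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(stacked trial matrices, day indices, labels) for one segment."""
        ts = [t for t in self.trials if t.segment == segment]
        X = np.stack([t.values for t in ts])
        days = np.array([t.day for t in ts])
        labels = np.array([t.label for t in ts])
        return X, days, labels


def _orthonormal(rng: np.random.Generator, m: int, r: int) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((m, r)))
    return q


def _day_basis(u0: np.ndarray, drift: float, rng: np.random.Generator) -> np.ndarray:
    """Random orthogonal perturbation of U_0 with angle growing with drift."""
    if drift == 0:
        return u0
    m, r = u0.shape
    g = rng.standard_normal((m, r)) / np.sqrt(m)
    q, _ = np.linalg.qr(u0 + drift * g)
    # Align column signs with U_0 so drift -> 0 is continuous.
    sign = np.sign(np.sum(q * u0, axis=0))
    sign[sign == 0] = 1.0
    return q * sign


def generate_feature_dataset(
    config: SyntheticConfig, include_baseline: bool = False
) -> SyntheticDataset:
    """Generate a multi-day feature-level dataset with ground truth.

    Each trial matrix is ``background + sparse + noise`` exactly, with
    all three components retained.  The class effect enters only the
    ``sparse_support`` rows: events at ``event_rate`` of the windows
    with amplitude ``sign * effect_size / (2 * event_rate)``, so the
    expected per-row trial mean is ``+-effect_size/2`` and the
    between-class gap is ``effect_size``.

    With ``include_baseline=True`` each music trial is paired with a
    baseline-segment trial drawn from the same day background but with
    no class component; it inherits the music trial's label, mirroring
    a pre-stimulus rest period tagged with the subsequently rated
    emotion.
    """
    config.validate()
    m, r, n = config.n_features, config.background_rank, config.windows_per_trial

    rng_support = substream(config.seed, "support")
    support = np.sort(rng_support.choice(m, size=config.sparse_support, replace=False))
    signs = rng_support.choice([-1.0, 1.0], size=config.sparse_support)

    u0 = _orthonormal(substream(config.seed, "basis"), m, r)

    trials: list[FeatureTrial] = []
    day_bases: list[np.ndarray] = []
    day_offsets: list[np.ndarray] = []
    amp = config.effect_size / (2.0 * config.event_rate)

    for day in range(1, config.n_days + 1):
        rng_day = substream(config.seed, "day", day)
        u_d = _day_basis(u0, config.day_drift, rng_day)
        b_d = config.day_drift * rng_day.standard_normal(m)
        day_bases.append(u_d)
        day_offsets.append(b_d)
        segments = ("music", "baseline") if include_baseline else ("music",)
        for label_idx, label in enumerate(CLASSES):
            class_sign = 1.0 if label == CLASSES[0] else -1.0
            # trial indices unique within a day across classes
            offset = label_idx * config.trials_per_day
            for i in range(config.trials_per_day):
                for segment in segments:
                    rng_t = substream(config.seed, "trial", day, segment, label, i)
                    v = rng_t.standard_normal((n, r))
                    background = config.background_scale * (u_d @ v.T) + b_d[:, None]
                    sparse = np.zeros((m, n))
                    if segment == "music" and config.effect_size > 0:
                        events = rng_t.random((config.sparse_support, n)) < config.event_rate
                        sparse[support] = events * (class_sign * signs[:, None] * amp)
                    noise = config.noise_sd * rng_t.standard_normal((m, n))
                    trials.append(FeatureTrial(
                        values=background + sparse + noise,
                        label=label, day=day, trial=offset + i, segment=segment,
                        background=background, sparse=sparse, noise=noise,
                    ))
    return SyntheticDataset(
        config=config, trials=trials, support=support, support_signs=signs,
        day_bases=day_bases, day_offsets=day_offsets,
    )


# ---------------------------------------------------------------------------
# raw-signal mode

#: band -> (representative frequency Hz, default amplitude uV)
DEFAULT_RAW_AMPLITUDES = {
    "delta": (2.0, 4.0),
    "theta": (5.5, 3.0),
    "alpha": (10.0, 5.0),
    "beta": (22.0, 2.0),
    "gamma": (37.0, 1.0),
}

#: channels whose alpha/gamma amplitudes are modulated by emotion class
DEFAULT_MODULATED_CHANNELS = ("AF3", "F7", "F3", "AF4", "F4", "F8")


def generate_raw_trial(
    label: str,
    sampling_rate: float = 128.0,
    duration: float = 37.0,
    seed: int = 0,
    amplitudes: dict[str, tuple[float, float]] | None = None,
    class_gain: float = 0.5,
    noise_scale: float = 1.0,
    modulated_channels: tuple[str, ...] = DEFAULT_MODULATED_CHANNELS,
    day: int = 1,
    trial: int = 0,
) -> RawTrial:
    """One 12-channel raw trial of band-limited sinusoids plus 1/f noise.

    Each channel is a sum of one sinusoid per canonical band (random
    phase per channel).  On ``modulated_channels`` the alpha amplitude
    is scaled by ``1 + class_gain`` for happiness and ``1 - class_gain``
    for sadness, and the gamma amplitude oppositely — a deliberately
    stylized class effect, not a physiological claim.  Ground-truth
    amplitudes are attached as ``trial.ground_truth``.
    """
    if label not in ("happiness", "sadness", "baseline"):
        raise ValueError(f"unknown label {label!r}")
    if duration < 2.0:
        raise ValueError("duration must be at least 2 s")
    amplitudes = DEFAULT_RAW_AMPLITUDES if amplitudes is None else amplitudes
    rng = substream(seed, "raw", label, day, trial)
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate
    n_ch = len(CHANNELS)
    x = np.zeros((n_ch, t.size))
    truth: dict[str, np.ndarray] = {}
    for band, (freq, amp) in amplitudes.items():
        amps = np.full(n_ch, float(amp))
        if label != "baseline":
            gain = 1.0 + class_gain if label == "happiness" else 1.0 - class_gain
            mod = np.array([ch in modulated_channels for ch in CHANNELS])
            if band == "alpha":
                amps[mod] *= gain
            elif band == "gamma":
                amps[mod] *= 2.0 - gain
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        x += amps[:, None] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
        truth[band] = amps
    if noise_scale > 0:
        x += noise_scale * _pink_noise(rng, n_ch, t.size)
    out = RawTrial(
        samples=x, sampling_rate=sampling_rate, channel_labels=CHANNELS,
        day=day, trial=trial, label=label,
        segment="baseline" if label == "baseline" else "music",
    )
    out.ground_truth = truth  # type: ignore[attr-defined]
    return out


def _pink_noise(rng: np.random.Generator, n_ch: int, n: int) -> np.ndarray:
    """Gaussian noise shaped to a 1/f amplitude spectrum."""
    freqs = np.fft.rfftfreq(n)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spectrum = (rng.standard_normal((n_ch, freqs.size))
                + 1j * rng.standard_normal((n_ch, freqs.size))) * shaping
    x = np.fft.irfft(spectrum, n=n, axis=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd
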