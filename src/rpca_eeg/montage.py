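"""Electrode montage and spectral-band definitions.

The montage is the 12-channel subset of a 14-channel consumer headset
(T7/T8 dropped), with six left-right (laterality) and four
fronto-posterior (caudality) electrode pairs used for power-asymmetry
features.
"""

from __future__ import annotations

#: 12 retained electrodes, in canonical order.
CHANNELS: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "P7", "O1",
    "O2", "P8", "FC6", "F4", "F8", "AF4",
)

#: Ordered left-right pairs; the asymmetry is power(left) - power(right).
LATERALITY_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "AF4"), ("F7", "F8"), ("F3", "F4"),
    ("FC5", "FC6"), ("P7", "P8"), ("O1", "O2"),
)

#: Ordered frontal-posterior pairs; the asymmetry is power(frontal) - power(posterior).
CAUDALITY_PAIRS: tuple[tuple[str, str], ...] = (
    ("AF3", "O1"), ("F7", "P7"), ("AF4", "O2"), ("F8", "P8"),
)

#: Band name -> inclusive (low, high) edge frequencies in Hz.  The gamma
#: band stops at 43 Hz, the upper bandwidth limit of the headset.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 13.0),
    "beta": (14.0, 30.0),
    "gamma": (31.0, 43.0),
}

BAND_ORDER: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Emotion labels a music trial may carry; neutral trials are excluded
#: from classification, baseline marks eye-closed rest segments.
LABELS: tuple[str, ...] = ("happiness", "sadness", "neutral", "baseline")

#: 22 electrode attributes x 5 bands.
N_MESH_FEATURES: int = (len(CHANNELS) + len(LATERALITY_PAIRS) + len(CAUDALITY_PAIRS)) * len(BANDS)
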