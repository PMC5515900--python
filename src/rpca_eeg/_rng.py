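"""Seed fan-out.

All randomness in the package flows from a single master seed.  Named
substreams are derived with ``numpy.random.SeedSequence`` so that each
component (simulation, class balancing, fold shuffling, ...) is
reproducible in isolation: the substream for a given name and master
seed never depends on how many other substreams were consumed.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: object) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The name path is hashed (CRC32 of its repr) into the spawn key, so
    ``substream(7, "balance", rep)`` yields independent, reproducible
    streams for every repetition index.
    """
    keys = [zlib.crc32(repr(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=keys))
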