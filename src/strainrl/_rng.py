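"""Seeded random-number substreams.

Every source of randomness in the package flows from a single root seed
through a named substream, so adding a new random consumer never perturbs
the draws of existing ones and any run is bit-reproducible from its seed.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, *names: str) -> np.random.Generator:
    """Return a Generator for the substream identified by ``names``.

    The stream is a pure function of ``(seed, names)``: the names are hashed
    with CRC-32 (stable across platforms and sessions, unlike Python's
    ``hash``) and folded into a :class:`numpy.random.SeedSequence`.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    entropy.extend(zlib.crc32(n.encode("utf-8")) for n in names)
    return np.random.default_rng(np.random.SeedSequence(entropy))
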