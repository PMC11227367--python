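"""Deterministic, position-based seed derivation.

Every stochastic step in the pipeline (a repetition of an engine fit, a
null permutation, a bootstrap draw) receives a seed derived from the master
seed and the *coordinates* of the step (gene index, alpha index, dataset
kind, repetition index) — never from the order in which work happens to be
scheduled. Results are therefore identical regardless of worker count.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed"]


def child_seed(master: int, *keys: object) -> np.random.SeedSequence:
    """Derive a :class:`numpy.random.SeedSequence` from a master seed and keys.

    Integer keys are used directly (mod 2**32); other keys are hashed with
    CRC32 so that string labels such as ``"null"`` participate stably.
    """
    words = [int(master) & 0xFFFFFFFF]
    for key in keys:
        if isinstance(key, (int, np.integer)):
            words.append(int(key) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(key).encode("utf8")))
    return np.random.SeedSequence(words)
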