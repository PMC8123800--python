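"""Deterministic random-stream derivation.

One root seed governs the whole pipeline; every stage, bootstrap resample and
iteration draws from an independent child stream derived with
``numpy.random.SeedSequence`` spawn keys.  String keys are hashed with CRC32 so
that streams can be keyed by stage or feature *name* (stable under column
reordering) rather than by position.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _as_key(part: int | str) -> int:
    if isinstance(part, str):
        return zlib.crc32(part.encode("utf-8"))
    return int(part) & 0xFFFFFFFF


def child_seed_sequence(seed: int, *key: int | str) -> np.random.SeedSequence:
    """Derive an independent :class:`~numpy.random.SeedSequence` child."""
    return np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_as_key(k) for k in key))


def child_rng(seed: int, *key: int | str) -> np.random.Generator:
    """A generator on an independent stream keyed by ``(seed, *key)``."""
    return np.random.default_rng(child_seed_sequence(seed, *key))
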