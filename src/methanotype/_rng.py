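"""Deterministic random-number streams.

Every stochastic routine in the package draws from a stream derived from an
explicit integer seed plus a tuple of context keys (cow id, period, library
id, ...).  Child streams are independent, and dropping one entity never
perturbs the stream of another.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_rng", "key_to_int"]


def key_to_int(key: object) -> int:
    """Map an arbitrary hashable key to a stable 32-bit integer."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def child_rng(seed: int, *keys: object) -> np.random.Generator:
    """Return a Generator seeded from ``seed`` and a tuple of context keys.

    The same (seed, keys) always yields the same stream, on any platform.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
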