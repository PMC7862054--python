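"""Shared helpers: seed fan-out and small numeric utilities."""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a global seed by stable hashing.

    Toggling one pipeline stage must not shift the random streams of the
    others, so each stage hashes its own name together with the global seed.
    The result is kept below 2**31 so it is a valid seed everywhere.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_from(seed_or_rng) -> np.random.Generator:
    """Accept an int seed or an existing Generator and return a Generator."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
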