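"""Deterministic seed fan-out.

A single global seed reproduces every stochastic component: sub-seeds are
derived by hashing the global seed together with a path of string/int
tokens, so independent components never share a stream and the derivation
is stable across processes and platforms.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]

_MOD = 2**31 - 1  # keep derived seeds comfortably below 2**31


def derive_seed(seed: int, *tokens: object) -> int:
    """Derive a sub-seed from ``seed`` and a token path.

    Uses SHA-256 over the textual path, reduced mod 2**31 - 1. The same
    (seed, tokens) pair always yields the same sub-seed.
    """
    h = hashlib.sha256()
    h.update(str(int(seed)).encode())
    for t in tokens:
        h.update(b"/")
        h.update(str(t).encode())
    return int.from_bytes(h.digest()[:8], "big") % _MOD


def rng_for(seed: int, *tokens: object) -> np.random.Generator:
    """A NumPy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, *tokens))
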