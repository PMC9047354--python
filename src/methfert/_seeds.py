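"""Deterministic seed fan-out.

A single top-level seed is expanded into independent per-stage child seeds so
that re-running one pipeline stage in isolation reproduces the full-run result.
The derivation is a stable hash of (seed, stage name); no global state.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "stage_rng"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a reproducible 31-bit child seed for a named stage."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Generator seeded for one named stage of a run."""
    return np.random.default_rng(child_seed(seed, stage))
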