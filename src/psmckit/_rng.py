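"""Seed-stream management.

All randomness flows through numpy's PCG64 generator.  A single master seed
plus a short text label deterministically derives every sub-stream (SHA-256 of
``"<master>:<label>"``, truncated to 31 bits), so each pipeline stage is
independently replayable from the logged (master, label) pair.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, label: str) -> int:
    digest = hashlib.sha256(f"{master}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def rng_for(master: int, label: str) -> np.random.Generator:
    """PCG64 generator for the sub-stream named ``label``."""
    return np.random.default_rng(derive_seed(master, label))
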