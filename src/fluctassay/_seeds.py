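"""Deterministic, label-keyed seed derivation.

Child streams are keyed by stable string labels (e.g. strain_id, reporter)
hashed with SHA-256, so adding or reordering strains in a panel never
perturbs another strain's draws, and the same (seed, labels) pair yields
identical streams on every platform.
"""

from __future__ import annotations

import hashlib

import numpy as np


def seed_sequence_for(seed: int, *labels: str) -> np.random.SeedSequence:
    digest = hashlib.sha256("\x1f".join(str(x) for x in labels).encode("utf-8")).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words])


def rng_for(seed: int, *labels: str) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(seed_sequence_for(seed, *labels)))
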