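"""Small shared helpers: symbol normalization, rounding, per-pair RNG streams."""

from __future__ import annotations

import hashlib
import math

import numpy as np


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol (applied before any set operation)."""
    return symbol.strip().upper()


def round_half_away(x: float) -> int:
    """Round half away from zero (the convention behind printed per-entity averages)."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


def mean_per_entity(n_interactions: int, n_entities: int) -> int:
    """Average set size over entities, rounded half away from zero.

    E.g. 43,839 compound-gene interactions over 102 compounds -> 430.
    """
    if n_entities <= 0:
        raise ValueError("n_entities must be positive")
    return round_half_away(n_interactions / n_entities)


def stable_hash64(*parts: str) -> int:
    """Deterministic 64-bit hash of string parts (independent of PYTHONHASHSEED)."""
    digest = hashlib.blake2b("\x1f".join(parts).encode("utf-8"), digest_size=8)
    return int.from_bytes(digest.digest(), "big")


def pair_rng(seed: int, *labels: str) -> np.random.Generator:
    """RNG substream keyed by (seed, labels) so results are order-independent."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), stable_hash64(*labels)]))
    )


def substream(seed: int, index: int) -> np.random.Generator:
    """Indexed RNG substream derived from a master seed."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), int(index)]))
    )
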