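"""Shared helpers: coordinate conventions, seeding, small I/O utilities.

Coordinate conventions used throughout the package:

* GWAS summary statistics carry 1-based positions (``BP`` column).
* BED peak intervals are 0-based half-open ``[start, end)``.
* FIMO motif-hit intervals are 1-based inclusive ``[start, stop]``.

All overlap queries are performed in 0-based half-open space; the two
converters below are the only place the off-by-one lives.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np


def pos_1based_to_0based(pos: int) -> int:
    """Convert a 1-based genomic position to its 0-based coordinate."""
    if pos < 1:
        raise ValueError(f"1-based position must be >= 1, got {pos}")
    return pos - 1


def fimo_to_half_open(start: int, stop: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    if stop < start:
        raise ValueError(f"interval stop {stop} < start {start}")
    return start - 1, stop


def derive_seed(seed: int, stage: int) -> int:
    """Per-stage seed derived from a single pipeline seed.

    Kept below 2**31 so every consumer (numpy, sklearn) accepts it.
    """
    return (int(seed) + int(stage)) % (2**31 - 1)


def rng_from(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(int(seed))


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def catalog_hash(feature_ids) -> str:
    """Stable hash of an ordered feature catalog, stored with trained models."""
    payload = json.dumps(list(map(str, feature_ids))).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
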