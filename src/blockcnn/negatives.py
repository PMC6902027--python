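"""False-case generation by within-group feature shuffling.

Negative training blocks are built from true blocks by permuting, for each
SNP column independently, the entries of that column within each feature
group (open chromatin, histone, pathway, TF motif). The per-column,
per-group count of active features is preserved exactly, so negatives match
the marginal annotation density of true cases while destroying any pattern
shared across blocks. Ten negatives per true block is the default ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BlockFeatureMatrix
from .util import rng_from

DEFAULT_NEG_RATIO = 10


@dataclass
class ShuffleSpec:
    """How negatives are drawn: ratio, feature-group partition, seed."""

    neg_ratio: int = DEFAULT_NEG_RATIO
    group_partition: dict[str, str] = field(default_factory=dict)  # feature_id -> group
    seed: int = 0
    per_block: bool = False  # one permutation per block instead of per SNP column

    def __post_init__(self) -> None:
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")


def _group_rows(feature_ids: list[str], partition: dict[str, str]) -> list[np.ndarray]:
    """Row-index arrays, one per feature group, covering every row once."""
    missing = [f for f in feature_ids if f not in partition]
    if missing:
        raise ValueError(
            f"group partition does not cover features {missing[:3]}"
            f"{'...' if len(missing) > 3 else ''}"
        )
    by_group: dict[str, list[int]] = {}
    for i, f in enumerate(feature_ids):
        by_group.setdefault(partition[f], []).append(i)
    return [np.asarray(idx) for idx in by_group.values()]


def shuffle_block_features(
    X: BlockFeatureMatrix,
    spec: ShuffleSpec,
    rng: np.random.Generator,
    copy_index: int = 0,
) -> BlockFeatureMatrix:
    """One shuffled (label-0) copy of a true block."""
    if X.label != 1:
        raise ValueError("negatives are shuffled from true (label-1) blocks")
    rows_by_group = _group_rows(X.feature_ids, spec.group_partition)
    shuffled = X.X.copy()
    for rows in rows_by_group:
        if spec.per_block:
            perm = rng.permutation(len(rows))
            shuffled[rows, :] = shuffled[rows[perm], :]
        else:
            for n in range(shuffled.shape[1]):
                perm = rng.permutation(len(rows))
                shuffled[rows, n] = shuffled[rows[perm], n]
    return BlockFeatureMatrix(
        block_id=f"{X.block_id}::neg{copy_index}",
        snp_ids=list(X.snp_ids),
        feature_ids=list(X.feature_ids),
        X=shuffled,
        label=0,
        lead_index=X.lead_index,
        source_id=X.block_id,
    )


def generate_negatives(
    true_blocks: list[BlockFeatureMatrix],
    spec: ShuffleSpec,
) -> list[BlockFeatureMatrix]:
    """``neg_ratio`` shuffled copies per true block, deterministic under seed."""
    if not true_blocks:
        raise ValueError("no true blocks to shuffle")
    rng = rng_from(spec.seed)
    negatives = []
    for block in true_blocks:
        for i in range(spec.neg_ratio):
            negatives.append(shuffle_block_features(block, spec, rng, copy_index=i))
    return negatives


def uniform_partition(feature_ids: list[str], group: str = "all") -> dict[str, str]:
    """Single-group partition (used when no group metadata is available)."""
    return {f: group for f in feature_ids}
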