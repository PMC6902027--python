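"""Prediction and performance evaluation.

A SNP is a positive call when its prediction score is strictly greater
than 0.5. Performance is reported at block level — true blocks against
their shuffled negatives — with rank-based AUC and F1 at the 0.5 calling
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .features import BlockFeatureMatrix
from .model import ModelParams, snp_scores, _block_view
from .util import catalog_hash

CALL_THRESHOLD = 0.5


@dataclass
class PredictionRecord:
    block_id: str
    snp_id: str
    score: float
    call: str  # "positive" | "negative"


@dataclass
class PerformanceReport:
    auc: float
    f1: float
    n_true: int
    n_false: int
    variant: str


def predict(
    model: ModelParams, blocks: list[BlockFeatureMatrix]
) -> tuple[list[PredictionRecord], pd.DataFrame]:
    """Per-SNP scores/calls plus a per-block table (max-pooled score).

    Refuses to score blocks whose feature catalog differs from the one the
    model was trained on.
    """
    records: list[PredictionRecord] = []
    block_rows = []
    for blk in blocks:
        if model.catalog and catalog_hash(blk.feature_ids) != model.catalog:
            raise ValueError(
                f"block {blk.block_id}: feature catalog does not match the "
                "catalog the model was trained on"
            )
        o = snp_scores(_block_view(blk, model.variant), model)
        view_ids = (
            [blk.snp_ids[blk.lead_index]] if model.variant == "lead_only" else blk.snp_ids
        )
        for snp_id, score in zip(view_ids, o):
            call = "positive" if score > CALL_THRESHOLD else "negative"
            records.append(PredictionRecord(blk.block_id, snp_id, float(score), call))
        block_rows.append((blk.block_id, blk.label, float(np.max(o))))
    block_table = pd.DataFrame(block_rows, columns=["block_id", "label", "score"])
    return records, block_table


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def f1(calls, labels) -> float:
    """F1 of positive calls (score > 0.5) against block labels."""
    calls = np.asarray(calls, dtype=bool)
    labels = np.asarray(labels, dtype=int)
    tp = int(np.sum(calls & (labels == 1)))
    fp = int(np.sum(calls & (labels == 0)))
    fn = int(np.sum(~calls & (labels == 1)))
    if tp + fp == 0:
        raise ValueError(
            "no predicted positives: F1 undefined; review the calling threshold"
        )
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return 2 * precision * recall / (precision + recall)


def performance_report(block_table: pd.DataFrame, variant: str = "full") -> PerformanceReport:
    scores = block_table["score"].to_numpy()
    labels = block_table["label"].to_numpy()
    return PerformanceReport(
        auc=auc(scores, labels),
        f1=f1(scores > CALL_THRESHOLD, labels),
        n_true=int((labels == 1).sum()),
        n_false=int((labels == 0).sum()),
        variant=variant,
    )


def lead_concordance(
    records: list[PredictionRecord], blocks: list[BlockFeatureMatrix]
) -> tuple[float | None, int, int]:
    """Among blocks with >= 1 positive call, fraction whose lead is positive.

    Returns (fraction, n_concordant, n_positive_blocks); fraction is None
    when no block has a positive call.
    """
    by_block: dict[str, list[PredictionRecord]] = {}
    for rec in records:
        by_block.setdefault(rec.block_id, []).append(rec)
    n_pos_blocks = 0
    n_concordant = 0
    for blk in blocks:
        recs = by_block.get(blk.block_id, [])
        if not any(r.call == "positive" for r in recs):
            continue
        n_pos_blocks += 1
        if blk.lead_index is None:
            continue
        lead_snp = blk.snp_ids[blk.lead_index]
        if any(r.snp_id == lead_snp and r.call == "positive" for r in recs):
            n_concordant += 1
    if n_pos_blocks == 0:
        return None, 0, 0
    return n_concordant / n_pos_blocks, n_concordant, n_pos_blocks


def write_predictions(records: list[PredictionRecord], path) -> None:
    pd.DataFrame(
        [(r.block_id, r.snp_id, r.score, r.call) for r in records],
        columns=["block_id", "snp_id", "score", "call"],
    ).to_csv(path, sep="\t", index=False)
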