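"""Functional validation statistics for positive versus negative calls.

Given per-SNP calls with genomic positions, these tests ask whether
positive calls (score > 0.5) are preferentially located in external
regulatory evidence: overlap fractions with interval sets (e.g. histone
peaks, TF footprints), enrichment ranking across tissues, and the odds
ratio of calls in evolutionarily conserved positions (conservation score
strictly greater than 0.5) with a Wald 95% confidence interval on the log
scale and a Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import fisher_exact

from .util import pos_1based_to_0based

CONSERVATION_THRESHOLD = 0.5
Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class OverlapResult:
    name: str
    fraction_positive: float
    fraction_negative: float
    table: tuple[tuple[int, int], tuple[int, int]]  # rows: pos/neg; cols: in/out
    p: float


@dataclass
class OddsRatioResult:
    or_value: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool = False  # Haldane-Anscombe 0.5 applied to a zero cell


def _interval_trees(intervals: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in intervals.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    return trees


def _overlap_mask(calls: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    trees = _interval_trees(intervals) if len(intervals) else {}
    mask = np.zeros(len(calls), dtype=bool)
    for i, row in enumerate(calls.itertuples(index=False)):
        tree = trees.get(str(row.chrom))
        if tree is not None and tree.overlaps_point(pos_1based_to_0based(int(row.pos))):
            mask[i] = True
    return mask


def _split_calls(calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Positive (> 0.5) and negative (< 0.5) masks; exactly 0.5 excluded."""
    score = calls["score"].to_numpy(dtype=float)
    pos = score > 0.5
    neg = score < 0.5
    if not pos.any():
        raise ValueError("no positive calls: overlap test undefined for an empty class")
    if not neg.any():
        raise ValueError("no negative calls: overlap test undefined for an empty class")
    return pos, neg


def overlap_fraction_test(
    calls: pd.DataFrame, intervals: pd.DataFrame, name: str = ""
) -> OverlapResult:
    """Fractions of positive/negative calls inside an interval set + Fisher p.

    ``calls`` needs columns chrom, pos (1-based), score; ``intervals`` is a
    BED-style frame (chrom, start, end; 0-based half-open).
    """
    pos, neg = _split_calls(calls)
    if len(intervals) == 0:
        return OverlapResult(name, 0.0, 0.0, ((0, int(pos.sum())), (0, int(neg.sum()))), 1.0)
    inside = _overlap_mask(calls, intervals)
    a = int((pos & inside).sum())
    b = int((pos & ~inside).sum())
    c = int((neg & inside).sum())
    d = int((neg & ~inside).sum())
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return OverlapResult(
        name=name,
        fraction_positive=a / (a + b),
        fraction_negative=c / (c + d),
        table=((a, b), (c, d)),
        p=float(p),
    )


def _haldane_or(a: int, b: int, c: int, d: int) -> float:
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def tissue_enrichment_rank(
    calls: pd.DataFrame, interval_sets: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Rank interval sets (tissues) by positive-call enrichment odds ratio.

    Descending odds ratio; ties broken by set name. Zero cells receive the
    Haldane-Anscombe 0.5 correction so every set gets a finite ratio.
    """
    pos, neg = _split_calls(calls)
    rows = []
    for name in sorted(interval_sets):
        inside = _overlap_mask(calls, interval_sets[name])
        a = int((pos & inside).sum())
        b = int((pos & ~inside).sum())
        c = int((neg & inside).sum())
        d = int((neg & ~inside).sum())
        rows.append((name, _haldane_or(a, b, c, d)))
    table = pd.DataFrame(rows, columns=["set", "odds_ratio"])
    return table.sort_values(
        ["odds_ratio", "set"], ascending=[False, True], ignore_index=True
    )


def odds_ratio_from_table(a: int, b: int, c: int, d: int) -> OddsRatioResult:
    """OR = (a/c)/(b/d) with Wald log-scale 95% CI and Fisher exact p.

    Zero cells get the Haldane-Anscombe 0.5 correction (flagged).
    """
    _, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    corrected = min(a, b, c, d) == 0
    aa, bb, cc, dd = (
        (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
    )
    or_value = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    return OddsRatioResult(
        or_value=float(or_value),
        ci_low=float(np.exp(np.log(or_value) - Z_95 * se)),
        ci_high=float(np.exp(np.log(or_value) + Z_95 * se)),
        p=float(p),
        corrected=corrected,
    )


def conserved_odds_ratio(
    calls: pd.DataFrame,
    conservation: pd.DataFrame,
    threshold: float = CONSERVATION_THRESHOLD,
) -> OddsRatioResult:
    """Odds of positive calls in conserved versus non-conserved positions.

    A SNP is conserved iff its conservation score is strictly greater than
    ``threshold``. ``conservation`` has columns chrom, pos (1-based),
    score; every call position must be covered.
    """
    pos, neg = _split_calls(calls)
    lookup = {
        (str(r.chrom), int(r.pos)): float(r.score)
        for r in conservation.itertuples(index=False)
    }
    cons = np.zeros(len(calls), dtype=bool)
    for i, row in enumerate(calls.itertuples(index=False)):
        key = (str(row.chrom), int(row.pos))
        if key not in lookup:
            raise ValueError(f"no conservation score for SNP at {key[0]}:{key[1]}")
        cons[i] = lookup[key] > threshold
    a = int((pos & cons).sum())       # positive, conserved
    b = int((pos & ~cons).sum())      # positive, non-conserved
    c = int((neg & cons).sum())       # negative, conserved
    d = int((neg & ~cons).sum())      # negative, non-conserved
    # OR = (positives/negatives in conserved) / (positives/negatives outside)
    return odds_ratio_from_table(a, c, b, d)


def read_conservation(path) -> pd.DataFrame:
    """Per-position conservation scores: TSV with chrom, pos, score."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "pos", "score"} <= set(df.columns):
        raise ValueError("conservation table needs columns chrom, pos, score")
    return df
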