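"""Binary feature mapping: annotations -> per-block feature matrices.

Each retained feature is one binary channel per SNP: open-chromatin or
histone peak overlap, pathway membership of a linked gene, or a significant
transcription-factor motif hit at the SNP position. Features mapped to at
least one SNP in more than 95% of association blocks are retained; the rest
are dropped (sparse features overfit the downstream model).

Assignments are carried as a long-format DataFrame with columns
``feature_id, group, block_id, snp_id`` (one row per 1-cell), the same
layout the sparse assignment TSV uses on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .blocks import SNP, AssociationBlock
from .util import fimo_to_half_open, pos_1based_to_0based

GROUP_OPEN_CHROMATIN = "open_chromatin"
GROUP_HISTONE = "histone"
GROUP_PATHWAY = "pathway"
GROUP_TF_MOTIF = "tf_motif"

DEFAULT_UPSTREAM_WINDOW = 500_000
DEFAULT_MOTIF_P_MAX = 1e-4
DEFAULT_MIN_BLOCK_FRACTION = 0.95

ASSIGNMENT_COLUMNS = ["feature_id", "group", "block_id", "snp_id"]


@dataclass
class BlockFeatureMatrix:
    """The M x N binary input of one block: features (rows) x SNPs (cols)."""

    block_id: str
    snp_ids: list[str]
    feature_ids: list[str]
    X: np.ndarray                      # int8, shape (M, N)
    label: int = 1
    lead_index: int | None = None      # column of the lead SNP, if known
    source_id: str | None = None       # true block a negative was shuffled from

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int8)
        if self.X.shape != (len(self.feature_ids), len(self.snp_ids)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.snp_ids)} SNPs"
            )
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("feature matrix must be binary")
        if self.source_id is None:
            self.source_id = self.block_id

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def _empty_assignments() -> pd.DataFrame:
    return pd.DataFrame(columns=ASSIGNMENT_COLUMNS)


def _rows_to_frame(rows: list[tuple]) -> pd.DataFrame:
    if not rows:
        return _empty_assignments()
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


# ---------------------------------------------------------------------------
# Readers for the annotation source formats


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ (chrom, start, end[, name]); 0-based half-open intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from exc
            if end <= start:
                raise ValueError(f"{path}: empty/inverted interval at line {lineno}")
            name = parts[3] if len(parts) > 3 else f"{path}"
            rows.append((parts[0], start, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene TSV: gene, chrom, strand, tss, start, end (1-based body interval)."""
    genes = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str, "strand": str})
    required = {"gene", "chrom", "strand", "tss", "start", "end"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene table missing columns {sorted(missing)}")
    return genes


def read_pathway_table(path: str | Path) -> pd.DataFrame:
    """Pathway membership TSV: pathway, gene."""
    pw = pd.read_csv(path, sep="\t", dtype=str)
    if not {"pathway", "gene"} <= set(pw.columns):
        raise ValueError("pathway table must have columns (pathway, gene)")
    return pw


def read_motif_hits(path: str | Path) -> pd.DataFrame:
    """FIMO-style TSV; requires motif_id, sequence_name, start, stop, p-value."""
    hits = pd.read_csv(path, sep="\t", comment="#", dtype={"motif_id": str})
    if "sequence_name" not in hits.columns and "chrom" in hits.columns:
        hits = hits.rename(columns={"chrom": "sequence_name"})
    required = {"motif_id", "sequence_name", "start", "stop"}
    missing = required - set(hits.columns)
    if missing:
        raise ValueError(f"motif table missing columns {sorted(missing)}")
    if "p-value" not in hits.columns:
        raise ValueError("motif table missing p-value column")
    return hits


# ---------------------------------------------------------------------------
# Mapping operations


def _interval_trees(frame: pd.DataFrame) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in frame.groupby("chrom"):
        trees[str(chrom)] = IntervalTree.from_tuples(
            (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
        )
    return trees


def _all_snps(blocks: list[AssociationBlock]):
    for block in blocks:
        for snp in block.members:
            yield block, snp


def map_peak_features(
    blocks: list[AssociationBlock],
    peak_tracks: dict[str, pd.DataFrame],
    group: str = GROUP_OPEN_CHROMATIN,
) -> pd.DataFrame:
    """Assign SNP to a peak track iff its (0-based) position lies in a peak.

    ``peak_tracks`` maps track/feature id -> BED frame (0-based half-open).
    """
    rows = []
    for track_id, bed in peak_tracks.items():
        trees = _interval_trees(bed)
        for block, snp in _all_snps(blocks):
            tree = trees.get(snp.chrom)
            if tree is not None and tree.overlaps_point(pos_1based_to_0based(snp.pos)):
                rows.append((track_id, group, block.block_id, snp.snp))
    return _rows_to_frame(rows)


def map_pathway_features(
    blocks: list[AssociationBlock],
    genes: pd.DataFrame,
    pathways: pd.DataFrame,
    upstream_window: int = DEFAULT_UPSTREAM_WINDOW,
) -> pd.DataFrame:
    """Assign SNP to every pathway of every gene it is linked to.

    A SNP links to a gene when it lies in the gene body (strand-agnostic,
    1-based inclusive interval) or within ``upstream_window`` bp 5' of the
    TSS (strand-aware; the boundary at exactly ``upstream_window`` bp is
    included).
    """
    known = set(genes["gene"])
    gene_pathways: dict[str, list[str]] = {}
    for r in pathways.itertuples(index=False):
        if r.gene not in known:
            continue  # pathway references a gene absent from the table: skip
        gene_pathways.setdefault(str(r.gene), []).append(str(r.pathway))

    # 1-based inclusive assignment intervals per gene: body + upstream.
    trees: dict[str, IntervalTree] = {}
    payload: list[str] = []
    for g in genes.itertuples(index=False):
        if str(g.strand) not in ("+", "-"):
            continue  # unstranded gene: upstream undefined, skip entirely
        body = (int(g.start), int(g.end))
        tss = int(g.tss)
        if str(g.strand) == "+":
            upstream = (tss - upstream_window, tss - 1)
        else:
            upstream = (tss + 1, tss + upstream_window)
        idx = len(payload)
        payload.append(str(g.gene))
        tree = trees.setdefault(str(g.chrom), IntervalTree())
        for lo, hi in (body, upstream):
            if hi >= lo:
                tree.addi(lo, hi + 1, idx)  # store 1-based inclusive as half-open

    rows = []
    for block, snp in _all_snps(blocks):
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        seen: set[str] = set()
        for iv in tree.at(snp.pos):
            gene = payload[iv.data]
            for pw in gene_pathways.get(gene, ()):
                if pw not in seen:
                    seen.add(pw)
                    rows.append((pw, GROUP_PATHWAY, block.block_id, snp.snp))
    return _rows_to_frame(rows)


def map_motif_features(
    blocks: list[AssociationBlock],
    motif_hits: pd.DataFrame,
    hit_p_max: float = DEFAULT_MOTIF_P_MAX,
) -> pd.DataFrame:
    """Assign SNP to a motif iff it overlaps a hit with p <= ``hit_p_max``.

    Hit intervals are 1-based inclusive (FIMO convention).
    """
    if "p-value" not in motif_hits.columns:
        raise ValueError("motif table missing p-value column")
    strong = motif_hits[motif_hits["p-value"].astype(float) <= hit_p_max]

    trees: dict[tuple[str, str], IntervalTree] = {}
    for hit in strong.itertuples(index=False):
        lo, hi = fimo_to_half_open(int(hit.start), int(hit.stop))
        key = (str(hit.motif_id), str(hit.sequence_name))
        trees.setdefault(key, IntervalTree()).addi(lo, hi)

    rows = []
    for block, snp in _all_snps(blocks):
        pos0 = pos_1based_to_0based(snp.pos)
        for (motif_id, chrom), tree in trees.items():
            if chrom == snp.chrom and tree.overlaps_point(pos0):
                rows.append((motif_id, GROUP_TF_MOTIF, block.block_id, snp.snp))
    return _rows_to_frame(rows)


def combine_assignments(*frames: pd.DataFrame) -> pd.DataFrame:
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_assignments()
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(ignore_index=True)


def filter_features(
    assignments: pd.DataFrame,
    blocks: list[AssociationBlock],
    min_block_fraction: float = DEFAULT_MIN_BLOCK_FRACTION,
) -> pd.DataFrame:
    """Block-coverage filter: retain features present in > 95% of blocks.

    Returns the retained feature catalog (feature_id, group, coverage) in
    first-appearance order. The inequality is strict: a feature mapped to
    SNPs in exactly 95% of blocks is dropped.
    """
    if not blocks:
        raise ValueError("coverage filter needs at least one block")
    n_blocks = len(blocks)
    rows = []
    seen: set[str] = set()
    if len(assignments):
        per_feature = assignments.drop_duplicates(["feature_id", "block_id"])
        counts = per_feature.groupby("feature_id", sort=False)["block_id"].nunique()
        groups = assignments.drop_duplicates("feature_id").set_index("feature_id")["group"]
        for feature_id in assignments["feature_id"].drop_duplicates():
            cov = counts[feature_id] / n_blocks
            if cov > min_block_fraction and feature_id not in seen:
                seen.add(feature_id)
                rows.append((feature_id, groups[feature_id], cov))
    return pd.DataFrame(rows, columns=["feature_id", "group", "coverage"])


def build_input_matrix(
    block: AssociationBlock,
    catalog: pd.DataFrame,
    assignments: pd.DataFrame,
) -> BlockFeatureMatrix:
    """Assemble the binary M x N matrix of one block.

    Rows follow catalog order; columns follow ascending genomic position of
    the block's SNPs. SNPs with no assignment rows are all-zero columns.
    """
    members = sorted(block.members, key=lambda s: (s.chrom, s.pos))
    snp_ids = [s.snp for s in members]
    feature_ids = list(catalog["feature_id"])
    feat_index = {f: i for i, f in enumerate(feature_ids)}
    snp_index = {s: j for j, s in enumerate(snp_ids)}
    X = np.zeros((len(feature_ids), len(snp_ids)), dtype=np.int8)
    here = assignments[assignments["block_id"] == block.block_id]
    for r in here.itertuples(index=False):
        i = feat_index.get(r.feature_id)
        j = snp_index.get(r.snp_id)
        if i is not None and j is not None:
            X[i, j] = 1
    lead_index = snp_index[block.lead.snp]
    return BlockFeatureMatrix(
        block_id=block.block_id,
        snp_ids=snp_ids,
        feature_ids=feature_ids,
        X=X,
        label=1,
        lead_index=lead_index,
    )


def build_input_matrices(
    blocks: list[AssociationBlock],
    catalog: pd.DataFrame,
    assignments: pd.DataFrame,
) -> list[BlockFeatureMatrix]:
    return [build_input_matrix(b, catalog, assignments) for b in blocks]


# ---------------------------------------------------------------------------
# On-disk formats


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def write_catalog(catalog: pd.DataFrame, path: str | Path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"feature_id": str, "group": str})
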