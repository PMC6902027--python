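"""Synthetic inputs for every stage of the pipeline.

Three generators:

* ``simulate_summary_stats`` — GWAS-like association tables with one
  intended lead SNP per locus and loci spaced more than 1 Mb apart.
* ``simulate_annotations`` — a bundle of peak tracks (BED), a gene table,
  a pathway-membership table, and FIMO-style motif hits, all parseable by
  the feature-mapping readers.
* ``simulate_block_dataset`` — labeled block feature matrices with a
  planted causal pattern carried by one or more "carrier" SNPs per true
  block, plus count-preserving shuffled negatives.

Pattern logics: ``AND`` (a carrier has every pattern feature set), ``OR``
(a carrier has a random non-empty subset set), and ``XOR-pair`` (the
pattern features split into two disjoint halves; a carrier has every
feature of exactly one half set and none of the other). The XOR-pair
construction is deliberately not separable by a single linear kernel under
max-pooling: any weight vector scoring both halves above all cross-mixed
columns leads to contradictory orderings, while two ReLU kernels (one per
half) separate it — which is what makes the two-layer model measurably
better than the one-layer ablation on such data.

Background cells — every cell outside the carrier-column pattern rows —
are independent Bernoulli draws; real annotation correlation structure is
not emulated. The carrier's column position is uniform at random and never
forced to coincide with the block's (randomly designated) lead SNP.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BlockFeatureMatrix
from .negatives import ShuffleSpec, generate_negatives, uniform_partition
from .util import rng_from

MIN_LOCUS_SPACING = 1_000_000
PATTERN_LOGICS = ("AND", "OR", "XOR-pair")


@dataclass
class PatternSpec:
    """Description of the planted causal pattern."""

    pattern_features: tuple[int, ...]
    logic: str = "AND"
    carrier_fraction: float = 1.0
    background_rate: float = 0.05
    n_carriers_per_block: int = 1

    def __post_init__(self) -> None:
        self.pattern_features = tuple(sorted(set(int(i) for i in self.pattern_features)))
        if self.logic not in PATTERN_LOGICS:
            raise ValueError(f"unknown pattern logic {self.logic!r}")
        if self.logic == "XOR-pair" and len(self.pattern_features) % 2:
            raise ValueError("XOR-pair needs an even number of pattern features")
        if not (0 <= self.background_rate <= 0.5):
            raise ValueError("background_rate must be in [0, 0.5]")
        if not (0 <= self.carrier_fraction <= 1):
            raise ValueError("carrier_fraction must be in [0, 1]")
        if self.n_carriers_per_block < 1:
            raise ValueError("n_carriers_per_block must be >= 1")


@dataclass
class SyntheticDataset:
    """Labeled blocks plus ground truth about the planted carriers."""

    blocks: list[BlockFeatureMatrix]
    truth: dict[str, list[int]]   # block_id -> carrier column indices
    seed: int = 0

    @property
    def true_blocks(self) -> list[BlockFeatureMatrix]:
        return [b for b in self.blocks if b.label == 1]

    @property
    def false_blocks(self) -> list[BlockFeatureMatrix]:
        return [b for b in self.blocks if b.label == 0]


# ---------------------------------------------------------------------------
# Summary statistics


def simulate_summary_stats(
    n_loci: int,
    snps_per_locus: int,
    chrom_length: int = 50_000_000,
    p_floor: float = 1e-12,
    seed: int = 0,
    chrom: str = "1",
    locus_halfwidth: int = 400_000,
) -> pd.DataFrame:
    """GWAS-like table with one intended lead per locus.

    Locus centers are evenly spaced (strictly more than 1 Mb apart); the
    center SNP of each locus gets the locus-minimal P value and its
    neighbors draw P log-uniformly from [p_floor, 0.05], scattered within
    ``locus_halfwidth`` of the center. Positions are 1-based and sorted.
    """
    if n_loci < 1 or snps_per_locus < 1:
        raise ValueError("n_loci and snps_per_locus must be >= 1")
    spacing = chrom_length // (n_loci + 1)
    if n_loci > 1 and spacing <= MIN_LOCUS_SPACING:
        raise ValueError(
            f"chrom_length {chrom_length} too small to space {n_loci} loci "
            f"more than {MIN_LOCUS_SPACING} bp apart"
        )
    rng = rng_from(seed)
    rows = []
    for locus in range(n_loci):
        center = spacing * (locus + 1)
        neighbor_p = 10 ** rng.uniform(np.log10(p_floor), np.log10(0.05), snps_per_locus - 1)
        lead_p = max(p_floor * 0.1, (neighbor_p.min() if len(neighbor_p) else p_floor) * 0.1)
        offsets: set[int] = set()
        while len(offsets) < snps_per_locus - 1:
            off = int(rng.integers(-locus_halfwidth, locus_halfwidth + 1))
            if off != 0:
                offsets.add(off)
        rows.append((f"rs{locus}_lead", chrom, center, lead_p))
        for i, (off, p) in enumerate(zip(sorted(offsets), neighbor_p)):
            rows.append((f"rs{locus}_{i}", chrom, center + off, float(p)))
    stats = pd.DataFrame(rows, columns=["SNP", "CHR", "BP", "P"])
    return stats.sort_values(["CHR", "BP"], ignore_index=True)


# ---------------------------------------------------------------------------
# Annotation bundle


@dataclass
class AnnotationBundle:
    peaks: dict[str, pd.DataFrame]    # track id -> BED frame (0-based half-open)
    genes: pd.DataFrame               # gene, chrom, strand, tss, start, end
    pathways: pd.DataFrame            # pathway, gene
    motif_hits: pd.DataFrame          # FIMO-style

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every source to ``outdir``; returns name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for track, bed in self.peaks.items():
            path = outdir / f"peaks_{track}.bed"
            bed.assign(name=track).to_csv(path, sep="\t", header=False, index=False)
            paths[f"peaks_{track}"] = path
        for name, frame in (
            ("genes", self.genes),
            ("pathways", self.pathways),
            ("motifs", self.motif_hits),
        ):
            path = outdir / f"{name}.tsv"
            frame.to_csv(path, sep="\t", index=False)
            paths[name] = path
        return paths


def simulate_annotations(
    genes: int = 20,
    pathways: int = 5,
    peaks_per_track: int = 100,
    tracks: int = 4,
    motifs: int = 10,
    seed: int = 0,
    chrom: str = "1",
    chrom_length: int = 50_000_000,
) -> AnnotationBundle:
    """Random but well-formed annotation sources over one chromosome.

    Peaks are drawn wide (5-50 kb) so tracks cover a substantial fraction
    of the chromosome and survive the downstream block-coverage filter on
    densely sampled blocks.
    """
    for name, v in (("genes", genes), ("pathways", pathways),
                    ("peaks_per_track", peaks_per_track), ("tracks", tracks),
                    ("motifs", motifs)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    rng = rng_from(seed)

    peak_tracks: dict[str, pd.DataFrame] = {}
    for t in range(tracks):
        starts = np.sort(rng.integers(0, chrom_length - 50_000, peaks_per_track))
        lengths = rng.integers(5_000, 50_000, peaks_per_track)
        peak_tracks[f"track{t}"] = pd.DataFrame(
            {"chrom": chrom, "start": starts, "end": starts + lengths, "name": f"track{t}"}
        )

    gene_rows = []
    for g in range(genes):
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, chrom_length - 200_000))
        end = start + int(rng.integers(5_000, 200_000))
        tss = start if strand == "+" else end
        gene_rows.append((f"gene{g}", chrom, strand, tss, start, end))
    gene_table = pd.DataFrame(
        gene_rows, columns=["gene", "chrom", "strand", "tss", "start", "end"]
    )

    pw_rows = []
    for p in range(pathways):
        size = int(rng.integers(1, max(2, genes // 2) + 1))
        for g in rng.choice(genes, size=size, replace=False):
            pw_rows.append((f"pathway{p}", f"gene{g}"))
    pathway_table = pd.DataFrame(pw_rows, columns=["pathway", "gene"])

    hit_rows = []
    for m in range(motifs):
        n_hits = int(rng.integers(50, 200))
        starts = rng.integers(1, chrom_length - 30, n_hits)  # 1-based inclusive
        widths = rng.integers(6, 20, n_hits)
        pvals = 10 ** rng.uniform(-6, -2, n_hits)
        for s, w, pv in zip(starts, widths, pvals):
            strand = "+" if rng.random() < 0.5 else "-"
            hit_rows.append(
                (f"motif{m}", chrom, int(s), int(s + w - 1), strand,
                 float(rng.uniform(5, 25)), float(pv))
            )
    motif_table = pd.DataFrame(
        hit_rows,
        columns=["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"],
    )
    return AnnotationBundle(peak_tracks, gene_table, pathway_table, motif_table)


# ---------------------------------------------------------------------------
# Labeled block datasets with planted patterns


def _carrier_column(spec: PatternSpec, rng: np.random.Generator, M: int) -> np.ndarray:
    """Pattern-row values of one carrier column according to the logic."""
    rows = np.array(spec.pattern_features)
    values = np.zeros(len(rows), dtype=np.int8)
    if spec.logic == "AND":
        values[:] = 1
    elif spec.logic == "OR":
        while values.sum() == 0:
            values = (rng.random(len(rows)) < 0.5).astype(np.int8)
    else:  # XOR-pair: all of one half, none of the other
        half = len(rows) // 2
        if rng.random() < 0.5:
            values[:half] = 1
        else:
            values[half:] = 1
    return values


def simulate_block_dataset(
    n_true: int,
    M: int,
    N: int,
    spec: PatternSpec,
    neg_ratio: int = 10,
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> SyntheticDataset:
    """Labeled dataset: n_true planted blocks + neg_ratio shuffled copies each.

    Every block is M features x N SNPs with a random lead column; true
    blocks carry ``spec.n_carriers_per_block`` carrier SNPs at uniform
    random columns (subject to ``carrier_fraction``). Negatives are drawn
    by the within-group shuffler (single group spanning all features unless
    ``groups`` is given).
    """
    if N > 31:
        raise ValueError("N must be <= 31 (lead + 30 neighbors)")
    if not spec.pattern_features or max(spec.pattern_features) >= M:
        raise ValueError("pattern features must be a non-empty subset of [0, M)")
    rng = rng_from(seed)
    feature_ids = [f"f{m}" for m in range(M)]
    pattern_rows = np.array(spec.pattern_features)

    true_blocks: list[BlockFeatureMatrix] = []
    truth: dict[str, list[int]] = {}
    for t in range(n_true):
        X = (rng.random((M, N)) < spec.background_rate).astype(np.int8)
        carriers: list[int] = []
        if rng.random() < spec.carrier_fraction:
            k = min(spec.n_carriers_per_block, N)
            carriers = sorted(rng.choice(N, size=k, replace=False).tolist())
            for col in carriers:
                X[pattern_rows, col] = _carrier_column(spec, rng, M)
        block_id = f"sim{t}"
        true_blocks.append(
            BlockFeatureMatrix(
                block_id=block_id,
                snp_ids=[f"{block_id}_snp{j}" for j in range(N)],
                feature_ids=feature_ids,
                X=X,
                label=1,
                lead_index=int(rng.integers(N)),
            )
        )
        truth[block_id] = carriers

    shuffle = ShuffleSpec(
        neg_ratio=neg_ratio,
        group_partition=groups or uniform_partition(feature_ids),
        seed=int(rng.integers(2**31 - 1)),
    )
    negatives = generate_negatives(true_blocks, shuffle)
    return SyntheticDataset(blocks=true_blocks + negatives, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# Dataset archive (shared JSON container)


def save_dataset(dataset: SyntheticDataset, path: str | Path) -> None:
    blocks = dataset.blocks
    payload = {
        "seed": dataset.seed,
        "feature_ids": blocks[0].feature_ids if blocks else [],
        "truth": dataset.truth,
        "blocks": [
            {
                "block_id": b.block_id,
                "snp_ids": b.snp_ids,
                "label": b.label,
                "lead_index": b.lead_index,
                "source_id": b.source_id,
                "X": b.X.tolist(),
            }
            for b in blocks
        ],
    }
    Path(path).write_text(json.dumps(payload))


def load_dataset(path: str | Path) -> SyntheticDataset:
    payload = json.loads(Path(path).read_text())
    feature_ids = payload["feature_ids"]
    blocks = [
        BlockFeatureMatrix(
            block_id=b["block_id"],
            snp_ids=b["snp_ids"],
            feature_ids=feature_ids,
            X=np.array(b["X"], dtype=np.int8),
            label=b["label"],
            lead_index=b["lead_index"],
            source_id=b["source_id"],
        )
        for b in payload["blocks"]
    ]
    return SyntheticDataset(
        blocks=blocks,
        truth={k: list(v) for k, v in payload["truth"].items()},
        seed=payload["seed"],
    )
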