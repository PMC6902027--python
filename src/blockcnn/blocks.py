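"""Association-block construction from GWAS summary statistics.

An association block is the unit the scoring model trains on: a lead SNP
(the locally strongest association, selected genome-wide with >1 Mb spacing
between leads) together with up to 30 significant neighboring SNPs
(P <= 5e-4) found in a window flanking the lead.

Summary statistics are held as a pandas DataFrame with columns
``SNP`` (unique id), ``CHR`` (chromosome label), ``BP`` (1-based position)
and ``P`` (association p-value). Extra columns are tolerated and ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("SNP", "CHR", "BP", "P")

DEFAULT_MIN_SPACING = 1_000_000      # leads must be strictly further apart
DEFAULT_FLANK = 500_000              # search window per side around a lead
DEFAULT_MAX_NEIGHBORS = 30
DEFAULT_NEIGHBOR_P_MAX = 5e-4
DEFAULT_LEAD_P_MAX = 5e-4


@dataclass(frozen=True)
class SNP:
    """One summary-statistic record."""

    snp: str
    chrom: str
    pos: int          # 1-based
    p: float


@dataclass
class AssociationBlock:
    """A lead SNP plus its significant neighbors, ordered by ascending P."""

    block_id: str
    lead: SNP
    neighbors: list[SNP] = field(default_factory=list)
    window: tuple[int, int] = (0, 0)   # 1-based inclusive interval searched

    @property
    def members(self) -> list[SNP]:
        """Lead first, then neighbors in ascending-P order."""
        return [self.lead, *self.neighbors]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp for s in self.members]

    def __len__(self) -> int:
        return 1 + len(self.neighbors)


def validate_summary_stats(stats: pd.DataFrame) -> pd.DataFrame:
    """Check the summary-statistics contract; returns the validated frame."""
    missing = [c for c in REQUIRED_COLUMNS if c not in stats.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns {missing}")
    if len(stats) == 0:
        return stats
    p = stats["P"].to_numpy(dtype=float)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = stats.index[(~np.isfinite(p)) | (p <= 0) | (p > 1)][0]
        raise ValueError(f"P value out of (0, 1] at row {bad}")
    bp = stats["BP"].to_numpy()
    if np.any(bp < 1):
        bad = stats.index[bp < 1][0]
        raise ValueError(f"position must be 1-based (>= 1) at row {bad}")
    if stats["SNP"].duplicated().any():
        dup = stats.loc[stats["SNP"].duplicated(), "SNP"].iloc[0]
        raise ValueError(f"duplicate SNP id {dup!r}")
    for i, chrom in enumerate(stats["CHR"]):
        if not str(chrom).strip():
            raise ValueError(f"malformed chromosome label at row {stats.index[i]}")
    return stats


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV with at least SNP, CHR, BP, P columns."""
    stats = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    return validate_summary_stats(stats)


def write_summary_stats(stats: pd.DataFrame, path: str | Path) -> None:
    stats.to_csv(path, sep="\t", index=False)


def _sorted_by_significance(stats: pd.DataFrame) -> pd.DataFrame:
    # Equal P broken by (chrom, pos) ascending for determinism.
    return stats.sort_values(["P", "CHR", "BP"], kind="mergesort")


def select_lead_snps(
    stats: pd.DataFrame,
    min_spacing: int = DEFAULT_MIN_SPACING,
    lead_p_max: float = DEFAULT_LEAD_P_MAX,
) -> list[SNP]:
    """Greedy genome-wide lead selection.

    SNPs are visited in ascending-P order; a candidate becomes a lead iff it
    is strictly more than ``min_spacing`` bp away from every previously
    accepted lead on the same chromosome. Candidates with P > ``lead_p_max``
    are never leads. Output is in acceptance order.
    """
    validate_summary_stats(stats)
    if len(stats) == 0:
        return []
    leads: list[SNP] = []
    accepted: dict[str, list[int]] = {}
    for row in _sorted_by_significance(stats).itertuples(index=False):
        p = float(row.P)
        if p > lead_p_max:
            break  # sorted by P: nothing later qualifies
        chrom, pos = str(row.CHR), int(row.BP)
        taken = accepted.get(chrom, [])
        if all(abs(pos - q) > min_spacing for q in taken):
            leads.append(SNP(str(row.SNP), chrom, pos, p))
            accepted.setdefault(chrom, []).append(pos)
    return leads


def build_block(
    stats: pd.DataFrame,
    lead: SNP,
    flank: int = DEFAULT_FLANK,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    neighbor_p_max: float = DEFAULT_NEIGHBOR_P_MAX,
    block_id: str | None = None,
) -> AssociationBlock:
    """Collect up to ``max_neighbors`` most significant neighbors of a lead.

    The window is ``[lead.pos - flank, lead.pos + flank]`` on the lead's
    chromosome. The ``max_neighbors`` smallest-P SNPs (lead excluded) are
    taken first, then any with P > ``neighbor_p_max`` are discarded;
    equality at the threshold is retained.
    """
    lo, hi = max(1, lead.pos - flank), lead.pos + flank
    inside = stats[
        (stats["CHR"].astype(str) == lead.chrom)
        & (stats["BP"] >= lo)
        & (stats["BP"] <= hi)
        & (stats["SNP"].astype(str) != lead.snp)
    ]
    ranked = _sorted_by_significance(inside).head(max_neighbors)
    kept = ranked[ranked["P"] <= neighbor_p_max]
    neighbors = [
        SNP(str(r.SNP), str(r.CHR), int(r.BP), float(r.P))
        for r in kept.itertuples(index=False)
    ]
    return AssociationBlock(
        block_id=block_id or f"{lead.chrom}:{lead.pos}",
        lead=lead,
        neighbors=neighbors,
        window=(lo, hi),
    )


def build_blocks(
    stats: pd.DataFrame,
    min_spacing: int = DEFAULT_MIN_SPACING,
    lead_p_max: float = DEFAULT_LEAD_P_MAX,
    flank: int = DEFAULT_FLANK,
    max_neighbors: int = DEFAULT_MAX_NEIGHBORS,
    neighbor_p_max: float = DEFAULT_NEIGHBOR_P_MAX,
) -> list[AssociationBlock]:
    """Lead selection followed by per-lead neighbor collection.

    Blocks are returned in genome order (chromosome label, then position).
    """
    leads = select_lead_snps(stats, min_spacing=min_spacing, lead_p_max=lead_p_max)
    blocks = [
        build_block(
            stats,
            lead,
            flank=flank,
            max_neighbors=max_neighbors,
            neighbor_p_max=neighbor_p_max,
        )
        for lead in leads
    ]
    blocks.sort(key=lambda b: (b.lead.chrom, b.lead.pos))
    return blocks


def write_blocks(blocks: list[AssociationBlock], path: str | Path) -> None:
    rows = []
    for b in blocks:
        for snp in b.members:
            role = "lead" if snp.snp == b.lead.snp else "neighbor"
            rows.append((b.block_id, role, snp.snp, snp.chrom, snp.pos, snp.p))
    pd.DataFrame(
        rows, columns=["block_id", "role", "SNP", "CHR", "BP", "P"]
    ).to_csv(path, sep="\t", index=False)


def read_blocks(path: str | Path) -> list[AssociationBlock]:
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "CHR": str})
    blocks = []
    for block_id, grp in df.groupby("block_id", sort=False):
        lead_row = grp[grp["role"] == "lead"].iloc[0]
        lead = SNP(str(lead_row.SNP), str(lead_row.CHR), int(lead_row.BP), float(lead_row.P))
        neighbors = [
            SNP(str(r.SNP), str(r.CHR), int(r.BP), float(r.P))
            for r in grp[grp["role"] == "neighbor"].itertuples(index=False)
        ]
        blocks.append(AssociationBlock(str(block_id), lead, neighbors))
    return blocks
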