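"""End-to-end orchestration of the synthetic demo pipeline.

``run_pipeline`` runs every stage in dependency order on seeded synthetic
data: summary statistics and annotations are simulated, association blocks
built, features mapped and coverage-filtered, a causal pattern planted
into the resulting block matrices, shuffled negatives generated, the
scoring model trained, SNPs predicted, feature importance estimated and
functional validation statistics computed. All artifacts land in one
output directory with an append-only manifest of sha256 checksums; a rerun
with the same config and seed reproduces the checksums.

A single pipeline seed fans out to per-stage seeds (seed + stage index) so
each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import blocks as blocks_mod
from . import evaluate as evaluate_mod
from . import features as features_mod
from . import importance as importance_mod
from . import model as model_mod
from . import negatives as negatives_mod
from . import simulate as simulate_mod
from . import validate as validate_mod
from .util import derive_seed, sha256_file


@dataclass
class PipelineConfig:
    """Every stage's parameters, with provenance per field."""

    # simulation
    n_loci: int = 30
    snps_per_locus: int = 15
    chrom_length: int = 40_000_000
    genes: int = 30
    pathways: int = 6
    peaks_per_track: int = 1000
    tracks: int = 6
    motifs: int = 8
    # block construction
    min_spacing: int = blocks_mod.DEFAULT_MIN_SPACING
    flank: int = blocks_mod.DEFAULT_FLANK
    max_neighbors: int = blocks_mod.DEFAULT_MAX_NEIGHBORS
    neighbor_p_max: float = blocks_mod.DEFAULT_NEIGHBOR_P_MAX
    lead_p_max: float = blocks_mod.DEFAULT_LEAD_P_MAX
    # feature mapping
    upstream_window: int = features_mod.DEFAULT_UPSTREAM_WINDOW
    motif_p_max: float = features_mod.DEFAULT_MOTIF_P_MAX
    min_block_fraction: float = features_mod.DEFAULT_MIN_BLOCK_FRACTION
    # planted pattern
    n_pattern_features: int = 3
    # negatives
    neg_ratio: int = negatives_mod.DEFAULT_NEG_RATIO
    # training
    k: int = 8
    batch_size: int = 100
    learning_rate: float = model_mod.DEFAULT_LEARNING_RATE
    momentum: float = model_mod.DEFAULT_MOMENTUM
    max_epochs: int = 60
    patience: int = model_mod.DEFAULT_PATIENCE
    pretrain_epochs: int = model_mod.DEFAULT_PRETRAIN_EPOCHS
    variant: str = "full"
    # importance
    n_perm: int = 30
    n_trees: int = 100
    # global
    seed: int = 1
    provenance: dict[str, str] = field(default_factory=dict)

    @classmethod
    def resolve(
        cls, config_file: str | Path | None = None, **flags
    ) -> "PipelineConfig":
        """Merge defaults < config file < explicit flags, tracking provenance."""
        values: dict = {}
        provenance: dict[str, str] = {
            f.name: "default" for f in dataclasses.fields(cls) if f.name != "provenance"
        }
        if config_file is not None:
            loaded = yaml.safe_load(Path(config_file).read_text()) or {}
            for key, val in loaded.items():
                if key not in provenance:
                    raise ValueError(f"unknown config key {key!r} in {config_file}")
                values[key] = val
                provenance[key] = "file"
        for key, val in flags.items():
            if val is None:
                continue
            if key not in provenance:
                raise ValueError(f"unknown parameter {key!r}")
            values[key] = val
            provenance[key] = "flag"
        return cls(**values, provenance=provenance)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("provenance", None)
        return d


class Manifest:
    """Append-only record of pipeline artifacts with checksums."""

    def __init__(self, outdir: Path) -> None:
        self.outdir = outdir
        self.entries: list[dict] = []

    def add(self, path: Path, stage: str) -> None:
        self.entries.append(
            {
                "file": str(path.relative_to(self.outdir)),
                "stage": stage,
                "sha256": sha256_file(path),
            }
        )

    def write(self, config: PipelineConfig) -> Path:
        path = self.outdir / "manifest.json"
        path.write_text(
            json.dumps(
                {"config": config.to_dict(), "files": self.entries},
                indent=2,
                sort_keys=True,
            )
        )
        return path


PLANTED_GROUP = "planted"


def _plant_pattern(
    matrices: list[features_mod.BlockFeatureMatrix],
    n_pattern_features: int,
    seed: int,
    n_planted_rows: int = 10,
) -> tuple[list[str], dict[str, list[int]]]:
    """Add a synthetic causal feature group and plant a carrier per block.

    ``n_planted_rows`` all-zero feature rows are appended to every matrix;
    one uniform-random carrier SNP per block gets ``n_pattern_features`` of
    them set. The group-wise shuffler then scrambles the pattern within
    these rows when negatives are drawn, so only true blocks carry it
    intact. Returns (planted feature ids, block -> carrier columns).
    """
    rng = np.random.default_rng(seed)
    planted_ids = [f"planted{i}" for i in range(n_planted_rows)]
    k = min(n_pattern_features, n_planted_rows)
    pattern_rows = sorted(rng.choice(n_planted_rows, size=k, replace=False).tolist())
    truth: dict[str, list[int]] = {}
    for blk in matrices:
        extra = np.zeros((n_planted_rows, blk.n_snps), dtype=np.int8)
        col = int(rng.integers(blk.n_snps))
        extra[pattern_rows, col] = 1
        blk.feature_ids = list(blk.feature_ids) + planted_ids
        blk.X = np.vstack([blk.X, extra])
        truth[blk.block_id] = [col]
    return planted_ids, truth


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(outdir)
    seed = config.seed

    # 1. summary statistics
    stats = simulate_mod.simulate_summary_stats(
        n_loci=config.n_loci,
        snps_per_locus=config.snps_per_locus,
        chrom_length=config.chrom_length,
        seed=derive_seed(seed, 1),
    )
    stats_path = outdir / "summary_stats.tsv"
    blocks_mod.write_summary_stats(stats, stats_path)
    manifest.add(stats_path, "simulate-stats")

    # 2. annotations
    bundle = simulate_mod.simulate_annotations(
        genes=config.genes,
        pathways=config.pathways,
        peaks_per_track=config.peaks_per_track,
        tracks=config.tracks,
        motifs=config.motifs,
        seed=derive_seed(seed, 2),
        chrom_length=config.chrom_length,
    )
    for name, path in bundle.write(outdir / "annotations").items():
        manifest.add(path, "simulate-annotations")

    # 3. association blocks
    blocks = blocks_mod.build_blocks(
        stats,
        min_spacing=config.min_spacing,
        lead_p_max=config.lead_p_max,
        flank=config.flank,
        max_neighbors=config.max_neighbors,
        neighbor_p_max=config.neighbor_p_max,
    )
    if not blocks:
        raise RuntimeError("no association blocks found in simulated statistics")
    blocks_path = outdir / "blocks.tsv"
    blocks_mod.write_blocks(blocks, blocks_path)
    manifest.add(blocks_path, "build-blocks")

    # 4. feature mapping + coverage filter + matrices
    assignments = features_mod.combine_assignments(
        features_mod.map_peak_features(blocks, bundle.peaks),
        features_mod.map_pathway_features(
            blocks, bundle.genes, bundle.pathways, upstream_window=config.upstream_window
        ),
        features_mod.map_motif_features(blocks, bundle.motif_hits, hit_p_max=config.motif_p_max),
    )
    catalog = features_mod.filter_features(
        assignments, blocks, min_block_fraction=config.min_block_fraction
    )
    if len(catalog) == 0:
        raise RuntimeError("coverage filter retained no features; densify annotations")
    assignments_path = outdir / "assignments.tsv"
    features_mod.write_assignments(assignments, assignments_path)
    manifest.add(assignments_path, "map-features")
    matrices = features_mod.build_input_matrices(blocks, catalog, assignments)

    # plant a shared causal pattern so downstream stages have signal
    planted_ids, truth = _plant_pattern(
        matrices, config.n_pattern_features, derive_seed(seed, 4)
    )
    catalog = pd.concat(
        [
            catalog,
            pd.DataFrame(
                {"feature_id": planted_ids, "group": PLANTED_GROUP, "coverage": 1.0}
            ),
        ],
        ignore_index=True,
    )
    catalog_path = outdir / "catalog.tsv"
    features_mod.write_catalog(catalog, catalog_path)
    manifest.add(catalog_path, "map-features")

    # 5. negatives
    partition = dict(zip(catalog["feature_id"], catalog["group"]))
    shuffle = negatives_mod.ShuffleSpec(
        neg_ratio=config.neg_ratio,
        group_partition=partition,
        seed=derive_seed(seed, 5),
    )
    dataset = simulate_mod.SyntheticDataset(
        blocks=matrices + negatives_mod.generate_negatives(matrices, shuffle),
        truth=truth,
        seed=seed,
    )
    dataset_path = outdir / "dataset.json"
    simulate_mod.save_dataset(dataset, dataset_path)
    manifest.add(dataset_path, "make-negatives")

    # 6. training
    train_config = model_mod.TrainConfig(
        K=config.k,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        momentum=config.momentum,
        max_epochs=config.max_epochs,
        patience=config.patience,
        pretrain_epochs=config.pretrain_epochs,
        seed=derive_seed(seed, 6),
    )
    result = model_mod.train(dataset.blocks, train_config, variant=config.variant)
    model_path = outdir / "model.json"
    result.params.save(model_path)
    manifest.add(model_path, "train")
    log_path = outdir / "training_log.tsv"
    pd.DataFrame(result.log).to_csv(log_path, sep="\t", index=False)
    manifest.add(log_path, "train")

    # 7. prediction + evaluation
    records, block_table = evaluate_mod.predict(result.params, dataset.blocks)
    predictions_path = outdir / "predictions.tsv"
    evaluate_mod.write_predictions(records, predictions_path)
    manifest.add(predictions_path, "predict")
    test_ids = {b.block_id for b in result.test_blocks}
    test_table = block_table[block_table["block_id"].isin(test_ids)]
    report = {
        "auc_test": evaluate_mod.auc(test_table["score"], test_table["label"]),
        "auc_all": evaluate_mod.auc(block_table["score"], block_table["label"]),
        "variant": config.variant,
    }
    frac, n_conc, n_posblk = evaluate_mod.lead_concordance(
        records, [b for b in dataset.blocks if b.label == 1]
    )
    report["lead_concordance"] = frac
    report_path = outdir / "performance.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest.add(report_path, "evaluate")

    # 8. feature importance
    true_records = [
        r for r in records if not r.block_id.split("::")[-1].startswith("neg")
    ]
    try:
        X, y, feat_ids = importance_mod.label_snps_for_importance(
            records, dataset.blocks
        )
        table = importance_mod.importance_table(
            X,
            y,
            feat_ids,
            n_perm=config.n_perm,
            config=importance_mod.ForestConfig(
                n_trees=config.n_trees, seed=derive_seed(seed, 8)
            ),
            groups=partition,
        )
    except ValueError as exc:
        table = pd.DataFrame({"note": [f"importance skipped: {exc}"]})
    importance_path = outdir / "importance.tsv"
    table.to_csv(importance_path, sep="\t", index=False)
    manifest.add(importance_path, "importance")

    # 9. validation statistics on the true-block SNPs
    rng = np.random.default_rng(derive_seed(seed, 9))
    pos_by_snp = {s.snp: (s.chrom, s.pos) for b in blocks for s in b.members}
    carrier_snps = {
        m.snp_ids[c] for m in matrices for c in truth.get(m.block_id, [])
    }
    call_rows = []
    for rec in true_records:
        if rec.snp_id not in pos_by_snp:
            continue
        chrom, pos = pos_by_snp[rec.snp_id]
        call_rows.append((rec.snp_id, chrom, pos, rec.score))
    calls = pd.DataFrame(call_rows, columns=["snp_id", "chrom", "pos", "score"])
    conservation = pd.DataFrame(
        {
            "chrom": calls["chrom"],
            "pos": calls["pos"],
            "score": [
                float(rng.uniform(0.55, 1.0))
                if snp in carrier_snps
                else float(rng.uniform(0.0, 1.0))
                for snp in calls["snp_id"]
            ],
        }
    ).drop_duplicates(["chrom", "pos"])
    conservation_path = outdir / "conservation.tsv"
    conservation.to_csv(conservation_path, sep="\t", index=False)
    manifest.add(conservation_path, "validate")

    validation: dict[str, object] = {}
    try:
        first_track = next(iter(bundle.peaks))
        ov = validate_mod.overlap_fraction_test(
            calls, bundle.peaks[first_track], name=first_track
        )
        validation["overlap"] = {
            "set": ov.name,
            "fraction_positive": ov.fraction_positive,
            "fraction_negative": ov.fraction_negative,
            "p": ov.p,
        }
        rank = validate_mod.tissue_enrichment_rank(calls, bundle.peaks)
        validation["tissue_rank"] = rank.to_dict(orient="records")
        orr = validate_mod.conserved_odds_ratio(calls, conservation)
        validation["conserved_odds_ratio"] = {
            "or": orr.or_value,
            "ci_low": orr.ci_low,
            "ci_high": orr.ci_high,
            "p": orr.p,
        }
    except ValueError as exc:
        validation["note"] = f"validation skipped: {exc}"
    validation_path = outdir / "validation.json"
    validation_path.write_text(json.dumps(validation, indent=2, sort_keys=True))
    manifest.add(validation_path, "validate")

    return manifest.write(config)
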