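"""Feature mapping: coordinate conventions, thresholds, coverage filter."""

import numpy as np
import pandas as pd
import pytest

from blockcnn.blocks import SNP, AssociationBlock
from blockcnn.features import (
    build_input_matrix,
    combine_assignments,
    filter_features,
    map_motif_features,
    map_pathway_features,
    map_peak_features,
    read_bed,
)
from blockcnn.simulate import simulate_annotations


def block_of(positions, chrom="1", block_id="b0"):
    snps = [SNP(f"{block_id}_s{i}", chrom, p, 1e-5) for i, p in enumerate(positions)]
    return AssociationBlock(block_id, snps[0], snps[1:])


def bed_frame(intervals, chrom="1"):
    return pd.DataFrame(
        [(chrom, s, e, "t") for s, e in intervals],
        columns=["chrom", "start", "end", "name"],
    )


class TestPeakMapping:
    def test_one_based_snp_inside_half_open_peak(self):
        # SNP at 1-based 101 is 0-based 100, the first base of [100, 200)
        block = block_of([101])
        out = map_peak_features([block], {"t": bed_frame([(100, 200)])})
        assert len(out) == 1

    def test_half_open_end_is_excluded(self):
        # 1-based 201 -> 0-based 200, one past the end of [100, 200)
        block = block_of([201, 200])
        out = map_peak_features([block], {"t": bed_frame([(100, 200)])})
        assert set(out["snp_id"]) == {"b0_s1"}  # 1-based 200 = 0-based 199 inside

    def test_empty_track_assigns_nothing(self):
        out = map_peak_features([block_of([101])], {"t": bed_frame([])})
        assert len(out) == 0

    def test_adding_a_peak_never_removes_assignments(self):
        block = block_of([101, 5000, 9000])
        before = map_peak_features([block], {"t": bed_frame([(100, 200)])})
        after = map_peak_features([block], {"t": bed_frame([(100, 200), (4000, 6000)])})
        pairs = lambda df: set(map(tuple, df[["feature_id", "snp_id"]].to_numpy()))
        assert pairs(before) <= pairs(after)


class TestPathwayMapping:
    def genes(self, strand="+", tss=1_000_000, start=1_000_000, end=1_050_000):
        return pd.DataFrame(
            [("g1", "1", strand, tss, start, end)],
            columns=["gene", "chrom", "strand", "tss", "start", "end"],
        )

    def pathways(self):
        return pd.DataFrame([("pw1", "g1")], columns=["pathway", "gene"])

    def test_upstream_boundary_inclusive_at_500kb(self):
        block = block_of([500_000])  # exactly 500 kb upstream of + strand TSS
        out = map_pathway_features([block], self.genes(), self.pathways())
        assert set(out["feature_id"]) == {"pw1"}

    def test_beyond_upstream_window_not_assigned(self):
        block = block_of([499_999])  # 500,001 bp upstream
        out = map_pathway_features([block], self.genes(), self.pathways())
        assert len(out) == 0

    def test_minus_strand_upstream_lies_at_higher_coordinates(self):
        genes = self.genes(strand="-", tss=1_050_000)
        out_hi = map_pathway_features(
            [block_of([1_550_000])], genes, self.pathways()
        )
        out_lo = map_pathway_features(
            [block_of([999_999])], genes, self.pathways()
        )
        assert len(out_hi) == 1 and len(out_lo) == 0

    def test_gene_body_assigns_regardless_of_strand(self):
        for strand in "+-":
            out = map_pathway_features(
                [block_of([1_020_000])], self.genes(strand=strand), self.pathways()
            )
            assert len(out) == 1

    def test_unknown_gene_in_pathway_table_skipped(self):
        pathways = pd.DataFrame(
            [("pw1", "g1"), ("pw2", "ghost")], columns=["pathway", "gene"]
        )
        out = map_pathway_features([block_of([1_020_000])], self.genes(), pathways)
        assert set(out["feature_id"]) == {"pw1"}

    def test_unstranded_gene_skipped(self):
        genes = self.genes(strand=".")
        out = map_pathway_features([block_of([1_020_000])], genes, self.pathways())
        assert len(out) == 0


class TestMotifMapping:
    def hits(self, p, start=100, stop=110, motif="m1"):
        return pd.DataFrame(
            [(motif, "1", start, stop, "+", 10.0, p)],
            columns=["motif_id", "sequence_name", "start", "stop", "strand", "score", "p-value"],
        )

    def test_threshold_inclusive_at_1e4(self):
        block = block_of([105])
        assert len(map_motif_features([block], self.hits(1e-4))) == 1
        assert len(map_motif_features([block], self.hits(2e-4))) == 0

    def test_hit_interval_one_based_inclusive(self):
        assert len(map_motif_features([block_of([110])], self.hits(1e-5))) == 1
        assert len(map_motif_features([block_of([111])], self.hits(1e-5))) == 0
        assert len(map_motif_features([block_of([100])], self.hits(1e-5))) == 1

    def test_two_motifs_set_two_features(self):
        hits = pd.concat([self.hits(1e-5, motif="m1"), self.hits(1e-5, motif="m2")])
        out = map_motif_features([block_of([105])], hits)
        assert set(out["feature_id"]) == {"m1", "m2"}

    def test_missing_pvalue_column_rejected(self):
        bad = self.hits(1e-5).drop(columns=["p-value"])
        with pytest.raises(ValueError, match="p-value"):
            map_motif_features([block_of([105])], bad)


class TestCoverageFilter:
    def assignments_with_coverage(self, counts, n_blocks=100):
        """feature fi assigned in the first counts[i] blocks."""
        rows = []
        for i, cnt in enumerate(counts):
            for b in range(cnt):
                rows.append((f"f{i}", "open_chromatin", f"b{b}", f"b{b}_s0"))
        return pd.DataFrame(rows, columns=["feature_id", "group", "block_id", "snp_id"])

    def blocks(self, n=100):
        return [block_of([100 + i], block_id=f"b{i}") for i in range(n)]

    def test_strict_inequality_at_95_percent(self):
        assignments = self.assignments_with_coverage([95, 96, 100])
        catalog = filter_features(assignments, self.blocks())
        assert list(catalog["feature_id"]) == ["f1", "f2"]

    def test_empty_block_list_rejected(self):
        with pytest.raises(ValueError, match="at least one block"):
            filter_features(self.assignments_with_coverage([100]), [])

    def test_retained_order_preserved(self):
        assignments = self.assignments_with_coverage([100, 100, 100])
        catalog = filter_features(assignments, self.blocks())
        assert list(catalog["feature_id"]) == ["f0", "f1", "f2"]


class TestInputMatrix:
    def test_single_snp_three_features(self):
        block = block_of([101])
        catalog = pd.DataFrame(
            {"feature_id": ["a", "b", "c"], "group": ["open_chromatin"] * 3}
        )
        assignments = pd.DataFrame(
            [("a", "open_chromatin", "b0", "b0_s0")],
            columns=["feature_id", "group", "block_id", "snp_id"],
        )
        mat = build_input_matrix(block, catalog, assignments)
        assert mat.X.tolist() == [[1], [0], [0]]

    def test_no_assignments_gives_zero_matrix(self):
        block = block_of([101, 200])
        catalog = pd.DataFrame({"feature_id": ["a"], "group": ["histone"]})
        empty = pd.DataFrame(columns=["feature_id", "group", "block_id", "snp_id"])
        mat = build_input_matrix(block, catalog, empty)
        assert mat.X.sum() == 0 and mat.X.shape == (1, 2)

    def test_columns_follow_genomic_position(self):
        lead = SNP("s_hi", "1", 900, 1e-9)
        block = AssociationBlock("b0", lead, [SNP("s_lo", "1", 100, 1e-5)])
        catalog = pd.DataFrame({"feature_id": ["a"], "group": ["histone"]})
        empty = pd.DataFrame(columns=["feature_id", "group", "block_id", "snp_id"])
        mat = build_input_matrix(block, catalog, empty)
        assert mat.snp_ids == ["s_lo", "s_hi"]
        assert mat.lead_index == 1

    def test_matrix_matches_brute_force_overlap_on_toy_bundle(self):
        """Peak-track cells agree with a per-cell nested-loop interval check."""
        bundle = simulate_annotations(3, 2, 15, 3, 2, seed=11, chrom_length=5_000_000)
        blocks = [
            block_of([100_000, 700_000, 1_500_000], block_id="b0"),
            block_of([2_000_000, 2_600_000], block_id="b1"),
        ]
        assignments = map_peak_features(blocks, bundle.peaks)
        catalog = pd.DataFrame(
            {"feature_id": list(bundle.peaks), "group": ["open_chromatin"] * 3}
        )
        for block in blocks:
            mat = build_input_matrix(block, catalog, assignments)
            for i, track in enumerate(catalog["feature_id"]):
                bed = bundle.peaks[track]
                for j, snp_id in enumerate(mat.snp_ids):
                    snp = next(s for s in block.members if s.snp == snp_id)
                    hit = any(
                        row.start <= snp.pos - 1 < row.end
                        for row in bed.itertuples(index=False)
                    )
                    assert mat.X[i, j] == int(hit)


class TestBedReader:
    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t100\t200\tok\n1\tnot_a_number\t300\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed(path)

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("1\t300\t200\tx\n")
        with pytest.raises(ValueError, match="inverted"):
            read_bed(path)
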