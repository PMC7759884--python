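from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import assembly, contamination
from genomesurvey.assembly import ContigRecord
from genomesurvey.contamination import (
    ContaminantDB,
    StrayRegion,
    build_db,
    extract_stray,
    filter_contaminant_reads,
    gc_depth_density,
    kmer_shares,
    label_contigs,
    parse_hits,
    removal_percent,
)

from conftest import random_dna


def contig(cid, gc_percent, depth, length=600):
    c = ContigRecord(id=cid, seq="A" * length)
    c.gc = gc_percent / 100.0
    c.mean_depth = depth
    return c


class TestStrayRegions:
    def test_bounds_validation(self):
        with pytest.raises(ValueError):
            StrayRegion(gc_min=80, gc_max=57, depth_min=0, depth_max=10)
        with pytest.raises(ValueError):
            StrayRegion(gc_min=0, gc_max=50, depth_min=10, depth_max=10)

    def test_high_gc_low_depth_extracted(self):
        region = StrayRegion(57, 80, 0, 10, "stray")
        points = [("c1", 70.0, 5.0), ("c2", 40.0, 50.0)]
        assert extract_stray(points, [region]) == {"stray": ["c1"]}

    def test_empty_region_list(self):
        assert extract_stray([("c1", 70.0, 5.0)], []) == {}

    def test_boundary_inclusive(self):
        region = StrayRegion(57, 80, 0, 10, "stray")
        assert extract_stray([("c1", 57.0, 10.0)], [region]) == {"stray": ["c1"]}

    def test_contig_in_multiple_regions(self):
        regions = [StrayRegion(0, 100, 0, 14, "a"), StrayRegion(57, 80, 0, 10, "b")]
        out = extract_stray([("c1", 70.0, 5.0)], regions)
        assert out == {"a": ["c1"], "b": ["c1"]}


class TestDensity:
    def test_single_contig_single_cell(self):
        points, grid, gc_edges, depth_edges = gc_depth_density(
            [contig("c1", 40.0, 50.0)], min_length=500
        )
        assert len(points) == 1
        assert grid.sum() == 1
        assert grid[40, 50] == 1

    def test_empty_input(self):
        points, grid, _, _ = gc_depth_density([], min_length=500)
        assert points == [] and grid.sum() == 0

    def test_min_length_filter(self):
        points, grid, _, _ = gc_depth_density(
            [contig("c1", 40, 50, length=499)], min_length=500
        )
        assert points == []

    def test_two_modes_host_vs_contaminant(self):
        rng = np.random.default_rng(41)
        contigs = [contig(f"h{i}", rng.normal(37, 2), rng.normal(50, 3)) for i in range(200)]
        contigs += [contig(f"m{i}", rng.normal(65, 2), rng.normal(6, 1)) for i in range(40)]
        _, grid, _, _ = gc_depth_density(contigs)
        host_mass = grid[30:45, 40:60].sum()
        cont_mass = grid[58:72, 0:12].sum()
        assert host_mass >= 190 and cont_mass >= 35


HIT_ROW = "c1\tMethylobacterium_x\t98.5\t500\t3\t0\t1\t500\t1\t500\t1e-50\t900\tMethylobacterium radiotolerans"


class TestHits:
    def test_parse_with_taxon_column(self):
        hits = parse_hits([HIT_ROW])
        assert hits[0].subject_id == "Methylobacterium_x"
        assert hits[0].taxon == "Methylobacterium radiotolerans"
        assert hits[0].bit_score == 900

    def test_parse_12_columns(self):
        hits = parse_hits(["\t".join(HIT_ROW.split("\t")[:12])])
        assert hits[0].taxon is None

    def test_malformed_row_names_line(self):
        with pytest.raises(ValueError, match=":2:"):
            parse_hits([HIT_ROW, "bad\trow"])

    def test_best_hit_by_bit_score_then_evalue(self):
        base = HIT_ROW.split("\t")
        row_hi = base.copy()
        row_lo = base.copy()
        row_lo[11] = "500"
        tie_a = base.copy()
        tie_a[10], tie_a[11], tie_a[1] = "1e-20", "700", "subjA"
        tie_b = base.copy()
        tie_b[10], tie_b[11], tie_b[1] = "1e-30", "700", "subjB"
        hits = parse_hits(["\t".join(r) for r in (row_lo, tie_a, tie_b)])
        best = contamination.best_hits(hits)
        assert best["c1"].subject_id == "subjB"  # equal bit score, lower e-value
        hits2 = parse_hits(["\t".join(r) for r in (row_lo, row_hi)])
        assert contamination.best_hits(hits2)["c1"].bit_score == 900

    def test_label_contigs(self):
        taxon_map = {"Methylobacterium": "microbe", "Helianthus": "host"}
        labels = label_contigs(["c1", "c2"], parse_hits([HIT_ROW]), taxon_map)
        assert labels == {"c1": "microbe", "c2": "unknown"}

    def test_evalue_filter(self):
        row = HIT_ROW.split("\t")
        row[10] = "1e-3"  # above the 1e-5 cut
        labels = label_contigs(["c1"], parse_hits(["\t".join(row)]), {"Methylobacterium": "microbe"})
        assert labels == {"c1": "unknown"}


class TestContaminantDB:
    def test_empty_contigs(self):
        assert len(build_db([], k=17)) == 0

    def test_20bp_contig_at_most_4_kmers(self):
        rng = np.random.default_rng(42)
        db = build_db([ContigRecord(id="c", seq=random_dna(rng, 20))], k=17)
        assert 1 <= len(db) <= 4

    def test_union_property(self):
        rng = np.random.default_rng(43)
        a = [ContigRecord(id="a", seq=random_dna(rng, 100))]
        b = [ContigRecord(id="b", seq=random_dna(rng, 100))]
        db_ab = build_db(a + b, k=17)
        union = build_db(a, k=17).union(build_db(b, k=17))
        assert np.array_equal(db_ab.kmers, union.kmers)

    def test_contig_shorter_than_k_skipped(self):
        assert len(build_db([ContigRecord(id="c", seq="ACGT")], k=17)) == 0


class TestFilterReads:
    def _pairs_from(self, genome, n, rng, read_len=100):
        from genomesurvey.qc import ReadPair

        pairs = []
        for i in range(n):
            start = int(rng.integers(0, len(genome) - read_len + 1))
            seq = genome[start : start + read_len]
            pairs.append(ReadPair(id=f"r{i}", seq1=seq, qual1="I" * read_len,
                                  seq2=seq, qual2="I" * read_len))
        return pairs

    def test_empty_db_removes_nothing(self):
        rng = np.random.default_rng(44)
        pairs = self._pairs_from(random_dna(rng, 5000), 20, rng)
        kept, removed, report = filter_contaminant_reads(pairs, ContaminantDB(k=17))
        assert removed == [] and len(kept) == 20
        assert report["removed_percent"] == 0.0

    def test_report_arithmetic(self):
        assert removal_percent(10.5, 120.1) == 8.7
        assert removal_percent(0.1, 154.3) == 0.06

    def test_recall_precision_on_truth(self):
        rng = np.random.default_rng(45)
        host = random_dna(rng, 20_000, gc=0.37)
        cont = random_dna(rng, 5_000, gc=0.65)
        db = build_db([ContigRecord(id="cont", seq=cont)], k=17)
        host_pairs = self._pairs_from(host, 300, rng)
        cont_pairs = self._pairs_from(cont, 30, rng)
        kept, removed, _ = filter_contaminant_reads(host_pairs + cont_pairs, db)
        removed_ids = {p.id for p in removed}
        cont_ids = {p.id for p in cont_pairs}
        # note host/cont share almost no 17-mers at these sizes
        tp = len(removed_ids & cont_ids)
        assert tp / len(cont_ids) >= 0.95
        assert tp / max(len(removed_ids), 1) >= 0.95

    def test_partition_and_order_independence(self):
        rng = np.random.default_rng(46)
        genome = random_dna(rng, 5000)
        db = build_db([ContigRecord(id="g", seq=genome[:1000])], k=17)
        pairs = self._pairs_from(genome, 50, rng)
        kept, removed, _ = filter_contaminant_reads(pairs, db)
        assert len(kept) + len(removed) == len(pairs)
        kept2, removed2, _ = filter_contaminant_reads(pairs[::-1], db)
        assert {p.id for p in removed} == {p.id for p in removed2}

    def test_monotonicity_db_and_threshold(self):
        rng = np.random.default_rng(47)
        genome = random_dna(rng, 4000)
        pairs = self._pairs_from(genome, 60, rng)
        small = build_db([ContigRecord(id="a", seq=genome[:800])], k=17)
        large = small.union(build_db([ContigRecord(id="b", seq=genome[800:2000])], k=17))
        _, removed_small, _ = filter_contaminant_reads(pairs, small)
        _, removed_large, _ = filter_contaminant_reads(pairs, large)
        assert {p.id for p in removed_small} <= {p.id for p in removed_large}
        _, removed_f5, _ = filter_contaminant_reads(pairs, small, share_threshold=0.5)
        _, removed_f9, _ = filter_contaminant_reads(pairs, small, share_threshold=0.9)
        assert {p.id for p in removed_f9} <= {p.id for p in removed_f5}

    def test_kmer_share_values(self):
        rng = np.random.default_rng(48)
        genome = random_dna(rng, 1000)
        db = build_db([ContigRecord(id="g", seq=genome)], k=17)
        inside = genome[100:200]
        outside = random_dna(rng, 100)
        shares = kmer_shares([inside, outside, "ACG"], db)
        assert shares[0] == 1.0
        assert shares[1] < 0.1
        assert shares[2] == 0.0  # shorter than k: no valid window
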