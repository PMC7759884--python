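from __future__ import annotations

import numpy as np
import pytest

from genomesurvey import assembly
from genomesurvey._encode import revcomp
from genomesurvey.assembly import AssemblyConfig, ContigRecord

from conftest import random_dna
from oracles import brute_kmer_counts, brute_n50


def no_repeated_km1(seq: str, k: int) -> bool:
    """True when no (k-1)-mer (canonical) occurs twice — unitig-safe."""
    seen = set()
    for i in range(len(seq) - (k - 1) + 1):
        w = seq[i : i + k - 1]
        w = min(w, revcomp(w))
        if w in seen:
            return False
        seen.add(w)
    return True


def tiled_reads(seq: str, read_len=100, step=5, copies=3) -> list[str]:
    reads = [seq[i : i + read_len] for i in range(0, len(seq) - read_len + 1, step)]
    return reads * copies


@pytest.fixture(scope="module")
def unique_source():
    rng = np.random.default_rng(21)
    for _ in range(50):
        seq = random_dna(rng, 5000)
        if no_repeated_km1(seq, 21):
            return seq
    raise RuntimeError("could not build repeat-free source")


class TestCountKmerStrings:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(22)
        reads = [random_dna(rng, 80) for _ in range(30)]
        for k in (17, 21):
            assert assembly.count_kmer_strings(reads, k) == brute_kmer_counts(reads, k)

    def test_python_fallback_above_31(self):
        rng = np.random.default_rng(23)
        reads = [random_dna(rng, 120) for _ in range(10)]
        assert assembly.count_kmer_strings(reads, 41) == brute_kmer_counts(reads, 41)


class TestBuildUnitigs:
    def test_single_unitig_reconstruction(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=2)
        contigs = assembly.build_unitigs(tiled_reads(unique_source), config)
        assert len(contigs) == 1
        assert contigs[0].seq in (unique_source, revcomp(unique_source))

    def test_error_kmers_pruned(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=2)
        reads = tiled_reads(unique_source)
        bad = list(reads[10])
        bad[50] = "A" if bad[50] != "A" else "C"
        reads.append("".join(bad))
        contigs = assembly.build_unitigs(reads, config)
        assert len(contigs) == 1
        assert contigs[0].seq in (unique_source, revcomp(unique_source))

    def test_repeat_block_breaks_assembly(self, unique_source):
        # duplicate an internal 100 bp block elsewhere: > k-1 repeat
        block = unique_source[1000:1100]
        seq = unique_source[:3000] + block + unique_source[3000:]
        config = AssemblyConfig(k=21, min_kmer_count=2)
        contigs = assembly.build_unitigs(tiled_reads(seq), config)
        assert len(contigs) > 1
        # no contig may span both flanks of the repeat junction ambiguously:
        # every emitted contig must be an exact substring of the source
        for contig in contigs:
            assert contig.seq in seq or revcomp(contig.seq) in seq

    def test_strand_invariance(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=1)
        reads = tiled_reads(unique_source, copies=1)
        fwd = {c.seq for c in assembly.build_unitigs(reads, config)}
        rev = {c.seq for c in assembly.build_unitigs([revcomp(r) for r in reads], config)}
        assert fwd == rev

    def test_no_n_in_contigs(self):
        rng = np.random.default_rng(24)
        seq = random_dna(rng, 1000)
        seq = seq[:500] + "N" * 5 + seq[500:]
        config = AssemblyConfig(k=15, min_kmer_count=1)
        contigs = assembly.build_unitigs(tiled_reads(seq, read_len=60, step=3, copies=1), config)
        assert contigs
        assert all("N" not in c.seq for c in contigs)

    def test_unitig_kmers_subset_of_solid_reads(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=2)
        reads = tiled_reads(unique_source)
        counts = assembly.count_kmer_strings(reads, 21)
        contigs = assembly.build_unitigs(counts, config)
        for contig in contigs:
            contig_kmers = assembly.count_kmer_strings([contig.seq], 21)
            for kmer in contig_kmers:
                assert counts.get(kmer, 0) >= 2

    def test_empty_reads_empty_graph(self):
        assert assembly.build_unitigs([], AssemblyConfig(k=21)) == []

    def test_canonical_orientation(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=1)
        contigs = assembly.build_unitigs(tiled_reads(unique_source, copies=1), config)
        for contig in contigs:
            assert contig.seq <= revcomp(contig.seq)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AssemblyConfig(k=20)
        with pytest.raises(ValueError):
            AssemblyConfig(min_kmer_count=0)


class TestContigStats:
    def test_hand_computed_n50(self):
        contigs = [ContigRecord(id=str(i), seq="A" * n) for i, n in enumerate([5, 4, 3, 2, 1])]
        stats = assembly.contig_stats(contigs, min_length=0)
        assert stats.total_length == 15
        assert stats.n50 == 4
        assert stats.max_length == 5

    def test_single_contig(self):
        stats = assembly.contig_stats([ContigRecord(id="c", seq="A" * 500)], min_length=0)
        assert stats.n50 == stats.max_length == stats.total_length == 500

    def test_equal_lengths(self):
        contigs = [ContigRecord(id=str(i), seq="A" * 7) for i in range(5)]
        assert assembly.contig_stats(contigs, min_length=0).n50 == 7

    def test_matches_oracle_on_random_lengths(self):
        rng = np.random.default_rng(25)
        lengths = [int(x) for x in rng.integers(100, 5000, size=40)]
        contigs = [ContigRecord(id=str(i), seq="A" * n) for i, n in enumerate(lengths)]
        assert assembly.contig_stats(contigs, min_length=0).n50 == brute_n50(lengths)

    def test_min_length_filter_and_empty(self):
        contigs = [ContigRecord(id="s", seq="A" * 50), ContigRecord(id="l", seq="A" * 200)]
        stats = assembly.contig_stats(contigs, min_length=100)
        assert stats.n_contigs == 1 and stats.total_length == 200
        assert assembly.contig_stats([], min_length=100).n50 == 0

    def test_n_base_fraction(self):
        contigs = [ContigRecord(id="c", seq="ACGT" * 25 + "N" * 100)]
        stats = assembly.contig_stats(contigs, min_length=0)
        assert stats.n_base_fraction == pytest.approx(0.5)


class TestGCDepth:
    def test_gc_simple(self):
        assert assembly.gc_content("ACGT") == 0.5
        assert assembly.gc_content("ACGTNN") == 0.5
        assert assembly.gc_content("NN") == 0.0

    def test_mean_depth_from_uniform_coverage(self, unique_source):
        config = AssemblyConfig(k=21, min_kmer_count=2)
        rng = np.random.default_rng(26)
        n_reads = 50 * len(unique_source) // 100
        reads = []
        for _ in range(n_reads):
            start = int(rng.integers(0, len(unique_source) - 100 + 1))
            reads.append(unique_source[start : start + 100])
        counts = assembly.count_kmer_strings(reads, 21)
        contigs = assembly.build_unitigs(counts, config)
        contigs = assembly.annotate_gc_depth(contigs, counts, 21)
        main = max(contigs, key=lambda c: c.length)
        assert abs(main.mean_depth - 50 * (100 - 20) / 100) < 5

    def test_contig_shorter_than_k_excluded(self):
        contigs = [ContigRecord(id="tiny", seq="ACGT")]
        assert assembly.annotate_gc_depth(contigs, {}, 21) == []

    def test_fasta_round_trip(self, tmp_path, unique_source):
        contigs = [ContigRecord(id="c1", seq=unique_source[:200])]
        path = tmp_path / "c.fasta"
        assembly.write_contigs_fasta(contigs, path)
        back = assembly.read_fasta(path)
        assert back[0].id == "c1" and back[0].seq == unique_source[:200]

    def test_contig_table_round_trip(self, tmp_path):
        contigs = [ContigRecord(id="c1", seq="A" * 600, gc=0.42, mean_depth=33.5)]
        path = tmp_path / "t.tsv"
        assembly.write_contig_table(contigs, path)
        back = assembly.read_contig_table(path)
        assert back[0].length == 600
        assert back[0].gc == pytest.approx(0.42)
        assert back[0].mean_depth == pytest.approx(33.5)
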