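"""Minimal de Bruijn unitig assembler and contig statistics.

A deliberately conservative stand-in for a production short-read
assembler: canonical k-mers with count >= min_kmer_count form the graph,
and maximal non-branching paths are emitted as contigs. No bubble
popping, no scaffolding, no gap filling — contiguity numbers from real
assemblers are out of reach by design. Contig depth is the mean read
k-mer count over the contig's windows (no alignment step).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _encode
from ._encode import revcomp

_BASES = "ACGT"


@dataclass
class AssemblyConfig:
    k: int = 41
    min_kmer_count: int = 2
    min_contig_length_stats: int = 100
    min_contig_length_profile: int = 500

    def __post_init__(self) -> None:
        if self.k % 2 == 0 or self.k < 3:
            raise ValueError(f"k must be odd and >= 3, got {self.k}")
        if self.min_kmer_count < 1:
            raise ValueError("min_kmer_count must be >= 1")


@dataclass
class ContigRecord:
    id: str
    seq: str
    gc: float = 0.0
    mean_depth: float = 0.0

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AssemblyStats:
    total_length: int = 0
    n_contigs: int = 0
    max_length: int = 0
    n50: int = 0
    n_base_fraction: float = 0.0

    def as_dict(self) -> dict:
        return {
            "total_length": self.total_length,
            "n_contigs": self.n_contigs,
            "max_length": self.max_length,
            "n50": self.n50,
            "n_base_fraction": self.n_base_fraction,
        }


def _canon(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def count_kmer_strings(reads: Iterable[str], k: int) -> dict[str, int]:
    """Canonical k-mer -> occurrence count over reads (N windows skipped).

    Packed numpy counting for k <= 31; a plain dict scan otherwise.
    """
    if k <= _encode.MAX_PACKED_K:
        values, counts = _encode.count_canonical(reads, k)
        return {
            _encode.decode_kmer(int(v), k): int(c) for v, c in zip(values.tolist(), counts.tolist())
        }
    counts_d: dict[str, int] = {}
    for read in reads:
        rc_read = revcomp(read)
        n = len(read)
        for i in range(n - k + 1):
            fwd = read[i : i + k]
            if "N" in fwd:
                continue
            rc = rc_read[n - k - i : n - i]
            kmer = fwd if fwd <= rc else rc
            counts_d[kmer] = counts_d.get(kmer, 0) + 1
    return counts_d


def _solid_kmers(reads: Iterable[str] | Mapping[str, int], config: AssemblyConfig) -> dict[str, int]:
    if isinstance(reads, Mapping):
        counts = dict(reads)
    else:
        counts = count_kmer_strings(reads, config.k)
    return {kmer: c for kmer, c in counts.items() if c >= config.min_kmer_count}


def build_unitigs(
    reads: Iterable[str] | Mapping[str, int], config: AssemblyConfig | None = None
) -> list[ContigRecord]:
    """Assemble maximal non-branching paths from solid canonical k-mers.

    ``reads`` may also be a precomputed canonical k-mer count mapping.
    Each unitig is emitted once, in the lexicographically smaller of its
    two orientations, with mean_depth set to the mean count of its k-mers.
    """
    config = config or AssemblyConfig()
    solid = _solid_kmers(reads, config)
    if not solid:
        return []
    k = config.k

    def fwd_exts(oriented: str) -> list[str]:
        suffix = oriented[1:]
        return [suffix + b for b in _BASES if _canon(suffix + b) in solid]

    def bwd_exts(oriented: str) -> list[str]:
        prefix = oriented[:-1]
        return [b + prefix for b in _BASES if _canon(b + prefix) in solid]

    visited: set[str] = set()
    contigs: list[ContigRecord] = []
    limit = len(solid) + 1

    for start in sorted(solid):
        if start in visited:
            continue
        path = [start]
        seen = {start}
        # extend right
        cur = start
        for _ in range(limit):
            nxt_list = fwd_exts(cur)
            if len(nxt_list) != 1:
                break
            nxt = nxt_list[0]
            if len(bwd_exts(nxt)) != 1 or _canon(nxt) in seen or _canon(nxt) in visited:
                break
            path.append(nxt)
            seen.add(_canon(nxt))
            cur = nxt
        # extend left
        cur = start
        for _ in range(limit):
            prev_list = bwd_exts(cur)
            if len(prev_list) != 1:
                break
            prev = prev_list[0]
            if len(fwd_exts(prev)) != 1 or _canon(prev) in seen or _canon(prev) in visited:
                break
            path.insert(0, prev)
            seen.add(_canon(prev))
            cur = prev

        visited.update(_canon(p) for p in path)
        seq = path[0] + "".join(p[-1] for p in path[1:])
        rc = revcomp(seq)
        if rc < seq:
            seq = rc
        depth = float(np.mean([solid[_canon(p)] for p in path]))
        contigs.append(ContigRecord(id="", seq=seq, mean_depth=depth))

    contigs.sort(key=lambda c: (-c.length, c.seq))
    for i, contig in enumerate(contigs):
        contig.id = f"utg{i + 1:06d}"
        contig.gc = gc_content(contig.seq)
    return contigs


def gc_content(seq: str) -> float:
    """GC over non-N bases."""
    acgt = len(seq) - seq.count("N")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def contig_stats(contigs: Sequence[ContigRecord], min_length: int = 100) -> AssemblyStats:
    """Length statistics over contigs of at least ``min_length``.

    N50 is the length of the contig at which cumulative length, in
    descending length order, first reaches half the total.
    """
    lengths = sorted((c.length for c in contigs if c.length >= min_length), reverse=True)
    if not lengths:
        return AssemblyStats()
    total = sum(lengths)
    half = total / 2
    cum = 0
    n50 = lengths[-1]
    for length in lengths:
        cum += length
        if cum >= half:
            n50 = length
            break
    n_bases = sum(c.seq.count("N") for c in contigs if c.length >= min_length)
    return AssemblyStats(
        total_length=total,
        n_contigs=len(lengths),
        max_length=lengths[0],
        n50=n50,
        n_base_fraction=n_bases / total,
    )


def annotate_gc_depth(
    contigs: Sequence[ContigRecord],
    kmer_counts: Mapping[str, int],
    k: int,
) -> list[ContigRecord]:
    """Set gc and mean_depth on contigs from a read k-mer count table.

    mean_depth is the mean, over the contig's N-free k-mer windows, of the
    window's canonical count in the reads. Contigs shorter than k are
    dropped (depth undefined).
    """
    out: list[ContigRecord] = []
    for contig in contigs:
        if contig.length < k:
            continue
        seq = contig.seq
        rc_seq = revcomp(seq)
        n = len(seq)
        depths = []
        for i in range(n - k + 1):
            fwd = seq[i : i + k]
            if "N" in fwd:
                continue
            rc = rc_seq[n - k - i : n - i]
            kmer = fwd if fwd <= rc else rc
            depths.append(kmer_counts.get(kmer, 0))
        if not depths:
            continue
        contig.gc = gc_content(seq)
        contig.mean_depth = float(np.mean(depths))
        out.append(contig)
    return out


def read_fasta(path: str | Path) -> list[ContigRecord]:
    from Bio import SeqIO

    return [ContigRecord(id=rec.id, seq=str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_contigs_fasta(contigs: Sequence[ContigRecord], path: str | Path) -> None:
    from .simulate import write_fasta

    write_fasta([(c.id, c.seq) for c in contigs], path)


def write_contig_table(contigs: Sequence[ContigRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tlength\tgc\tmean_depth\n")
        for c in contigs:
            fh.write(f"{c.id}\t{c.length}\t{c.gc:.6f}\t{c.mean_depth:.4f}\n")


def read_contig_table(path: str | Path) -> list[ContigRecord]:
    contigs: list[ContigRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ValueError(f"{path}: missing contig table header")
        for line in fh:
            cid, length, gc, depth = line.rstrip("\n").split("\t")
            contigs.append(
                ContigRecord(id=cid, seq="N" * int(length), gc=float(gc), mean_depth=float(depth))
            )
    return contigs
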