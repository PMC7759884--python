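"""Ground-truthed simulation of a contaminated diploid sequencing sample.

Generates a diploid host genome (configurable GC, SNP heterozygosity and
implanted exact repeat copies), haploid contaminant genomes with distinct
GC, and error-bearing paired-end reads with per-pair origin labels, so
every downstream stage can be validated against known truth.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _encode
from .qc import ReadPair

DEFAULT_REPEAT_UNIT_LENGTHS = (50, 100, 200, 500)

_Q_GOOD = 35
_Q_BAD = 2


class SimulationConfigError(ValueError):
    pass


@dataclass
class ContaminantSpec:
    length: int
    gc: float
    abundance: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise SimulationConfigError("contaminant length must be positive")
        if not 0 <= self.gc <= 1 or not 0 <= self.abundance < 1:
            raise SimulationConfigError("contaminant gc/abundance out of range")


@dataclass
class SimulationConfig:
    host_length: int = 100_000
    host_gc: float = 0.37
    snp_rate: float = 0.005
    repeat_fraction: float = 0.0
    repeat_unit_lengths: Sequence[int] = DEFAULT_REPEAT_UNIT_LENGTHS
    contaminants: Sequence[ContaminantSpec] = ()
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 30
    coverage: float = 50.0
    base_error_rate: float = 0.0
    adapter: str = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"
    seed: int = 0
    # fraction of pairs deliberately made to violate each QC rule
    qc_n_violation_rate: float = 0.0
    qc_adapter_violation_rate: float = 0.0
    qc_lowq_violation_rate: float = 0.0

    def __post_init__(self) -> None:
        fracs = (
            self.host_gc,
            self.snp_rate,
            self.repeat_fraction,
            self.base_error_rate,
            self.qc_n_violation_rate,
            self.qc_adapter_violation_rate,
            self.qc_lowq_violation_rate,
        )
        if any(not 0 <= f <= 1 for f in fracs):
            raise SimulationConfigError("all fractions must lie in [0, 1]")
        if self.snp_rate >= 0.1:
            raise SimulationConfigError("snp_rate must be < 0.1")
        if self.repeat_fraction > 0.95:
            raise SimulationConfigError("repeat fraction above 0.95 is unreachable")
        if sum(c.abundance for c in self.contaminants) >= 1:
            raise SimulationConfigError("contaminant abundances must sum to < 1")
        if self.read_length > self.insert_mean:
            raise SimulationConfigError("read_length must not exceed insert_mean")
        if self.repeat_fraction > 0 and self.host_length < 10 * max(self.repeat_unit_lengths):
            raise SimulationConfigError("host genome too short for the repeat unit lengths")


@dataclass
class SyntheticTruth:
    haplotype_a: str
    haplotype_b: str
    snp_positions: list[int]
    repeat_annotations: list[tuple[int, int, int]]  # (start, end, family_id)
    repeat_fraction: float
    host_gc: float
    contaminant_gcs: list[float] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#host_gc\t{self.host_gc:.6f}\n")
            fh.write(f"#repeat_fraction\t{self.repeat_fraction:.6f}\n")
            fh.write(f"#n_snps\t{len(self.snp_positions)}\n")
            fh.write("#repeat_annotations: start\tend\tfamily\n")
            for start, end, fam in self.repeat_annotations:
                fh.write(f"{start}\t{end}\t{fam}\n")


def _random_codes(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(4, size=length, p=probs).astype(np.uint8)


def simulate_contaminant_genome(length: int, gc: float, seed: int) -> str:
    """i.i.d. genome with P(G or C) = gc."""
    if length <= 0:
        raise SimulationConfigError("length must be positive")
    rng = np.random.default_rng(seed)
    return _encode.decode(_random_codes(rng, length, gc))


def simulate_host_genome(config: SimulationConfig) -> tuple[tuple[str, str], SyntheticTruth]:
    """Diploid host: haplotype A with implanted repeats, B = A + SNPs."""
    rng = np.random.default_rng(config.seed)
    length = config.host_length
    codes = _random_codes(rng, length, config.host_gc)

    covered = np.zeros(length, dtype=bool)
    annotations: list[tuple[int, int, int]] = []
    family = 0
    unit_lengths = np.asarray(config.repeat_unit_lengths)
    while config.repeat_fraction > 0 and covered.mean() < config.repeat_fraction:
        unit_len = int(rng.choice(unit_lengths))
        src = int(rng.integers(0, length - unit_len + 1))
        unit = codes[src : src + unit_len].copy()
        n_copies = int(rng.integers(2, 11))
        tandem = bool(rng.random() < 0.5)
        if tandem:
            block = np.tile(unit, n_copies)
            start = int(rng.integers(0, length - block.size + 1))
            codes[start : start + block.size] = block
            covered[start : start + block.size] = True
            annotations.append((start, start + block.size, family))
        else:
            for _ in range(n_copies):
                start = int(rng.integers(0, length - unit_len + 1))
                codes[start : start + unit_len] = unit
                covered[start : start + unit_len] = True
                annotations.append((start, start + unit_len, family))
        family += 1

    hap_a = codes
    hap_b = codes.copy()
    snp_mask = rng.random(length) < config.snp_rate
    snp_positions = np.flatnonzero(snp_mask)
    if snp_positions.size:
        shifts = rng.integers(1, 4, size=snp_positions.size).astype(np.uint8)
        hap_b[snp_positions] = (hap_b[snp_positions] + shifts) % 4

    gc_realized = float(np.isin(hap_a, (1, 2)).mean())
    truth = SyntheticTruth(
        haplotype_a=_encode.decode(hap_a),
        haplotype_b=_encode.decode(hap_b),
        snp_positions=[int(p) for p in snp_positions],
        repeat_annotations=annotations,
        repeat_fraction=float(covered.mean()),
        host_gc=gc_realized,
    )
    return (truth.haplotype_a, truth.haplotype_b), truth


@dataclass
class ReadSource:
    """One genome contributing reads; abundance None takes the remainder."""

    name: str
    haplotypes: Sequence[str]
    abundance: float | None = None

    @property
    def length(self) -> int:
        return len(self.haplotypes[0])


@dataclass
class ReadSet:
    pairs: list[ReadPair]
    labels: list[str]

    def __len__(self) -> int:
        return len(self.pairs)

    def label_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.labels:
            out[label] = out.get(label, 0) + 1
        return out

    @property
    def total_bases(self) -> int:
        return sum(len(p.seq1) + len(p.seq2) for p in self.pairs)

    def sequences(self) -> list[str]:
        seqs: list[str] = []
        for pair in self.pairs:
            seqs.append(pair.seq1)
            seqs.append(pair.seq2)
        return seqs

    def write_fastq(self, path1: str | Path, path2: str | Path) -> int:
        from .qc import write_fastq_pairs

        return write_fastq_pairs(self.pairs, path1, path2)

    def write_labels_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pair_id\torigin\n")
            for pair, label in zip(self.pairs, self.labels):
                fh.write(f"{pair.id}\t{label}\n")


def _codes_to_strings(codes: np.ndarray) -> list[str]:
    """(n, L) code matrix -> list of n sequence strings."""
    n, read_len = codes.shape
    blob = _encode._ASCII[codes.reshape(-1)].tobytes().decode("ascii")
    return [blob[i * read_len : (i + 1) * read_len] for i in range(n)]


def _quals_to_strings(quals: np.ndarray) -> list[str]:
    n, read_len = quals.shape
    blob = (quals.reshape(-1) + 33).astype(np.uint8).tobytes().decode("ascii")
    return [blob[i * read_len : (i + 1) * read_len] for i in range(n)]


def _simulate_batch(
    rng: np.random.Generator,
    haplotypes: list[np.ndarray],
    n_pairs: int,
    config: SimulationConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised fragment sampling for one genome; returns code/qual arrays."""
    read_len = config.read_length
    genome_len = haplotypes[0].size
    if genome_len < read_len:
        raise SimulationConfigError("fragment longer than genome")

    frag = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n_pairs)).astype(np.int64)
    frag = np.clip(frag, read_len, genome_len)
    starts = (rng.random(n_pairs) * (genome_len - frag + 1)).astype(np.int64)
    hap_idx = rng.integers(0, len(haplotypes), size=n_pairs)

    hap_matrix = np.stack(haplotypes)
    offsets = np.arange(read_len)
    pos1 = starts[:, None] + offsets
    codes1 = hap_matrix[hap_idx[:, None], pos1]
    pos2 = (starts + frag - read_len)[:, None] + offsets
    codes2 = (3 - hap_matrix[hap_idx[:, None], pos2])[:, ::-1]

    quals1 = np.full((n_pairs, read_len), _Q_GOOD, dtype=np.int16)
    quals2 = np.full((n_pairs, read_len), _Q_GOOD, dtype=np.int16)
    if config.base_error_rate > 0:
        for codes, quals in ((codes1, quals1), (codes2, quals2)):
            err = rng.random((n_pairs, read_len)) < config.base_error_rate
            shifts = rng.integers(1, 4, size=(n_pairs, read_len)).astype(codes.dtype)
            codes[err] = (codes[err] + shifts[err]) % 4
            quals[err] = _Q_BAD
    return codes1, quals1, codes2, quals2


def simulate_reads(sources: Sequence[ReadSource], config: SimulationConfig) -> ReadSet:
    """Paired-end reads from a genome mixture with per-pair origin labels.

    Total read bases ~= coverage x sum of source genome lengths,
    apportioned across sources by their abundance fractions. Read 2 is the
    reverse complement of the far end of each fragment. Deterministic for
    a fixed config (one RNG seeded with config.seed drives everything).
    """
    if config.coverage <= 0:
        raise SimulationConfigError("coverage must be positive")
    if not sources:
        raise SimulationConfigError("at least one read source is required")

    rng = np.random.default_rng(config.seed)
    total_bases = config.coverage * sum(s.length for s in sources)
    n_pairs = int(round(total_bases / (2 * config.read_length)))

    abundances = []
    remainder_idx = None
    for i, src in enumerate(sources):
        if src.abundance is None:
            if remainder_idx is not None:
                raise SimulationConfigError("only one source may have abundance None")
            remainder_idx = i
            abundances.append(0.0)
        else:
            abundances.append(src.abundance)
    declared = sum(abundances)
    if declared > 1:
        raise SimulationConfigError("abundances sum above 1")
    if remainder_idx is not None:
        abundances[remainder_idx] = 1.0 - declared

    per_source = rng.multinomial(n_pairs, abundances)

    all_codes1, all_quals1, all_codes2, all_quals2 = [], [], [], []
    labels: list[str] = []
    for src, count in zip(sources, per_source):
        if count == 0:
            continue
        haps = [_encode.encode(h) for h in src.haplotypes]
        c1, q1, c2, q2 = _simulate_batch(rng, haps, int(count), config)
        all_codes1.append(c1)
        all_quals1.append(q1)
        all_codes2.append(c2)
        all_quals2.append(q2)
        labels.extend([src.name] * int(count))

    codes1 = np.concatenate(all_codes1)
    quals1 = np.concatenate(all_quals1)
    codes2 = np.concatenate(all_codes2)
    quals2 = np.concatenate(all_quals2)
    label_arr = np.array(labels)

    order = rng.permutation(len(label_arr))
    codes1, quals1 = codes1[order], quals1[order]
    codes2, quals2 = codes2[order], quals2[order]
    label_arr = label_arr[order]

    _inject_qc_violations(rng, codes1, quals1, quals2, config)

    seqs1 = _codes_to_strings(codes1)
    seqs2 = _codes_to_strings(codes2)
    q1s = _quals_to_strings(quals1)
    q2s = _quals_to_strings(quals2)
    width = len(str(max(len(label_arr) - 1, 0)))
    pairs = [
        ReadPair(id=f"sim_{i:0{width}d}", seq1=seqs1[i], qual1=q1s[i], seq2=seqs2[i], qual2=q2s[i])
        for i in range(len(label_arr))
    ]
    return ReadSet(pairs=pairs, labels=[str(x) for x in label_arr])


def _inject_qc_violations(
    rng: np.random.Generator,
    codes1: np.ndarray,
    quals1: np.ndarray,
    quals2: np.ndarray,
    config: SimulationConfig,
) -> None:
    """Explicitly corrupt a configurable fraction of pairs per QC rule."""
    n_pairs, read_len = codes1.shape
    if n_pairs == 0:
        return
    u = rng.random(n_pairs)
    lo = 0.0
    for rate, kind in (
        (config.qc_n_violation_rate, "n"),
        (config.qc_adapter_violation_rate, "adapter"),
        (config.qc_lowq_violation_rate, "lowq"),
    ):
        idx = np.flatnonzero((u >= lo) & (u < lo + rate))
        lo += rate
        if idx.size == 0:
            continue
        if kind == "n":
            n_bases = int(np.ceil(0.12 * read_len))
            codes1[idx[:, None], np.arange(n_bases)] = 4
            quals1[idx[:, None], np.arange(n_bases)] = _Q_BAD
        elif kind == "adapter":
            adapter = _encode.encode(config.adapter)[: read_len // 2]
            pos = read_len - adapter.size
            codes1[idx[:, None], pos + np.arange(adapter.size)] = adapter
        elif kind == "lowq":
            n_bases = int(np.ceil(0.22 * 2 * read_len))
            half = min(n_bases - n_bases // 2, read_len)
            quals1[idx[:, None], np.arange(n_bases // 2)] = _Q_BAD - 1
            quals2[idx[:, None], np.arange(half)] = _Q_BAD - 1


def hits_from_truth(
    contigs: Sequence,
    references: dict[str, tuple[str, str]],
    k: int = 21,
    min_share: float = 0.5,
) -> list[str]:
    """Synthesize BLAST-style tabular hit rows from known source genomes.

    ``references`` maps subject name -> (sequence, taxon_label). Each
    contig is assigned to the reference sharing the largest fraction of
    its canonical k-mers (if above ``min_share``); contigs matching
    nothing get no row, mimicking a no-hit query. Returns 13-column rows
    (standard 12 + taxon label).
    """
    ref_sets = {}
    for name, (seq, taxon) in references.items():
        vals = _encode.canonical_window_values(_encode.encode(seq), k)
        ref_sets[name] = (np.unique(vals), taxon)
    rows: list[str] = []
    for contig in contigs:
        vals = _encode.canonical_window_values(_encode.encode(contig.seq), k)
        if vals.size == 0:
            continue
        vals = np.unique(vals)
        best_name, best_share = None, 0.0
        for name, (ref_vals, _taxon) in ref_sets.items():
            idx = np.searchsorted(ref_vals, vals)
            idx[idx >= ref_vals.size] = 0
            share = float((ref_vals[idx] == vals).mean())
            if share > best_share:
                best_name, best_share = name, share
        if best_name is None or best_share < min_share:
            continue
        taxon = ref_sets[best_name][1]
        length = len(contig.seq)
        identity = round(100.0 * best_share, 2)
        bit_score = round(2.0 * length * best_share, 1)
        rows.append(
            "\t".join(
                [
                    contig.id,
                    best_name,
                    f"{identity:.2f}",
                    str(length),
                    "0",
                    "0",
                    "1",
                    str(length),
                    "1",
                    str(length),
                    "1e-50",
                    f"{bit_score:.1f}",
                    taxon,
                ]
            )
        )
    return rows


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    """Write (id, sequence) records as 60-column-wrapped FASTA."""
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
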