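"""Whole-read paired-end quality filtering and sequencing summary stats.

Reads are kept or discarded whole (no trimming). A pair is discarded, in
this priority order, when:

1. ``adapter``     — either mate contains an exact substring (>= 12 bp by
   default) of a configured adapter;
2. ``n_fraction``  — either mate has more than 10% N bases;
3. ``low_quality`` — more than 20% of the bases of the two mates combined
   are below Phred 5.

All comparisons at the thresholds are strictly-greater, so a mate at
exactly 10% N is kept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

PHRED_OFFSET = 33

# Illumina TruSeq paired-end adapter prefixes; override in QCConfig when the
# library prep differs.
DEFAULT_ADAPTERS = (
    "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA",
    "AGATCGGAAGAGCGTCGTGTAGGGAAAGAGTGT",
)

DISCARD_REASONS = ("adapter", "n_fraction", "low_quality")


class FastqFormatError(ValueError):
    pass


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"sequence/quality length mismatch in read {self.id}")
        if not self.seq1 or not self.seq2:
            raise ValueError(f"empty read in pair {self.id}")

    def phred(self, mate: int) -> np.ndarray:
        qual = self.qual1 if mate == 1 else self.qual2
        return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int16) - PHRED_OFFSET


@dataclass
class QCConfig:
    adapters: Sequence[str] = DEFAULT_ADAPTERS
    adapter_min_match: int = 12
    max_n_fraction: float = 0.10
    low_q_threshold: int = 5
    max_low_q_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 <= self.max_n_fraction <= 1 or not 0 <= self.max_low_q_fraction <= 1:
            raise ValueError("fractions must lie in [0, 1]")
        # every adapter window of length adapter_min_match; presence of any
        # one of them is equivalent to presence of a >= min_match substring
        self._adapter_seeds: tuple[str, ...] = tuple(
            {
                adapter[i : i + self.adapter_min_match]
                for adapter in self.adapters
                for i in range(0, max(0, len(adapter) - self.adapter_min_match) + 1)
                if len(adapter) >= self.adapter_min_match
            }
        )
        self._low_chars = tuple(chr(PHRED_OFFSET + q) for q in range(self.low_q_threshold))


def _has_adapter(seq: str, config: QCConfig) -> bool:
    return any(seed in seq for seed in config._adapter_seeds)


def _low_q_count(qual: str, config: QCConfig) -> int:
    return sum(qual.count(c) for c in config._low_chars)


def filter_pair(pair: ReadPair, config: QCConfig | None = None) -> str | None:
    """Return None to keep the pair, or the discard reason.

    Reasons are mutually exclusive and checked in the order
    adapter -> n_fraction -> low_quality.
    """
    config = config or QCConfig()
    if _has_adapter(pair.seq1, config) or _has_adapter(pair.seq2, config):
        return "adapter"
    for seq in (pair.seq1, pair.seq2):
        if seq.count("N") / len(seq) > config.max_n_fraction:
            return "n_fraction"
    combined = len(pair.seq1) + len(pair.seq2)
    low = _low_q_count(pair.qual1, config) + _low_q_count(pair.qual2, config)
    if low / combined > config.max_low_q_fraction:
        return "low_quality"
    return None


@dataclass
class QCStats:
    raw_pairs: int = 0
    raw_bases: int = 0
    clean_pairs: int = 0
    clean_bases: int = 0
    discarded: dict[str, int] = field(default_factory=lambda: {r: 0 for r in DISCARD_REASONS})
    q30_fraction: float = 0.0
    gc_fraction: float = 0.0

    @property
    def clean_gb(self) -> float:
        return self.clean_bases / 1e9

    @property
    def raw_gb(self) -> float:
        return self.raw_bases / 1e9

    def validate(self) -> None:
        if self.raw_pairs != self.clean_pairs + sum(self.discarded.values()):
            raise ValueError("pair accounting does not balance")

    def as_dict(self) -> dict:
        return {
            "raw_pairs": self.raw_pairs,
            "raw_bases": self.raw_bases,
            "raw_gb": round(self.raw_gb, 4),
            "clean_pairs": self.clean_pairs,
            "clean_bases": self.clean_bases,
            "clean_gb": round(self.clean_gb, 4),
            "discarded": dict(self.discarded),
            "q30_fraction": self.q30_fraction,
            "gc_fraction": self.gc_fraction,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | Path) -> None:
        d = self.as_dict()
        disc = d.pop("discarded")
        for reason, count in disc.items():
            d[f"discarded_{reason}"] = count
        with open(path, "w") as fh:
            for key in sorted(d):
                fh.write(f"{key}\t{d[key]}\n")


def run_qc(
    pairs: Iterable[ReadPair], config: QCConfig | None = None
) -> tuple[list[ReadPair], dict[str, list[ReadPair]], QCStats]:
    """Filter pairs and compute clean-set summary statistics."""
    config = config or QCConfig()
    kept: list[ReadPair] = []
    discarded: dict[str, list[ReadPair]] = {r: [] for r in DISCARD_REASONS}
    for pair in pairs:
        reason = filter_pair(pair, config)
        if reason is None:
            kept.append(pair)
        else:
            discarded[reason].append(pair)
    stats = qc_summary(kept, discarded)
    return kept, discarded, stats


def qc_summary(
    kept: Sequence[ReadPair], discarded: dict[str, Sequence[ReadPair]] | None = None
) -> QCStats:
    """Summary statistics over a clean set (Q30, GC, volumes).

    Q30 is the fraction of clean bases at Phred >= 30; GC is computed over
    clean A/C/G/T bases (N excluded from both numerator and denominator).
    """
    discarded = discarded or {}
    stats = QCStats()
    q30 = gc = acgt = 0
    for pair in kept:
        stats.clean_pairs += 1
        for seq, qual in ((pair.seq1, pair.qual1), (pair.seq2, pair.qual2)):
            stats.clean_bases += len(seq)
            q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8)
            q30 += int((q >= PHRED_OFFSET + 30).sum())
            gc += seq.count("G") + seq.count("C")
            acgt += len(seq) - seq.count("N")
    stats.q30_fraction = q30 / stats.clean_bases if stats.clean_bases else 0.0
    stats.gc_fraction = gc / acgt if acgt else 0.0
    stats.raw_pairs = stats.clean_pairs
    stats.raw_bases = stats.clean_bases
    for reason, pairs in discarded.items():
        stats.discarded[reason] = len(pairs)
        stats.raw_pairs += len(pairs)
        for pair in pairs:
            stats.raw_bases += len(pair.seq1) + len(pair.seq2)
    stats.validate()
    return stats


# --- FASTQ I/O (4-line records, Phred+33) ---------------------------------


def _read_records(path: str | Path) -> Iterator[tuple[str, str, str]]:
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            lineno += 4
            name = header.strip()
            if not header.startswith("@"):
                raise FastqFormatError(f"{path}: record at line {lineno - 3} lacks '@' header")
            if not qual:
                raise FastqFormatError(f"{path}: truncated record {name} at line {lineno - 3}")
            if not plus.startswith("+"):
                raise FastqFormatError(f"{path}: record {name} lacks '+' separator")
            seq, qual = seq.strip(), qual.strip()
            if len(seq) != len(qual):
                raise FastqFormatError(f"{path}: record {name} seq/qual length mismatch")
            yield name[1:], seq, qual


def _pair_id(name: str) -> str:
    base = name.split()[0]
    if base.endswith("/1") or base.endswith("/2"):
        base = base[:-2]
    return base


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    """Iterate synchronized mate files as ReadPairs."""
    it1, it2 = _read_records(path1), _read_records(path2)
    sentinel = object()
    while True:
        r1 = next(it1, sentinel)
        r2 = next(it2, sentinel)
        if r1 is sentinel and r2 is sentinel:
            return
        if r1 is sentinel or r2 is sentinel:
            raise FastqFormatError("mate files are desynchronized: unequal record counts")
        n1, s1, q1 = r1  # type: ignore[misc]
        n2, s2, q2 = r2  # type: ignore[misc]
        if _pair_id(n1) != _pair_id(n2):
            raise FastqFormatError(f"mate ids differ: {n1!r} vs {n2!r}")
        yield ReadPair(id=_pair_id(n1), seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def read_fastq_interleaved(path: str | Path) -> Iterator[ReadPair]:
    it = _read_records(path)
    for n1, s1, q1 in it:
        nxt = next(it, None)
        if nxt is None:
            raise FastqFormatError(f"{path}: odd record count; pair {n1!r} lacks a mate")
        n2, s2, q2 = nxt
        if _pair_id(n1) != _pair_id(n2):
            raise FastqFormatError(f"mate ids differ: {n1!r} vs {n2!r}")
        yield ReadPair(id=_pair_id(n1), seq1=s1, qual1=q1, seq2=s2, qual2=q2)


def write_fastq_pairs(pairs: Iterable[ReadPair], path1: str | Path, path2: str | Path) -> int:
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for pair in pairs:
            f1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            f2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
            n += 1
    return n
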