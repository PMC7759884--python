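"""Independent brute-force oracles used to validate the fast paths.

These deliberately avoid the package's vectorised/streaming machinery:
plain string scans and exhaustive enumeration only.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def brute_kmer_counts(reads: list[str], k: int) -> dict[str, int]:
    """Canonical k-mer counts by direct window enumeration."""
    counts: dict[str, int] = {}
    for read in reads:
        for i in range(len(read) - k + 1):
            window = read[i : i + k]
            if any(b not in "ACGT" for b in window):
                continue
            kmer = min(window, rc(window))
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def brute_kmer_histogram(reads: list[str], k: int) -> dict[int, int]:
    hist: dict[int, int] = {}
    for depth in brute_kmer_counts(reads, k).values():
        hist[depth] = hist.get(depth, 0) + 1
    return hist


def _primitive(motif: str) -> bool:
    n = len(motif)
    return not any(n % d == 0 and motif == motif[:d] * (n // d) for d in range(1, n))


def brute_ssrs(seq: str, min_repeats=(10, 6, 5, 5, 5, 5)) -> list[tuple[int, int, int, int]]:
    """Exhaustive SSR detection; returns (start0, end0, unit, repeats).

    Tests every (start, unit) pair, computes the maximal full-unit run,
    requires left-maximality (no partial extension), the per-unit minimum,
    then resolves overlaps: sort by (start, unit) and keep greedily.
    """
    n = len(seq)
    candidates: list[tuple[int, int, int, int]] = []
    for start in range(n):
        for unit in range(1, 7):
            motif = seq[start : start + unit]
            if len(motif) < unit or "N" in motif or not _primitive(motif):
                continue
            # maximal run of full units from start
            count = 1
            while True:
                nxt = seq[start + count * unit : start + (count + 1) * unit]
                if len(nxt) < unit or nxt != motif:
                    break
                count += 1
            if count < min_repeats[unit - 1]:
                continue
            # left-maximality incl. partial: one base left keeps the period?
            if start > 0 and seq[start - 1] != "N" and seq[start - 1] == seq[start + unit - 1]:
                continue
            candidates.append((start, start + unit * count, unit, count))
    candidates.sort(key=lambda c: (c[0], c[2]))
    kept: list[tuple[int, int, int, int]] = []
    last_end = 0
    for cand in candidates:
        if cand[0] >= last_end:
            kept.append(cand)
            last_end = cand[1]
    return kept


def brute_n50(lengths: list[int]) -> int:
    lengths = sorted(lengths, reverse=True)
    half = sum(lengths) / 2
    cum = 0
    for length in lengths:
        cum += length
        if cum >= half:
            return length
    return 0
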