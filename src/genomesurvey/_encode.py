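"""Vectorised 2-bit DNA encoding and canonical k-mer extraction.

Bases map A=0, C=1, G=2, T=3; anything else (N, lowercase handled, IUPAC
ambiguity codes) maps to 4 and invalidates every window that covers it.
k-mers are packed into uint64, which limits the fast path to k <= 31.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

MAX_PACKED_K = 31

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i

_BASES = "ACGT"
_ASCII = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str | bytes) -> np.ndarray:
    """Sequence -> uint8 code array (A0 C1 G2 T3, other 4)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def decode_kmer(value: int, k: int) -> str:
    out = []
    for shift in range(2 * (k - 1), -1, -2):
        out.append(_BASES[(int(value) >> shift) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    value = 0
    for base in kmer:
        code = int(_CODE[ord(base)])
        if code > 3:
            raise ValueError(f"non-ACGT base in k-mer: {kmer!r}")
        value = (value << 2) | code
    return value


def window_values(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward, reverse-complement and validity arrays for every window.

    Returns (fwd, rc, valid) of length len(codes) - k + 1. Values in
    invalid windows (containing code 4) are garbage and must be masked.
    """
    if not 1 <= k <= MAX_PACKED_K:
        raise ValueError(f"k must be in [1, {MAX_PACKED_K}] for packed counting, got {k}")
    n = codes.size - k + 1
    if n <= 0:
        e = np.empty(0, dtype=np.uint64)
        return e, e.copy(), np.empty(0, dtype=bool)

    bad = np.cumsum(np.concatenate(([0], (codes > 3).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0

    # k shifted-add passes over the full array beat a per-window dot product;
    # invalid windows accumulate garbage (incl. code-4 bits) and are masked
    c64 = codes.astype(np.uint64)
    fwd = np.zeros(n, dtype=np.uint64)
    rc = np.zeros(n, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        np.add(fwd, c64[j : j + n] << np.uint64(2 * (k - 1 - j)), out=fwd)
        np.add(rc, (three - c64[j : j + n]) << np.uint64(2 * j), out=rc)
    return fwd, rc, valid


def canonical_window_values(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (min of strand pair) packed values of all valid windows."""
    fwd, rc, valid = window_values(codes, k)
    return np.minimum(fwd, rc)[valid]


def _join_codes(seqs: Iterable[str]) -> np.ndarray:
    """Concatenate sequences with a single invalid separator code between."""
    parts: list[np.ndarray] = []
    sep = np.array([4], dtype=np.uint8)
    for seq in seqs:
        if parts:
            parts.append(sep)
        parts.append(encode(seq))
    if not parts:
        return np.empty(0, dtype=np.uint8)
    return np.concatenate(parts)


def iter_canonical_batches(seqs: Iterable[str], k: int, batch_bases: int = 8_000_000) -> Iterator[np.ndarray]:
    """Yield canonical k-mer value arrays over batches of sequences."""
    buf: list[str] = []
    size = 0
    for seq in seqs:
        buf.append(seq)
        size += len(seq)
        if size >= batch_bases:
            yield canonical_window_values(_join_codes(buf), k)
            buf, size = [], 0
    if buf:
        yield canonical_window_values(_join_codes(buf), k)


def count_canonical(seqs: Iterable[str], k: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact canonical k-mer counting.

    Returns (values, counts): distinct canonical k-mer values (sorted,
    uint64) and their occurrence counts. N-containing windows are skipped.
    """
    batches = [b for b in iter_canonical_batches(seqs, k) if b.size]
    if not batches:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    allk = np.concatenate(batches) if len(batches) > 1 else batches[0]
    del batches
    values, counts = np.unique(allk, return_counts=True)
    return values, counts.astype(np.int64)
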