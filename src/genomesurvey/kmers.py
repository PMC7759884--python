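"""k-mer spectrum analysis: counting, peak finding, and genome estimates.

The survey estimates follow the classic k-mer arithmetic:

* genome size = total k-mer occurrences / main-peak depth
* error rate = depth-1 occurrences / total occurrences,
  revised size = size * (1 - error rate)
* heterozygosity = a / (k * (2 - a)) where a is the fraction of k-mer
  species attributed to the half-depth (heterozygous) peak
* repetitive rate = fraction of occurrences deeper than 1.8x the main peak

"Occurrences" means window instances; "species" means distinct k-mers.
The size formula divides occurrences (not species) by the peak depth —
the only reading consistent with read-volume accounting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import _encode

DEFAULT_K = 17


class SpectrumError(ValueError):
    """Raised when a histogram has no usable genomic peak."""


@dataclass
class KmerHistogram:
    """Depth -> number of distinct k-mer species at that depth."""

    k: int
    species: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for depth, count in self.species.items():
            if depth < 1:
                raise ValueError(f"depths must be positive, got {depth}")
            if count < 0:
                raise ValueError(f"species counts must be >= 0, got {count}")

    @property
    def n_species(self) -> int:
        return sum(self.species.values())

    @property
    def n_occurrences(self) -> int:
        return sum(d * c for d, c in self.species.items())

    @property
    def max_depth(self) -> int:
        return max(self.species, default=0)

    def get(self, depth: int) -> int:
        return self.species.get(depth, 0)

    @classmethod
    def from_depths(cls, depths: np.ndarray, k: int) -> "KmerHistogram":
        """Build from per-species occurrence counts (one entry per species)."""
        depths = np.asarray(depths)
        if depths.size == 0:
            return cls(k=k)
        binned = np.bincount(depths.astype(np.int64))
        species = {int(d): int(c) for d, c in enumerate(binned) if d > 0 and c > 0}
        return cls(k=k, species=species)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("depth\tspecies\n")
            for depth in sorted(self.species):
                fh.write(f"{depth}\t{self.species[depth]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, k: int = DEFAULT_K) -> "KmerHistogram":
        species: dict[int, int] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("depth"):
                    continue
                depth_s, count_s = line.split("\t")[:2]
                species[int(depth_s)] = int(count_s)
        return cls(k=k, species=species)

    def smoothed(self, window: int = 3) -> "KmerHistogram":
        """Moving-average smoothing (optional; off by default in pipelines)."""
        if window < 1 or window % 2 == 0:
            raise ValueError("smoothing window must be a positive odd integer")
        if not self.species:
            return KmerHistogram(k=self.k)
        half = window // 2
        max_d = self.max_depth
        dense = np.zeros(max_d + 1, dtype=np.float64)
        for d, c in self.species.items():
            dense[d] = c
        out: dict[int, int] = {}
        for d in range(1, max_d + 1):
            lo, hi = max(1, d - half), min(max_d, d + half)
            # zero-padded window: divide by the full width, not the overlap
            val = int(round(dense[lo : hi + 1].sum() / window))
            if val > 0:
                out[d] = val
        return KmerHistogram(k=self.k, species=out)


@dataclass
class SpectrumPeaks:
    error_boundary: int
    main_peak: int
    half_peak: float = 0.0
    repeat_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not self.half_peak:
            self.half_peak = self.main_peak / 2
        if not self.repeat_threshold:
            self.repeat_threshold = 1.8 * self.main_peak
        if self.error_boundary >= self.main_peak:
            raise SpectrumError(
                f"error boundary {self.error_boundary} not below main peak {self.main_peak}"
            )


@dataclass
class GenomeEstimate:
    """One survey row: peak depth, volumes, sizes, heterozygosity, repeats."""

    main_peak_depth: int
    n_17mer: int
    genome_size: float
    error_rate: float
    revised_genome_size: float
    a_half: float
    heterozygosity: float
    repetitive_rate: float

    def as_dict(self) -> dict[str, float]:
        return {
            "main_peak_depth": self.main_peak_depth,
            "n_17mer": self.n_17mer,
            "genome_size_bp": self.genome_size,
            "genome_size_mb": round(self.genome_size / 1e6, 2),
            "error_rate": self.error_rate,
            "revised_genome_size_bp": self.revised_genome_size,
            "revised_genome_size_mb": round(self.revised_genome_size / 1e6, 2),
            "a_half": self.a_half,
            "heterozygosity": self.heterozygosity,
            "repetitive_rate": self.repetitive_rate,
        }


def count_kmers(reads: Iterable[str], k: int = DEFAULT_K) -> KmerHistogram:
    """Count canonical k-mers over reads and return the depth histogram.

    Every length-k window free of N contributes one occurrence of its
    canonical form (lexicographic min of the window and its reverse
    complement). Reads shorter than k contribute nothing.
    """
    if k % 2 == 0:
        raise ValueError(f"k must be odd, got {k}")
    if not 3 <= k <= _encode.MAX_PACKED_K:
        raise ValueError(f"k must be in [3, {_encode.MAX_PACKED_K}], got {k}")
    _values, counts = _encode.count_canonical(reads, k)
    return KmerHistogram.from_depths(counts, k=k)


def find_peaks(hist: KmerHistogram) -> SpectrumPeaks:
    """Locate the error boundary and the main genomic peak.

    The error boundary is the smallest depth d >= 2 that is a local
    minimum (species(d) <= species(d-1) and species(d) <= species(d+1),
    absent depths counting as zero). The main peak is the argmax of
    species counts strictly beyond the boundary; ties go to the smaller
    depth.
    """
    if not hist.species or hist.max_depth < 2:
        raise SpectrumError("histogram is empty beyond depth 2; no genomic peak")
    max_d = hist.max_depth
    if hist.get(1) <= hist.get(2):
        # no elevated depth-1 error peak (e.g. error-free data): the whole
        # histogram beyond depth 1 is genomic
        boundary = 1
    else:
        boundary = None
        for d in range(2, max_d + 2):
            if hist.get(d) <= hist.get(d - 1) and hist.get(d) <= hist.get(d + 1):
                boundary = d
                break
        if boundary is None:  # pragma: no cover - a finite histogram always dips
            raise SpectrumError("no local minimum found after depth 1")
    best_depth, best_count = None, 0
    for d in range(boundary + 1, max_d + 1):
        c = hist.get(d)
        if c > best_count:
            best_depth, best_count = d, c
    if best_depth is None:
        raise SpectrumError(
            "histogram decreases monotonically: no genomic peak beyond the "
            f"error boundary at depth {boundary}"
        )
    return SpectrumPeaks(error_boundary=boundary, main_peak=best_depth)


def genome_size(n_occurrences: int | float, main_peak_depth: int | float) -> float:
    """Total k-mer occurrences divided by the main-peak depth."""
    if main_peak_depth <= 0:
        raise ValueError("main peak depth must be positive")
    return n_occurrences / main_peak_depth


def estimate_genome_size(hist: KmerHistogram, peaks: SpectrumPeaks) -> float:
    return genome_size(hist.n_occurrences, peaks.main_peak)


def error_rate(hist: KmerHistogram, denominator: str = "occurrences") -> float:
    """Fraction of k-mers at depth 1, attributed to sequencing error.

    `denominator` selects occurrences (default) or species as the base of
    the proportion.
    """
    singles = hist.get(1)
    if denominator == "occurrences":
        total = hist.n_occurrences
    elif denominator == "species":
        total = hist.n_species
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return singles / total if total else 0.0


def revised_size(size: float, err: float) -> float:
    return size * (1.0 - err)


def revise_genome_size(size: float, hist: KmerHistogram, denominator: str = "occurrences") -> float:
    if size <= 0:
        raise ValueError("genome size must be positive")
    return revised_size(size, error_rate(hist, denominator))


def heterozygosity_from_a(a_half: float, k: int = DEFAULT_K) -> float:
    """Convert the heterozygous species ratio a into per-base heterozygosity."""
    if not 0 <= a_half < 2:
        raise ValueError(f"a_half must lie in [0, 2), got {a_half}")
    return a_half / (k * (2.0 - a_half))


def a_from_heterozygosity(het: float, k: int = DEFAULT_K) -> float:
    """Analytic inverse of :func:`heterozygosity_from_a`."""
    return 2.0 * k * het / (1.0 + k * het)


def estimate_heterozygosity(
    hist: KmerHistogram,
    peaks: SpectrumPeaks,
    window: tuple[float, float] = (0.4, 0.6),
) -> tuple[float, float]:
    """(a_half, heterozygosity) from the half-depth species fraction.

    a_half = species with depth in [window] x main_peak over species
    deeper than the error boundary. The attribution window is a declared
    convention (the half peak is rarely sharp); widen or narrow as needed.
    """
    lo = window[0] * peaks.main_peak
    hi = window[1] * peaks.main_peak
    half_species = 0
    genomic_species = 0
    for depth, count in hist.species.items():
        if depth > peaks.error_boundary:
            genomic_species += count
            if lo <= depth <= hi:
                half_species += count
    a_half = half_species / genomic_species if genomic_species else 0.0
    return a_half, heterozygosity_from_a(a_half, hist.k)


def estimate_repetitive_rate(hist: KmerHistogram, peaks: SpectrumPeaks) -> float:
    """Occurrence fraction above 1.8x the main peak, over genomic occurrences."""
    threshold = peaks.repeat_threshold
    repeat_occ = 0
    genomic_occ = 0
    for depth, count in hist.species.items():
        occ = depth * count
        if depth > peaks.error_boundary:
            genomic_occ += occ
            if depth > threshold:
                repeat_occ += occ
    return repeat_occ / genomic_occ if genomic_occ else 0.0


def survey(hist: KmerHistogram, smooth: bool = False) -> GenomeEstimate:
    """Run the full estimate chain on one histogram."""
    peaks = find_peaks(hist.smoothed() if smooth else hist)
    size = estimate_genome_size(hist, peaks)
    err = error_rate(hist)
    a_half, het = estimate_heterozygosity(hist, peaks)
    return GenomeEstimate(
        main_peak_depth=peaks.main_peak,
        n_17mer=hist.n_occurrences,
        genome_size=size,
        error_rate=err,
        revised_genome_size=revised_size(size, err),
        a_half=a_half,
        heterozygosity=het,
        repetitive_rate=estimate_repetitive_rate(hist, peaks),
    )


def plot_spectrum(
    hist: KmerHistogram,
    path: str | Path,
    depth_cap: int = 250,
    freq_cap_fraction: float = 0.01,
) -> None:
    """Depth-vs-frequency line plot with the conventional display cut-offs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depths = np.arange(1, min(hist.max_depth, depth_cap) + 1)
    total = hist.n_species or 1
    freqs = np.array([hist.get(int(d)) / total for d in depths])
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(depths, np.minimum(freqs, freq_cap_fraction))
    ax.set_xlabel("depth (x)")
    ax.set_ylabel("k-mer species frequency")
    ax.set_title(f"{hist.k}-mer spectrum")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
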