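"""GC-depth profiling, stray-region extraction, and read decontamination.

Contigs are points in (GC%, mean depth) space; contaminants of different
GC and abundance fall off the host cloud into "stray regions". Stray
contigs are pulled out by config-supplied rectangles, labeled from an
external hit table (BLAST tabular; running the search itself is out of
scope), and microbe-labeled contigs seed a canonical k-mer database used
to filter read pairs by k-mer share.

Note the label, not the location, decides db membership: a stray region
may consist mostly of low-depth host contigs and must not poison the db.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _encode
from .assembly import ContigRecord
from .qc import ReadPair
from .report_format import round_percent


@dataclass
class StrayRegion:
    """Axis-aligned rectangle in (GC%, depth) space; bounds inclusive."""

    gc_min: float
    gc_max: float
    depth_min: float
    depth_max: float
    label: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min < self.gc_max <= 100:
            raise ValueError(f"invalid GC bounds [{self.gc_min}, {self.gc_max}]")
        if not 0 <= self.depth_min < self.depth_max:
            raise ValueError(f"invalid depth bounds [{self.depth_min}, {self.depth_max}]")

    def contains(self, gc_percent: float, depth: float) -> bool:
        return (
            self.gc_min <= gc_percent <= self.gc_max
            and self.depth_min <= depth <= self.depth_max
        )


# Shipped presets mirroring the published survey's hand-drawn rectangles.
IN_VIVO_STRAY_REGIONS = (
    StrayRegion(0, 100, 0, 14, "low-depth"),
    StrayRegion(0, 60, 14, 24, "low-depth-host-gc"),
    StrayRegion(60, 100, 20, 35, "high-gc-mid-depth"),
    StrayRegion(60, 100, 40, 80, "high-gc-high-depth"),
)
IN_VITRO_STRAY_REGIONS = (StrayRegion(57, 80, 0, 10, "high-gc-low-depth"),)


@dataclass
class HitRecord:
    """One row of 12-column BLAST tabular output (+ optional taxon label)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float
    taxon: str | None = None

    def __post_init__(self) -> None:
        if self.evalue < 0 or self.bit_score < 0:
            raise ValueError("e-value and bit score must be non-negative")


def parse_hits(lines: Iterable[str], source: str = "<hits>") -> list[HitRecord]:
    """Parse BLAST outfmt-6 rows, tolerating an extra taxon column."""
    hits: list[HitRecord] = []
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise ValueError(f"{source}:{lineno}: expected >= 12 tab-separated columns, got {len(fields)}")
        try:
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                    taxon=fields[12] if len(fields) > 12 else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{source}:{lineno}: malformed hit row: {exc}") from exc
    return hits


def read_hits(path: str | Path) -> list[HitRecord]:
    with open(path) as fh:
        return parse_hits(fh, source=str(path))


def gc_depth_points(contigs: Sequence[ContigRecord], min_length: int = 500) -> list[tuple[str, float, float]]:
    """(id, GC%, depth) for contigs of at least ``min_length``."""
    return [(c.id, 100.0 * c.gc, c.mean_depth) for c in contigs if c.length >= min_length]


def gc_depth_density(
    contigs: Sequence[ContigRecord],
    min_length: int = 500,
    gc_bin: float = 1.0,
    depth_bin: float = 1.0,
    depth_cap: float = 100.0,
) -> tuple[list[tuple[str, float, float]], np.ndarray, np.ndarray, np.ndarray]:
    """Binned density grid over the GC-depth plane.

    Returns (points, grid, gc_edges, depth_edges) where grid[i, j] counts
    contigs with GC% in bin i and depth (capped at depth_cap) in bin j.
    """
    points = gc_depth_points(contigs, min_length)
    gc_edges = np.arange(0.0, 100.0 + gc_bin, gc_bin)
    depth_edges = np.arange(0.0, depth_cap + depth_bin, depth_bin)
    if not points:
        grid = np.zeros((len(gc_edges) - 1, len(depth_edges) - 1), dtype=np.int64)
        return points, grid, gc_edges, depth_edges
    gcs = np.array([p[1] for p in points])
    depths = np.minimum(np.array([p[2] for p in points]), depth_cap - 1e-9)
    grid, _, _ = np.histogram2d(gcs, depths, bins=(gc_edges, depth_edges))
    return points, grid.astype(np.int64), gc_edges, depth_edges


def extract_stray(
    points: Sequence[tuple[str, float, float]], regions: Sequence[StrayRegion]
) -> dict[str, list[str]]:
    """Contig ids falling inside each region (a contig may hit several)."""
    out: dict[str, list[str]] = {}
    for i, region in enumerate(regions):
        label = region.label or f"region_{i}"
        out[label] = [cid for cid, gc, depth in points if region.contains(gc, depth)]
    return out


def best_hits(hits: Sequence[HitRecord], evalue_max: float = 1e-5) -> dict[str, HitRecord]:
    """Best hit per query: max bit score, ties to min e-value, then file order."""
    best: dict[str, HitRecord] = {}
    for hit in hits:
        if hit.evalue > evalue_max:
            continue
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
        elif hit.bit_score > cur.bit_score or (
            hit.bit_score == cur.bit_score and hit.evalue < cur.evalue
        ):
            best[hit.query_id] = hit
    return best


def _lookup_category(hit: HitRecord, taxon_map: Mapping[str, str]) -> str:
    keys = []
    if hit.taxon:
        keys.append(hit.taxon)
        keys.append(hit.taxon.split()[0])  # genus
    keys.append(hit.subject_id)
    keys.append(hit.subject_id.split()[0])
    for key in keys:
        if key in taxon_map:
            return taxon_map[key]
    return "unknown"


def label_contigs(
    contig_ids: Sequence[str],
    hits: Sequence[HitRecord],
    taxon_map: Mapping[str, str],
    evalue_max: float = 1e-5,
) -> dict[str, str]:
    """Per contig: host | microbe | unknown from its best hit's taxon."""
    best = best_hits(hits, evalue_max)
    labels: dict[str, str] = {}
    for cid in contig_ids:
        hit = best.get(cid)
        labels[cid] = _lookup_category(hit, taxon_map) if hit else "unknown"
    return labels


@dataclass
class ContaminantDB:
    """Canonical k-mer set of contigs judged to be contaminant."""

    k: int
    kmers: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint64))
    source_ids: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return int(self.kmers.size)

    def contains(self, values: np.ndarray) -> np.ndarray:
        if self.kmers.size == 0 or values.size == 0:
            return np.zeros(values.size, dtype=bool)
        idx = np.searchsorted(self.kmers, values)
        idx[idx >= self.kmers.size] = 0
        return self.kmers[idx] == values

    def union(self, other: "ContaminantDB") -> "ContaminantDB":
        if self.k != other.k:
            raise ValueError("cannot union databases with different k")
        return ContaminantDB(
            k=self.k,
            kmers=np.union1d(self.kmers, other.kmers),
            source_ids=sorted(set(self.source_ids) | set(other.source_ids)),
        )


def build_db(contigs: Sequence[ContigRecord], k: int = 17) -> ContaminantDB:
    """Canonical k-mer set over all N-free windows of the given contigs."""
    values = [
        _encode.canonical_window_values(_encode.encode(c.seq), k)
        for c in contigs
        if c.length >= k
    ]
    kmers = (
        np.unique(np.concatenate(values)) if values else np.empty(0, dtype=np.uint64)
    )
    return ContaminantDB(k=k, kmers=kmers, source_ids=[c.id for c in contigs])


def kmer_shares(seqs: Sequence[str], db: ContaminantDB) -> np.ndarray:
    """Fraction of each sequence's N-free canonical k-mers present in db.

    Sequences with no valid window get share 0. Vectorised over the whole
    batch: one encode pass, one membership pass, per-sequence reductions
    via cumulative sums.
    """
    k = db.k
    if not seqs:
        return np.empty(0, dtype=np.float64)
    codes = _encode._join_codes(seqs)
    fwd, rc, valid = _encode.window_values(codes, k)
    member = np.zeros(valid.size, dtype=bool)
    if valid.any():
        member[valid] = db.contains(np.minimum(fwd, rc)[valid])
    cum_valid = np.concatenate(([0], np.cumsum(valid)))
    cum_member = np.concatenate(([0], np.cumsum(member)))
    shares = np.zeros(len(seqs), dtype=np.float64)
    offset = 0
    n_windows = valid.size
    for i, seq in enumerate(seqs):
        lo = offset
        hi = min(offset + len(seq) - k + 1, n_windows)
        if hi > lo:
            nv = cum_valid[hi] - cum_valid[lo]
            if nv:
                shares[i] = (cum_member[hi] - cum_member[lo]) / nv
        offset += len(seq) + 1  # +1 for the separator
    return shares


def filter_contaminant_reads(
    pairs: Sequence[ReadPair],
    db: ContaminantDB,
    share_threshold: float = 0.5,
) -> tuple[list[ReadPair], list[ReadPair], dict]:
    """Remove pairs where either mate shares >= threshold k-mers with db.

    Returns (kept, removed, report); the report carries raw counts plus
    the removed-volume percentage under the display rounding rule.
    """
    if not 0 < share_threshold <= 1:
        raise ValueError("share_threshold must lie in (0, 1]")
    kept: list[ReadPair] = []
    removed: list[ReadPair] = []
    if pairs and len(db):
        shares1 = kmer_shares([p.seq1 for p in pairs], db)
        shares2 = kmer_shares([p.seq2 for p in pairs], db)
        hit = (shares1 >= share_threshold) | (shares2 >= share_threshold)
        for pair, is_hit in zip(pairs, hit):
            (removed if is_hit else kept).append(pair)
    else:
        kept = list(pairs)
    total_bases = sum(len(p.seq1) + len(p.seq2) for p in pairs)
    removed_bases = sum(len(p.seq1) + len(p.seq2) for p in removed)
    report = removal_report(removed_bases / 1e9, total_bases / 1e9)
    report.update(
        {
            "total_pairs": len(pairs),
            "removed_pairs": len(removed),
            "kept_pairs": len(kept),
            "share_threshold": share_threshold,
            "db_kmers": len(db),
        }
    )
    return kept, removed, report


def removal_report(removed_gb: float, total_gb: float) -> dict:
    """Removed-volume arithmetic on Gb inputs, with display rounding."""
    percent_raw = 100.0 * removed_gb / total_gb if total_gb else 0.0
    return {
        "removed_gb": removed_gb,
        "total_gb": total_gb,
        "removed_percent_raw": percent_raw,
        "removed_percent": round_percent(percent_raw),
    }


def removal_percent(removed_gb: float, total_gb: float) -> float:
    return removal_report(removed_gb, total_gb)["removed_percent"]


def write_density_tsv(
    grid: np.ndarray, gc_edges: np.ndarray, depth_edges: np.ndarray, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("gc_bin_lo\tdepth_bin_lo\tcount\n")
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                if grid[i, j]:
                    fh.write(f"{gc_edges[i]:g}\t{depth_edges[j]:g}\t{int(grid[i, j])}\n")


def write_report_json(report: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(report), fh, indent=2, sort_keys=True)
        fh.write("\n")


def plot_gc_depth(
    points: Sequence[tuple[str, float, float]],
    path: str | Path,
    regions: Sequence[StrayRegion] = (),
    depth_cap: float = 100.0,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(6, 5))
    if points:
        gcs = [p[1] for p in points]
        depths = [min(p[2], depth_cap) for p in points]
        ax.scatter(gcs, depths, s=4, alpha=0.4, linewidths=0)
    for region in regions:
        ax.add_patch(
            Rectangle(
                (region.gc_min, region.depth_min),
                region.gc_max - region.gc_min,
                min(region.depth_max, depth_cap) - region.depth_min,
                fill=False,
                edgecolor="red",
                linestyle="--",
            )
        )
    ax.set_xlim(0, 100)
    ax.set_ylim(0, depth_cap)
    ax.set_xlabel("GC content (%)")
    ax.set_ylabel("mean depth (x)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
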