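"""Perfect microsatellite (SSR) detection and motif-class summaries.

Detects maximal perfect tandem runs of primitive 1-6 bp motifs meeting
per-unit-length minimum repeat counts (default 10, 6, 5, 5, 5, 5 for
mono- through hexanucleotides). Only full motif units count toward the
repeat number and the reported coordinates; a run is nevertheless
required to be unextendable even by a partial unit. Motif classes
collapse rotations and strands (e.g. TTA -> AAT/ATT). Output coordinates
are 1-based inclusive; compound/imperfect SSRs are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from ._encode import revcomp
from .report_format import share_percent

DEFAULT_MIN_REPEATS = (10, 6, 5, 5, 5, 5)

_UNIT_NAMES = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass
class SSRConfig:
    min_repeats: Sequence[int] = DEFAULT_MIN_REPEATS
    max_unit_length: int = 6

    def __post_init__(self) -> None:
        if len(self.min_repeats) != self.max_unit_length:
            raise ValueError("min_repeats must give one threshold per unit length")
        if any(m < 2 for m in self.min_repeats):
            raise ValueError("minimum repeat counts must be >= 2")

    def min_for(self, unit_length: int) -> int:
        return self.min_repeats[unit_length - 1]


@dataclass
class SSRRecord:
    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str
    motif_class: str
    unit_length: int
    repeats: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != self.unit_length * self.repeats:
            raise ValueError(f"length identity violated for SSR at {self.seq_id}:{self.start}")


def is_primitive(motif: str) -> bool:
    """True when the motif is not a repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def motif_class(motif: str) -> str:
    """Strand- and rotation-collapsed class label "X/Y" (X <= Y)."""
    if not motif or len(motif) > 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")
    if any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be over ACGT: {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif is not primitive: {motif!r}")
    x = min(_rotations(motif))
    y = min(_rotations(revcomp(motif)))
    lo, hi = sorted((x, y))
    return f"{lo}/{hi}"


def find_ssrs(seq: str, config: SSRConfig | None = None, seq_id: str = "seq") -> list[SSRRecord]:
    """All maximal perfect tandem runs meeting the repeat thresholds.

    Runs containing N are excluded; when an interval qualifies under
    several unit lengths the smallest primitive unit wins; output records
    never overlap and are ordered by start.
    """
    config = config or SSRConfig()
    seq = seq.upper()
    n = len(seq)
    records: list[SSRRecord] = []
    i = 0
    while i < n:
        if seq[i] == "N":
            i += 1
            continue
        found = None
        for unit in range(1, config.max_unit_length + 1):
            if i + unit * config.min_for(unit) > n:
                continue
            motif = seq[i : i + unit]
            if "N" in motif or not is_primitive(motif):
                continue
            # left-maximality: one more base to the left would extend the
            # periodicity, so the true maximal run starts earlier
            if i > 0 and seq[i - 1] == seq[i + unit - 1] and seq[i - 1] != "N":
                continue
            j = i + unit
            while j < n and seq[j] != "N" and seq[j] == seq[j - unit]:
                j += 1
            repeats = (j - i) // unit
            if repeats >= config.min_for(unit):
                found = (unit, repeats)
                break
        if found is None:
            i += 1
            continue
        unit, repeats = found
        motif = seq[i : i + unit]
        records.append(
            SSRRecord(
                seq_id=seq_id,
                start=i + 1,
                end=i + unit * repeats,
                motif=motif,
                motif_class=motif_class(motif),
                unit_length=unit,
                repeats=repeats,
            )
        )
        i += unit * repeats
    return records


def find_ssrs_fasta(records: Iterable[tuple[str, str]], config: SSRConfig | None = None) -> list[SSRRecord]:
    out: list[SSRRecord] = []
    for seq_id, seq in records:
        out.extend(find_ssrs(seq, config, seq_id=seq_id))
    return out


@dataclass
class SSRSummary:
    total: int = 0
    by_unit: dict[int, int] = field(default_factory=dict)
    by_unit_share: dict[int, float] = field(default_factory=dict)
    by_class: dict[str, int] = field(default_factory=dict)
    by_class_share: dict[str, float] = field(default_factory=dict)
    top_classes: list[tuple[str, int]] = field(default_factory=list)
    by_unit_repeats: dict[int, dict[str, int]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_unit": {_UNIT_NAMES[u]: c for u, c in sorted(self.by_unit.items())},
            "by_unit_share": {_UNIT_NAMES[u]: s for u, s in sorted(self.by_unit_share.items())},
            "top_classes": [[cls, count, self.by_class_share[cls]] for cls, count in self.top_classes],
            "by_unit_repeats": {_UNIT_NAMES[u]: d for u, d in sorted(self.by_unit_repeats.items())},
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def class_share(count: int, total: int) -> float:
    """Display-rounded percentage share of one class/unit count."""
    return share_percent(count, total)


def summarize(records: Sequence[SSRRecord], top_n: int = 20, repeat_cap: int = 15) -> SSRSummary:
    """Counts and percentage shares by unit length, motif class, and
    repeat number (repeat numbers >= repeat_cap pooled into one bucket)."""
    summary = SSRSummary(total=len(records))
    if not records:
        return summary
    for rec in records:
        summary.by_unit[rec.unit_length] = summary.by_unit.get(rec.unit_length, 0) + 1
        summary.by_class[rec.motif_class] = summary.by_class.get(rec.motif_class, 0) + 1
        bucket = str(rec.repeats) if rec.repeats < repeat_cap else f">={repeat_cap}"
        unit_d = summary.by_unit_repeats.setdefault(rec.unit_length, {})
        unit_d[bucket] = unit_d.get(bucket, 0) + 1
    summary.by_unit_share = {u: class_share(c, summary.total) for u, c in summary.by_unit.items()}
    summary.by_class_share = {
        cls: class_share(c, summary.total) for cls, c in summary.by_class.items()
    }
    summary.top_classes = sorted(summary.by_class.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
    return summary


def write_records_tsv(records: Sequence[SSRRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tunit_length\trepeats\tmotif\tmotif_class\n")
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.start}\t{r.end}\t{r.unit_length}\t{r.repeats}\t{r.motif}\t{r.motif_class}\n"
            )


def plot_summary(summary: SSRSummary, path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(11, 4))
    units = sorted(summary.by_unit)
    ax1.bar([_UNIT_NAMES[u] for u in units], [summary.by_unit[u] for u in units])
    ax1.set_ylabel("SSR count")
    ax1.set_title("by unit length")
    if summary.top_classes:
        names = [c for c, _ in summary.top_classes]
        counts = [n for _, n in summary.top_classes]
        ax2.bar(range(len(names)), counts)
        ax2.set_xticks(range(len(names)))
        ax2.set_xticklabels(names, rotation=90, fontsize=7)
        ax2.set_title("top motif classes")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
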