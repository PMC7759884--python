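"""Pipeline orchestration and survey report arithmetic.

``run_pipeline`` drives the whole survey on a config: QC -> k-mer survey
-> assembly -> GC-depth profile -> stray extraction -> contaminant
labeling -> read decontamination -> re-QC/re-survey -> SSR -> report.
``report_arithmetic`` reproduces the derived report lines (overestimation
due to contaminants, genome coverage of the assembly, removed volume).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import assembly, contamination, kmers, qc, simulate, ssr
from .report_format import round_percent, round_size


def overestimation(revised_contaminated_mb: float, revised_clean_mb: float) -> tuple[float, float]:
    """Contaminant-attributed size overestimation in Mb and as % of the
    clean revised size."""
    diff_mb = round_size(revised_contaminated_mb - revised_clean_mb)
    pct = round_percent(100.0 * diff_mb / revised_clean_mb) if revised_clean_mb else 0.0
    return diff_mb, pct


def genome_coverage_percent(assembly_total_gb: float, estimated_size_gb: float) -> float:
    """Assembly total / estimated genome size, as a 2-decimal percentage."""
    if estimated_size_gb <= 0:
        raise ValueError("estimated size must be positive")
    return round(100.0 * assembly_total_gb / estimated_size_gb, 2)


def report_arithmetic(
    revised_contaminated_mb: float | None = None,
    revised_clean_mb: float | None = None,
    assembly_total_gb: float | None = None,
    estimated_size_gb: float | None = None,
    removed_gb: float | None = None,
    total_clean_gb: float | None = None,
) -> dict:
    """Derived report lines from raw numerators/denominators."""
    out: dict = {}
    if revised_contaminated_mb is not None and revised_clean_mb is not None:
        mb, pct = overestimation(revised_contaminated_mb, revised_clean_mb)
        out["overestimation_mb"] = mb
        out["overestimation_percent"] = pct
    if assembly_total_gb is not None and estimated_size_gb is not None:
        out["genome_coverage_percent"] = genome_coverage_percent(assembly_total_gb, estimated_size_gb)
    if removed_gb is not None and total_clean_gb is not None:
        out["contamination_percent"] = contamination.removal_percent(removed_gb, total_clean_gb)
    return out


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    outdir: str = "survey_out"
    seed: int = 0
    plots: bool = False
    # input mode 1: simulate everything
    simulate: simulate.SimulationConfig | None = None
    # input mode 2: existing files
    reads1: str | None = None
    reads2: str | None = None
    hits: str | None = None
    taxon_map: dict[str, str] = field(default_factory=dict)
    stray_regions: list[contamination.StrayRegion] = field(
        default_factory=lambda: list(contamination.IN_VITRO_STRAY_REGIONS)
    )
    qc_config: qc.QCConfig = field(default_factory=qc.QCConfig)
    kmer_k: int = 17
    assembly_config: assembly.AssemblyConfig = field(default_factory=assembly.AssemblyConfig)
    db_k: int = 17
    share_threshold: float = 0.5
    ssr_config: ssr.SSRConfig = field(default_factory=ssr.SSRConfig)

    def validate(self) -> None:
        if self.simulate is None:
            if not self.reads1 or not self.reads2:
                raise PipelineConfigError("either a simulate section or reads1/reads2 is required")
            for path in (self.reads1, self.reads2, self.hits):
                if path and not Path(path).exists():
                    raise PipelineConfigError(f"input file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("outdir", "seed", "plots", "reads1", "reads2", "hits", "taxon_map",
                    "kmer_k", "db_k", "share_threshold"):
            if key in raw:
                kwargs[key] = raw[key]
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "contaminants" in sim:
                sim["contaminants"] = [
                    simulate.ContaminantSpec(**c) for c in sim["contaminants"]
                ]
            kwargs["simulate"] = simulate.SimulationConfig(**sim)
        if "stray_regions" in raw:
            kwargs["stray_regions"] = [
                contamination.StrayRegion(**r) for r in raw["stray_regions"]
            ]
        if "qc" in raw:
            kwargs["qc_config"] = qc.QCConfig(**raw["qc"])
        if "assembly" in raw:
            kwargs["assembly_config"] = assembly.AssemblyConfig(**raw["assembly"])
        if "ssr" in raw:
            kwargs["ssr_config"] = ssr.SSRConfig(**raw["ssr"])
        return cls(**kwargs)


def _survey_stage(reads: Sequence[str], k: int, outdir: Path, tag: str) -> tuple[kmers.KmerHistogram, kmers.GenomeEstimate]:
    hist = kmers.count_kmers(reads, k=k)
    hist.to_tsv(outdir / f"kmer_hist_{tag}.tsv")
    estimate = kmers.survey(hist)
    return hist, estimate


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full survey; returns the report dict (also written as
    JSON under the output directory). Deterministic for a fixed seed."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {"seed": config.seed}

    def stage(name: str, **counts) -> None:
        log.append({"stage": name, **counts})

    # --- inputs -----------------------------------------------------------
    truth = None
    references: dict[str, tuple[str, str]] = {}
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        haps, truth = simulate.simulate_host_genome(sim_cfg)
        sources = [simulate.ReadSource("host", list(haps), None)]
        references["host"] = (haps[0], "host_plant")
        for i, spec in enumerate(sim_cfg.contaminants):
            genome = simulate.simulate_contaminant_genome(
                spec.length, spec.gc, seed=config.seed + 1000 + i
            )
            name = f"contaminant_{i}"
            sources.append(simulate.ReadSource(name, [genome], spec.abundance))
            references[name] = (genome, f"Microbe sp. {i}")
        readset = simulate.simulate_reads(sources, sim_cfg)
        readset.write_fastq(outdir / "reads_1.fastq", outdir / "reads_2.fastq")
        readset.write_labels_tsv(outdir / "read_origins.tsv")
        truth.write_tsv(outdir / "truth.tsv")
        raw_pairs = readset.pairs
        stage("simulate", pairs=len(raw_pairs), sources=len(sources))
    else:
        raw_pairs = list(qc.read_fastq_pairs(config.reads1, config.reads2))
        stage("load", pairs=len(raw_pairs))

    # --- QC ---------------------------------------------------------------
    kept, discarded, qc_stats = qc.run_qc(raw_pairs, config.qc_config)
    qc_stats.to_json(outdir / "qc_stats.json")
    report["qc"] = qc_stats.as_dict()
    stage("qc", kept=len(kept), discarded=sum(len(v) for v in discarded.values()))
    clean_seqs = [s for p in kept for s in (p.seq1, p.seq2)]

    # --- k-mer survey (pre-decontamination) -------------------------------
    hist_pre, est_pre = _survey_stage(clean_seqs, config.kmer_k, outdir, "pre")
    report["survey_pre"] = est_pre.as_dict()
    stage("kmer_pre", n_occurrences=hist_pre.n_occurrences)

    # --- assembly + GC-depth profile --------------------------------------
    acfg = config.assembly_config
    kmer_counts = assembly.count_kmer_strings(clean_seqs, acfg.k)
    contigs = assembly.build_unitigs(kmer_counts, acfg)
    contigs = assembly.annotate_gc_depth(contigs, kmer_counts, acfg.k)
    assembly.write_contigs_fasta(contigs, outdir / "contigs_pre.fasta")
    assembly.write_contig_table(contigs, outdir / "contigs_pre.tsv")
    stats_pre = assembly.contig_stats(contigs, acfg.min_contig_length_stats)
    report["assembly_pre"] = stats_pre.as_dict()
    stage("assemble_pre", contigs=len(contigs))

    points, grid, gc_edges, depth_edges = contamination.gc_depth_density(
        contigs, min_length=acfg.min_contig_length_profile
    )
    contamination.write_density_tsv(grid, gc_edges, depth_edges, outdir / "gc_depth_pre.tsv")
    if config.plots:
        contamination.plot_gc_depth(points, outdir / "gc_depth_pre.png", config.stray_regions)

    # --- stray extraction + labeling + db ---------------------------------
    stray = contamination.extract_stray(points, config.stray_regions)
    stray_ids = sorted({cid for ids in stray.values() for cid in ids})
    if config.hits:
        hits = contamination.read_hits(config.hits)
    elif references:
        by_id = {c.id: c for c in contigs}
        rows = simulate.hits_from_truth([by_id[c] for c in stray_ids if c in by_id], references)
        (outdir / "stray_hits.tsv").write_text("".join(r + "\n" for r in rows))
        hits = contamination.parse_hits(rows)
    else:
        hits = []
    taxon_map = dict(config.taxon_map)
    if references and not taxon_map:
        taxon_map = {name: ("host" if name == "host" else "microbe") for name in references}
    labels = contamination.label_contigs(stray_ids, hits, taxon_map)
    microbe_ids = {cid for cid, lab in labels.items() if lab == "microbe"}
    db = contamination.build_db([c for c in contigs if c.id in microbe_ids], k=config.db_k)
    stage("label", stray=len(stray_ids), microbe=len(microbe_ids), db_kmers=len(db))

    # --- decontamination --------------------------------------------------
    kept2, removed, decon_report = contamination.filter_contaminant_reads(
        kept, db, config.share_threshold
    )
    contamination.write_report_json(decon_report, outdir / "decontamination.json")
    report["decontamination"] = decon_report
    qc.write_fastq_pairs(kept2, outdir / "decontaminated_1.fastq", outdir / "decontaminated_2.fastq")
    stage("decontaminate", kept=len(kept2), removed=len(removed))
    assert len(kept2) + len(removed) == len(kept)

    # --- post-decontamination survey --------------------------------------
    clean_seqs2 = [s for p in kept2 for s in (p.seq1, p.seq2)]
    hist_post, est_post = _survey_stage(clean_seqs2, config.kmer_k, outdir, "post")
    report["survey_post"] = est_post.as_dict()
    stage("kmer_post", n_occurrences=hist_post.n_occurrences)

    kmer_counts2 = assembly.count_kmer_strings(clean_seqs2, acfg.k)
    contigs2 = assembly.build_unitigs(kmer_counts2, acfg)
    contigs2 = assembly.annotate_gc_depth(contigs2, kmer_counts2, acfg.k)
    assembly.write_contigs_fasta(contigs2, outdir / "contigs_post.fasta")
    assembly.write_contig_table(contigs2, outdir / "contigs_post.tsv")
    stats_post = assembly.contig_stats(contigs2, acfg.min_contig_length_stats)
    report["assembly_post"] = stats_post.as_dict()
    points2, grid2, gc_e2, d_e2 = contamination.gc_depth_density(
        contigs2, min_length=acfg.min_contig_length_profile
    )
    contamination.write_density_tsv(grid2, gc_e2, d_e2, outdir / "gc_depth_post.tsv")
    if config.plots:
        contamination.plot_gc_depth(points2, outdir / "gc_depth_post.png", config.stray_regions)
        kmers.plot_spectrum(hist_post, outdir / "spectrum_post.png")
    stage("assemble_post", contigs=len(contigs2))

    # --- SSR --------------------------------------------------------------
    ssr_records = ssr.find_ssrs_fasta(((c.id, c.seq) for c in contigs2), config.ssr_config)
    ssr.write_records_tsv(ssr_records, outdir / "ssr_records.tsv")
    ssr_summary = ssr.summarize(ssr_records)
    ssr_summary.to_json(outdir / "ssr_summary.json")
    report["ssr"] = ssr_summary.as_dict()
    stage("ssr", records=len(ssr_records))

    # --- derived arithmetic ----------------------------------------------
    report["derived"] = report_arithmetic(
        revised_contaminated_mb=est_pre.revised_genome_size / 1e6,
        revised_clean_mb=est_post.revised_genome_size / 1e6,
        assembly_total_gb=stats_post.total_length / 1e9,
        estimated_size_gb=est_post.revised_genome_size / 1e9,
        removed_gb=decon_report["removed_gb"],
        total_clean_gb=decon_report["total_gb"],
    )
    report["coverage_fraction"] = (
        stats_post.total_length / est_post.revised_genome_size
        if est_post.revised_genome_size
        else 0.0
    )
    if truth is not None:
        report["truth"] = {
            "host_length": len(truth.haplotype_a),
            "host_gc": truth.host_gc,
            "n_snps": len(truth.snp_positions),
            "repeat_fraction": truth.repeat_fraction,
        }
    report["log"] = log

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def render_text(report: Mapping) -> str:
    """Human-readable summary of a pipeline report."""
    lines = ["Genome survey report", "====================="]
    if "qc" in report:
        q = report["qc"]
        lines.append(
            f"QC: {q['clean_pairs']}/{q['raw_pairs']} pairs kept "
            f"({q['clean_gb']:.4f} Gb clean, Q30 {100 * q['q30_fraction']:.1f}%, "
            f"GC {100 * q['gc_fraction']:.2f}%)"
        )
    for tag, label in (("survey_pre", "Survey (pre-decontamination)"),
                       ("survey_post", "Survey (decontaminated)")):
        if tag in report:
            s = report[tag]
            lines.append(
                f"{label}: peak {s['main_peak_depth']}x, size {s['genome_size_mb']} Mb, "
                f"revised {s['revised_genome_size_mb']} Mb, "
                f"het {100 * s['heterozygosity']:.2f}%, "
                f"repeats {100 * s['repetitive_rate']:.2f}%"
            )
    if "decontamination" in report:
        d = report["decontamination"]
        lines.append(
            f"Decontamination: removed {d['removed_pairs']}/{d['total_pairs']} pairs "
            f"({d['removed_percent']}% of volume)"
        )
    if "derived" in report:
        dv = report["derived"]
        if "overestimation_mb" in dv:
            lines.append(
                f"Overestimation due to contaminants: {dv['overestimation_mb']} Mb "
                f"({dv['overestimation_percent']}%)"
            )
        if "genome_coverage_percent" in dv:
            lines.append(f"Assembly covers {dv['genome_coverage_percent']}% of the estimated genome")
    if "ssr" in report:
        lines.append(f"SSRs: {report['ssr']['total']}")
    return "\n".join(lines) + "\n"
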