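# genomesurvey

A genome survey sequencing toolkit for short-read data: quality filtering,
17-mer spectrum genome characterization (genome size, heterozygosity,
repetitive rate), minimal de Bruijn unitig assembly with GC-depth
profiling, stray-region contaminant screening with k-mer based read
decontamination, and perfect-microsatellite (SSR) detection. A
ground-truthed simulator of contaminated diploid samples makes every
stage testable offline.

## Modules

| module                       | what it does |
|------------------------------|--------------|
| `genomesurvey.simulate`      | diploid host genomes (GC, SNP rate, implanted repeat copies), contaminant genomes, paired-end reads with per-pair origin labels and injectable QC violations |
| `genomesurvey.qc`            | whole-pair read filtering (adapter / >10% N / >20% bases under Q5) and Q30/GC summary statistics; strict 4-line FASTQ I/O |
| `genomesurvey.kmers`         | canonical k-mer counting (packed uint64, k ≤ 31), spectrum peak finding, and the survey estimates: size = occurrences/peak, error-rate revision, heterozygosity from the half-depth species ratio, repetitive rate above 1.8× the peak |
| `genomesurvey.assembly`      | unitig assembly from solid canonical k-mers, N50/length statistics, per-contig GC and k-mer depth |
| `genomesurvey.contamination` | GC-depth density grids, stray-region rectangle extraction, BLAST-tabular best-hit labeling, contaminant k-mer database, read-pair filtering by k-mer share |
| `genomesurvey.ssr`           | maximal perfect tandem repeats of primitive 1–6 bp motifs (MISA-style minima 10,6,5,5,5,5), rotation/strand-collapsed motif classes, summaries |
| `genomesurvey.report`        | pipeline orchestration and derived report arithmetic (removed volume %, size overestimation, genome coverage) |

## CLI

Every stage is a subcommand (`simulate`, `qc`, `kmer`, `assemble`,
`gcdepth`, `decontam`, `ssr`, `report`), plus `all` for the full pipeline
from a YAML config:

```bash
genomesurvey simulate --host-length 100000 --coverage 40 \
    --contaminant 20000,0.65,0.05 --seed 1 --outdir sim/
genomesurvey qc sim/reads_1.fastq sim/reads_2.fastq \
    --out1 clean_1.fastq --out2 clean_2.fastq --report qc.json
genomesurvey kmer clean_1.fastq clean_2.fastq \
    --hist-out hist.tsv --survey-out survey.json
genomesurvey all config.yaml
```

Example `config.yaml`:

```yaml
outdir: survey_out
seed: 1
simulate:
  host_length: 100000
  coverage: 40.0
  base_error_rate: 0.002
  contaminants:
    - {length: 20000, gc: 0.65, abundance: 0.05}
assembly: {k: 31, min_kmer_count: 3}
stray_regions:
  - {gc_min: 55, gc_max: 85, depth_min: 0, depth_max: 25}
```

## Conventions worth knowing

- "Number of k-mers" in the size formula means total window occurrences,
  not distinct species; the error rate is depth-1 occurrences over total
  occurrences (a species-based denominator is available as an option).
- k-mers are strand-collapsed (canonical = lexicographic min of the
  window and its reverse complement) everywhere.
- The heterozygous species ratio attributes species with depth in
  [0.4, 0.6] × main peak to the half-depth peak (window configurable).
- Stray regions are inclusive rectangles in (GC%, depth) space; the hit
  label, not the region, decides what enters the contaminant database.
- Display rounding: Mb/Gb to 2 decimals; percentages to 1 decimal,
  2 decimals below 1%; assembly genome coverage to 2 decimals.
- SSR output coordinates are 1-based inclusive; only full motif units
  count toward repeat numbers; overlapping/nested runs are suppressed in
  favor of the earliest, smallest-unit run.
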