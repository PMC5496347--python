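# txscape

Transcriptome landscape analysis for small prokaryotic genomes.

`txscape` is built for the kind of experiment in which a single bacterial or
archaeal chromosome is deeply sequenced (bulk RNA-seq, paired-end cDNA
fragments, no rRNA depletion) under one or two conditions, and the questions
are descriptive and genome-positional: where do the reads go, which genes
dominate the transcriptome, which chromosomal regions are transcriptionally
silent, how does expression line up with codon adaptation and GC composition,
which gene runs are transcribed as polycistronic messages, and which
intergenic intervals carry enough coverage to be candidate small non-coding
RNAs.  The motivating use case is the transcriptome of a halophilic archaeon
whose chromosome carries two rRNA operon clusters that soak up ~80% of all
fragments, a heavy-tailed expression distribution, and two large
low-expression regions co-locating with GC-deviant, hypothetical-gene-rich
islands.

## What it computes

**Quantification.** Fragments are assigned in two passes, mimicking an
rRNA-first mapping strategy: any fragment touching a ribosomal RNA feature by
≥1 nt is an rRNA fragment; the rest go to the annotated feature with the
largest overlap, provided that overlap covers at least half the fragment
(ties to the leftmost feature), and are intergenic otherwise.  Per-gene
expression is TPM (transcripts per million),

```
tpm_i = 10^6 · (c_i / L_i) / Σ_j (c_j / L_j)
```

with counts `c`, lengths `L`, and `j` running over CDS (the convention that
excludes rRNA and other non-coding features from genome-wide averages).
Genes are tiered relative to the mean CDS TPM (silent, <1 TPM, below/at
average, ≥2.5×, ≥5×, ≥10×).  UTRs are called as coverage plateaus contiguous
with expressed CDS boundaries, and intergenic fragments falling mostly inside
a UTR call are re-categorised, yielding the rRNA / CDS / UTR /
other-intergenic read accounting of the classic general-statistics table.

**Comparison.** With one library per condition there is nothing to estimate a
dispersion from, so the light/dark comparison is a descriptive outlier
screen: per-gene `delta = log10((tpm_b+c)/(tpm_a+c))` standardised over the
gene set, flagged at |z| > 2.5, with a secondary |log2 fold change| > 1 flag.
Conditions that do not differ are then averaged for the positional analyses.

**Codon adaptation.** CAI follows Sharp & Li (1987): relative adaptiveness
`w = count / max synonymous count` over a reference set of (by default the 40
longest) ribosomal-protein CDS, pseudo-count 0.5 for unobserved codons, and
per-gene CAI as the geometric mean of `w`, computed in the log domain.

**Landscape.** Sliding-window GC with |z| > 2.5 SD region calls; percent
hypothetical proteins in a window of 100 consecutive genes; low-expression
regions from gene-window median TPM below the 10th percentile of all window
medians; TPM shares of genome halves and quarters (with filters to restrict
to highly expressed genes or drop the top k); per-arCOG-category expression
summaries.

**Units and islands.** Transcription units are maximal same-strand gene runs
with intergenic gaps ≤ 30 nt (overlaps count), split where per-gene coverage
becomes uneven (member-coverage CV > 1) — an operon should show an even read
distribution.  Transcribed islands are intervals of depth ≥ 5× the median
expressed-CDS depth lying entirely outside annotation and UTR calls, 30–500
nt long: candidate small RNAs.

**Synthetic data.** A seeded generator (`txscape.simulate`) produces a
genome, GFF3 annotation, and per-condition fragment TSVs with all of the
structure above planted — rRNA clusters, operons, UTR plateaus,
low-expression blocks co-locating with GC islands and hypothetical-gene
enrichment, intergenic islands — plus a machine-readable ground truth, so
every caller can be scored against what was actually planted.

## Worked example

```bash
# generate a ~400 kb synthetic experiment with two conditions
txscape simulate --seed 7 --out demo/sim --config small.json
# small.json: {"genome_len": 400000, "n_genes": 300, "n_islands": 6,
#              "n_ribosomal": 45, "nb_mean": 60.0}

# full pipeline: quantify -> compare -> CAI -> landscape -> units
txscape report --config pipeline.json   # names the genome/gff/fragment files
```

From the resulting `report.json` (seed 7):

* `category_percent` (light): rRNA 79.0, CDS 6.2, UTR 14.5, other
  intergenic 0.3 — the rRNA operons dominate exactly as configured, and UTR
  reads outnumber CDS reads, as they do in deeply sequenced archaeal
  transcriptomes.
* `average_tpm_per_cds` 3333.3 vs `median_tpm_per_cds` 982.4 — a
  mean/median ratio of ~3.4, the signature of a heavy-tailed expression
  distribution; 2 genes sit above 10× the average.
* `n_sd_outliers_cds` 9 of 300 between the two identically distributed
  conditions — the 2.5-SD screen flags roughly its Gaussian tail, i.e. no
  differential expression.
* `n_low_expression_regions` 2, at 147.5–162.5 kb and 282.7–297.8 kb —
  precisely the two planted low-expression gene blocks, which also carry the
  planted GC shift (3 GC-deviant calls) and hypothetical-gene enrichment.
* `units`: 139 transcription units, 79 polycistronic, largest 5 genes;
  `n_transcribed_islands` 6 — all six planted intergenic small-RNA islands,
  none elsewhere.

Per-feature tables (`expression_*.tsv`, `cai.tsv`), tracks
(`gc_track.tsv`, `hypothetical_density.tsv`, `coverage_*.bedgraph`) and
region calls (`*.bed`) are written next to the report.

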