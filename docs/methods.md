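# Methods

This note documents the models, conventions and numerical choices behind
`txscape`, and what the synthetic-data experiments do and do not establish
about real data.

## Coordinates and formats

All internal intervals are 0-based half-open on a single linear replicon.
GFF3 (1-based inclusive) and BED/bedGraph (0-based half-open) are converted
at the I/O boundary only.  The chromosome is treated as linear: the
positional analyses (halves, quarters, windows) are linear by nature, and
origin-spanning features are rejected rather than silently split;
circularity is recorded as a flag but never modelled.  One replicon per run
— a plasmid is analysed in a separate run.

A plain fragment TSV (`fragment_id, start, end, strand`) is accepted
alongside SAM/BAM so the pipeline can be exercised and tested without any
alignment tooling; SAM/BAM input collapses properly aligned mate pairs to
one fragment spanning the leftmost to the rightmost mate coordinate,
dropping unmapped and secondary records with logged counts.

## Fragment assignment

Assignment is per fragment, in two passes:

1. **rRNA first.**  Any overlap of ≥1 nt with an rRNA feature sends the
   fragment to the rRNA category.  This mimics a two-pass mapping strategy
   (reads aligned against the ribosomal operons before the genome) without
   re-running an aligner.
2. **Largest overlap, half-fragment minimum.**  Among remaining annotated
   features the largest overlap wins, provided it covers ≥50% of the
   fragment; ties go to the leftmost feature start.  Below the threshold the
   fragment is intergenic.  The behaviour is deliberately htseq-comparable
   and deterministic; no multi-mapping redistribution is attempted
   (single-isoform prokaryotic assumption).

Counting is unstranded by default because library strandedness is often
unknown for archival data; `stranded=True` restricts candidates to
strand-matching features (fragments of unknown strand always match).

**UTRs.**  From each boundary of an expressed CDS, coverage is extended
outward while per-base depth stays above `max(5, 0.1 × the gene's mean
coverage)`, stopping at the nearest annotated feature or 500 nt.  Both the
floor of 5 and the 10% fraction are heuristic: there is no community
standard for plateau-based UTR attribution, and the defaults are chosen so
a plateau an order of magnitude weaker than its gene still counts while
isolated noise does not.  Intergenic fragments overlapping a UTR call by
≥50% are re-categorised as UTR reads.  Coverage islands detached from any
CDS are left to the island caller.

## TPM and tiers

`tpm_i = 1e6·(c_i/L_i)/Σ_j(c_j/L_j)` with the denominator over CDS only by
default (`all_features` is available for sensitivity analysis); means and
medians are reported over CDS.  Σ TPM = 1e6 to 1e-6 relative whenever any
count is nonzero; all-zero inputs yield all-zero TPM with a warning rather
than a division error.  Tier boundaries are inclusive (`tpm ≥ k·mean`), a
gene exactly at the mean is `avg`, `silent` (zero count) takes precedence
over everything, then `sub_tpm` (<1 TPM).

## Condition comparison

One library per condition means no replication, so the screen is
descriptive: `delta = log10((tpm_b+0.1)/(tpm_a+0.1))`, standardised over the
table (population SD, so z has unit variance by construction), flagged at
|z| > 2.5, plus a secondary |log2 FC| > 1 flag.  The pseudocount of 0.1 TPM
keeps silent genes finite and is configurable.  This is not a calibrated
differential-expression test and the package does not correct it for
multiple testing — there is no p-value to correct.  z is invariant to the
logarithm base (the scale cancels in standardisation), and swapping the
conditions negates delta and z without changing the flags.

Under an exchangeable null (both conditions drawn from one negative-binomial
model), the standardized log-ratio is close to Gaussian and the |z| > 2.5
fraction sits at 2·Φ(−2.5) ≈ 1.24%.  The calibration benchmark runs at a
mean of 1000 fragments per gene — the depth regime of a deeply sequenced
transcriptome.  At desk-scale depth (mean ~80) the log count ratio carries
visible excess kurtosis from the Gamma mixing (empirically ~1.33% beyond
2.5 SD) and the Gaussian reference is no longer the right yardstick; this
is a property of shallow counts, not of the screen.

With genuinely heterogeneous per-gene variances (expression means spanning
orders of magnitude at finite depth), the pooled z is a scale mixture and
its 2.5-SD tail exceeds the Gaussian value — the pipeline reports ~3% flags
between two identically distributed realistic conditions.  Users should
read the flag fraction against this baseline, not against 1.24%.

## Codon adaptation index

Sharp & Li (1987) semantics: relative adaptiveness `w_c = n_c / max_family
n`, pseudo-count 0.5 for codons unobserved in the reference so no `w` is
zero, per-gene CAI as `exp(mean log w)` over sense codons (stop and
N-containing codons excluded from both table and scoring, with exclusion
counts reported).  The log-domain mean is exact for genes of any length —
a naive running product underflows near 10³–10⁴ codons, which is why the
test suite pins agreement with a brute-force log-domain recomputation to
1e-12.  The reference set is the 40 longest ribosomal-protein CDS when more
are annotated; length is a deliberate tie-break (longer genes contribute
more codons and more stable frequencies).  The translation table is the
bacterial/archaeal code (NCBI table 11).

## Genome landscape

**GC track.**  Windows of 5000 nt at 1000-nt steps (both configurable); N
bases excluded from numerator and denominator; z against the mean and SD of
all window values.  Only the 2.5×SD criterion is inherent to the analysis;
the window geometry is a default.

**Region calls from window tracks.**  A window statistic is an estimate
centred at the window midpoint.  Merging *full extents* of flagged
overlapping windows pads every region boundary by up to a window width,
which for regions only a few windows long destroys boundary accuracy.
Merged calls therefore span the **centers** of the flagged windows (a lone
flagged window spans ±step/2 around its center).  For a median-based gene
window the same logic is exact: a 100-gene window's median flips when just
over half its genes are low, so the center-gene span of the flagged run
recovers the block boundary to ~1 gene.  This refinement is what lets
planted regions be recovered at Jaccard ≳ 0.9 rather than ~0.6–0.7.

**Low-expression regions.**  Per 100-gene window median TPM; windows
strictly below the 10th percentile of all window medians are flagged and
runs of flagged windows (within one window of each other in gene space) are
merged.  Strict inequality means a perfectly flat profile yields no calls.
The quantile form implies ~10% of windows are flagged somewhere even in a
homogeneous genome; the analysis is meaningful when low windows cluster, as
they do when silent gene blocks exist.  The genome halves/quarters analysis
assigns genes by start coordinate to equal *nucleotide* intervals (the
alternative — equal gene-count intervals — is not implemented); share =
percent of summed TPM, with optional min/max-TPM filters and top-k removal
for the "is it just the few hottest genes" follow-up.

**Hypothetical density.**  Percent hypothetical proteins in a sliding
window of 100 consecutive CDS (one-gene step); "window of 100" is read as
100 genes, not 100 kb, because the quantity is a percentage of proteins.
Hypothetical status comes from a case-insensitive "hypothetical" substring
in the product, overridable by an explicit `hypothetical=` GFF attribute.

**arCOG summaries.**  Per single-letter category: n, median and quartiles
of log10(TPM + 0.1).  The 0.1-TPM pseudocount is used for every log
transform in the package.  A `top_n` mode restricts to the n
highest-expressed genes and drops categories with fewer than 3 members.

## Transcription units and transcribed islands

**Units.**  Candidate units are maximal runs of same-strand consecutive CDS
with intergenic gap ≤ 30 nt, boundary inclusive; overlapping genes are gaps
≤ 0.  The 30-nt default reflects observed within-operon spacing (overlaps
of a few nt up to ~24-nt gaps) against between-unit spacing of hundreds of
nt.  With coverage, a unit is grown greedily and split before any gene
whose addition pushes the sample CV (ddof = 1) of member mean coverages
above 1.0 — the sample CV is the right scale here because a 10:1 coverage
pair gives CV ≈ 1.16 (split) while NB-level noise among true co-transcribed
genes stays far below 1.  Singletons are monocistronic units; the units
partition the CDS set by construction.

**Islands.**  Threshold = 5 × median mean-depth of expressed CDS; maximal
above-threshold runs entirely outside annotation and UTR calls, kept at
30–500 nt (the size range of small non-coding RNAs); score = mean depth.  A
run that directly abuts covered annotated/UTR sequence (neighbouring base
excluded *and* above threshold) is a clipped continuation of that signal —
e.g. the far tail of a very hot gene's UTR — and is discarded rather than
reported as a detached island.  The depth factor is a formalisation choice;
nothing in the size range depends on it.

## The synthetic-data generator

The generator is the package's study-condition model, not a test prop.  Its
defaults describe a deeply sequenced halophilic-archaeon-like experiment:

| parameter | default | rationale |
|---|---|---|
| genome_len / n_genes | 2.4 Mb / 2000 | desk-scale version of a ~3 Mb, ~2600-CDS chromosome |
| gc_background | 0.479 | the unusually AT-rich haloarchaeal chromosome |
| rrna_read_frac | 0.79 | share of fragments on the two rRNA operon clusters |
| utr_read_ratio | 5.0 | UTR reads ≈ 5× CDS reads, matching ~15% vs ~3% read shares |
| nb_mean / nb_dispersion | 80 / 50 | desk-scale depth; variance = μ + μ²/50, the near-technical-replicate regime consistent with two libraries from one culture and no differential expression |
| expression_sigma | 1.3 | log-normal spread of per-operon means; reproduces the ~2.4 mean/median TPM ratio of a bulk prokaryotic transcriptome |
| low blocks | 2 × 100 genes at 0.02× | two silent chromosomal regions (~5% of genes each) |
| gc islands | 30 kb at +5 GC points, centred on the low blocks | genomic-island-like composition anomaly co-locating with low expression |
| hypothetical fraction | 0.30 background, 0.80 in low blocks | hypothetical-gene enrichment of the low regions |
| islands | 12 intergenic, 30–500 nt, ~30× median CDS depth | planted small-RNA candidates |
| fragment_len | 200 nt | paired-end insert scale; uniform length |

Structure worth knowing when interpreting tests:

* Per-operon expression means are shared exactly by member genes (operonic
  coherence), so unit inference under coverage can be scored against the
  planted operon map.  Operons are truncated at low-block boundaries.
* CDS fragments are placed strictly inside their gene; UTR fragments are
  drawn separately (mean = `utr_read_ratio/2 × λ` per eligible side), only
  at transcription-unit boundaries (a polycistronic message has one 5'
  UTR), within margins capped so they never touch neighbouring features and
  always overlap their own gene by less than half a fragment.  Consequence:
  assigned CDS counts reproduce the drawn NB counts exactly, and the UTR
  read category is populated the way the read-accounting table expects.
* Reference (ribosomal) genes are rewritten with a planted codon preference
  whose preferred codons are chosen GC-neutral and whose amino-acid weights
  are exponentially tilted to the background GC — the codon signal must not
  double as a GC anomaly on the genome track.  Reference genes are only
  drawn from genes that do not overlap their neighbours, so the rewrite
  never corrupts an adjacent reading frame.
* Intergenic islands are emitted as full-length fragments at exactly the
  planted coordinates, ≥600 nt from any feature, giving sharp-edged,
  detached coverage islands.
* `null_pair` draws two count vectors from one shared NB model (flat means
  across genes): an exchangeable calibration null for the z-screen.  A
  heterogeneous-mean null is *not* used for calibration because its z is a
  variance mixture with a provably inflated 2.5-SD tail (see above).
* Everything derives from one `numpy` Generator seeded from the config;
  identical configs give byte-identical output files.

**What passing tests do and do not show.**  The generator plants exactly
the structure the callers look for, with sharp boundaries, no mapping
error, no sequencing-error model, no coverage bias (GC, position or
fragment-length), uniform fragment length, and an annotation that is
complete and correct.  Recovery scores (Jaccard ≥ 0.9, island
sensitivity/precision ≈ 1) therefore establish correctness of the
algorithms under their own assumptions — not expected performance on real
libraries, where boundary blur, mis-annotation and coverage bias will
degrade all of these.  The read-category percentages likewise confirm
bookkeeping, not biology.

## Scale of the shipped experiments

The default configuration (2.4 Mb, 2000 genes, ~5.5 M fragments per
condition counting rRNA) runs the full pipeline in well under a minute;
benchmarks use 20 seeded replicates for region recovery and 50 seeded
pairs × 2000 genes for null calibration, and the test fixtures use a 400-kb,
300-gene version of the same configuration.  These sizes are the package's
chosen desk-scale study conditions; all thresholds and tolerances are
independent of them.

## Known limitations

* No aligner: alignments (or fragment placements) are inputs.
* No replicate-based dispersion model; the comparison is a screen.
* Linear chromosome only; origin-spanning features are rejected.
* Island classification (CRISPR RNA vs snoRNA vs tRNA families) is out of
  scope; islands can be annotated against a user-supplied ncRNA BED but are
  otherwise reported by coordinates and depth only.
* The exact identity of a study's CAI reference set is rarely published;
  CAI values are comparable within a run, not bit-for-bit across tools.
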