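# Methods

## Study design being emulated

The pipeline targets a two-genotype × two-condition × three-replicate
small-RNA experiment on mature pollen: a heat-tolerant restorer line (NH)
and its heat-sensitive near-isogenic counterpart with sterile cytoplasm
(SH), each sampled under mild (AP) and extreme (JP) continuous
high-temperature field stress. Samples are named `AP_NH_r1` … `JP_SH_r3`.
Degradome libraries are pooled per genotype (`P_NH`, `P_SH`); hormone
measurements (IAA, JA, MeJA) have six replicates per genotype.

## Synthetic study generator

The generator (`synthetic_data`) produces the full set of inputs the
analysis consumes, with recorded ground truth. All randomness derives from
`SyntheticConfig.seed` through per-stage child streams, so a seed
reproduces byte-identical files.

**Genome and precursors.** Each precursor is built as
`mature + loop + reverse-complement(mature)`, which folds into a hairpin
with a fully paired stem; loop length is at least `52 − 2·mature_length`
so the hairpin clears the 50-nt minimum. Mature lengths follow a
distribution peaked at 24 nt (weight 0.40, with 21 nt second at 0.20), and
first bases follow per-length biases (U-start for 19–22 nt, C-start for
23–24 nt, G-start at the 18/25-nt extremes), mirroring the base-bias
profile of pollen libraries. A `cluster_fraction` share of precursors is
laid out in runs of 2–4 with intra-run gaps below 50 kb; all other
spacings exceed 50 kb, so the planted cluster structure is exactly what
the cluster caller should report. Placement that cannot fit the
chromosomes raises a configuration error rather than silently truncating.

**Reads and counts.** Per sample, miRNA counts are drawn from a negative
binomial with Var = μ + φμ² (φ = `dispersion`, default 0.05), the standard
overdispersion model for replicate sRNA counts; the generative model is a
package choice since none is prescribed by the protocol being emulated.
Baseline abundances are log-normal (σ = 1) scaled so mature reads make up
`1 − background_fraction` of the library. Planted fold changes multiply
one contrast group's mean by 2^lfc; by default eight of 24 miRNAs (a
third, matching the differential fraction reported in pollen heat-stress
libraries) carry ±2 log2 effects split between the AP and JP genotype
contrasts. Planted miRNAs are floored at the baseline-abundance median:
reported differential miRNAs in this setting are moderately-to-highly
expressed, and a recovery target of ≥90 % is meaningful only in that
regime. Background reads are random genome windows with the configured
length/first-base distributions; windows identical to a mature arm are
discarded so `background_fraction = 1` yields libraries with no exact
mature matches. The default library depth of 50 000 reads keeps the
package desk-scale while putting expressed-miRNA counts in the hundreds
to thousands, the regime where biological overdispersion (not Poisson
sampling noise) dominates, as in real libraries.

**Transcripts and degradome.** Planted target transcripts embed the exact
reverse complement of the miRNA at a recorded position; the expected
cleavage position is the transcript base paired with miRNA nucleotide 10,
`site_start + len(miRNA) − 10`. Each degradome library places
`slice_signal_fraction` of a planted transcript's tags exactly at that
position (20-nt tags) and the rest uniformly; half the library is
allocated to planted transcripts so the signal is depth-robust.

**What the generator does not model:** sequencing errors, adapter
chimeras, quality-score realism, multi-locus miRNA families,
strand-specific expression, isomiR spectra beyond exact mature reads, and
transcriptome count libraries (gene-level differential expression on real
data comes from an external RNA-seq analysis; tests synthesize DEG tables
directly). Passing tests therefore demonstrate correctness of the
analysis logic under the stated statistical assumptions, not robustness
to real-data artifacts.

## Read cleaning and annotation

The 3′ adapter is removed at its leftmost exact occurrence at or after
position 18, so the insert never drops below the minimum length; reads are
kept if 18–25 nt after trimming, with N-fraction ≤ 10 % and no single base
at ≥ 80 %. For FASTQ input a mean phred < 20 drops the read; these
thresholds are declared package conventions (the upstream tools leave
"poor quality" unspecified). Annotation classing is exact-substring
against the provided sets with a fixed priority (rRNA > tRNA > snRNA >
snoRNA > other Rfam > repeat > mRNA); exact matching keeps the step
reproducible and is sufficient for synthetic data, where matches are
planted, not approximate.

## Hairpin screening definitions

The eleven structural criteria operate on a dot-bracket structure plus
MFE. Terms the field's vendor pipelines use but do not define are pinned
down as follows and unit-tested: the *terminal loop* is the largest
unpaired run enclosed by an innermost pair; the *stem* is the span between
the outermost paired positions minus that loop; a *bulge* is any other
maximal unpaired run, measured by its full length even when it straddles
the mature-region boundary (the terminal loop is a loop, not a bulge); a
bulge is *biased* when its two flanking pairs are adjacent on the partner
strand (all unpaired bases on one side); an *error* in the mature region
is an unpaired mature position. With these definitions each criterion can
be violated independently, and the test suite carries an 11-structure
matrix in which each structure fails exactly one criterion.

Folding is pluggable: any caller may supply precomputed structures, and
`fold_sequence` delegates to the ViennaRNA bindings when importable.
Tests use constructed structures for determinism, with one cross-check
that a constructed precursor also passes when folded thermodynamically.

## Known-miRNA variant grammar

A read matches a database mature if it equals the reference after at most
3 nt of trimming/extension at either end plus at most one internal
substitution (substitutions only; indels inside the read are not
considered variants). The emitted descriptor concatenates `L±n`, `R±n`,
then `<k>ss<pos><ref><obs>` with positions 1-based in the observed read,
reproducing printed names such as `_R + 1` and `_R + 1_1ss18TG`.
Descriptors record gained end bases, so applying a descriptor to its
reference reconstructs the read exactly. Ties across references resolve
to the lexicographically smallest name, with a logged warning.

## Cluster calling

Per chromosome, loci sorted by start are chained while the gap from the
running chain end to the next start is ≤ 50 kb; maximal chains with ≥ 2
distinct precursors become clusters (a single precursor's 5p/3p pair is
not a cluster). Chaining is pairwise, so a cluster's span may exceed
50 kb. The end-to-start gap convention and strand-blindness are declared
choices; an independent neighbour-chaining oracle in the tests confirms
the caller on random locus sets.

## Differential expression

TPM follows `count / total clean tags × 10⁶`. When the count matrix
covers only a feature subset (miRNAs out of a whole library), the
per-sample library totals should be passed explicitly: this matches the
formula's denominator and decouples features — normalizing by the
subset's own column sums transmits strong true effects into spurious
shifts of every null feature. Without explicit totals the column sums are
used and each normalized column sums to exactly 10⁶.

Fold changes are log2 ratios of replicate means on the normalized scale,
with +∞/−∞ sentinels when one mean is zero and an undefined (excluded)
value when both are. Testing uses a pooled two-sample t-test on
log2(x + 1)-transformed normalized values, with Benjamini–Hochberg
correction per contrast and a corrected-P 0.05 call threshold. Two
numerical choices matter at n = 3 and are deliberate: (i) the log
transform stabilizes the variance of overdispersed counts, and (ii) the
pooled (Student) test is preferred over Welch for balanced designs with
similar group variances — Welch's Satterthwaite correction can halve the
already-tiny degrees of freedom on chance variance imbalances, costing
substantial power while buying nothing here; Welch remains available via
`equal_var=False`, and raw-scale testing via `log_values=False`. Under
the generator's study conditions (|log2FC| = 2, n = 3, dispersion 0.05)
this recovers ≥ 90 % of planted effects with the false-discovery
proportion controlled at the nominal level; under the global null, BH at
q = 0.05 yields rejections in ≲ 5 % of simulated studies.

Zero variance in both groups with equal means returns P = 1 by
convention. Venn percentages are reported to two decimals with half-up
rounding, matching the convention of published tables. Hormone-style
measurement comparisons use the classical two-tailed unpaired Student
t-test at P < 0.05.

## Degradome analysis

Tags ≥ 15 nt map to transcripts by exact match only; multi-mapping tags
contribute their full count at every placement (the simplest reproducible
convention; placements are enumerated in the output). miRNA–target
alignment scores antisense duplexes with mismatch 1, G:U wobble 0.5, at
most one single-nucleotide gap (penalty 1) on either strand, and all
penalties doubled opposite miRNA positions 2–13; sites above a total of 4
are discarded. The scheme beyond the ≤ 4 ceiling follows the Allen-style
convention of the established degradome pipelines and is configurable.
For a gap adjacent to the core boundary the doubling applies when the
bulge sits between miRNA positions 2 and 13. The cleavage site is the
transcript position paired with miRNA nucleotide 10 or 11 — whichever
carries more degradome signal, ties to 10 — and events with no signal at
either are dropped. Categories follow the CleaveLand-style convention:
4 = exactly one read; 0 = unique profile maximum; 1 = tied maximum;
2 = above the median of nonzero positions; 3 = otherwise; the median is
computed over nonzero positions only. A vectorized scanner produces the
alignments; tests hold it equal to an explicit enumeration of every
duplex configuration on transcripts up to 2 kb.

## Network integration

A regulatory pair requires all three evidence layers in one contrast: a
differential miRNA, a differential target gene (direction taken at the
gene level, since published pair tables mix transcript ids and gene
symbols), and a degradome cleavage event linking them;
`require_cleavage=False` relaxes to predicted-only for exploration.
Patterns are the four sign combinations; the negative subset (up–down,
down–up) drives the network export, where miRNA→transcript edges carry an
inhibitory flag and genes without pathway annotation simply lack a
pathway edge. The curated 35-pair cotton table ships with the package as
a reference input; its published condition split (mild vs extreme) is not
reproduced because the table does not label pairs by condition.

## Enrichment

Classical one-sided hypergeometric upper-tail over-representation with BH
correction, background configurable (default: all annotated genes).
Terms with zero background hits are skipped. This is a plain
over-representation test: read-length bias weighting (GOseq-style) and
ontology ancestor propagation are out of scope.

## Problem sizes

Defaults are chosen for desk-scale runs: 4 × 400-kb chromosomes, 24
precursors, 12 libraries of 50 000 reads, 30 transcripts, 5 000 degradome
tags per pooled library. The recovery suites run 20 independently seeded
studies each for differential-expression recall, null calibration, and
degradome slice recovery; the full test suite and the acceptance script
each complete in about a minute on one CPU.

## Known limitations

- Exact-match mapping everywhere (reads, tags, annotation): adequate for
  planted data, not for real mismatch-laden libraries.
- The t-test on three replicates has limited power for sub-two-fold
  effects; no variance moderation across features is applied.
- The hairpin-criteria definitions, while internally consistent and
  tested, are one defensible reading of vendor-pipeline terminology.
- Degradome P-values for peak significance are not computed; evidence is
  ranked by category only.
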