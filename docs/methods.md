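# Methods

## The experimental design being modelled

A nuclear PIP-seq experiment produces, per condition and biological
replicate, four sequencing libraries: two *footprint* libraries (RNA digested
by a double- or single-strand-specific nuclease while proteins are still
bound, so protein-occupied regions are protected) and two *structure-only*
libraries (proteinase K first, then the same nucleases, so coverage reflects
intrinsic base pairing). With two conditions (control and salt stress) and
two replicates this is the 16-track design the package operates on. Two
companion assays enter the integrative layer as count tables: mRNA-seq and
GMUCT (a degradome protocol capturing uncapped, degradation-intermediate 5′
ends), plus label-free proteomics (iBAQ intensities) and antibody-derived
m⁶A peak intervals.

## Protein-protected site calling

Coverage is compared per nucleotide between a footprint library and its
matched structure-only library after depth equalization (the larger read set
is randomly downsampled without replacement to the size of the smaller,
seeded). The enrichment score at position *i* is
`−log10 P(Poisson(s_i + c) ≥ f_i)` with pseudocount `c = 1`; a pseudocount is
required because the Poisson rate would otherwise be zero wherever the
structure-only library has no reads, and 1 read is the smallest
non-degenerate choice. Scores are computed per nucleotide with no smoothing
window (a window width is exposed as a knob but defaults to 1 nt).

The null distribution comes from swapping the footprint and structure-only
labels of the same pair — the only permutation available in a two-sample
design — and the calling threshold is the smallest score *t* (inclusive,
`≥ t`) at which `#{null ≥ t} / #{observed ≥ t} ≤ q`, with `q = 0.05` by
default. If no threshold qualifies (e.g. observed and null are exchangeable)
the caller returns an empty set rather than guessing. Runs of
above-threshold positions become intervals; intervals sharing at least one
nucleotide are merged (book-ended intervals stay separate), and each interval
keeps the maximum score of its positions as its summary — region-level score
aggregation is otherwise unspecified in this design, and the maximum is the
summary that determines whether any part of the run survives a stricter
threshold.

Replicate intersection and condition classification both use the ≥ 1-nt
overlap rule and are *anchored*: `high_confidence(rep1, rep2)` returns rep1's
geometry, and `classify_condition` reports shared sites in the control
anchor's geometry. Anchoring matters because overlap counts are asymmetric
when one interval spans two of the other set's; the convention is documented
and the partition invariant (`specific + shared = anchor total`) is tested.

## Structure scores

The dsRNA-seq library (ssRNase-treated) and ssRNA-seq library
(dsRNase-treated) are first rescaled by total covered length: with
`L_ds`, `L_ss` the genome-wide counts of positions holding ≥ 1 read,
`ds_i = n_ds,i · max(L_ds, L_ss)/L_ds` and symmetrically for `ss`. The score
is `S_i = glog(ds_i) − glog(ss_i)` with `glog(x) = log2(x + √(1+x²))`, a
log-like transform defined at zero; `S_i` is antisymmetric under swapping the
two libraries when covered lengths are equal, strictly increasing in dsRNA
coverage, and approaches `log2(2x)` for large `x`. Positions with zero
coverage in both libraries are *undefined* (NaN) and excluded from every
downstream mean — treating them as 0 would pull transcript means toward zero
in a depth-dependent way.

"Standardization to normalize by read coverage" is under-specified in the
methods tradition this follows; it is implemented as per-transcript
population z-scoring (scope configurable to `global`). Because structure
scores are already log-scale, the salt-vs-control fold change of a region is
the difference of region means (log of a ratio = difference of logs), with
sign classes greater-in-salt / lower-in-salt and a third class `unchanged`
for an exact 0, which is excluded from two-class comparisons. Profile
normalization by the transcript mean is likewise implemented as subtraction
(division is available by flag). Constraint strings use strict thresholds:
score > 2.0 → `|` (force paired), score < −0.5 → `x` (force unpaired),
boundary values and undefined positions → `.`.

## Profiles

Metagene rows live in spliced transcript space (introns removed,
minus-strand transcripts reversed); windows that extend past a transcript
end contribute NaN, never genomic intronic or intergenic signal. Start and
stop anchors are the first nucleotide of the start and stop codon
respectively (the stop codon being the last 3 nt of the CDS). Expression
filters for mRNA metagenes are ≥ 50 reads in *every* library plus a ≥ 45 nt
5′UTR and ≥ 140 nt 3′UTR; lncRNA-like transcripts (the merged
lncRNA/antisense_lncRNA/antisense_RNA/ncRNA group) need ≥ 5 reads. Binning
uses the floor partition `[⌊bL/n⌋, ⌊(b+1)L/n⌋)`, deterministic and equal up
to ±1 nt, with regions shorter than the bin count repeating single
positions; a bin with no defined position stays undefined. Occupancy
profiles (PPS and m⁶A density share one code path) are scaled so the maximum
of the mean profile within each declared window is 1.0; per-window rather
than joint normalization was chosen where the two readings are possible, with
the window argument allowing joint scaling. SEM uses the number of defined
rows per column (population SD). Shuffled peak controls keep count, length
and chromosome, land wholly within gene intervals, and never overlap each
other; placement is rejection sampling, uniform over feasible positions,
seeded, with a hard failure naming the chromosome when space runs out.

## Integrative statistics

RPM = counts · 10⁶ / library total, with a half-read pseudocount before logs
so zero-count transcripts stay finite. Proportion uncapped is
`PU = log2(RPM_GMUCT / RPM_mRNA)`; its salt-vs-control fold change is
implemented as `PU_salt − PU_control` rather than a literal log of the
(already-log) ratio, which is ill-defined for negative PU — the difference
preserves the intended sign convention (ΔPU > 0 ⇒ destabilized in salt).
Protein intensities are normalized per run (run total by default, median
optional) and proteins must be detected in ≥ 2 replicates of *each*
condition; the fold change is `log2(mean_salt / mean_control)` of normalized
intensities. "Wilcoxon" comparisons of transcript sets are unpaired
Mann-Whitney rank-sum tests with tie-corrected normal approximation (a
paired signed-rank mode exists for aligned per-position rows); Spearman
p-values use the asymptotic t approximation; no multiple-testing correction
is applied by default (raw p-values are reported; Benjamini–Hochberg is
available but off). m⁶A transcript dynamics distinguish transcripts that
lose all peaks in salt, gain them only in salt, keep overlapping peaks
(`both-same`) or are modified in both conditions at disjoint locations
(`both-shifted`).

## Synthetic data generator

The generator emulates the study conditions at desk scale: 200 transcripts
of 800–1,200 nt on two chromosomes, 0–2 introns, 10% lncRNA-like, mean
exonic depth 30, planted protein footprints (1 per kb, 20–50 nt, 4×
enrichment in footprint libraries, 0.6 probability of appearing in both
replicates of a condition), planted double/single-stranded regions (1 per
kb, 30–80 nt, 4× ds/ss coverage contrast), condition-specific m⁶A peaks
(0.6 / 1.0 per transcript for control / salt, reflecting net m⁶A gain under
stress), stability shifts and protein effects drawn N(0, 0.5²) on the log2
scale. Coverage noise is Poisson; count tables are negative binomial
(dispersion 0.1, 2 replicates); proteins get 3 runs per condition with
log-normal noise (σ = 0.3 in log2) and 10% per-run dropout. Where the
original study fixes no value (noise model, intron/intergenic geometry,
UTR ranges, peak lengths, m⁶A rates) the defaults are one-time choices of
values typical for an Arabidopsis nuclear RNA-seq experiment and are not
revisited. 80% of mRNAs are drawn to satisfy the metagene UTR filters so
both filter branches are exercised.

What the generator deliberately does **not** model: read-level sequences and
quality scores, aligner artifacts and multimapping, splice-isoform
diversity, positional coverage biases, batch effects, or any biological
coupling between m⁶A location and structure. Passing tests therefore
demonstrate the correctness and calibration of the *statistical machinery*
under the stated noise model, not robustness to real-library artifacts.
Planted footprints, structure regions and m⁶A peaks are each placed within a
single exon (so every planted interval is one contiguous genomic interval),
and m⁶A peaks are uniform over exonic space rather than 3′UTR-biased — no
downstream computation depends on within-transcript peak location.

One generator hook exists purely for testability: `simulate_counts_and_proteins`
accepts an explicit per-protein effect map overriding the random draws, so
the stratified-recovery test can plant protein effects exactly in the
transcripts carrying salt-specific m⁶A and planted stabilization. That test
defines its strata from the planted ground truth (not the estimated
stability classes) so that it isolates protein-level recovery; estimated
stability classes of transcripts with small planted shifts flip sign with
sampling noise, which is expected behaviour of the metric, not a defect of
the strata machinery.

## Numerical and interface choices

Internal coordinates are 0-based half-open everywhere (BED-native); GFF3 is
shifted on ingest/emission. Analyses assume one transcript model per locus —
the synthetic genome tiles transcripts without same-strand overlap; with a
real multi-isoform annotation the caller should pre-select one
representative model per gene (e.g. longest spliced form). Poisson tail
probabilities use `logsf` to avoid underflow at extreme enrichment.
Z-scores use the population convention (ddof = 0); zero-spread windows map
to zeros. Flanks falling off a chromosome edge drop the interval with a log
record (conservation comparison, peak-centered profiles). Determinism:
every stochastic routine takes an explicit seed, and the generator derives
independent named streams from `SimulationConfig.seed`, so identical
configurations give bit-identical outputs.

## Problem sizes

The test suite and acceptance script use 20 seeds × 200 transcripts
(~250 kb of genome, 16 libraries per seed) for the calibration and recovery
properties, which the package processes in seconds per seed; these sizes
give Monte-Carlo error comfortably inside the stated tolerances (e.g. the
FDR check allows 2 percentage points above the 5% target).

## Known limitations

- The permutation FDR is estimated position-wise, matching the calling
  granularity, so the quoted rate is per called nucleotide, not per
  interval.
- The empirical FDR definition counts nucleotides of calls that extend past
  a planted footprint's edge as false discoveries, which is conservative.
- `feature_enrichment` uses the greedy multi-label convention, so observed
  fractions can double-count nucleotides under overlapping labels, exactly
  as the annotation distribution does.
- The replicate-overlap percentages reported alongside the original
  replicate-level counts have ambiguous denominators and are not
  reproduced.
- DESeq2-style shrinkage, GO enrichment, thermodynamic folding and spectral
  proteomics processing are out of scope; the pipeline starts from coverage
  tracks, peak intervals, count tables and iBAQ tables.
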