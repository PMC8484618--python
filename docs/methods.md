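# Methods

chromalink implements an integrative epigeno-proteomics analysis for
patient-matched, multi-state cancer cohorts profiled at three layers:
chromatin accessibility (ATAC-seq peaks and gene-body signal), RNA
abundance, and protein abundance (isobaric-label proteomics with a
reference channel).  This note records the models, the numerical choices,
what the synthetic cohort does and does not emulate, and the known
limitations.

## Coordinate conventions and genomic geometry

All coordinates are 0-based, half-open (BED).  Peaks are built from
insertion-density summits extended by 100 bp on either side (200 bp final
width, clamped at chromosome edges) and union-merged into a disjoint peak
set; each merged peak keeps its member summits and is represented by the
median member summit.

Promoter windows are strand-aware: −1000/+100 around the first TSS *in
transcription orientation* (on the minus strand the upstream kilobase lies
genomically right of the TSS).  A peak is a promoter element if its
interval overlaps any gene's promoter window (the more inclusive reading;
a summit-only mode is available via `classify_peaks(mode="summit")`).
Everything else is a non-promoter (NP) element — the putative enhancers
this analysis centres on.  Distance to a gene body is the unsigned gap
between nearest interval edges with a containment flag; exon/intron
assignment uses the peak summit so that every summit inside a gene body
gets exactly one label (a peak can straddle a junction, the summit
cannot).  Contact-domain membership requires full containment, not mere
overlap.

## Normalization chains

* **ATAC peaks** — log2 counts-per-million with a library-scaled
  pseudo-count of 5 (`log2((c + p_j) / (L_j + 2 p_j) * 1e6)` with
  `p_j = 5 L_j / mean(L)`), quantile normalization across all replicate
  columns, then log-scale averaging of technical replicates.
* **RNA** — the same log-CPM transform.  A variance-stabilizing regression
  transform is *not* re-implemented: the downstream correlation and linear
  model statistics need only an approximately linear log-scale value, and
  log-CPM with a prior of 5 behaves nearly identically away from very low
  counts.
* **Protein** — per run: missing peptide intensities are set to the run
  minimum (the smallest observed intensity over all peptides and channels
  in the run — the most literal reading of a per-run minimum); every
  channel is rescaled so its total matches the reference-channel total;
  gene abundance is the ratio of summed sample-channel peptides to summed
  reference-channel peptides (weighting intense, more reliable peptides);
  ratios are log2-transformed and technical replicates averaged *after*
  the log.  A gene undetected in a run is missing (NaN) for that run's
  samples, never zero.
* **Gene accessibility** — RPKM over the gene body (reads / gene length in
  kb / library in millions) followed by cohort-wide quantile
  normalization.  The denominator uses the full gene-body length; a
  promoter-subtracted variant is a caller option.  Library size is total
  insertions (column sums) unless supplied.

Quantile-normalization ties receive the mean of the tied reference
quantiles — deterministic and order-independent, at the cost of the exact
shared-multiset property for tied values.

## Differential testing

Each layer is tested per feature with a Welch two-sample t-test on
normalized log-scale values for every pairwise state comparison, with BH
correction within each layer × comparison.  FDR thresholds: 0.01 for peak
accessibility (union peak sets are noisy, so the chromatin layer is held
to a stricter FDR), 0.1 for RNA, protein and gene accessibility.  A gene
is "differentially expressed" if significant at RNA or protein in any
pairwise comparison.  Moderated/empirical-Bayes variance models are
deliberately out of scope; every downstream consumer depends only on
(logFC, q, flag), so the substitution is contained.  Tests are unpaired
(patient matching enters the simulator and the sample-split protocol, not
the test); a paired mode would be a natural extension.

## Peak–gene linkage

For each gene and state, Pearson correlations are computed between the
gene's transformed RNA and the accessibility of every *cis* peak (within
250 kb of the first TSS on each side, 500 kb total).  Significance comes
from a per-gene, per-state **trans-peak Gaussian null**: 10,000 peaks
drawn from other chromosomes (with replacement when fewer are eligible —
inevitable on toy genomes), correlated with the gene's RNA, and fitted
with a Gaussian (mean, n−1 standard deviation).  Because the null is
rebuilt per gene, gene-specific pathologies (heavy-tailed expression,
outlier samples) widen that gene's null instead of producing spurious
links.  The p-value is the one-sided upper tail `1 − Φ((r − μ)/σ)` —
activating regulation is the hypothesis of interest; a two-sided option
exists.  BH runs within state across all tested gene–peak pairs at FDR
0.05, and the union of per-state significant links (with per-state
provenance) is the link set.  Constant peak or RNA vectors are skipped;
a zero-sigma null is a signalled error.

## Integration statistics

* **Sample-wise correlations**: per linked element–gene pair, Pearson
  r(element accessibility, RNA) and Spearman r(protein, RNA) across
  shared samples (≥6 required; protein NaNs dropped pairwise).  A pair is
  *high paired* when both exceed 0.5 (strict), and the fraction of
  high-paired pairs is compared between differential and not-differential
  categories, stratified by promoter class.
* **Gene-wise correlation**: Spearman of RNA vs protein log fold changes
  over differential records, plus the sign-concordance fraction (zero
  logFC counts as non-concordant).
* **Differential NP activity score**: per gene and comparison, the sum of
  log2 fold changes of its differential non-promoter peaks (0 with
  `n_peaks=0` when there are none).
* **Exon/intron enrichment**: exact upper-tail binomial test of the
  exonic NP count against the expected exonic rate.  The expected rate
  defaults to the mean exonic length fraction computed from the analyzed
  annotation (a pooled-length variant is equally easy to feed in; both
  conventions are exposed because the choice materially changes the
  p-value and the field is not consistent about it).

## Protein predictive significance

Gene–element pairs are categorized by differential status — (a) neither,
(b) gene expression only, (c) element only, (d) both — and each pair is
fitted with the interaction model

    protein = β0 + β1·RNA + β2·(RNA × accessibility)

with **no accessibility main effect**, exactly as the statistic is
defined.  The added term is judged by the partial F against the RNA-only
reduced model, `F = (RSS_red − RSS_full)/(RSS_full/(n−3))` with an
F(1, n−3) tail; for a single added term this F equals the squared t of
the interaction coefficient (asserted to 10 significant digits in the
tests).  After BH at FDR 0.05 within the union of the compared
categories, the counts of significant pairs are compared between two
categories (default d vs a) with a two-sided Fisher exact test — that p
is the *protein predictive significance*.

Selection bias is controlled by a split protocol: patients (not samples —
patient-matched tissues are not exchangeable) are randomly halved; one
half supplies the differential categorization, the other the F-tests.
The *modified* no-split variant for small cohorts uses a two-class
partition ("differentially active" = differential at RNA and protein and
linked to differential gene-body footprints) on the full cohort.
Degenerate fits are flagged rather than silently dropped: constant
accessibility (collinear interaction) and numerically perfect fits carry
status flags; empty categories make the enrichment `undefined`.

## Footprints and networks

A *differential footprint* is a site with a bound call in one state and
an explicit unbound call in the opposite state; absence of a call is not
evidence of unbound.  The location test is a two-sided Fisher exact test
of gene-body vs distal location, footprinted NP links vs background NP
links.  Network enrichment of a gene set against an interaction edge
list: 1000 permutations draw random gene sets of equal size from the
network-overlapped proteome, the permuted within-set edge counts are
fitted with a Gaussian, and `p = 1 − Φ(z)` for the observed count.  The
uniform node-draw null is the default (the simplest null consistent with
permuting the database); a degree-stratified draw is available because
hub-heavy gene sets inflate the uniform null, and the empirical-quantile
p `(1 + #{perm ≥ obs})/(n_perm + 1)` is always reported alongside since
the Gaussian tail is unreliable for small sets.

## The synthetic cohort

The generator emulates the study design — 18 patients × 3 states
(normal, tumor, metastasis) with one sample of each omic per state,
2 ATAC technical replicates, TMT-style runs of 3 patients (9 sample
channels + 1 reference) — on a toy genome (4 × 12 Mb chromosomes, 500
non-overlapping genes with exon structure, ~4 peaks per gene plus
intergenic peaks).

Counts (peaks, gene bodies, RNA) are negative-binomial (Gamma–Poisson)
around log-normal baselines (log2 mean 8 ± 1), the standard minimal model
for over-dispersed sequencing counts; dispersion defaults to 0.05.
Peptide intensities are log-normal (σ = 0.3 log2) around peptide
baselines times the gene's sample/reference ratio, with 10% of sample
channel intensities missing at random.  Each gene carries a per-sample
latent activity mixing a patient random effect (σ = 0.3; the cohort is
patient-matched) with sample noise; RNA loads on it with σ = 1 log2.

Couplings are planted against *realized* values so the configured targets
are directly recoverable from the emitted matrices (verified to ±0.1):
the linked peak's log-mean tracks the gene's observed within-state
standardized log RNA with correlation `rho_acc_rna` (default 0.75 — the
weakest coupling that remains BH-discoverable at this cohort size, i.e. a
planted link is a *true, detectable* regulatory link); protein tracks
cohort-wide standardized log RNA with `rho_rna_prot` (default 0.25,
placing the cohort-wide median protein–RNA Spearman near the weak
positive values typical of tumor proteogenomics, ~0.22–0.27) and 0.45 for
differential genes.  Coupling is state-invariant by default.

Differential genes (20%) shift one non-reference state by ±2 log2 units
at RNA and protein; the coordinated half also shifts the linked peak and
gene-body accessibility, receives a bound-in-tumor/met gene-body
footprint (placed inside the linked peak when it lies in the gene body),
and seeds a dense interaction module (size 15, density 0.9) on an
Erdős–Rényi background (p = 0.005).  The fixed 4-fold effect keeps the
accessibility shift detectable at the chromatin layer's FDR 0.01 even on
a split half-cohort; real effect-size spectra are continuous, which the
generator does not emulate.

What passing tests therefore show — and what they do not: calibration
results (uniform null p-values, FDR control) transfer to real data only
insofar as real noise is NB-like and state groups are exchangeable under
the null; power results are specific to the planted effect sizes.  Two
known divergences from the real cohort: (1) because planted effects are
strong and fully coordinated, the differential subset's protein–RNA
correlation (median ≈ 0.6) exceeds what mixed-magnitude real effects
produce (≈ 0.36 in comparable cohorts); (2) no read-level structure,
GC/mappability bias, motif sequence realism, isotope-level MS structure,
or batch effects are simulated.  The generator also plants no true
RNA × accessibility interaction in the protein model, so the end-to-end
demo's predictive-significance p is expectedly null; the dedicated power
study plants explicit interaction effects (β = 0.6, n = 27, 60 pairs per
category).

## Numerical choices and degenerate inputs

* BH excludes NaN p-values from the test count and propagates them.
* Welch tests: both groups constant with equal means → p = 1; constant
  with unequal means → p → 0 with infinite t.
* Zero variance anywhere in a correlation → the pair/peak/gene is skipped
  with a warning, never silently imputed.
* All randomness flows through `numpy.random.Generator` seeded from
  explicit arguments; per-replicate seeds in the evaluation studies are
  spawned from a base seed via `SeedSequence`.  Identical config + seed
  reproduces every TSV byte-for-byte (fixed column order, `%.6g` floats).
* Evaluation studies use 2,000 trans-null draws instead of the production
  10,000: the toy genome holds only ~2,000 trans peaks, so larger draws
  only resample; null moments are unchanged.  Problem sizes throughout
  the evaluation suite (500 genes, 54 samples, 20 seeds, 1000 null
  repeats) are the package's chosen desk-scale study conditions.

## Limitations

* The linkage null assumes trans-peak correlations are approximately
  Gaussian; at very small n the empirical correlation distribution has
  heavier tails, which the per-gene fit absorbs only partially.
* The one-sided linkage test cannot find repressive elements (by design;
  use `two_sided=True` to look).
* Pairwise Welch tests ignore the patient pairing across states, costing
  some power on strongly patient-structured features.
* The network Gaussian p can be anticonservative for very small gene
  sets; prefer `p_empirical` there.
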