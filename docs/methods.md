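# Methods

## Problem and model

Two species that diverged tens of millions of generations ago share no
ancestral polymorphism, yet their windowed nucleotide diversity can still
covary if the *processes* shaping diversity are conserved. The working model
is linked selection: purifying selection at coding sites removes linked
neutral variation, more strongly where the density of selection targets is
high and recombination is low. If the recombination landscape and the gene
landscape are conserved between the species (a stable karyotype), the
diversity-reducing factor is conserved too, and π in homologous windows
correlates even though the individual variants are entirely independent.

The package estimates windowed π in two species over windows of conserved
synteny, audits the trans-species sharing of individual variants (a control:
it should be near zero), and partitions π variance among genomic covariates
with OLS and principal component regression.

## Coordinates and lift-over

All internal coordinates are 0-based half-open; VCF positions are converted
at the reader boundary, GFF3 on read (via pyranges). Chain files follow the
UCSC convention: the t-side is the lift source, the q-side the target;
`size dt dq` triples advance the source by `size+dt` and the target by
`size+dq`, and negative-strand target blocks are normalised to forward
coordinates at parse time. Parsing validates that blocks tile the declared
spans exactly and reports the offending line otherwise.

Lift-over resolves overlapping chains per base by chain score (ties: input
order), exactly once, by subtracting already-claimed source intervals from
lower-priority blocks; the result is a sorted set of gapless pieces per
source chromosome, so position lifts are binary searches. Lifted bases are
grouped into **runs**: maximal source-ordered stretches sharing (chain,
target chromosome, target strand). A 200 kb window is retained when its best
run lifts strictly more than 80% of the window (the `>` is deliberate) and
the run's target span — first to last lifted base, internal target-side gaps
included — lies in [180 kb, 220 kb], bounds inclusive. A window whose best
run is below threshold is `rejected_split` if the runs jointly exceed the
threshold (a genuine split) and `rejected_low_remap` otherwise. `lifted_length`
defaults to the target span; a lifted-base-count mode exists
(`span_mode="bases"`) because either reading of "alignment length" is
defensible. Trailing sub-200 kb windows are tiled but flagged partial and
excluded from analysis: unequal window sizes would inflate π variance
heterogeneously.

## Diversity estimator

Per population and window,

    π̂ = Σ_variable sites 2 p̂ (1 − p̂) · n/(n−1)  /  n_qualifying,

with p̂ the alternate-allele frequency among the n *called* allele copies at
the site (missing genotypes are excluded from allele counts but do not
disqualify a site) and n_qualifying the number of sites at which **every**
individual has depth ≥ `min_dp` (default 4, inclusive). The per-site term is
the unbiased estimator of heterozygosity and equals the mean pairwise
difference among sampled copies, so π̂ is phase-free; an uncorrected
2p̂(1−p̂) variant sits behind `unbiased=False`. A window with zero qualifying
sites has *missing* π, never 0.

Variant-only VCFs cannot supply n_qualifying, so the module accepts either an
all-sites VCF or a per-window accessible-site count (TSV); the simulator
emits the latter. Masking (e.g. coding sequence) drops variant sites inside
the mask and scales the window's qualifying count by the unmasked fraction of
the window — accessibility is assumed uniform within a window, the best
available under a count-only accessibility input.

Windows with fewer than 10 000 qualifying sites in *any* population are
dropped (the per-population rule is the stricter of the two possible
readings; the species-average alternative is a switch). Species π is the
arithmetic mean of the two population values. Outlier windows (species π
above Q3 + k·IQR, default k=10) are always flagged but only removed when
`drop_outliers` is set: the analogous manual exclusion in real analyses
should stay an explicit, visible decision.

## Trans-species polymorphism audit

A site is variable in a species when it is a coverage-passing bi-allelic SNP
in at least one of its populations (sites failing coverage everywhere count
as non-variable, consistent with the diversity filter). Species-A variable
sites are lifted per base; those hitting chain gaps leave the denominator.
Matching is by coordinate — "variable in both" — with an allele-aware mode
behind a flag. With independent mutation histories the expected shared count
is coincidental: Σ_w n_A,w · n_B,w / span_w, which the null-control test
verifies within 99% Poisson bounds.

## Covariates

- **CDS density**: union of CDS features ∩ window / window length
  (strand-agnostic, overlaps counted once).
- **Repeat density**: BED union coverage / window length.
- **Intergenic GC**: GC fraction over non-N bases outside annotated gene
  spans ("intergenic" = complement of gene records — transcript-level
  definitions would need richer annotation); missing below 1000 usable bases.
  Accepts a FASTA or a precomputed per-window table.
- **Weighted dS**: after dropping genes with dS = 0 (unresolved branches) or
  dS > 2 (alignment artefacts), the mean dS of genes overlapping the window,
  weighted by overlap length so border-spanning genes contribute
  proportionally and are never double-counted (whole-gene-to-midpoint mode
  available); a window mean above 0.3 becomes missing.
- **Recombination rate**: ingested per window (cM/Mb) from linkage-map
  estimates; the package does not estimate maps.
- Transforms: √ for CDS density and dS, log10(x+1) for recombination rate;
  GC and repeat density are left raw. Raw and transformed columns coexist.

Regressions use complete cases only.

## Statistics

`spearman` computes the Pearson correlation of midranks (average ranks on
ties); p-values use the exact permutation distribution for n ≤ 8 and the
t-approximation otherwise. `ols` wraps statsmodels with an intercept,
classical SEs and the overall F; rank-deficient designs raise an error naming
the collinear columns. PCR standardises the predictors on complete cases,
eigendecomposes their correlation matrix (units are incommensurate, so the
covariance matrix would be meaningless), orients each PC so its
largest-magnitude loading is positive, and reports per-PC squared
correlations with the response; because scores are uncorrelated these shares
sum to the joint OLS R² to numerical precision — an identity the acceptance
suite checks at 1e-10. Near-zero eigenvalues (duplicated predictors) carry
zero share. Decile strata take the floor(0.1·n) extreme complete-case
windows, ties broken by window coordinate; this floor rule reproduces
residual df 247 for strata drawn from 2490 windows. No multiple-testing
correction is applied anywhere; none is standard for this battery.

## Synthetic data generator

The generator emulates the study conditions, not sequencing reality. Per
window it draws five landscapes (recombination, CDS density, repeat density,
GC, mutation scale) through a Gaussian copula whose latent variable mixes a
shared component z with a species-specific one as (s·z + (1−s)·e)/√(s²+(1−s)²),
so `s ∈ [0,1]` tunes cross-species landscape correlation while preserving the
marginals. Expected diversity is

    E[π] = 4·N_e·μ · m_w · B_w · exp(η),   B_w = exp(−k·d_w/(r_w+ε)),

with m_w the lognormal mutation landscape, d_w CDS density, r_w recombination
(cM/Mb), ε = 0.1, and η per-species N(0, noise_sd²) window noise.

Defaults (chosen once, as study conditions): N_e = 200 000 for both species;
μ_a = 5.5e-9 and μ_b = 1.55e-9, set so genome-wide mean π lands near 0.0039
and 0.0011 after the average background-selection reduction — the typical
flycatcher-like vs crow-like contrast; recombination lognormal(ln 2, 0.7)
cM/Mb; CDS density Beta(0.55, 27) (mean 0.02, range ~0–0.15); repeat density
Beta(2, 23); GC = 0.40 + 0.35·(d−d̄) + N(0, 0.025), clipped to [0.25, 0.75],
giving a GC–CDS Pearson r ≈ 0.28; mutation landscape lognormal with sdlog
0.25; dS per gene = 0.12·m_w·lognormal(0.2)-noise with 2% dS=0 and 0.5%
dS>2 genes, exercising the exclusion rules; k = 2, s = 0.8, noise sd = 0.3;
two populations of 15 diploids per species resampling one panmictic pool
(which reproduces the near-unity between-population window correlation of
real data without modelling structure); mean depth Poisson(20), so the
depth-≥4 filter passes >99.99% of sites. Chromosome lengths decline linearly
3:1 around the configured mean (a macro/micro contrast) so chromosome length
is a usable covariate, and every length is a multiple of the window size.

Variant realisation is a windowed sufficient-statistic scheme, not a
coalescent: S_w ~ Poisson(E[π]·accessible_w·a_n) segregating sites (a_n the
Watterson sum for the 2×15 sampled copies), alternate-allele counts from the
neutral SFS P(i) ∝ 1/i, genotypes by random assortment of copies, positions
uniform and distinct within the (lifted) window, per-sample depths
Poisson(mean depth). Under this scheme the window estimator is exactly
unbiased for E[π] (the expected per-site heterozygosity of an SFS draw is
1/a_n), which the Monte-Carlo tests verify. What the generator does **not**
emulate: linkage disequilibrium and coalescent variance within windows,
population structure, sequencing/genotyping error, reference bias, indels
and multi-allelic sites. Passing tests therefore demonstrate correctness of
the estimators and bookkeeping under the designed statistical structure, not
robustness to real-data artefacts.

Chain emission writes one near-identity chain per window (four blocks,
≤120 bp gaps; 10% of retained windows on the reverse strand to exercise
strand handling), and converts a configurable fraction of windows into
engineered failures: split across target chromosomes (55%/45%, defeating the
single-run rule), target-side inflation (+30 kb, defeating the size band),
source-side deletion (25%, defeating the remap threshold), or no chain at
all. A separate fraction gets sub-10 000 accessible-site counts to trigger
the diversity QC. The truth table records every window's intended verdict.

A file-free path (`simulate_windows`) realises the identical statistical
model directly at the window-summary level for the large replicate
experiments; coordinates, genotype matrices and text I/O carry no
information the window statistics use.

## Problem sizes and determinism

Analysis drivers and the file-based acceptance checks use 2 chromosomes
averaging 8 Mb (80 windows); replicate experiments use the acceptance scale
of 5 chromosomes averaging 120 Mb (3000 windows) — matching the real study's
window count — with 20 genomes for correlation recovery and 200 for
effect-sign rates. A seed is mandatory everywhere; identical seeds give
byte-identical output files (verified by test).

## Known limitations

- The accessible-site input is a per-window count, so masking rescales
  rather than recomputes the denominator (exact under within-window
  uniformity of accessibility).
- Lift runs break at chain boundaries; a rearrangement modelled as two
  abutting chains on the same target chromosome counts as a split even if
  the target coordinates happen to be contiguous.
- The allele-aware shared-polymorphism mode compares alternate bases without
  strand-flipping them for reverse-strand chains; coordinate matching (the
  default) is orientation-safe.
- Windows are treated as independent in all regressions; adjacent windows
  share linked-selection structure in reality, so classical SEs are
  anti-conservative there — a property inherited from the analysis design,
  not corrected here.
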