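# Methods

## Scope and model overview

walnutkit implements five connected analyses for diploid, highly
heterozygous perennials: (1) windowed diversity/differentiation statistics
(π, S, Tajima's D, Weir–Cockerham F_ST, ROD), (2) a top-quantile F_ST
outlier scan with permutation FDR and sweep classification, (3) a
single-genotype low-heterozygosity (autozygosity) scan, (4) haplotype-block
inheritance tracing through a pedigree, and (5) scaffold anchoring to a
genetic map with AGP construction and Marey-map recombination rates.  A
synthetic-data module generates every input with ground truth.

## Coordinates and genotype encoding

Internal coordinates are 0-based half-open (BED convention); VCF positions
are converted on ingest and back on output, so a 1-based position 100,000
falls in window [0, 100000).  Genotypes are dosages 0/1/2 with −1 for
missing; only biallelic SNP records are ingested (multiallelic and indel
records are counted and dropped — the statistics are defined on biallelic
sites).  The variant filter retains sites with missing-call fraction ≤ 0
(configurable) and minor-allele frequency strictly > 0.10 computed over
non-missing calls; the strict/non-strict pair mirrors the usual
"no missing data and MAF > 10%" filter wording.  Tiling windows cover the
whole chromosome and flag the final partial window; sliding windows
(recombination rate) are emitted only where fully inside the chromosome.

## Estimators

**π.** Per site, the mean pairwise difference among the k non-missing
chromosomes is 2c(k−c)/(k(k−1)) (the unbiased form); a window's π divides
the sum of these terms by the full window length in bp, so monomorphic and
unobserved positions dilute the estimate as in the standard windowed
convention.  Sites with k < 2 are skipped and counted.

**Tajima's D.** The 1989 constants are computed from their series
definitions for the window's chromosome count n.  When a window has no
missing data n = 2 × samples; with missing data we use the per-window
modal chromosome count and flag the window — a pragmatic choice where no
convention exists, affecting only windows with missingness.  D is
undefined (NaN) at S = 0, and n < 4 is an error.

**F_ST.** Per-site Weir–Cockerham variance components for two populations
(a: among-population, b: among-individual, c: within-individual) use the
sample-size-corrected formulas with n_c; windows use the ratio-of-sums
("weighted") estimator Σa/Σ(a+b+c).  Sites where either population has no
called diploid, or fewer than 2 diploids are called in total, are excluded
from both numerator and denominator.  Negative window estimates are kept
as computed: truncation at 0 would distort the empirical distribution from
which the outlier percentile is taken.

**ROD** = 1 − π₁/π₂ with group 1 the diversity-reduced slot; undefined
when π₂ = 0.

## Outlier scan and permutation FDR

The cutoff is the linear-interpolation empirical quantile (default 0.95)
of defined window F_ST values; windows with F_ST ≥ cutoff are flagged
(undefined windows never are).  The FDR of that cutoff is estimated by
permuting the individual→population assignment genome-wide (group sizes
preserved), recomputing all window F_ST values per permutation (default
1,000) and taking mean permuted count / observed count, capped at 1.
Permuting labels genome-wide rather than per window preserves the LD
structure within individuals.  Per-window F_ST is the permutation
statistic; a genome-wide-maximum variant would control FWER instead and is
intentionally not what is estimated here.  Sweep classification is by sign:
an outlier window is a candidate sweep in a group when that group's
Tajima's D is negative (both groups possible); ROD is carried along.

## Autozygosity scan

Heterozygous calls of one focal genotype are counted in 1-Mb tiling
windows.  The threshold is the linear-interpolation 10th percentile of
full-window counts (fractional values are expected); windows strictly
below it are flagged and adjacent flagged windows merge into regions that
never span chromosomes.  Partial terminal windows are excluded from
threshold estimation but flagged after rescaling count × size/length,
avoiding spurious terminal flags.  A structural property worth noting: the
percentile threshold can only recover autozygous segments when the
genome-wide autozygous fraction is below the chosen percentile — if more
than 10% of windows are fully autozygous, the 10th percentile falls inside
the autozygous count cluster and recall degrades proportionally.  Recovery
experiments therefore use a first-cousin-parent pedigree (expected
autozygosity 1/16), while the half-sib topology (expected 1/8) appears in
a fixed-seed example.

## Pedigree gene-drop and haplotype blocks

Founders receive two uniquely labelled haplotypes; each meiosis draws a
crossover count ~ Poisson(map length in Morgans) with positions uniform on
the cM axis (Haldane model, no interference — the truth-based tests do not
depend on interference) and transmits the recombinant mosaic.  Founder
marker alleles are either the unique haplotype labels (fully informative)
or Bernoulli(0.5) biallelic draws, optionally perturbed by an
allele-flipping genotyping-error rate.  The default error rate used in the
autozygosity experiments is 0.005 per allele, giving autozygous windows a
small nonzero heterozygote count as real short-read data show (residual
miscalls), and removing the degenerate all-zero atom that would otherwise
sit at the percentile boundary.

Blocks are the half-open intervals between the sorted union of crossover
positions of the chosen ancestral meioses (the truth-derived helper uses
all simulated meioses, so no block recombines anywhere in the pedigree).
Tracing compares a focal haplotype's block alleles to the relevant
parent's two haplotypes at all mutually non-missing markers: a unique
exact match is followed upward recursively; zero or two matches stop at
"unknown" (never guessed).  Identity with an ancestor requires exact
agreement of either focal haplotype with either ancestor haplotype across
the block — blocks are short by construction, so no mismatch tolerance is
allowed.  Phase is consumed, not inferred: statistical phasing is out of
scope.

## Anchoring and Marey maps

Alignments are retained iff identity ≥ 98%, probe coverage ≥ 95% and the
probe hits the genome once (boundary values pass; the rule filters *out*
records below the thresholds).  A scaffold's linkage group is the modal LG
of its retained markers, accepted only when the mode holds > 2/3 of them —
otherwise the scaffold is flagged as conflicting and left unplaced,
avoiding chimeric pseudomolecules.  Order within an LG is by mean marker
cM; orientation is the sign of the Spearman rank correlation between
marker cM and scaffold bp (rank rather than linear correlation is robust
to uneven marker spacing); scaffolds with < 2 distinct positions are
"unknown" and laid out as "+".  AGP v2.1 rows use known-length 100,000-nt
"N" gaps between consecutive scaffolds; the coordinate lift is an exact
bijection on component spans (for a "−" scaffold of length L at object
start s, position x lifts to s − 1 + (L − x + 1)).  Recombination rate per
10-Mb window sliding by 1 Mb is the least-squares slope of cM on Mb over
the markers inside; windows with < 2 markers (or no bp spread) are NaN,
and non-monotone cM triggers a warning but still yields a slope.

## Synthetic two-population model

Ancestral frequencies are Uniform(0.05, 0.95) — bounded away from 0/1 so
the MAF filter's pass rate stays high and stable.  Population frequencies
follow the Balding–Nichols parameterisation Beta(p(1−F)/F, (1−p)(1−F)/F)
(p itself at F = 0) and genotypes are Binomial(2, p_k) under
Hardy–Weinberg.  Defaults mirror the motivating founder panel: 11 + 12
diploids and F = 0.15.  Planted sweeps replace the sweep population's
frequency, with probability 0.9 per site, by a draw near fixation
(Uniform(0, 0.02) or Uniform(0.98, 1), side chosen by rounding p); this
frequency-replacement model is not a coalescent sweep but produces the
three signatures the scan consumes — low π, excess rare alleles (negative
D) and elevated F_ST — at negligible cost.  Sites are unlinked, so LD
patterns of real data (and haplotype-based sweep statistics) are outside
what these simulations can validate; passing tests demonstrate estimator
and scan correctness under the stated sampling model, not robustness to
linked selection or complex demography.  All randomness flows from one
integer seed through `numpy.random.default_rng`; the draw order is
documented per generator, making outputs byte-identical across runs.

## Problem sizes in tests and the acceptance script

The test experiments use desk-scale versions of the study design chosen as
the smallest sizes at which the checked quantities are statistically
stable: 20,000 sites / 200 100-kb windows for scan calibration (20 seeds,
1,000 permutations), 50,000 sites for estimator recovery (±0.02), six
30-Mb chromosomes at 200 markers/Mb for autozygosity recovery, and
5 markers/Mb genomes for block tracing.  The identity-peak experiment uses
~300-cM chromosomes so each carries ~20 blocks and identity totals vary
continuously rather than saturating at whole-chromosome ties.

## Known limitations

* Two populations only for F_ST (the r-population generalisation is not
  needed by any downstream consumer here).
* The gene-drop has no mutation model; genotyping error is the only source
  of heterozygosity inside autozygous segments.
* Sweep simulation is frequency-replacement, not a coalescent; no LD.
* Phase is taken as given; tracing stops ("unknown") at any ambiguity,
  including truly autozygous ancestors whose haplotypes are identical.
* Anchoring assumes probe alignments are precomputed (BLAT/minimap-style
  mapping is upstream) and orientation needs ≥ 2 distinct marker positions.
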