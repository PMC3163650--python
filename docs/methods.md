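# Methods

This note describes the statistical and computational methods implemented in
`divergene`, in the order they appear in the analysis pipeline. The package
targets a two-line study design: two mouse lines bred for high (HAB) and low
(LAB) anxiety-related behavior, compared by two-colour cDNA microarrays across
several limbic brain regions, followed up by qPCR, and complemented by an
allelic-variant catalogue of a candidate gene (Ctsb).

## Synthetic data model

Because the original raw data are not redistributable, every input the
pipeline consumes can be generated synthetically with known ground truth
(`divergene.synth`). The generator is first-class, tested code, not a test
helper.

Per-probe true expression is described by a log2 HAB/LAB ratio; a configurable
number of probes (default 300 of 24,192) carry a nonzero ratio whose magnitude
is log-uniform between 1.4- and 6-fold with random sign, shared across brain
regions. A two-colour array observes, for each spot,

```
M = s * log2_ratio + bias(A) + block_offset + noise
```

where `s` is +1 when HAB sits on the Cy5 channel and -1 on dye-swapped slides,
`bias(A)` is a smooth intensity-dependent dye bias
(`amplitude * sin(pi*A/A_max)`), `block_offset` is a per-sub-array
(print-tip group) Gaussian offset, and `noise` is per-spot Gaussian on the
log2 scale. Channel intensities are reconstructed as `R = 2^(A + M/2)`,
`G = 2^(A - M/2)`. The dye bias and block offsets attach to the physical
channels, not to the lines, so they do not flip with the dye swap.
Self-hybridization (null) arrays use the same machinery with all true ratios
set to 1.

All randomness flows from a single integer seed through named
`numpy.random.default_rng` substreams; identical configurations produce
bit-identical output.

## Two-colour normalization

Arrays are reduced to the MA plane (`M = log2 R - log2 G`,
`A = (log2 R + log2 G)/2`; spots with a zero channel are flagged unusable) and
normalized in three ordered steps, tracked by an explicit state machine
(raw → global → loess → subarray):

1. **Global median**: subtract the median of usable `M`.
2. **Intensity-dependent LOESS**: fit a locally linear LOWESS curve of `M` on
   `A` (span 0.40, tricube weights, zero robustness iterations, with
   point-collapsing for speed via `statsmodels`) and subtract the fitted
   curve. Zero robustness iterations keep the fit linear in `M`, which makes
   the whole chain exactly equivariant under a channel swap: swapping `R` and
   `G` and relabelling the dye orientation yields a bit-identical stacked
   result.
3. **Sub-array median**: subtract each print-tip block's median, absorbing
   spatial offsets exactly.

Normalized arrays are stacked into a probe-by-array matrix with dye-swapped
columns sign-flipped, so every column estimates log2(HAB/LAB).

## Differential expression: sign-flip permutation test

Under the dye-swap design, the null hypothesis of no line difference makes
each array's column sign exchangeable. Per probe we compute a one-sample t
statistic of the oriented `M` values; family-wise error is controlled with
Westfall–Young maxT step-down adjustment over sign-flip permutations:

- For each sign assignment, null |t| values are computed for all probes;
  step-down successive maxima are taken over the observed-|t| ranking.
- `p_adj(i) = (1 + #{assignments with step-down max null |t| >= |t_i|}) / (1 + B)`,
  with monotonicity enforced along the ranking.
- When the requested number of permutations reaches `2^n - 1` (all
  non-identity assignments for `n` arrays), the procedure switches to complete
  enumeration and the adjusted p-values are exact randomization p-values. The
  attainable minimum is `2/2^n`, because the global complement of the identity
  assignment reproduces every |t| exactly.

The implementation exploits the invariance of per-probe sums of squares under
sign flips: null means come from a single matrix product and null variances
from `(ss - n*mean^2)/(n-1)`, so tens of thousands of probes times ~1000 flips
run in about a second. The observed statistics pass through the same
arithmetic path as the null statistics so that exact ties (the complement
assignment) are counted correctly in either float precision.

For single-channel matrices the package instead offers quantile normalization
to the mean quantile profile of log2 intensities and an empirical-Bayes
moderated two-sample t statistic: the variance prior `(d0, s0^2)` is estimated
by closed-form moment matching on log residual variances (digamma/trigamma
inversion), per-probe variances are shrunk as
`s~^2 = (d0*s0^2 + d*s^2)/(d0 + d)`, and p-values use a t reference with
`d0 + d` degrees of freedom. The `d0 -> 0` and `d0 -> infinity` limits recover
the ordinary t and a common-variance z statistic; the implementation is
cross-checked against the R package limma.

## Candidate selection across regions

Percent regulation of a fold ratio `r` is direction-fair:
`(max(r, 1/r) - 1) * 100`, so 1.4-fold up or down both count as 40%. Two
explicit rules operate on a bundle of per-region DE tables:

- **strictA** — at least 40% regulation with adjusted p < 0.05 in at least one
  region, and at least 30% regulation in every analyzed region;
- **strictB** — at least 30% regulation with adjusted p < 0.10 in all, or in
  at least three, of the analyzed regions.

Probes regulated in opposite directions across regions are excluded from the
cross-region track (and surfaced by a separate direction report); probes
missing from a region's table fail that region.

## qPCR relative quantification (2^-ddCt)

Duplicate wells are averaged on the crossing-point (Cp) scale. For each
sample, `dCt = Cp(target) - Cp(reference)`, where the reference is one
housekeeping gene or the arithmetic-mean Cp of a pair (equivalently the
geometric mean of their expression levels); relative expression is `2^-dCt`.
Group fold-regulation is reported relative to the group with the lowest mean
expression, whose fold is exactly 1 by construction. Adding a constant to all
of a sample's Cp values (a loading difference) leaves relative expression
bit-identical. In situ hybridization values are the maximum over sections of
(signal minus nearby background).

## Allelic variants

A gene model lives in a 1-based TSS-relative frame with no zero: +1 is the
transcription start, negative positions run upstream through the promoter,
exons and introns tile the gene body, and a downstream enhancer region (DER)
follows the gene end. Variant discovery aligns two allele sequences globally
(match 1, mismatch -1, gap open -5, gap extend -1, via Biopython); SNPs are
reported at their position, indel events are left-aligned and anchored at the
preceding base, and a multi-base gap run counts as one event. Following the
reference-strain (C57BL/6J-relative) convention, an insertion is sequence
present in the LAB allele and absent from HAB; a deletion is the reverse.

Annotation assigns each position a region label (promoter, 5'UTR, exon-k,
intron-k, 3'UTR, DER, flanking; UTR labels take precedence over exon
numbering), a genomic coordinate, and a spliced-mRNA coordinate. Cluster
detection slides a half-open window `[start, start + window)` anchored at
variant positions and reports maximal-count windows; the count is monotone
non-decreasing in the window width. Coding consequences translate the
affected codon under both alleles with the standard codon table (synonymous /
missense with three-letter amino-acid names); CDS indels are reported as
frame-affecting.

The packaged Ctsb catalogue (`data/ctsb_variants_synthetic.tsv` and its gene
model) is a synthetic stand-in constructed to match the published summary
statistics of the real catalogue (76 SNPs, 8 insertions, 9 deletions; 10 SNPs
plus 2 insertions in the promoter; 8 exonic sites, all SNPs; an 18-variant
550-bp intronic cluster, a 12-variant DER cluster, and a ~6-variant 230-bp
promoter cluster); individual positions and alleles are invented.

## Group statistics

Behavioral endpoints and qPCR folds are compared nonparametrically:
Kruskal–Wallis H (tie-corrected; exact permutation p by enumeration for total
n <= 10, chi-square approximation otherwise), pairwise two-sided Mann–Whitney
U (exact when the smaller group has n <= 8 and there are no ties), and Holm
step-down ("sequential Bonferroni") correction. The full chain gates pairwise
tests on the omnibus p < 0.10 and is calibrated on synthetic null tables: its
empirical type-I error stays within Monte-Carlo error of the nominal level.
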