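# Methods

## Scope and model

`vomeroseq` implements the post-counting analyses of a strain x sex bulk
RNA-seq comparison of the mouse vomeronasal organ: all statistics act on
a gene x sample integer count matrix with per-sample strain and sex
labels, a gene annotation (1-based inclusive coordinates, GFF3-style),
per-gene reference sequences with strain variants, and nothing upstream
of counting (alignment, QC and quantification are out of scope).

Counts are modelled as negative binomial in the mean-dispersion form,
`Var(K) = mu + alpha * mu^2`, with one dispersion `alpha >= 0` per gene.
This is the minimal model that captures the overdispersion of biological
replicates while reducing to Poisson at `alpha = 0`.

## Differential expression core

**Normalization.** Median-of-ratios size factors: for genes detected in
every sample, `s_j = median_g (K_gj / geomean_g)`, rescaled so the
factors have geometric mean 1.  If no gene is detected in all samples
the estimator is undefined and we raise rather than fall back to a
pseudo-reference.  Note a structural property of this family of
estimators: because the reference includes the scaled sample, multiplying
one sample's counts by `c` scales its factor by `c^(1-1/m)` and every
normalized value by the common constant `c^(1/m)`; all *ratios* between
factors scale by exactly `c`.  Tests assert the scale-free form.

**Dispersion.** Method of moments from the pooled within-replicate-group
variance of normalized counts: `alpha = max(0, (s^2 - m) / m^2)`, clipped
at 100.  No shrinkage or mean-dispersion trend is fitted: at the
package's design scale (4 strains x 2 sexes x 4 replicates) the extra
machinery is unidentifiable, and the cost — noisier per-gene `alpha` —
is absorbed by the recovery-based tests rather than hidden.  All-zero
genes are flagged, not estimated.  Designs without replication raise.

**Wald test.** `LFC = log2((m_A + c)/(m_B + c))` on group-mean normalized
counts with pseudocount `c = 0.5` (keeps the statistic finite when one
group is all zero).  The standard error propagates `Var(m) = (m +
alpha*m^2)/n` through the log by the delta method; `p` is the two-sided
standard normal tail of `LFC/SE`.  No small-sample t correction is
applied — an acknowledged approximation whose practical effect is the
measured null type-I rate of ~0.014-0.017 at nominal `p < 0.01` (within
the calibration band the tests assert).

**Outlier filter.** Per sample, `D = (K - group mean)^2 / (p * (mu +
alpha*mu^2))` is compared with the 99th percentile of `F(p, n-p)`, `p`
the number of fitted group means.  The variance here uses the *median*
dispersion across genes, not the gene's own estimate: a single aberrant
count inflates the per-gene moment estimate enough to mask itself
(`D` is then bounded near `(n-1)^2/(p n)`), whereas the dataset-wide
typical dispersion is robust to it.  This plays the role the fitted
dispersion trend plays in GLM pipelines.  Filtered genes get no q-value
and are never called DE.  The filter can be disabled.

**Calling.** BH q-values are computed per contrast over unfiltered genes
with the definitional step-up `q_(i) = min_{j>=i} n p_(j)/j` (bit-exact
against the formula; cross-checked against statsmodels).  A gene is DE
if any pairwise strain contrast has `|LFC| > 1` and `q < 0.05`.

## Sex dimorphism and dosage

The cross-strain screen computes a per-strain male/female `LFC` and
combines them as a sample-size-weighted mean (a weighted geometric mean
on the FC scale; reduces to the plain FC for balanced designs — the
weighting is configurable).  The default variance combines per-strain
delta-method variances with the same weights; a pooled all-males-vs-
all-females Wald test is available behind `variance="pooled"` since the
choice is not determined by the design.  The flag requires weighted
FC > 2, `p < 0.01` (a screen-level p, deliberately not FDR-adjusted) and
the per-strain fold changes to agree in sign — the operationalization of
"consistently observed across all strains", togglable.

Within-strain tests rerun the Wald test inside each strain (sex as the
group, per-strain dispersion) with BH per strain; genes significant in
>= 1 strain are reported with their strain labels.  This recovers
effects confined to single strains that vanish when strains are pooled
(Simpson's paradox).

The dosage report computes, per X/Y homolog pair on normalized counts,
`ratio = female X / (male X + male Y)`; the male combined value is the
exact sum by construction.  Nonzero female counts on a Y gene are
rejected as an input error.

## Hotspot scan

Windows of `W = 25` expressed genes (raw count > 0 in >= 1 sample by
default) slide along each chromosome with step 1 gene; chromosomes with
fewer than `W` expressed genes contribute no windows.  The DE count `k`
of a window is tested against Poisson(`lambda = W * r`) with the
inclusive upper tail `P(X >= k)`; `r` is (total DE)/(total expressed)
over the same expressed set that built the windows.  BH runs genome-wide
across all windows (a single FDR for all hotspots); significant windows
sharing >= 1 gene on a chromosome merge, and the hotspot interval spans
the first to last member gene.  Step 1 and the inclusive tail are
explicit choices where the convention is ambiguous; both are parameters.
Summaries print span in Mb to 2 decimals and percentages half-up to 1
decimal, the convention of published hotspot tables; the package bundles
one such published 12-row interval table as worked-example input and
recomputes every derived column from it.

## Presence patterns

Two absence rules are reported side by side, neither canonical:
`zero_raw` (absent iff every raw count in a strain is zero — the literal
reading of "completely lacked expression") and `mean_norm_gt1` (strain
mean normalized count <= 1, the detection threshold used for the
dendrograms).  Venn counts cover all `2^S - 1` nonempty strain subsets
and sum to the number of genes expressed in >= 1 strain.

## Pseudogene functionalization

Variants (SNVs and single-base-anchored insertions only) are applied
right-to-left so positions always refer to the original reference; REF
alleles are verified.  ORF search scans the three forward frames for the
longest ATG-initiated ORF ending at its first in-frame stop (sequences
are supplied sense-strand per gene, so reverse frames are out of scope);
ties break to the earliest start.  Functional = the edited allele's ORF
covers >= 95% of the declared homolog's ORF while the reference's does
not; "full-length" has no numeric definition in the field, so the 95% is
explicit configuration.  Percent identity is global alignment with fixed
scoring (nt: +1/-1, gap -5/-1; aa: BLOSUM62, gap -11/-1), identity =
matches / alignment columns — fixed so reported percentages are
bit-reproducible.  Local alignment would inflate identity on truncated
alleles, which is why global is the default and the only mode.

## Dendrograms and correlation clusters

Strain trees use 1 - Spearman rho between per-strain mean expression
profiles (genes as observations; per-sample profiles are available but
strain means match trees whose leaves are strains).  Average-linkage
agglomeration is implemented in-package so ties break deterministically
to the pair containing the lexicographically smallest leaf; scipy's
implementation is the independent cross-check in tests.  Bootstrap
support resamples genes with replacement; `bp` of a node is the fraction
of bootstrap trees containing the same leaf set.  The approximately
unbiased value runs the bootstrap at scales r in {0.6..1.4} (resample
size `ceil(r n)`), fits `z(r) = Phi^{-1}(1 - bp(r)) = v sqrt(r) +
c / sqrt(r)` by weighted least squares with binomial weights
`B phi(z)^2 / (bp (1 - bp))` (bp clipped to (1/(B+1), B/(B+1)) for the
probit), and reports `au = 1 - Phi(v - c)`.  Nodes with bp identically
0 or 1 at every scale are degenerate: au is set to that bp and flagged.
Default 1000 replicates per scale; 10,000 available by flag.  lncRNA/
receptor reports cluster receptors by average linkage of 1 - rho and
label each lncRNA with the sign of its mean correlation to each cluster.

## Synthetic data

The generator's defaults are the study conditions the analyses assume:
4 strains (B6, 129, SJL, SWR) x 2 sexes x 4 replicates, 10,000 genes on
5 chromosomes, baseline means log-normal(log 60, 1.5), per-gene
dispersion log-normal(log 0.08, 0.5), library-size factors uniform on
[0.7, 1.3], genome-wide DE fraction 0.128 concentrated in 12 planted
clusters at local rate 0.42, DE effect +-2 log2 units in one random
strain.  Cluster sizes follow the published hotspot-size distribution
(25-122 expressed genes, 575 total), and each cluster is planted with
exactly `round(0.42 * size)` DE members at random positions — mirroring
how published hotspot tables pair sizes with DE counts, and guaranteeing
the generator's invariant that every planted effect is recoverable in
expectation (a cluster whose DE count fluctuated below the Poisson/BH
detection boundary would be planted-but-undetectable by construction).
Background DE is Bernoulli at a rate adjusted so the genome-wide
expectation stays 0.128.

Augmentations add: dosage-compensated X/Y pairs (female X mean = male X
+ male Y; Y counts exactly zero in females), a female-only Xist-like
gene, positively correlated lncRNA/receptor blocks sharing one strain
profile and an antagonistic pair on a monotone-decreasing transform of
it (planted Spearman exactly -1), genes with a sex effect in exactly one
strain, and pseudogene loci.  The SNV locus is a 990-nt coding sequence
carrying two premature stops among ten strain-specific SNVs; restoring
it yields a 329-aa receptor whose homolog is built by exactly 53
nonsynonymous + 36 synonymous single-base codon changes (planted 91% nt,
83.9% -> prints 84% protein identity).  The insertion locus deletes one
base so the frame shifts 359 bp after the start codon; a single C
insertion restores a 318-aa ORF (homolog at 97% nt / 95% protein).
Construction is retried over seeded substreams until the reference is
verifiably pseudogenized and the homolog ORF is intact.

What the generator does *not* emulate: batch effects, GC/length bias,
isoforms, correlated dispersion-mean trends, linkage between clusters,
or real receptor sequence families.  Passing recovery tests therefore
demonstrates the algorithms are correct and calibrated under the stated
model, not that real VNO data meet that model.

## Problem sizes and numerics

Recovery suites run at: 10,000 genes for DE and hotspot recovery (50
seeds for the scanner's median recall and false-call checks; 25 in the
acceptance script), 5,000 null genes for type-I calibration, 500 genes
for LFC recovery, 50-200 small simulations for dimorphism/dosage rates,
100 seeds per pseudogene mode, 1000 bootstrap replicates per scale for
tree support.  These sizes make the full suite run in well under a
minute each while leaving the Monte-Carlo bands far from their
thresholds.  Oracle-equivalence tests (BH, Spearman, average linkage,
Poisson tails, window enumeration) are exact to 1e-12 or bit-exact.
Degenerate inputs are defined behaviors, not crashes: empty variant sets
are identities, ORF-less sequences return an empty result, constant
genes get flagged missing correlations, empty hotspot lists still
produce totals and genome rows.

## Known limitations

Normal (not t) Wald tails slightly inflate the type-I rate at n = 4 per
group; the MoM dispersion is noisy per gene and unshrunk; the hotspot
null treats genes as exchangeable within the expressed set (no local
gene-density correction beyond windowing in gene space); the AU fit uses
WLS rather than maximum likelihood, adequate at B >= 1000; and the
pseudogene caller only handles SNVs and insertions (no deletions or
splice-aware ORFs).
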