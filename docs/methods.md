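# Methods

This note documents the models, parameter choices and numerical
conventions behind each stage, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Filtering

The chain runs in a fixed order — site screen, sample drop, genotype-level
rules, positional rules — because each stage's semantics depend on what
precedes it (e.g. the "no missing data" rule is applied *after*
low-quality calls have been set missing, mirroring a BCFtools-then-R
two-tool workflow).

Conventions that the raw rules leave open:

- **Allele depth ≥ 10** is enforced *per allele at heterozygous calls*
  (default), consistent with how the ploidy module reads allele balance;
  `allele_depth_mode="site_sum"` switches to summed-per-site semantics.
- **Site depth bounds** are read as: retain loci whose **mean** total
  depth across samples lies in `[15, 100]`. The raw phrasing ("minimum
  depth 15 and maximum 100 over all samples were removed") is
  self-contradictory; the mean-bounds reading is the common practice the
  range implies, and the bounds are configurable.
- **Thinning** is a greedy first-kept scan per contig in ascending
  position (keep a locus iff ≥ `thin_bp` from the last kept locus),
  deterministic with input-order tie-break on equal positions.
- Coordinates are 1-based fully-closed, as in VCF.
- A site QUAL of '.' (NaN) is not held against a locus.

Idempotence (re-applying any stage is a no-op) and monotonicity
(tightening a threshold never keeps more loci) are tested properties.

## Ploidy from allele balance

At a heterozygous site with total depth *n* and alt count *a*, diploids
generate `a ~ Binom(n, 1/2)` and triploids `a ~ Binom(n, 1/3)` or
`Binom(n, 2/3)` depending on which allele is duplicated; the triploid
model is the equal-weight mixture. The visual histogram-reading procedure
is formalised as the log-likelihood difference of these two models over a
sample's usable het sites.

Filters before the comparison: both allele depths ≥ 10 at each site
(low-depth balances are uninformative), and a sample median read depth
≥ 30 (below this the histogram is uninterpretable, and the sample is
skipped rather than called). A call also requires ≥ 50 usable sites and a
log-likelihood margin ≥ 10; otherwise `undetermined`. The margin and site
minimum are conservatism defaults — with 500 sites at depth 60 the margin
between the true and wrong model is typically hundreds of log-units, so
these defaults cost essentially no power while guarding shallow samples.
A beta-binomial variant (`overdispersion=rho`) widens both models for
data with mapping bias; off by default.

Both models are symmetric in ref/alt, so mirroring a profile cannot change
a call (tested).

## Clonal lineages

**Distance.** Allele-count Hamming distance normalised by `ploidy × L`,
so 0 = identical multilocus genotype and 1 = opposite homozygote at every
locus, and thresholds are comparable across datasets of different size.
The alternative (genotype mismatch count) compresses het/hom differences;
allele counting preserves them.

**Threshold.** Somatic mutations make true clonemates differ slightly, so
lineages are cut at a nonzero distance. Sweeping the threshold upward,
the lineage count drops at the agglomeration's merge heights; within-clone
heights are small and tightly spaced, between-lineage heights large. The
predictor takes the first `ceil(fraction · m)` candidate heights
(`fraction = 0.5`, the referenced implementation's default; at least two
so a gap exists) and returns the midpoint of the largest gap in that
prefix. This fails gracefully (returns 0 with a warning) when fewer than
two candidates exist — i.e. when no clonal structure is detectable.
The prefix logic presumes clones are less than about half the merges; in
heavily clonal datasets pass an explicit threshold instead.

**Assignment.** Deterministic average-linkage agglomeration
(Lance–Williams update), merging while linkage ≤ threshold,
smallest-linkage-first with lowest-sample-index tie-break. The ≤ ensures
threshold 0 merges exactly-identical genotypes, so MLLs coincide with
MLGs there. Cross-checked against scipy's average-linkage dendrogram on
tie-free matrices; with exact ties the two may choose different, equally
valid merge orders, which is why the in-package implementation (with its
pinned tie-break) is the one used.

**Diversity.** λ = 1 − Σ(n_i/N)² over samples-per-MLL; Pareto β is the
negative OLS slope of log(reverse cumulative fraction of genets of size
≥ x) on log(x) over the *distinct observed sizes* (the standardisation
from the clonal-ecology literature), +∞ when every genet is a singleton
(no clones), NaN when only one distinct size > 1 exists (nothing to
regress). Rarefied intervals resample min-site-size individuals without
replacement (1000 replicates, seeded) and take 2.5/97.5 percentiles.

## Diversity and differentiation

Per locus, H_O is the heterozygote fraction and
H_S = 2n/(2n−1)·(1 − Σp̂²); site values are means over loci and
F_IS = 1 − mean(H_O)/mean(H_S) (ratio of means, not mean of ratios — the
basic-stats convention; the per-locus alternative is exposed via the
returned per-locus quantities). Loci monomorphic within a site but
polymorphic globally are included by default
(`polymorphic_within_site_only` restricts). Genet-level statistics keep
the first sample of each (site, MLL) pair. Triploid samples are excluded
from diversity and F_ST by default: their diploid-coded genotypes bias
allele-frequency estimators.

Pairwise F_ST is Weir & Cockerham's (1984) θ with the per-locus a/b/c
variance components summed across loci before the ratio. θ may be
slightly negative by construction and is not clamped. Sites with fewer
than 2 usable samples are dropped from the matrix.

## Genotype–environment association

**Space.** Least-cost distances run Dijkstra over 8-connected sea cells
(diagonal √2·cell), with land sites snapped within a tolerance and
disconnected pairs an explicit error. Any distance matrix can be supplied
instead. dbMEMs: truncate at the largest minimum-spanning-tree edge,
replace larger distances by 4t, Gower-centre −½D², eigendecompose, and
retain eigenvectors with Moran's I above its expectation −1/(n−1) under
binary truncation-neighbour weights — the standard dbMEM construction
(positive spatial autocorrelation only; `autocorrelation="all"` keeps
every positive-eigenvalue vector). With few sites this choice matters: a
basis that saturates the between-site space leaves no identifiable
degrees of freedom for any conditioned analysis.

**Model.** Environmental variables are screened for collinearity
(greedy pairwise |r| > 0.9 drop, reported not silent), detrended by OLS
on the dbMEMs, and entered into a partial RDA: genotypes and predictors
are residualised on the conditions (two genotype PCs + per-sample
dbMEMs), the residual genotypes are regressed on the residual predictors,
and the constrained axes are the SVD of the fitted values. R² is the
fitted fraction of the conditioned genotype variance, adjusted by the
Ezekiel correction; both match vegan's `rda()`/`RsquareAdj()` on
unconditioned problems (tested).

**Outliers.** Per locus, the squared Mahalanobis distance of its loading
vector (3 axes) from the loading centroid, under a robust
minimum-covariance-determinant estimate (so the outliers sought do not
inflate the covariance; plain covariance is the small-L fallback). The
genomic inflation factor λ = median(D²)/median(χ²₃) rescales the bulk to
the null; p-values are χ²₃ upper tails of D²/λ, Bonferroni-corrected, and
flagged at adjusted p < 0.01. Mahalanobis distances are invariant to
per-axis scaling, so the loading normalisation convention does not affect
calls.

**Degrees-of-freedom accounting.** Environment is attached per sample but
varies only per site, so with S sites the analysis has S−1 informative
dimensions, of which the conditions absorb (#PCs + #MEMs). Associations
collinear with conditioned-out structure are unidentifiable *by design* —
the conservative trade-off of the conditioned test. The synthetic
recovery experiments therefore plant their signal in the identifiable
subspace (below).

## Genomic offset

Effects and latent factors are estimated by alternating least squares:
B from OLS of centred genotypes on standardized environment, factors as
the top-K left singular vectors of `Y − XB̂` (not the OLS residual, which
is orthogonal to X by construction and would make the adjustment a
no-op), joint re-estimation, iterate to convergence (tol 1e-8). K
defaults to 4 — one less than the number of genetic clusters a
structured dataset of this kind typically shows — and an optional ridge
penalty stabilises near-collinear designs. Structure *independent* of the
environment is removed; structure collinear with it is absorbed into B
(inherent to any such decomposition). Over-specifying K beyond the true
structure rank can absorb real signal, so K should come from the
structure analysis, not be maximised.

The offset between baseline x and future x* is `(1/L)·‖B(x*−x)‖²` with
both scenarios expressed in baseline units (baseline mean/sd stored in
the model). It is zero iff the standardized change is in B's null space,
scales quadratically with the change, and is a *relative* quantity:
comparable across sites within one analysis, meaningless across analyses.

## The synthetic-data generator

What it emulates: site structure with a hierarchical Balding–Nichols
island model (3 clusters at F = 0.2 between clusters, F = 0.01 between
sites within a cluster — spanning the within-/between-cluster
differentiation range typical of strongly structured coastal
populations); genets drawn per site with geometric size distribution
(mean ≈ 1.7 ramets per genet, i.e. most lineages singletons with
occasional dominant clones); somatic mutations as ±1 dosage steps at rate
1e-3 per locus per ramet (so clonemates differ by small Hamming
distances — the reason the clone threshold exists); a fraction of
triploid genets whose VCF calls are diploid-coded (any intermediate
dosage het), so read depths carry the only triploidy signal; negative
binomial depths (mean 60, dispersion 8) with binomial allele split and 1%
allele miscall; and 50 adaptive loci whose site frequencies shift on the
logit scale (effect size 3) along a standardized temperature anomaly,
with Balding–Nichols noise around the shifted mean.

The environmental driver is the **local temperature anomaly**,
constructed orthogonal at site level to smooth coastal trends (degree ≤ 4
polynomials in site order) and to the genetic-cluster contrasts. This is
deliberate: micro-habitat anomalies, not the regional gradient, are what
remain after spatial detrending, and any planted association collinear
with trend or neutral structure is provably unrecoverable by the
conditioned analysis. Planting an identifiable signal makes the recovery
experiments measure the method's power rather than the (known,
documented) confounding loss. The effect size is large because the loci
the outlier test is built to find are precisely the strong,
outlier-class ones.

What it does not emulate — and hence what passing tests do *not* show
about real data: linkage and recombination (loci are independent), so
thinning is exercised only mechanically; coalescent ancestry and
admixture gradients; mapping bias and paralogy (allele-balance peaks are
clean binomials); missingness that correlates with sample quality;
selection acting over time. Real datasets will show broader allele-balance
peaks, heavier-tailed outlier statistics and messier clone-size
distributions than the generator produces.

Depth, error, structure and clone-size defaults are set once from the
study system the package emulates (median depths ≥ 30–60×, a handful of
genets per bed, dominant clones at some sites) and are all configurable.

## Numerical conventions

- Missing genotype sentinel −1; all-integer dosage storage (int16).
- Determinism: every stochastic routine takes a seed or Generator; the
  robust covariance uses a fixed random_state; the agglomeration and
  thinning have pinned tie-breaks.
- Degenerate inputs return sentinels with warnings (β with one distinct
  clone size, F_IS with H_S = 0) or explicit errors naming the remedy
  (missing data in distances → filter first; all samples dropped →
  threshold review).
- The F → 0 Balding–Nichols limit returns the ancestral frequencies
  exactly rather than sampling a degenerate Beta.

## Limitations

- The clone-threshold predictor assumes a bimodal merge-height series;
  datasets where clones dominate need an explicit threshold.
- F_IS conventions differ across software (ratio-of-means vs
  mean-of-ratios, H_S corrections); published tables may not be exactly
  reproducible under any single convention, and rounded published values
  need not satisfy F_IS = 1 − H_O/H_S exactly.
- The offset estimator is a closed-form latent-factor approximation of
  ridge-regularised factor regression; it diverges from the reference
  method when structure and environment are strongly collinear.
- With ~10 sites, GEA power and calibration are dominated by the site
  count, not the sample count; Bonferroni at 5000 loci requires strong
  per-locus signals, and a handful of neutral loci can be chance-aligned
  with any site-level variable.
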