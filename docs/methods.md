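# Methods

This note documents the models, estimators, numerical conventions and
design choices behind `selflines`, in the order the pipeline runs them.

## Genotype model and QC

Genotypes are biallelic diploid SNP calls stored as alt-allele dosage
(0/1/2, −1 missing), keyed by (RAD locus id, SNP offset) where a RAD locus
is a 93-bp reduced-representation tag. QC applies, in fixed order:
individuals with missing fraction > 0.25 removed, then loci with missing
fraction > 0.10 removed, then one SNP (the smallest offset) kept per RAD
locus. Both thresholds are strict inequalities — boundary cases are
retained — and the filters are applied once, not iterated. The order
matters (an individual removed first can rescue a locus) and is covered by
a test. Genotype-likelihood filtering belongs to the upstream caller
pipeline and is out of scope here; the package accepts called genotypes.

## Diversity and divergence estimators

* **H_o** — mean over loci of the heterozygote fraction among non-missing
  calls.
* **H_e** — Nei's unbiased gene diversity per locus,
  `n/(n−1) · (1 − Σ p̂² − H_o/(2n))` with `n` the non-missing diploid
  count, averaged over loci with `n ≥ 2`. This convention (the one used by
  the standard hierarchical-F-statistics packages) is equivalent to
  `2n/(2n−1)(1 − Σ p̂²)` when genotype frequencies are binomial, but remains
  well-behaved under extreme inbreeding.
* **F_IS** = 1 − H_o/H_e, reported as NaN when H_e = 0.
* **Allelic richness** — Hurlbert rarefaction to a common number of
  sampled genes (default: the smallest per-locus non-missing gene count
  over groups, at least 2), averaged over loci.
* **Private alleles** — alleles observed in exactly one group of the
  partition in use; the partition (lineages, or sites within a lineage) is
  a parameter. Hybrids must be excluded by the caller.
* **Nei's D** (1972) — `−ln(J_xy/√(J_x J_y))` with J terms averaged over
  loci, frequencies plugged in from samples, loci with missing frequencies
  dropped pairwise; infinite when J_xy = 0.
* **Weir–Cockerham θ** — the 1984 variance-components estimator computed
  per locus from per-subpopulation sample sizes, allele frequencies and
  heterozygote fractions; the multilocus value is the ratio of sums
  Σa / Σ(a+b+c). A locus contributes when ≥ 2 subpopulations have data and
  the components are defined; monomorphic loci (zero denominator) are
  skipped and counted. Negative per-locus estimates are retained in
  distributions (they are clipped into the lowest histogram bin, with a
  count of negatives reported, only for display). Because the estimator
  conditions on observed heterozygosity it remains unbiased under the
  near-complete selfing this package targets.
* **Genotype PCA** — centered (not variance-scaled) dosages with per-locus
  mean imputation of missing calls, following the convention of the
  standard genotype-PCA packages; eigendecomposition via SVD. Candidate
  hybrids are flagged by a documented convention (distance to the nearest
  group centroid on the first two axes exceeding 3× that group's RMS
  radius), since visual identification does not automate.

## Hybrid simulation and classification

`cross` draws one uniform gamete per parent per locus independently
(missing parent call ⇒ missing offspring call); `self_` draws two
independent gametes from one individual, so an Aa locus segregates
1/4 : 1/2 : 1/4. Reference classes are F1 (cross of individuals sampled
uniformly from each parental population), F2 (one selfing of each F1) and
F3 (one more). Sampling parental *individuals* (rather than gametes from
pooled allele frequencies) is the primary mode because under near-complete
selfing individuals are far less diverse than the pooled frequency vector
suggests; a frequency-based mode can be emulated by passing synthetic
parents drawn from frequencies.

The hybrid index h (proportion of ancestry from population B) maximizes
the likelihood in which each gene copy derives from B with probability h,
so the per-locus alt-allele probability is `h·p_B + (1−h)·p_A` and
genotypes are binomial. The maximizer is located on a 1001-point grid and
refined by solving the score equation with Brent's method; the reported
interval is the 2-log-likelihood-unit support region read off the grid. A
counting estimator (fraction of B-diagnostic alleles among fixed
differences) is provided as a cross-check and coincides with the MLE when
all loci are fixed differences with no missing data.

Classification compares an observed (heterozygosity, h) pair with each
simulated class's joint empirical distribution. The acceptance region is a
per-margin percentile box at overall level 1 − α (default α = 0.05); the
margins use Bonferroni-split levels (each margin keeps its central
1 − α/2 interval) so the box covers at least 1 − α jointly. Ties between
overlapping boxes resolve to the class with the greatest two-sided
percentile depth. Outside all boxes: near-zero heterozygosity (< 1/4 of
the smallest class mean) with h ≤ 0.1 or ≥ 0.9 is "parental"; elevated
heterozygosity with h outside every class's h-interval is
"backcross-like"; anything else is "uncertain". A percentile box was
preferred to a Mahalanobis ellipse because the selfed-class margins are
strongly non-normal.

## Divergence scan

Per-locus F_ST histograms are computed on [0, 1] (negatives clipped into
the lowest bin and flagged), with counts above a threshold (default 0.9,
the conventional "divergence island" display cut) and set intersections of
outlier loci across comparisons. The scalar U-shape index is the package's
own convention: with m_low/m_high the mass below 0.1 / above 0.9 and m_mid
the mass in [0.3, 0.7), the index is
`(2·min(m_low, m_high) − m_mid) / (2·min(m_low, m_high) + m_mid)`.
Taking the *minimum* of the two extreme-decile masses is deliberate: a
drift-only distribution also piles mass in the lowest decile, and a plain
sum of the extremes would call it U-shaped; requiring mass at both ends
makes the index positive exactly for the two-sided pattern of divergence
with gene flow. Mass is apportioned to deciles by fractional bin overlap,
so the sign is stable across bin counts. The migration container only
converts mutation-scaled coalescent output (θ = 4N_e μ, M = m/μ) into
migrants per generation N_e m = θ·M/4; running a coalescent sampler is out
of scope, and the settings used to produce any external θ/M estimates
should be recorded alongside them.

## Diagnostic panels

A locus is diagnostic for a bipartition of groups when every group is
monomorphic at it (ignoring missing calls; a group with no data
disqualifies the locus) and the two sides carry different alleles.
Assay suitability requires the locus's allele sequences to differ at
exactly one position with ≥ 18 invariant bases on each side — an explicit,
parameterizable proxy for "suitable priming sites", which is
instrument-specific and cannot be derived from sequence alone. Panels take
the k (default 4) suitable loci with the highest support (smallest
per-group non-missing count), ties broken by locus id, so panel selection
is deterministic. Assignment intersects, over all observed panel alleles,
the groups compatible with each allele's side: a unique group is reported;
an empty intersection (including any heterozygous panel call, whose
two-side evidence is reported rather than collapsed) is a conflict, to be
discarded or examined as a putative hybrid; a partition with no
informative call makes the sample "insufficient" even if the other
partition is decisive.

## Elliptic Fourier morphometrics

Outlines are closed polygons (≥ 32 points; self-intersection is screened
and warned, not rejected). The decomposition is the chain-summation
elliptic Fourier formulation with arc-length parameterization; harmonics
are capped at floor(n_points/2) with a warning (the "399 harmonics"
convention of leaf-shape studies far exceeds what modest outlines
support). One consequence of arc-length parameterization, worth knowing
when validating against textbook formulas: an ellipse traced at uniform
speed is *not* a single-harmonic shape, so the first-harmonic semi-axes of
an eccentric ellipse differ slightly from its geometric semi-axes (for a
2:1 ellipse the first-harmonic ratio is ≈ 1.704). Tests therefore validate
coefficients against a direct Fourier-integral oracle rather than against
the geometric axes.

Normalization removes translation (offsets dropped), rotates the start
point and the coordinate frame so the first harmonic is an axis-aligned
ellipse traced from its semi-major axis (a1 > 0, b1 = c1 ≈ 0), and scales
by the semi-major length. The residual two-fold ambiguities (start point
± half a period; traversal direction) are resolved by enumerating the
candidates and keeping the lexicographically largest coefficient vector,
with reversal canonicalized to d1 ≥ 0 by default — making normalized
coefficients invariant to rotation, scale, translation, start point and
traversal direction (each to ~1e−8 in the tests, against a 1e−6
requirement).

Trait comparisons use one-way fixed-effects ANOVA per trait (between-group
mean square and F reported) with Tukey HSD letters at α = 0.05
(Tukey–Kramer adjustment for unbalanced groups, via statsmodels; the
compact letter display is built greedily from the pairwise rejections).
LDA uses priors proportional to class frequencies and standardizes
features to unit variance by default (a recorded choice; the source
analyses do not state theirs), refitting n times for leave-one-out
cross-validation. The terminal-leaflet shape PC is excluded from the LDA
feature set because it is nearly collinear with the terminal length:width
ratio (r ≈ 0.97 in the motivating data); the lateral-shape PC1 is used
instead.

## Synthetic-data generator

The generator is a two-level model chosen as the minimal structure that
reproduces the observed group-level statistics (the motivating study used
real data and reports estimates, not a generative model):

1. **Lineage ancestral frequencies.** A fraction of loci is assigned to
   lineage-specific "star" patterns — pattern i fixes the alternate allele
   in lineage i only — so pairwise fixed-difference fractions satisfy
   d_ij = f_i + f_j. Pairwise targets inconsistent with such patterns, or
   summing beyond 1, are rejected as infeasible. Remaining loci carry
   shared ancestral polymorphism with minor allele frequency
   0.5·Beta(a, b) and random allele orientation.
2. **Site frequencies.** Within each lineage, per-site frequencies follow
   the Balding–Nichols beta distribution with mean p and variance
   F·p(1−p), F the target among-site F_ST (fixed loci stay fixed; F = 0
   copies the lineage vector; fewer than two sites is an error).
3. **Individuals.** Genotypes are drawn with inbreeding coefficient
   F_IS = 1 − 2^−t after t selfing generations from a randomly mating
   base (t = ∞ gives complete homozygosity): P(het) = 2pq(1−F_IS),
   P(alt hom) = p² + F_IS·pq. Residual heterozygosity is thus modelled by
   the number of selfing generations, the mechanism-free summary the
   observed F_IS values support.
4. **Missing data.** The real missingness process is not characterized,
   so two independent per-call dropout rates (individual-level and
   locus-level) are exposed.
5. **Hybrids.** Injected by running the package's own cross/self
   operators on sampled parents (F1, F2, F3, or F1×parent backcross), so
   simulated truth and analysis share no shortcuts.
6. **Sequences, outlines, traits.** Each RAD locus gets a random 93-mer
   whose two allelic variants differ exactly at the recorded SNP offsets;
   a configurable fraction of loci carries a second, fully linked SNP
   (plausible under extreme linkage disequilibrium in selfers, and the
   mechanism by which loci fail the one-variable-site assay rule). Leaf
   outlines are star-shaped noisy ellipses rescaled to an exact target
   bounding-box aspect ratio; traits are normal draws from per-group
   means with SDs recovered from printed standard errors as SE·√n using
   assumed near-equal group sizes (25, 26, 25; total 76, matching the
   reported ANOVA df of 73). Hair counts are truncated at zero by
   default, with a Poisson alternative behind a flag.

### Calibration

Configurations are usually built from target summary statistics. For a
two-lineage design the helper solves, in closed form plus one scalar root
find, for the fixed-difference fraction d and per-polymorphic-locus
diversity hp = E[2pq] such that the *expected values of the estimators*
equal the targets under the model above:

* E[unbiased Ĥ_e] = (1−d) · hp · κ, with
  κ = N/(N−1) · [1 − F_ST/S − (1+F_IS)/(2N) − (1−F_ST)(1−F_IS)/(2N)]
  capturing the loss of pooled diversity to among-site drift (−F_ST/S for
  S sites) and the finite-sample terms for N individuals under
  inbreeding;
* E[plug-in Nei's D] uses J_xy = (1−d)(1−hp) (between-group products are
  unbiased) and J_x = d + (1−d)(1 − hp·c₁) with
  c₁ = 1 − F_ST/S − (1+F_IS)/(2N) (within-group squared frequencies are
  inflated by sampling variance).

Calibrating to the estimator expectation rather than to the raw parameter
is what makes the parameter-recovery suite a test of correctness instead
of a test of tolerance width: with 3,928 loci the seed-to-seed standard
error of Ĥ_e is ~2×10⁻⁴, smaller than the O(F_ST/S) ≈ 1.4% bias the κ
factor absorbs. The beta parameter b is then solved (given a = 1.2) so
that E[2pq] under 0.5·Beta(a, b) equals hp.

## What the generator does and does not emulate

It reproduces: near-zero H_o with moderate H_e (extreme selfing),
among-site structure at a target F_ST, planted fixed-difference fractions
(hence targeted Nei's D and U-shaped between-lineage per-locus F_ST),
rare hybrids of known pedigree, linked multi-SNP RAD loci, and group-level
trait/shape differences with realistic within-group spread. It does not
emulate: sequencing error or allelic dropout correlated with depth, linkage
disequilibrium between *different* RAD loci, selection (divergence islands
are planted, not evolved), site-specific lineage composition, or leaf-shape
features beyond the aspect-ratio family (lobing, serration). Passing tests
therefore certify the estimators and the pipeline logic on data with the
right first- and second-order statistical structure, not robustness to
every artifact of real reduced-representation data.

## Problem sizes and defaults

Defaults mirror the motivating study's scale: 3,928 loci, three lineages
across seven sites, 1000 simulated individuals per hybrid class, α = 0.05,
F_ST threshold 0.9, panels of four loci per bipartition, 20 harmonics for
synthetic outlines (399 is accepted and capped by the Nyquist rule).
The test suite uses these sizes where the check depends on them (hybrid
classification, parameter recovery at 20 seeds) and smaller matrices for
exact oracle comparisons.

## Known limitations

* The hybrid-index interval is a 2-log-likelihood support region, not a
  calibrated confidence interval; under few informative loci it can be
  wide and asymmetric.
* The classification fallback labels ("parental", "backcross-like",
  "uncertain") use fixed conventions (h cut at 0.1/0.9; heterozygosity
  floor at a quarter of the smallest class mean) that are sensible for
  strongly diverged, highly inbred parents and untested outside that
  regime.
* Allelic-richness rarefaction uses a single global gene count; groups
  with very uneven missingness rarefy to the worst case.
* The PCA-intermediate hybrid-candidate rule is a heuristic for
  automation; low-divergence lineage pairs will need the threshold
  loosened or candidates supplied explicitly.
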