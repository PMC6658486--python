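# Methods

This note documents the models, estimators and numerical choices behind
`patchkin`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where the design was genuinely open.

## Genotypes and locus filtering

Genotypes are diploid biallelic SNP calls stored as an N×L dosage matrix
(copies of each locus' lexicographically smaller allele; −1 missing), so
every supported file dialect (slash calls, two-column alleles, VCF)
normalizes to the same object. Missing data are handled pairwise-complete
throughout; nothing is imputed.

The Hardy–Weinberg filter uses the exact conditional test: given the
allele counts, the heterozygote count follows the Levene–Haldane
distribution, P(h) ∝ 2^h n!/(n₁! h! n₂!), and the two-sided p-value sums
the probabilities of all heterozygote counts no more probable than the
observed one (with a 1+1e−12 relative tolerance on the "no more probable"
comparison, which protects ties against floating-point noise; log-space
evaluation via `gammaln`). Monomorphic loci return p = 1 by convention.
The test is conservative by construction; under Hardy–Weinberg sampling
(p = 0.5, n = 100) its rejection rate at α = 0.05 stays below 0.06.

Filter defaults: drop loci with exact-test p below 0.05/L (Bonferroni
across loci — unfiltered, a 192-locus panel would reject ~10 loci by
chance alone), then greedily prune one locus of each pair with dosage
r² > 0.8, keeping the better-typed member (ties: the smaller column
index survives). Both thresholds are conventional and configurable; the
filter writes a report rather than acting silently, and is idempotent.

## Pairwise relatedness

The Queller–Goodnight estimator relative to reference allele frequencies:
per locus, with focal alleles (a,b) and partner alleles (c,d),

    num = ½(δ_ac + δ_ad + δ_bc + δ_bd) − p_a − p_b
    den = 1 + δ_ab − p_a − p_b .

The multilocus, symmetrized estimate pools numerators and denominators
over loci **and both focal directions** before dividing (ratio of sums).
This keeps pairs informative even where a single-locus denominator is
zero (e.g. two heterozygotes at p = ½ contribute (0,0)) and is stable
when one direction's denominator sum is small. Reference frequencies come
from the whole cohort including the focal pair; an externally supplied
frequency vector is accepted for sensitivity checks. Pairs with zero
pooled denominator are masked. For dosage data the per-locus terms reduce
to polynomials in the two dosages, so the full matrix is computed with a
handful of matrix products; the vectorized path is tested to 1e−12
against a naive per-pair, per-allele double loop.

Expected values under the estimator: full sibs and parent–offspring pairs
≈ 0.5, unrelated pairs ≈ 0 (slightly negative within a finite cohort,
since the cohort-referenced values must average near zero). At 178 loci
the pairwise sampling noise is roughly ±0.05 (1 sd).

The relatedness ratio of individual i is #{j : r_ij > 0.1}/(N−1) over
defined pairs — the threshold is strictly "above 0.1". The quantile
classifier labels the k = round-half-up(q·N) highest ratios 'local' and
the k lowest 'recent migrant' (q = 0.25 by default, 0.10 as the
alternative); round-half-up makes a 627-individual cohort yield exactly
157 + 157. Ties are broken by stable input order with a warning, and the
two sets are disjoint by construction.

## Spatial Gaussian mixture

Coordinates are projected from WGS84 degrees to meters with a local
equirectangular projection about the centroid (x = R·Δλ·cos φ₀,
y = R·Δφ, R = 6 371 000 m); at 41°N a degree of longitude is ~25%
shorter than a degree of latitude, so fitting isotropic-looking models in
degrees would distort shapes. The projection is exactly invertible.

EM details: full 2×2 covariances; covariance regularization
+1e−6·trace·I (+1e−12·I floor); convergence at |ΔlogL| < 1e−6; at most
500 iterations. Initialization is a seeded random partition with
distance-weighted (k-means++-style) seed spreading followed by
nearest-seed grouping. Two plainer schemes fail in ways worth recording:
uniformly random labels put every initial component at the global
centroid, where EM stalls at a symmetric saddle for well-separated tight
clusters; uniformly drawn seed points miss one of K equal clusters with
high probability (coupon collector — only ~1.5% of draws cover 6 equal
blobs with 6 seeds). Components whose weight falls below 1e−3 are dropped
and EM continues, so the effective K can be smaller than requested; the
log-likelihood is non-decreasing between (rare) drop events, and drop
iterations are recorded on the fit.

Model selection: AIC = 2k − 2 lnL with k = 2K + 3K + (K−1) = 6K − 1 free
parameters at effective K, minimized jointly over all runs and component
counts (defaults: K ∈ {4,5,6}, 10 seeded runs each). AIC is permissive —
with fewer planted clusters than max(K), it may accept a small extra
component for a chance clump — so the chosen labeling is validated in
tests by adjusted Rand index against planted truth rather than by K
alone. Components of the chosen fit are re-ordered by increasing mean x,
so labels run SW→NE along a coastline-oriented frame. MAP ties go to the
lowest component index.

## Normalization, rIN/rOUT, and binary clustering

Relatedness is min–max rescaled using the observed extremes a = min r,
b = max r. The default, order-preserving map is d = (r−a)/(b−a); the
literal-inverted mode d = 1 − (r−a)/(b−a) is also provided. The two modes
disagree about orientation: under the inverted map, high relatedness
becomes *low* d, so with the fixed code→category map (HH→MIXED, HL→SHORT,
LH→MEDIUM, LL→LONG) switching modes exactly swaps MIXED↔LONG and
SHORT↔MEDIUM. The order-preserving default keeps the axes readable as
relatedness, matching the verbal category semantics ("high rIN" = high
relatedness within the cluster); the inverted mode exists for parity with
pipelines that used the inverted formula. Because categories depend on r
only through this normalization, they are invariant under any increasing
affine rescaling of r.

rIN_i is the mean d over i's own spatial cluster (excluding i); rOUT_i
the mean over everyone else; masked pairs are excluded from both.
Members of singleton clusters (rIN undefined) or of a cluster covering
the whole cohort (rOUT undefined) are flagged invalid and reported as
UNASSIGNED rather than dropped. rOUT includes all non-cluster members
with defined d, whether or not their own rIN is defined. Cohorts (adults,
juveniles) are processed separately end to end.

The binary clustering fits a 4-component full-covariance Gaussian mixture
to the (rIN, rOUT) cloud by EM, from several quadrant-split starts (axis
cuts at the median and the quartiles, plus seeded random assignments).
Components are assigned binary codes by corner matching: corner
prototypes are built from per-axis lower/upper half means, and the
component→corner bijection minimizing total squared distance over all 24
permutations is taken. Per-axis delimiters sit where the weighted 1-D
marginal densities of the L-coded and H-coded components are equal
(bisection between the group means to 1e−9, with a grid scan fallback if
the bracket has no sign change, and the group-mean midpoint as a last
resort). Individuals get the code of their MAP component.

Fit selection is constrained maximum likelihood: among the converged
starts, the highest-likelihood fit whose smallest component weight is at
least 0.03 wins; fits with a near-empty component are used only if
nothing better converged. The constraint is what makes the clustering
*binary*: each of the four low/high regions must be carried by a real
component. An unconstrained mixture will sometimes spend a component on a
sliver of density or split one heavy cloud along an uninformative
direction — slightly better likelihood, meaningless low/high semantics.
On realistic relatedness data the dominant nuisance direction is a
"genotype commonness" ridge: an individual's mean relatedness to
everybody varies with how common its own alleles are (sd ≈ 0.02–0.03 in
normalized units at 178 loci), which elongates all four classes along the
rIN = rOUT diagonal. The kin signal that separates SHORT-range dispersers
lives on the perpendicular rIN − rOUT axis, where the commonness
component cancels.

## Life history

Age is regressed on body length by ordinary least squares over the
otolith-read subset (prediction target is age, so no inverse regression),
and predictions are rounded to whole days (clipped at 1) so hatch dates
are calendar dates; lengths outside the calibration range are flagged as
extrapolations. Hatch date = collection date − age. Season cohorts:
'early' hatchers in [Apr 1, May 15], 'late' in [Jun 15, Sep 7]; the
verbal window bounds ("mid-May", "beginning of September") are fixed to
those dates by convention and are configurable. Settlement classes:
recent settlers < 30 mm and < 30 d; survivors > 35 mm and > 50 d; the
deliberate gap between the rules leaves intermediate fish as 'neither',
and the classes cannot overlap. PLD–hatch-date association is Pearson
correlation of PLD against hatch day-of-year.

Cohort contrasts default to Welch's t (unequal n and variance;
Satterthwaite df), with the degenerate both-constant-equal-means case
defined as t = 0, p = 1. Spatial distributions are compared with the
two-sample Kolmogorov–Smirnov test after projecting the meter-frame
coordinates onto the first principal axis of the pooled cloud, oriented
SW→NE — the sampling area is a quasi-one-dimensional coastline, and a 1-D
KS on its principal axis is the package's documented convention (2-D KS
variants are out of scope). KS p-values use the exact small-sample
distribution when feasible, otherwise the asymptotic Kolmogorov
distribution. Note that at equal group sizes the KS statistic is coarsely
quantized; null p-value uniformity holds only for unequal (ideally
coprime) sizes. No multiple-testing correction is applied across the
report's comparisons.

## The synthetic-data generator

The generator emulates the statistical structure of a dense coastal
cohort sample with planted truth at every stage. Defaults describe the
study conditions and were fixed by the design analysis below.

- **Scale:** 627 individuals, 178 loci, 6 spatial clusters along a
  SW→NE coastline axis (spacing 330 m, isotropic sd 30 m — 11σ
  separation, ~2 km total, bearing 40°), 2% missing calls, 200
  otolith-read fish.
- **Base frequencies:** p ~ U(0.1, 0.9) i.i.d. Immigrant source
  frequencies follow the Balding–Nichols model, p′ ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F) with F = 0.1, then are shifted 35% toward each locus'
  locally-minor allele. The shift models local ascertainment of the SNP
  panel: markers developed in the focal population carry alleles that are
  rarer elsewhere. It matters for the method's semantics — under pure
  Balding–Nichols divergence the expected Queller–Goodnight relatedness
  between an immigrant and a local, referenced to cohort frequencies with
  a small immigrant fraction, is ~0, not the low value the LONG category
  is built on; the rarity shift is what gives immigrants their (low rIN,
  low rOUT) signature.
- **Classes (per-cluster proportions):** SHORT rises SW→NE
  (0.20 … 0.60 by default) and trades against MEDIUM; MIXED (0.25) and
  LONG (0.07) are constant per cluster so the rIN/rOUT baselines do not
  drift along the coast. SHORT members are full-sib family blocks
  retained in their natal cluster; each family exports at most one mover
  per non-natal cluster (MEDIUM), so movers carry no sib co-placement
  signal; leftover MEDIUM demand is met by scattered all-mover families.
  MIXED are unrelated singles drawn from frequencies shifted 35% toward
  the major allele ("common genotypes"); LONG are the immigrants, placed
  uniformly.
- **Families:** two Hardy–Weinberg parents per family, offspring by
  Mendelian transmission (audited in tests); default family size 24 with
  stayer counts balanced across a cluster's families. The size is set by
  a detectability analysis: a SHORT member's rIN elevation is
  ≈ (s−1)·Δd/(n_c−1) with s stayers, cluster size n_c ≈ 105 and sib
  contrast Δd ≈ 0.42 in normalized units, while the per-individual noise
  on the rIN−rOUT axis is ≈ 0.015; balanced stayers ≥ 14 keep the
  separation above ~3.5σ in every cluster, including the low-SHORT SW
  end. Large surviving full-sib cohorts are plausible for a marine fish
  with clutch sizes in the thousands; what matters here is the planted
  effect size, not demographic realism.
- **Traits:** hatch days uniform over the spawning season (Apr 1–Jul 31);
  PLD = 25 − 0.05·hatch_day + N(0, 2²), floored at 5 d — which makes
  mean PLD ≈ 19.4 d for early hatchers vs ≈ 15.7 d for late ones, a
  ≈ 3.8 d gap, and a PLD–hatch-day correlation ≈ −0.67; age adds a
  uniform 0–80 d post-settlement tenure; length = 15 + 0.45·age +
  N(0, 4.5²) mm, giving an age–length Pearson R ≈ 0.91 and settlement
  classes on both sides of the rule gap. Otolith sizes at hatching
  (~12 µm) and settlement (~120 µm) are plausible constants with noise
  and carry no planted signal.

All randomness flows from one root seed through named substreams
(frequencies, immigrants, composition, genotypes, placement, traits,
missingness, otolith subset), so outputs are byte-identical given a seed
and each stage is independently reproducible.

**What the generator does not emulate:** linkage and genuine LD between
loci (loci are independent; the LD filter is exercised on constructed
duplicates), genotyping error, null alleles, coalescent ancestry beyond
single full-sib families, isolation-by-distance within clusters,
hydrodynamic larval transport, temperature itself (the PLD decline is a
reduced-form linear model), and selective mortality. Passing end-to-end
tests therefore demonstrate that the pipeline recovers planted structure
of the stated effect sizes under clean assumptions — not that real data
of this size always carry recoverable signal.

## Recovery performance and known limitations

On the default configuration the pipeline recovers the planted
per-cluster SHORT proportions within ±0.06 on most seeds (worst observed
±0.13 across a 12-seed panel, driven by one cluster whose families drew
unusually uninformative parents) and always recovers the SW→NE gradient
sign. MEDIUM and LONG are only partially separable from each other —
both sit near the centre/low end of the commonness diagonal — so their
individual proportions are less reliable than SHORT's and MIXED's; the
four-corner geometry is sharpest exactly where the planted structure is
strongest. Relatedness-ratio 'locals'/'recent migrants' counts are exact
by construction; their composition inherits the noise of pairwise
relatedness at 178 loci. The spatial mixture recovers planted clusters at
≥10σ separation essentially perfectly; with overlapping clusters AIC may
over- or under-split, which propagates into rIN/rOUT (a misassigned
individual's rIN mixes clusters). Problem sizes throughout the tests and
the acceptance script (N ≈ 600, L = 178, 10⁴ statistical replicates)
were chosen as the smallest that exercise every claim at the study's own
scale.
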