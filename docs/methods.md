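# Methods

## The model

Structural covariance treats the inter-individual correlation of regional
gray-matter volumes within a population as a proxy for coupling between
regions. For a group g with n_g subjects, the association matrix is the
Pearson correlation of residualized volumes: each region's column is
replaced by its least-squares residual against an intercept plus age, sex,
education and total brain volume, and the full region × region correlation
matrix of those residuals is the group's network. Adjustment is fitted
*within* each group — pooling the regression across groups would let group
mean structure leak into the residuals and inflate within-group
correlations. Sex and education enter as numeric codes (configurable);
no harmonization or partial-volume corrections are applied.

Assumptions worth stating: linearity of the covariate effects, a common
covariate model across regions, and enough subjects per group for the
correlation estimates to be meaningful (the code enforces
n ≥ covariates + 3 per group, and ≥ 8 per group for inference).

## Thresholding and topology

Association matrices are reduced to undirected binary graphs by keeping
the k = round(d·N(N−1)/2) edges with the largest *signed* correlation at
each density d (positive-first is the structural-covariance convention;
an absolute-value mode is not provided because negative edges are rare at
analysis densities — when a density does demand them a warning is
emitted). `round` is half-away-from-zero, which matters at exact halves.
Ties at the cut break by (row, column) lexicographic order of atlas
indices, so a graph is a pure function of the weights and the atlas
order. One edge ranking serves the whole grid, which makes edge sets
nested along densities and degree curves monotone.

The analysis grid runs from D_min — the smallest grid-aligned density at
which every group's graph has a single connected component — to D_max in
2 % steps. "Connections becoming progressively more random" does not pin
down an operational D_max, so the default is a fixed upper bound of 0.50,
recorded in the run metadata; if D_min exceeds it (possible on very small
atlases) the grid collapses toward D_min.

Metrics: nodal degree (row sums), unnormalized betweenness (Brandes
accumulation; a 4-node star's center scores C(3,2) = 3), characteristic
path length (mean shortest-path length over *connected* ordered pairs,
with a connectivity flag — permutation replicates may be disconnected and
are kept, not discarded), global efficiency (mean inverse distance,
disconnected pairs contributing 0), binary local clustering and its mean,
and small-worldness σ = (C/C_rand)/(L/L_rand). Implementations are
straight numpy/scipy array code because the permutation engine evaluates
them tens of thousands of times; the test suite checks every metric
against exhaustive pure-python enumeration on all 208 isomorphism classes
of graphs with ≤ 6 nodes, and against networkx on random instances.

Hubs default to degree > mean + 2·SD across nodes (k configurable); the
criterion is a convention, not a calibrated test.

## HQS null models

Null networks come from the Hirschberger–Qi–Steuer construction:
C = BBᵀ with B an N × m matrix of i.i.d. normal(μ, σ²) entries, which is
positive semi-definite by construction and matches the observed
off-diagonal moments through m·μ² = ē and m·(σ⁴ + 2μ²σ²) = v̄, giving
μ = √(ē/m) and σ² = −μ² + √(μ⁴ + v̄/m). The factor count m is not fixed
by the moment identities; the default m = clip(round((d̄² − ē²)/v̄), 2, N)
matches the diagonal scale and is logged. Draws are rescaled to
correlation form before thresholding so null and observed graphs are
binarized under identical rules (hence identical edge counts). Each group
gets nulls matched to its own moments. The construction requires a
positive off-diagonal mean; a negative mean fails loudly rather than
silently switching to |r|. The default is 20 nulls per group.

A subtlety found while validating the generator: the within-draw sample
variance of C's off-diagonals is a *biased-low* estimator of the ensemble
variance (entries of one draw are correlated through the shared B and are
centered on the draw's own mean), so moment checks estimate the variance
as the mean squared deviation about the known target mean.

## Permutation/FDA inference

For a metric evaluated along the density grid, the test statistic per
node (or per global metric) is the curve sum S = Σ_d (m_a(d) − m_b(d)).
Group labels are permuted preserving group sizes, and the *entire*
pipeline — residualization, correlation, thresholding, metric curves — is
re-run inside every replicate, so the null distribution includes
adjustment variability. Two-sided p-values use the add-one rule
p = (#{|S*| ≥ |S_obs|} + 1)/(B + 1), which cannot reach zero; B defaults
to 1000. The raw sum (not a normalized area) is used; on a fixed grid
they differ by a constant factor and give identical p-values. A
t-standardized per-density variant is not provided.

Nodal p-values are BH-corrected within the analyzed node family, which
defaults to the 18 amygdala subnuclei (whole-brain correction is a
parameter away: pass the full region list as the scope).

## The covariance-comparison cascade

Stage 1: per subnucleus, the Fisher-z profile (one z per non-subnucleus
partner; 87 with the default atlas) is compared across the three groups
by a tie-corrected Kruskal–Wallis test, gated at p ≤ 0.02 (0.05 split
over three group comparisons; the constant is a parameter). Stage 2:
Dunn's rank tests with tie correction pick the driving group pairs
(unadjusted, gate role only, p ≤ 0.05). Stage 3: for each surviving
(subnucleus, group pair), every partner region's correlations are
compared as independent correlations,

    Z = (atanh r₁ − atanh r₂) / √(1/(n₁−3) + 1/(n₂−3)),

with Zou's interval for r₁ − r₂ assembled from the per-group Fisher CIs,
and BH correction within the 87-region family. The n − 3 weighting uses
the group sample sizes as-is despite the four adjustment covariates — it
reproduces the statistics a practitioner computes from reported r and n;
a covariate-adjusted df variant would subtract 4 more and is deliberately
not the default. Correlations at ±1 are clamped to ±0.999999 with a
warning before atanh. With exactly two groups the omnibus stages are
skipped; passing `gate_alpha=None` / `dunn_alpha=None` disables the gates
explicitly.

**Caveat.** The omnibus stage treats the 87 profile values as
exchangeable observations, but they share the subnucleus and are strongly
mutually dependent, which makes the Kruskal–Wallis gate anticonservative:
with identically generated groups most subnuclei pass the 0.02 gate. The
gate is therefore a screening device inherited from the procedure it
reimplements, not a calibrated test; inferential weight rests on the
FDR-corrected stage-3 comparisons, whose Fisher/Zou machinery *is*
calibrated (and whose significance decisions agree with the Zou interval
excluding zero in > 95 % of a |r| ≤ 0.9 grid — the two are approximately,
not exactly, equivalent). Zou CIs are reported at 95 % regardless of the
FDR level.

## The synthetic generator

Volumes are generated as
`v = μ_region + sd·z + Σ_c γ_c (c − c̄) + noise`, where z is a
unit-variance latent field from a factor model: every region loads on a
shared positive factor (loading 0.55, unique noise SD 0.85, giving a mean
off-diagonal adjusted correlation ≈ 0.28 — the positive-mean covariance
the analysis assumes), secondary factors (N(0, 0.15) loadings) add
between-pair variability, and covariates are drawn independently (age
18–55, sex Bernoulli(½), ordinal education, TBV ≈ 10⁶ mm³ scale; an
imbalanced mode mimics the study's demographic skew — mostly-female
PTSD group, younger controls — and is off by default). Region baselines
are class-specific (cortical ≈ 8000 mm³, subcortical ≈ 4000, subnuclei
≈ 300, ±30 % per-region). Covariate effects are small standardized
coefficients recoverable by OLS, so residualization provably removes
them.

Planted effects are extra factor columns, never post-hoc matrix surgery,
so the implied covariance stays PSD by construction:

- a **planted pair** (a, b) with target ρ in a group gets a dedicated
  factor with loadings (s, ±s); with shared loadings (l_a, l_b) and unique
  variance v, the pair correlation (l_a l_b ± s²)/√((l_a²+s²+v)(l_b²+s²+v))
  runs monotonically from the baseline toward ±1 as s grows, so any
  target in (−1, 1) is solvable (closed form when l_a = l_b, bracketed
  root otherwise). Side effect: the extra variance attenuates the planted
  regions' correlations with third regions, so a plant also perturbs the
  rest of those two rows — visible at small n.
- a **planted hub** replaces one region's shared loading in one group.
  The scenario default is loading 2.0 (communality ≈ 0.85, mean partner
  correlation ≈ 0.49 vs ≈ 0.28 baseline). The magnitude is a design
  choice: a node's whole profile fluctuates coherently by ~1/√n because
  its own residual correlates with the factor in-sample, so at n = 60 per
  group a hub must shift its profile by ≳ 0.2 to dominate 17 competitor
  subnuclei reliably — i.e. the scenario plants an effect of the size the
  analysis can actually detect at these sample sizes.

Canned scenarios: `make_recovery_spec` plants one pairwise difference
(0.9 in the non-exposed group vs 0.7 in both trauma groups) on a
subnucleus whose shared loading is also raised in that group — a single
differing pair among 87 dependent profile values cannot move a rank test,
so the recoverable scenario couples the pair difference with the
profile-wide shift that real gated subnuclei show. `make_fixture_small`
is a deterministic 30-subject, 8-region cohort; with 10 subjects per
group its planted contrast is deliberately extreme (0.95 vs −0.6,
expected Fisher Z ≈ 4.7) so that detection is designed-in rather than
borderline.

What the generator does **not** emulate: segmentation error and scanner
effects, non-linear covariate effects, non-Gaussian volume distributions
(the cascade's rank tests are exercised, but their robustness rationale —
real volumes are skewed — is not stressed), spatial autocorrelation
beyond the factor structure, and missing data. Passing recovery tests
therefore shows the pipeline detects the effects it models, not that real
cohorts are this clean.

## Test and acceptance problem sizes

The package's own checks run at sizes chosen to make their statistics
meaningful yet quick: graph-metric oracles enumerate all ≤ 6-node graphs;
HQS moments use 200 draws at 40 regions; permutation calibration uses two
identical groups of 40 on the 8-region atlas (200 permutations × 50
repetitions, rejection count compared to the binomial 95 % interval at
α = 0.05); recovery uses 25 seeds at the study's group sizes (59/78/73)
on the full 105-region atlas for the cascade and 60/60 for the hub.
Worked-example reproduction feeds published correlation pairs (printed to
2 dp) and group sizes into the Fisher comparison; agreement is asserted
within the discrepancy that 2-dp rounding permits — ±0.005 on r maps to
±0.005/(1−r²) on atanh r, which exceeds a flat 0.05 band on Z for the
high-|r| rows.

## Known limitations

- The KW gate's anticonservativeness (above) means cascade output on null
  data contains gated subnuclei and, across many 87-region families,
  occasional FDR-level false positives; interpret `significant_pairs()`
  per family.
- D_max and the hub criterion are conventions; both are parameters.
- The pipeline's runtime is dominated by the permutation engine; nodal
  degree uses an incremental-sort fast path, but betweenness/path-length
  FDA over 1000 permutations on 105 regions is minutes, not seconds.
- `fisher_z` refuses |r| ≥ 1 rather than clamping; the cascade clamps at
  ±0.999999 with a warning because profile values of exactly ±1 occur in
  degenerate (collinear) inputs.
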