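# Methods

This note documents the statistical procedures implemented in `lmadecomp`,
the assumptions behind them, the defaults of the synthetic-data generator,
and the numerical choices that a maintainer or reviewer would want stated.

## Trait identities and units

All volume-per-area quantities (tissue VA, LVA) are carried in mL m⁻²,
which is numerically identical to thickness in μm, so no unit conversion is
ever applied between the two labels. LMA (g m⁻²), LVA and LD (g mL⁻¹) obey
LMA = LVA × LD exactly; when a table supplies only LMA and LVA, LD is
derived as their ratio (and flagged as derived). When all three are
supplied the supplied LD wins and a disagreement beyond 10⁻⁶ relative is
logged, because LD may have been computed upstream from independently
measured thickness. Measured LVA and the sum of measured tissue VAs come
from different measurements (thickness transects vs. cross-section areas),
so record-level consistency between them is checked against a configurable
relative tolerance with a 5% default rather than asserted exactly.

Soil water content is gravimetric: per sample, (fresh − dry) mass in grams
equals the water volume in mL; dividing by the auger cross-section in cm²
and converting (1 mL cm⁻² = 10 L m⁻²) gives L of water per m² of ground,
averaged over the site's samples. C and N concentrations are stored in
mg g⁻¹; every regression involving them is scale-invariant, so the unit
choice affects no reported statistic.

## Variance partition without covariation

For a response y and predictors x₁…x_k, the full additive OLS model gives
SS_error and SS_model. Each predictor's unique sum of squares is the
leave-one-out increment SS_model(full) − SS_model(full \ {xⱼ}); the pooled
covariation term is SS_model(full) − Σ uniques. This makes
SS_total = Σ uniques + covariation + SS_error an identity, so the
percentage partition closes to 100 by construction (tested to 10⁻⁶). The
reading of the two-factor ANOVA-style decomposition as leave-one-out unique
components is the only one under which the closure identity holds for
correlated regressors; it coincides with all-subsets commonality analysis
with the common components pooled, which the test suite verifies by brute
force (solving the 2^k−1 commonality system) to 10⁻⁸ relative on random
instances up to n = 100, k = 4.

Choices: the x₁·x₂ interaction is off by default and enters, when
requested, as a third component with its own unique share. Negative unique
or covariation shares (suppression) are reported with a warning and never
truncated — truncation would silently break closure. Missing values are
deleted listwise per model so that SS_total is identical across all
sub-models. Significance tiers are the field's conventional
{0.10, 0.05, 0.01, 0.001} bands, with `+` marking the marginal
0.05 < P < 0.10 band; all p-values are two-sided.

## Phylogenetic comparative methods

**Covariance.** Under Brownian motion the expected trait covariance of two
tips is the shared root-to-tip path length; `brownian_vcv` builds this
matrix directly from node depths. Pagel's λ multiplies the off-diagonal
entries; `fixed_1` (full Brownian) is the default and `ml` estimates λ by
restricted maximum likelihood on a 21-point grid over [0, 1] followed by
bounded local refinement — a coarse-then-fine scheme that avoids the flat
or multimodal profiles small trees produce.

**PIC.** Felsenstein's recursion: contrast (x_i − x_j)/√(v_i + v_j) at each
internal node of the polytomy-resolved tree, ancestral value as the
branch-length-weighted average, branch augmentation v + v_i v_j/(v_i+v_j).
Polytomies are resolved deterministically (first two children grouped under
a zero-length branch, repeatedly), which leaves contrasts well defined and
their count equal to tips − 1. Zero-length terminal branches are perturbed
by 10⁻⁸ × tree depth with a warning, for the contrasts only. The
implementation is checked against values from an independent implementation
of the same recursion (R's `ape::pic`) frozen into the test suite, and
against the theorem that the λ=1 PGLS slope equals the through-origin
regression of y-contrasts on x-contrasts (10⁻⁸ on random trees).

**PGLS.** GLS via Cholesky whitening: β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y with an
intercept, t-tests on n − p degrees of freedom. Several R² conventions
exist for GLS; here R² = 1 − RSS_gls/TSS_gls with both sums on the
whitened scale and TSS from the GLS intercept-only model — this reduces
exactly to OLS R² on a star phylogeny. A singular covariance (e.g. a
zero-length cherry duplicating rows of C) is reported with the offending
taxa rather than regularized. The deciduous/evergreen comparison is PGLS of
the trait on a 0/1 evergreen indicator, which on a star tree is the
ordinary two-sample comparison.

**Phylogeny dependence.** A pairwise relationship is *absent* if the
ordinary regression is not significant at α; otherwise *independent* if
the companion PGLS is also significant, *dependent* if it is not. The flag
is attached to every network edge rather than encoded in a line style.

**Branch-length adjustment.** Given ages for the root and any subset of
labelled internal nodes (tips at age 0), undated nodes are assigned ages in
preorder: each interpolates between its (already aged) parent and the
oldest dated node below it reachable without crossing another dated node,
spaced evenly by the count of undated nodes on that path. On a bare chain
this is exact even spacing; choosing the *oldest* lower anchor guarantees
monotone ages and hence non-negative branch lengths. Branch lengths are
then parent-minus-child ages, so the output is exactly ultrametric, dated
nodes keep their ages, and re-running the adjustment is the identity. Age
inversions (a dated node older than its nearest dated ancestor) are
rejected.

## Correlation networks

Edges require both p < α (default 0.05) and |r| > 0.5: at n ≈ 34 the
p-gate alone would admit |r| ≈ 0.34 edges, so the |r| gate is the binding
one, and under independent traits the per-pair false-edge rate equals
P(|r| > 0.5) under the exact null distribution of Pearson's r (verified by
simulation). Strength classes bin |r| at 0.5, √0.5 and √0.75 — the R²
quartiles 0.25/0.50/0.75. No multiple-testing correction is applied by
default (a Holm option exists). The default trait set is LMA, LVA, LD, the
four grouped tissue VAs, the four volume fractions, and C and N
concentrations; constant traits are dropped with a warning.

## Synthetic-data generator

The generator emulates a species-mean community study, not individual
leaves. One master seed drives four independent child streams (tree,
habits, traits, sites) so stages can be regenerated in isolation and a
dataset is bit-reproducible.

- **Tree**: Yule (pure birth) with exponential waiting times, depth
  normalized to 1; 34 tips by default.
- **Habits**: the largest clade of at most `n_evergreen` (default 20) tips
  seeds the evergreen set, topped up with the patristically nearest outside
  tips — leaf habit is phylogenetically clustered, as in real Mediterranean
  floras where sclerophylls concentrate in particular lineages.
- **Tissues**: each tissue's log VA follows Brownian motion (rate `sigma2`
  per unit depth) around a configured baseline, exponentiated; evergreens
  get a +0.4 log (×1.49) mesophyll offset. Evolving on the log scale keeps
  volumes positive and makes habit offsets multiplicative.
- **Density and mass**: tissue densities are drawn per species around class
  means (epidermis 0.3, mesophyll 0.3, vascular+sclerenchyma 1.0, air
  exactly 0 g mL⁻¹); LD is the exact fraction-weighted mean and
  LMA = LVA × LD exactly.
- **Chemistry**: C and N are linear in the mesophyll and vascular fractions
  plus Gaussian noise — N negatively, so high-LMA leaves are N-poor.
- **Sites**: soil water content is coupled to log LMA through a Gaussian
  copula targeting correlation −0.5, then mapped to the configured range
  (100–500 L m⁻²); the copula reproduces the correlation structure of a
  moisture gradient without asserting a causal mechanism. The uniform
  margin attenuates the realized Pearson correlation by √(3/π) ≈ 0.977, so
  the expected sample correlation is ≈ −0.49, within the ±0.05 calibration
  band the tests check.

`sigma2` defaults to 0.04 (log-scale variance per unit depth). This value
was fixed by a design-stage power analysis: the generator is required to
make its own built-in effects recoverable — in particular the evergreen
mesophyll offset must be detected by the PGLS habit contrast in ≥ 90% of
replicates, a demanding target because clustered habit and Brownian noise
are partially confounded on a tree. At 0.04 the detection rate is ≈ 94%
while the mesophyll term still dominates the thickness partition in
essentially every replicate.

**What the generator does not emulate.** Generated LMA spans roughly
75–155 g m⁻², narrower than the several-fold ranges real regional floras
show, a direct consequence of the modest Brownian rate chosen above and of
tissue-level independence (summing six independent lognormals shrinks
relative spread). Because LD is built mechanistically from fractions and
densities, LD and LVA are *negatively* correlated here (thick leaves are
mesophyll- and air-rich, hence lighter per volume), giving the LMA
partition a negative covariation term; field datasets often show LD and
LVA varying independently. LD also carries a smaller share of LMA variance
than LVA, so its correlations with LMA and with soil water are
correspondingly weaker than LVA-driven ones. There is no measurement
error, no intraspecific variation, and exactly two habit classes. Passing
tests therefore demonstrate correctness of the estimators and the internal
consistency of the pipeline under a known truth — not that any particular
field system behaves like the defaults.

## Numerical conventions and degenerate inputs

- Rank-deficient designs are rejected with the collinear columns named;
  zero-variance responses yield slope 0, R² 0 and tier `ns` rather than
  NaNs.
- Partitions require a strictly positive SS_total.
- All-zero tissue profiles have undefined volume fractions and are
  rejected; negative measured VAs are rejected, not clamped, since they
  indicate upstream digitization errors.
- Tip labels are matched after whitespace/underscore normalization; species
  missing from the tree abort the analysis with the offenders listed.
- Group analyses require ≥ 4 species (regressions) or ≥ 5 (networks,
  partitions with more predictors); smaller groups are skipped with a
  warning in the pipeline and are errors when requested directly.

## Problem sizes used by the test and acceptance runs

The bundled checks run at the scale of the study design they emulate:
34-species datasets, trees up to 40 tips, 100–500 generator replicates for
Monte-Carlo summaries, and 200 random instances (n ≤ 100, k ≤ 4) for the
partition-vs-commonality equivalence. These sizes were chosen as the
smallest at which the sampling distributions of the checked quantities are
tight enough for the stated tolerances.
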