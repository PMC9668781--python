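# Methods

## The statistical model

Every trait is analysed one at a time with the linear mixed model of an
augmented block design replicated over environments (trial-years):

```
y_ijk = µ + T_k′ + E_i + B_(i)j + T_(j)k + GE_ik + ε_ijk
```

The genotype effect splits into the **fixed** effect of a common check
cultivar `T_k′` (checks are replicated in every block and calibrate block
and trial effects) and the **random** effect of an unreplicated test clone
`T_(j)k ~ N(0, σ²g)`. Environments `E_i`, blocks nested in environments
`B_(i)j`, genotype-by-environment cells `GE_ik` and plot errors are
independent Gaussians with their own variances. The fixed part is coded as
an intercept plus one treatment contrast per check, so `µ̂` is the
test-population mean and BLUP + `µ̂` is directly comparable across traits.
The G×E incidence is built only over genotype–trial combinations actually
observed.

### REML implementation

With variance ratios `γ_t = σ²_t/σ²_e`, the residual variance and the
fixed effects profile out of the restricted likelihood. Writing
`W = [X Z]` and `M(γ) = W′W + diag(0, 1/γ)`, one factorisation of `M`
per evaluation yields

```
-2ℓ_R = (n−p)·log σ̂²_e + log|M| + Σ_t q_t·log γ_t + (n−p)(1 + log 2π),
σ̂²_e = (y′y − sol′W′y)/(n−p),   sol = M⁻¹W′y,
```

whose leading blocks of `sol` are the GLS fixed effects and the BLUPs —
Henderson's mixed-model equations evaluated for free at the optimum. `M`
is factorised dense (Cholesky) below dimension 500 and by sparse LU with a
symmetric minimum-degree ordering above it; a full 265-genotype ×
21-trial fit (≈11 000 plots, MME dimension ≈7 000) takes about two
minutes on one core, and the compact designs used in the simulation
studies fit in well under a second.

The criterion is minimised over `log γ` (bounds ±e¹²·σ²_e, so a ratio
pinned at the lower bound is a boundary/zero estimate) with L-BFGS-B and
polished with Nelder–Mead (`xatol 1e-9`, `fatol 1e-10`); the polish is
what brings balanced-design fits to within 1e-6 of the closed-form ANOVA
estimators. The implementation was additionally cross-validated against
lme4 on a simulated dataset: restricted log-likelihood agrees to 4
decimals and all five variance components and the BLUPs to ≈1e-5 (one
test in `tests/test_lmm.py` re-runs this comparison whenever `Rscript`
is available).

Deviance tests of a random term refit the model without that term and
refer `χ² = 2(ℓ_full − ℓ_reduced)` to χ²₁ at the 1 % level. Because the
null value σ² = 0 lies on the boundary of the parameter space this is
conservative (true size well below 1 %, confirmed by the 1000-replicate
null calibration); no 50:50 mixture correction is applied, matching
common breeding-trial practice.

`e` is the number of trials in which the trait was measured. The
effective replication `r` entering clonal-mean heritability is the
harmonic mean over test genotypes of their plot counts across those
trials, divided by `e` — so `r·e` is a typical per-genotype plot total.
With unreplicated test clones appearing once per trial this gives `r = 1`;
the quantity is reported with every fit so any alternative convention can
be applied downstream.

## Genetic parameters and gain

* plot-basis broad-sense heritability `h² = σ²g/(σ²g+σ²ge+σ²e)`;
* clonal-mean heritability `h²ₘ = σ²g/(σ²g + σ²ge/e + σ²e/(re))`;
* predicted gain `G = h²ₘ·S` with `S` the mean BLUP + intercept of the
  selected parents minus the population mean, and `G% = 100·G/mean`.

The published panel tables shipped in `biofortqg/data/` tie these formulas
to reality: the printed per-trait h² values are reproduced exactly (2 dp)
from the printed variance components, and averaging the 30 published
parent BLUPs reproduces the printed selected-mean row to ±0.01 for all 11
traits. The published percentage gains themselves are *not* reproducible
from the printed means and heritabilities under `G = h²ₘS` (nor `h²S`);
the package therefore reports its own internally consistent gains rather
than reverse-engineering undisclosed rounding. For the same reason the
reporting function takes whichever heritability the caller supplies
(clonal-mean by default in the drivers; plot-basis h² is equally valid
input).

The selection index defaults to the literal weighted sum of BLUP +
intercept values. Because such a sum is unit-dependent, a per-trait
z-scoring flag and a Mulamba–Mock-style rank-summation mode (each trait
ranked in its favourable direction — ascending cyanogenic score is good —
and weighted by |w|) are provided. Genotypes missing any weighted trait
are excluded from the ranking with a warning; an index over unequal trait
sets is not comparable. Ties in the ranking break lexicographically by
genotype identifier.

## The synthetic-data generator

`generate_dataset` draws plots from exactly the fitted model. The
published-panel preset uses the published design: 265 test genotypes, 21
trials with 5–22 blocks, 4–34 checks per trial drawn from a pool of 34,
the published per-trait means and genotype/G×E/residual variances, and
carotenoid content observed only in the last two trial-years. Environment
and block variances are not published; they default to 1.0× and 0.25× the
residual variance (a typical multi-environment ratio) and are flagged as
non-published values. Genotype effects are drawn jointly across traits
from `N(0, D·R·D)` where `R` encodes the panel's signed correlation
structure (strong TCC–PulpColor, near-zero TCC–DMC, a positive yield
block, negative ShY–HI); anchor values are projected to the nearest
correlation matrix by eigenvalue clipping. Ordinal scores (pulp colour
1–3, cyanogenic picrate score 1–9) threshold the latent Gaussian at
half-integer cut points; the latent values stay available in the truth
object. All draws flow from a single `numpy` Generator seeded by one
integer, so identical seeds give byte-identical CSV output.

`backfill_raw_measurements` inverts the trait formulas (air/water weights
at 5 kg air weight, absorbance at 50 mL extract and 10 g sample, humidity,
plot weights on a 14.4 m² 20-plant plot — the 0.90 m × 0.80 m spacing) so
the derivation step can run end to end. Two deliberate consequences:
values outside an assay's invertible range (negative TCC from the
Gaussian tail, gravimetric DMC ≤ 16.3 %) either raise or, with
`on_invalid="skip"`, leave the raw fields missing; and harvest index /
dry root yield are *recomputed* from the backfilled yields and dry matter
(they are deterministic functions of other traits), which overwrites
their independently simulated values. Fits of HI and DRY on backfilled
data therefore reflect the ratio/product structure, not the configured
components — visible in the demo pipeline, where HI's h² drops below its
nominal input. Discretisation similarly shrinks the fitted genotype
variance of PulpColor. Datasets used for parameter-recovery studies skip
the backfill step.

What the generator does **not** emulate: spatial field trends, year
autocorrelation, heteroscedastic residuals across trials, non-Gaussian
assay error, genotype attrition across years, pedigree structure. Passing
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated model, not robustness to these real-data
features.

## Networks

Pearson correlations use pairwise-complete observations (carotenoid
content exists only for a genotype subset) with the `t`-test on `n−2`
degrees of freedom; no multiple-testing correction by default (a
Holm/BH flag exists). Correlogram ordering is average-linkage
agglomerative clustering on `1 − r`.

The partial-correlation network fits graphical lasso on the standardised
BLUP covariance over 50 log-spaced penalties in [0.01, 1]. Each distinct
support along the path is refit as the graph-constrained Gaussian MLE
(iterative proportional fitting over node-wise regressions) and scored
with the extended BIC (γ = 0.5): scoring the *refit* rather than the
shrunken estimate is what separates support selection from shrinkage —
scoring the penalised estimate directly made the EBIC minimum drift to
the densest model on the grid. Edge weights are
`−Θ_ij/√(Θ_ii·Θ_jj)` from the winning precision matrix. On simulated
12-trait graphs (n = 500) this recovers true edges with ≈0.97 recall at
≈0.1 false-edge rate and correctly deletes the indirect edge of a
three-variable chain.

## Clustering

Genotype BLUP profiles are z-scored (units range from t/ha to 1–9
scores), mean-imputed per trait where missing (fraction logged), and
projected onto all principal components with a
largest-loading-positive sign convention. K-means (k-means++, 25
restarts per k, all seeded from one root) runs over k = 2..15 and the
lowest BIC wins, ties toward smaller k.

The BIC is `n·ln(WSS/n) + k·d·ln(n)` with `d` the score dimensionality —
each extra cluster is charged for its `d` centroid coordinates. The
lighter `k·ln(n)` penalty (available via `bic_params_per_cluster=1`) was
rejected empirically: K-means extracts enough within-cluster variance
from splitting a pure Gaussian cluster that the one-parameter penalty
never stops it, and its "lowest BIC" landed at k = 11–15 on data
simulated with six well-separated groups, while the centroid-count
penalty recovered k = 6 in 10/10 seeds. Known limitation: in very low
dimensions (d ≲ 4) even this form over-splits, because the WSS gain from
splitting a Gaussian cluster grows relative to `d·ln n`; the panel's
trait space (11 traits) is comfortably above that regime. Note that on
data without genuine group structure — including the generator's own
multivariate-normal genotype effects — the scan correctly settles on
small k; recovering a specific cluster count requires genuinely separated
subpopulations.

Cluster contrasts are Welch two-sample t-tests over all cluster pairs,
Holm-adjusted within each trait family, starred at 0.05/0.01/0.001;
clusters with fewer than two members are excluded with a warning.

## Study sizes

The simulation studies run at: REML recovery — 300 genotypes × 6 trials ×
5 blocks × 5 checks, 20 seeds; deviance-test null calibration — 30
genotypes × 2 trials, 1000 replicates; network recovery — 12 traits,
n = 500, 12 true edges, 10 seeds; cluster recovery — 6 groups × 40
genotypes in 11 traits, 10 seeds. The analysis drivers default to a
120-genotype × 8-trial demo scale and accept `--full` for the
265 × 21 design (≈2 minutes per trait for the REML fit).

## Numerical conventions

* Variance ratios bounded in `log γ ∈ [−14, 12]`; a lower-bound estimate
  is a zero component.
* CSV interchange: comma, UTF-8, `.` decimals, empty field = missing,
  `%.12g` floats (round-trip to 12 significant digits).
* Strict validation (default) rejects a file on the first violated
  invariant naming the row; lenient mode drops offending rows and logs
  each one. Values are never silently altered.
* Out-of-range gravimetric DMC (an empirical regression can leave
  [0, 100]) is returned and flagged, never clamped.
* Roots-per-plant with zero harvested plants is missing, not zero.
* The cyanogenic sweet/bitter boundary (≤100 mg/kg) applies to
  quantitative assays only; the 1–9 picrate score is modelled as-is.
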