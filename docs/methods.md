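# Methods

## Connectivity measures and conventions

Inputs per subject are a symmetric, non-negative streamline-weight matrix
(zero diagonal) and a symmetric fiber-length matrix (mm, positive wherever
a connection exists) over a labeled parcellation with hemisphere tags
(L/R/M) and cortical flags. Invariants are validated on load; subjects
violating them are excluded and counted, mirroring a quality-control step.

* **Length normalization.** Weights are divided entrywise by fiber length
  (`W_ij / L_ij` where `W_ij > 0`) to remove the bias toward long fibers.
  The operation is deliberately not idempotent and the pipeline applies it
  exactly once, before cortical subsetting.
* **Cortical subsetting.** Graph analysis uses cortical regions only
  (60 of 76 in the default parcellation). Midline (M) regions inside a
  hemispheric partition are excluded with a machine-parsable warning by
  default (configurable to an error).
* **Commissural ratio.** Share of connection weight over unordered
  cortical pairs whose endpoints lie in opposite hemispheres. Computed
  from raw streamline counts by default, since the quantity is defined as
  a count share; a toggle computes it on length-normalized weights
  instead. The ratio is invariant to any global weight rescaling.
* **CC ratio.** `CC_area / BrainVol^(2/3)`. The 2/3 exponent makes the
  quotient dimensionless (area over area) and follows the comparative
  literature on commissural scaling; the exponent is a configuration
  option for sensitivity analyses.
* **Distances.** Edge lengths are the reciprocal of length-normalized
  weights; absent connections are absent edges (never stored as infinite
  lengths). All-pairs distances run Dijkstra on a sparse graph
  (`scipy.sparse.csgraph`); tests pin them to a brute-force
  Floyd–Warshall oracle at 1e-10.
* **Mean SPL and efficiency.** Both are means over *unordered* node pairs
  (the ordered-pair double sum with denominator N(N−1) gives the identical
  mean; we use N(N−1)/2 pairs). Disconnected pairs: mean SPL averages
  over reachable pairs and reports the unreachable count; efficiency uses
  the standard 0-contribution convention and needs no special casing.
  Per-hemisphere values are averaged into `spl_mean`, `eff_mean`.
* **Ratios.** Each interhemispheric measure divided by each averaged
  intrahemispheric measure: four ratios per subject.

## Synthetic cohort generative model

No public cohort accompanies this analysis, so the generator is the
package's own model of the study conditions: a 7-center cohort of 697
subjects (~70% patients, per-center sizes, ages, and female fractions
loosely following a real multi-center MS cohort's demographic table), a
desk-scale streamline budget of 10,000 per subject (a stand-in for the
6,000,000-streamline tractograms of real pipelines; the budget is a
config knob), and 30 cortical regions per hemisphere plus 16 subcortical.

Per subject: a latent conservation factor `u ~ N(0,1)`; for patients a
latent severity `s ~ N(0,1)` truncated to [−2, 2]. The interhemispheric
logit is `z = 0.35·u − d·(1+s)·is_ms + ε`, `ε ~ N(0, 0.15)`, and
`p_inter = logistic(log(0.2/0.8) + z)` — baseline interhemispheric share
0.2. The severity term is anchored at a disease baseline (the `(1+s)`
factor) so that being a patient lowers the interhemispheric share on
average (default standardized effect d = 0.4) and higher severity lowers
it further; `s` itself stays zero-mean within patients and drives the
clinical maps (EDSS rises with `s` on the 0–10 half-point grid, SDMT
falls as an integer score, LVF rises log-normally; HC have no
EDSS/SDMT — as in cohorts where controls lack clinical scores).

**Streamline allocation.** One multinomial draw distributes the budget
over the edge support: the interhemispheric cortical block receives the
`p_inter` share, each intrahemispheric block `(1 − p_inter)/2`, and 15%
of the budget goes to subcortical-involving edges. Within a block,
per-edge probabilities are Gamma(2)-distributed (heterogeneous edge
strengths). Each hemisphere's support is a random spanning tree plus
random extra edges to 35% density, and tree edges are pre-seeded with one
streamline each, so hemisphere graphs are connected by construction and
the per-subject weight sum equals the budget exactly (disconnection is
exercised by separate fixtures, not by the generator).

**Planted conservation coupling.** An intrahemispheric strength latent
`v` is drawn with in-sample correlation ρ (`conservation_coupling`,
default −0.4) to the standardized interhemispheric logit, and realized
through intra fiber lengths: `L_intra = 40 mm / exp(0.25·v)` (per-edge
lognormal jitter, σ = 0.2). Strong-intra subjects thus have shorter intra
fibers, larger length-normalized intra weights, higher efficiency, and
lower SPL — while interhemispheric fibers keep a longer callosal-scale
mean length (90 mm) independent of `v`. Because lengths are not
constrained by the streamline budget, the planted coupling is independent
of the mechanical share trade-off; the *effective* latent intra strength
is `(1 − p_inter)·exp(0.25·v)` (share × length effect), and the
latent-variable oracle used in the coupling-recovery checks is the
correlation of `p_inter` with that quantity. The generator's Monte-Carlo
contract (ρ = −0.4 → sample correlation of `p_inter` with the stored
strength factor in [−0.5, −0.3] at n = 500) is tested directly.

**Batch effects.** Per center: independent multiplicative scales
(log-normal, σ = `site_scale_sd`, default 0.15) on the interhemispheric
and intrahemispheric weight blocks — drawn separately so that even the
scale-invariant commissural ratio carries a center signature — and
scale-plus-shift distortions on the volumetric scalars (CC area, brain
volume, GMF/WMF/LVF; shifts are `site_shift_sd` = 0.3 of a nominal
cross-subject scale). An additive shift on a sparse count matrix would
create negative or asymmetric-support entries, so weight matrices receive
scales only. Consequently the exact streamline-sum conservation holds
with site effects disabled; with them enabled the sum equals
scale × budget by construction.

**Other scalars.** CC area is proportional to `p_inter` with substantial
independent lognormal noise (σ = 0.5): the volumetric measure is a loose
proxy for one commissural system, not a tract count, so its coupling to
the graph measures is deliberately much weaker than the commissural
ratio's. WMF rises with `p_inter`; GMF falls slightly with severity;
brain volume is `N(1.5e6, 1e5²)` mm³. Sex is binary (female = 1) with
per-center fractions in the 0.40–0.88 range; it is only ever used as a
covariate.

**What the generator does not emulate:** streamline geometry, lesion
masks, scanner protocols, spatially structured topology (lobes,
hubs, hemispheric asymmetries), non-Gaussian site effects, or missing
data beyond HC clinical scores. Passing tests therefore demonstrate that
the *pipeline* recovers planted statistical structure under realistic
noise and batch conditions — not that real MS cohorts show these effect
sizes.

## Harmonization

Parametric empirical-Bayes ComBat, the standard location/scale model:

1. least-squares fit of batch offsets plus covariate effects (no
   intercept; the grand mean is the batch-proportion-weighted combination
   of batch offsets);
2. pooled residual variance per feature over all subjects;
3. standardization to Z;
4. per-batch, per-feature sample means and variances of Z;
5. moment-matched priors — normal across features for locations,
   inverse-gamma for scales;
6. conditional posterior means iterated until every location/scale
   changes by < `tol` (default 1e-4 absolute, max 100 iterations; the
   default cohort converges in ≤ 4 iterations).

`mean_only` mode adjusts locations and leaves per-batch variances exactly
unchanged. A single batch yields an identity model with a warning; a
batch with < 2 subjects, an unseen batch level at apply time, or
covariates collinear with batch are errors. Features with (numerically)
zero pooled or within-batch variance get location-only adjustment with a
warning. Models serialize to JSON. The implementation matches
`sva::ComBat` to ~1e-7 on a two-batch fixture (tested via Rscript).

Covariates preserved in the pipeline: age, sex, and diagnosis as an HC/MS
binary (subtypes collapsed; diagnosis proxies the clinical scores that
controls lack). The harmonized feature set is the 12 metric columns plus
GMF, WMF, LVF, CC area, and brain volume.

Two properties of the EB estimator are worth knowing. Shrinkage leaves a
residual batch difference of roughly half the sampling noise of a batch
mean/variance (at n = 200/batch: ~0.03 SD in means, ~±0.1 in cross-batch
variance ratios on single draws) — so harmonization is idempotent only up
to contraction (a second pass moves values by ~1e-2 SD, an order of
magnitude less than the first), and grand means move by ~1e-3 SD even
with centered covariates. Seed-averaged recovery of planted effects is
tight (mean SMD < 0.05, mean variance ratio within [0.9, 1.1]); per-seed
per-feature ratios fluctuate more, identically to the reference
implementation.

The PCA diagnostic standardizes features, projects onto two components
(fit separately before/after), and reports the between/within-center
variance ratio of PC1.

## Statistical battery

* **Residualization**: least-squares projection on [intercept,
  covariates]; categorical covariates (center) are dummy-coded; collinear
  designs are rejected by name.
* **Partial correlation**: Pearson r of the two residual vectors, two-
  sided p from the t transform with n − 2 − k degrees of freedom (k =
  non-intercept design columns). Equals the textbook single-covariate
  closed form to 1e-10 and plain Pearson when no covariates are given.
* **Families and correction**: Bonferroni within each family of tests
  shown together — (a) inter×intra pairs split HC/patients (m = 8), (b)
  inter-measure agreement (m = 2), (c) measures and ratios vs
  GMF/WMF/LVF/EDSS/SDMT in patients (m = 40, center dummies optional).
  Family sizes are printed in every report.
* **Clinical splits**: high disability ⇔ EDSS ≥ 3.0; cognitively
  preserved ⇔ SDMT ≥ 40. The cutoffs are standard; the *side* the
  boundary falls on is not, so it is a config flag (`boundary_high`,
  default: boundary joins the "high" group). HC always form their own
  group; patients missing a score are excluded and counted.
* **Group comparisons**: one-way three-group ANOVA (the "two-way" wording
  that sometimes accompanies three-group figures is interpreted as
  one-way; there is only one factor) on age/sex-residualized measures,
  Tukey HSD post hoc pairs via the studentized-range distribution with
  the Tukey–Kramer correction for unequal group sizes (statsmodels;
  pinned in tests to a direct studentized-range oracle). Identical-data
  degenerate input is defined as F = 0, all pairwise p = 1.

## Pipeline and determinism

One seed drives everything: cohort-level draws use one substream, each
subject's connectome another (derived by counter from the seed), so
subject-level data are reproducible under cohort subsetting. Runs with
the same configuration are byte-identical (fixed CSV dialect, `%.12g`
floats); every output carries a version + configuration-hash annotation
line. The configuration hash covers scientific settings only, not paths.

## Problem sizes

Defaults are chosen so the whole suite runs on one CPU in a few minutes:
cohorts of 80–697 subjects with 76-region connectomes and 10,000-streamline
budgets; coupling recovery on ten 500-subject cohorts; harmonization
recovery at n = 200/site over ten seeds; graph-metric oracle on 200
random 12-node graphs. The full end-to-end pipeline at n = 100 completes
in ~3 s; the acceptance script in ~30 s.

## Known limitations

* The generator's topology is an unstructured random graph; degree
  distributions, community structure, and geometric embedding of real
  connectomes are not modeled.
* Harmonization assumes additive/multiplicative Gaussian site effects on
  each feature independently; real scanner effects can be nonlinear and
  correlated across features.
* The EDSS/SDMT maps are linear in a single severity latent; real
  disability and cognition dissociate.
* CC area is treated as a given scalar; whether it derives from a true
  midsagittal slice or a segmentation volume is outside scope.
* Mean SPL on disconnected graphs depends on the reachable-pairs policy;
  efficiency is the robust choice there and both are always reported with
  the unreachable-pair count.
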