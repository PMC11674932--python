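# hemiconn

Hemispheric structural-connectivity conservation analysis for multi-center
diffusion-MRI cohorts, with a focus on multiple sclerosis (MS).

Across subjects (and species), interhemispheric and intrahemispheric
structural connectivity trade off against each other — the *conservation
principle*: brains with a larger share of commissural (cross-hemisphere)
connections tend to have weaker within-hemisphere connectivity, and vice
versa. `hemiconn` implements the full analysis needed to test whether this
trade-off survives in a disease that damages commissural systems: from
streamline-count/fiber-length connectomes to harmonized connectivity
measures to the statistical battery relating them to brain structure,
disability (EDSS), and cognition (SDMT). It is written for network
neuroscientists working with multi-center tractography-derived connectomes.

Because the clinical cohorts this kind of analysis runs on are restricted,
the package ships a first-class **synthetic cohort generator** that emulates
a 7-center, ~700-subject MS/HC cohort with planted effects (inter/intra
coupling, disease effects, per-center batch effects), so every pipeline
stage is testable end to end and all planted parameters are recoverable.

## Measures

For each subject, from a symmetric streamline-weight matrix `W` and fiber
length matrix `L` over a labeled parcellation (60 cortical regions, 30 per
hemisphere, plus subcortical regions that are excluded from the graph
analysis):

* **Commissural ratio** = (streamline weight crossing hemispheres) /
  (total streamline weight), computed over cortical region pairs — the
  tractography-derived interhemispheric measure, in [0, 1].
* **CC ratio** = CC_area / BrainVol^(2/3) — corpus callosum midsagittal
  area (mm²) over brain volume (mm³) raised to 2/3 for dimensional
  consistency (the exponent is configurable) — the volumetric
  interhemispheric measure.
* **Mean shortest path length (SPL)** = mean over unordered within-
  hemisphere node pairs of the graph distance d(i,j), averaged across
  hemispheres. Distances run on the graph whose edge lengths are
  1 / (W_ij / L_ij), i.e., the inverse of length-normalized connection
  strength — lower SPL means stronger intrahemispheric connectivity.
* **Efficiency** = mean over unordered pairs of 1/d(i,j) (0 for
  unreachable pairs), averaged across hemispheres — robust on graphs with
  disconnected nodes.

plus the four inter/intra ratios {commissural, CC} / {SPL, efficiency}.

The processing order is fixed: divide weights by fiber length → restrict
to cortical regions → commissural ratio (from raw counts by default) →
invert into distances → graph metrics.

## Harmonization and statistics

Multi-center tractography carries large scanner/protocol batch effects.
`hemiconn.combat` implements parametric empirical-Bayes location/scale
harmonization (ComBat): least-squares standardization with batch
proportions and biological covariates (age, sex, diagnosis), per-batch
location/scale estimates shrunk toward moment-matched normal /
inverse-gamma priors, iterated to convergence. It reproduces the
Bioconductor `sva::ComBat` reference to ~1e-7 (tested). A PCA diagnostic
quantifies the drop in center separation.

The battery (`hemiconn.stats`) provides covariate residualization,
partial correlations (t-test with n−2−k df), Bonferroni correction per
test family, clinical splits (EDSS ≥ 3 = high disability, SDMT < 40 =
cognitively impaired), and three-group one-way ANOVA with Tukey HSD
(Tukey–Kramer for unequal n) post hoc pairs.

## Worked example

The numbered drivers under `analysis/` run the study-scale analysis on the
synthetic cohort (connectome files are written under `scratch/`, tables
under `results/`):

```sh
python analysis/01_generate_cohort.py
python analysis/02_compute_metrics.py
python analysis/03_harmonize.py
python analysis/04_correlations.py
python analysis/05_group_comparisons.py
```

`01` prints the cohort composition (697 subjects, 488 MS / 209 HC across
7 centers, EDSS median 3.0, SDMT mean 50.5). `02` prints the measure
summaries, e.g. commissural ratio 0.185 ± 0.075 and efficiency
0.513 ± 0.157. `03` fits ComBat and reports the PCA diagnostic:

```
harmonized 697 subjects across 7 centers (full mode, 3 EB iterations max)
PC1 center separation: before=0.0495 after=0.0017
```

— the between/within-center variance of the first principal component
drops ~30-fold after harmonization. `04` prints the correlation families;
the conservation signature on this cohort (planted coupling −0.4):

```
commissural_ratio [MS]  vs spl_mean  r=+0.643 n=488 p_corr=4.2e-57
commissural_ratio [MS]  vs eff_mean  r=-0.569 n=488 p_corr=3.7e-42
cc_ratio [MS]           vs eff_mean  r=-0.360 n=488 p_corr=2.0e-15
```

A higher interhemispheric share goes with *longer* intrahemispheric paths
and *lower* efficiency — the inverse inter/intra trade-off — and the
signature is weaker through the volumetric CC ratio than through the
tract-count measure, as expected for a noisier proxy. `05` runs the
HC/low/high group comparisons (all 16 ANOVAs significant on this cohort,
with cognitively impaired patients showing the lowest connectivity).

The same pipeline is scriptable in one shot (`hemiconn all --seed 0 --out
results/run`) or from a YAML config; `hemiconn generate/metrics/harmonize/
analyze` expose the individual stages.

## Layout

```
src/hemiconn/      library: connectome, metrics, combat, stats, synthetic,
                   io, pipeline, cli
analysis/          numbered narrative drivers over the library
tests/             pytest suite (unit, property, and acceptance tests)
scripts/           acceptance.py
docs/methods.md    model, conventions, and limitations
```
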