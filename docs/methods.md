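# Methods

## Scope and data model

The package analyzes segmented multiplexed-immunofluorescence TMA data at
three levels: cells (one row per segmented cell with coordinates,
subcellular compartment areas, nucleus count, epithelial-mask membership,
and mean/SD intensity per marker), cores (one ~1 mm punch per row, with
patient linkage, image dimensions, assessability and categorical
pathologist immune/stroma scores), and patients (clinical covariates plus
DFS/OS times and event indicators). It does not perform segmentation,
registration or autofluorescence correction — those belong to the imaging
platform upstream — and it does not synthesize realistic pixel data; the
optional label-mask TIFFs are centroids rendered as discs, for exercising
image-reading code only.

## Synthetic cohort generator

The generator exists so that every downstream stage can be validated
against known truth; it emulates the *structure* of a stage III colorectal
cancer TMA study, not the appearance of real tissue.

**Cohort structure.** Default 117 patients; each contributes 1–3 cores with
mixing weights 7:99:62 (the shape of a typical multi-core TMA design where
most patients have two or three assessable punches). Cells per core are
lognormal around 2000 (σ = 0.25, floor 50); configurations requesting fewer
than 50 expected cells per core are rejected because core-level percentages
become degenerate.

**Cell classes.** Every cell carries one of eight ground-truth classes
(Th, ThPD1, Tc, TcPD1, Treg, TregPD1, Epithelial, Other). The default
mixture puts ~2.7% of cells in the six T-cell subtypes (tenths of a percent
each, matching per-subtype cohort means reported for this tumor type), 52%
epithelial and the rest unclassified stroma. Class fractions are perturbed
per patient (logit-normal, σ = 0.4) and again per core (σ = 0.3): the
logit-normal keeps fractions in (0,1), and the core-level dispersion is
what produces realistic core-to-core discordance of categorical scores
within a patient. Zero entries of the mixture stay zero under perturbation.

**Intensities.** Per marker, log intensity is a two-component Gaussian:
negative cells at `neg_loc` (default log 100, σ = 0.5) and positive cells
displaced by `separation` negative-SDs (default 5, i.e. d′ = 5). Lognormal
components were chosen because fluorescence intensities are strictly
positive and right-skewed. A cell draws from the positive component exactly
for the markers its true class requires (plus DAPI for all cells, CD45 for
T cells, and the epithelial structural markers for epithelial cells), so
ground-truth positivity is recoverable per marker. The within-cell SD
feature is proportional to the mean (CV ~ 0.25), mimicking shot-noise-like
texture. The separation factor is the single knob controlling problem
difficulty; classifier accuracy must be non-decreasing in it.

**Positions and morphology.** Cells are uniform in the inscribed core disc
(no spatial clustering — spatial statistics beyond compartment membership
are out of scope). Epithelial cells are inside the epithelial mask with
probability 0.95, others with probability 0.10. Small rates of QC-relevant
defects are injected deliberately: 0-nucleus segmentation failures (1–2%),
tri-nucleated epithelial cells (2%), misaligned cells (1%), and area
distributions whose tails cross the QC bounds, so the filter criteria have
real work to do.

**Pathologist-style scores.** The stroma category compares true stromal
(unclassified, non-epithelial) vs epithelial cell counts: `high` above a
+10% margin, `low` below −10%, `moderate` inside the equivalence band — an
operational rendering of "stromal area higher / equivalent / lower than
epithelial area". The immune category is cohort-wide tertiles of the true
immune-cell fraction. With probability `pathologist_noise` (default 0.1) a
label flips to an adjacent category, emulating inter-observer variability;
boundary categories flip inward.

**Survival.** Relapse times are exponential with hazard
`baseline_hazard · exp(beta_treg · 1[Treg fraction > cohort median])`
(defaults 0.010/month and log 0.5, i.e. Treg-high patients at half hazard —
the protective direction). Death follows relapse after an independent
exponential gap (0.03/month), and a shared exponential censoring time
(0.012/month) applies to both endpoints, so observed OS ≥ DFS always. The
proportional-hazards form is exactly what the Cox layer assumes; parameter
recovery therefore tests estimation, not model misspecification. Coupling
OS to DFS is a generator choice — the analysis treats them as separate
endpoints. Clinical covariates are sampled with marginals matching a
published stage III cohort table (T 10/70/37, N 83/34, sex 46/71, LVI
49/68, differentiation 99/16/2 out of 117, age ~N(59, 11) in 26–79) but are
independent of outcome by construction; only the Treg fraction carries
signal.

What passing tests on this generator do **not** show: robustness to
non-lognormal intensity distributions, batch/slide effects beyond the
per-slide threshold fitting, spatially structured infiltration, informative
censoring, or covariate-confounded biomarker effects. Real cohorts can
violate all of these.

## Cell QC

Six criteria, applied as a conjunction (a kept cell passes all):

1. epithelial-mask cells need 1–2 nuclei (inclusive);
2. every compartment area (nucleus, membrane, cytoplasm) strictly inside
   (10, 1500) px;
3. good alignment with staining round 0 (skippable);
4. Chebyshev distance to the nearest image border strictly greater than
   25 px;
5. nuclear mask area strictly inside (100, 3000) px — the source phrasing
   "(>100 or <3000)" excludes nothing as written, so it is read as the
   conjunction, consistent with the phrasing of criterion 2;
6. duplicates: cells sharing (core, rounded x, rounded y) collapse to the
   lexicographically smallest cell id, making the kept set independent of
   input row order.

The kept set is order-independent; the report attributes each excluded cell
to its lowest-numbered failing criterion so exclusion counts reconcile
exactly with `cells_in − cells_out`. Cores are assessable with ≥ 100 kept
cells (configurable); patients with fewer than two assessable cores are
flagged for exclusion from per-patient averaging, since one core cannot
express intra-tumor heterogeneity.

## Classification

**Positivity.** The rule path needs explicit per-marker thresholds. The
default (`gmm2`) fits a two-component Gaussian mixture to log intensities
per slide. Because positive populations can be rare (a few percent),
components are initialized at the bulk median and the 99.5th percentile
rather than by k-means, which routinely merges a rare component into the
bulk. The call threshold is the log intensity where the upper component's
posterior crosses 0.5 (bisection between the component means), so calls are
monotone in intensity. Two guards declare a marker all-negative with a
warning: Ashman's D < 2 between the fitted components, or one component
beating two on BIC — both fire on unimodal (negative-only) markers and
protect against hallucinating a positive population. Otsu and fixed
thresholds are available alternatives.

**Gating table.** Decision order: AE1+ → Epithelial; else CD3+CD8+CD4− →
Tc/TcPD1 by PD1; else CD3+CD4+CD8− → Treg/TregPD1 if FOXP3+ else Th/ThPD1,
by PD1; anything else → Other. The table is total on all 64 patterns and is
verified in tests against an independently written brute-force mapping.
CD4+CD8+ double positives are deliberately routed to Other: the source
table does not cover them, and refusing to guess a lineage is safer than an
arbitrary precedence. A strict invariant follows from the shared
binarization: Treg + TregPD1 counts never exceed FOXP3-positive counts.

**SVMs.** Linear-kernel SVC (C = 1) on standardized log features — (mean,
SD) of one marker for the binary models, all six classification markers (12
features) for the eight-class one-vs-rest model. Log features make the
lognormal intensities approximately Gaussian, which suits a linear
boundary. Generalization is reported as stratified 3-fold cross-validation
(folds reduce with a warning when the smallest class is tiny); the
deployment model is refit on all annotations. Classes with < 3 annotations
are dropped with a warning; single-class annotation sets are an error
asking for more annotation.

**Automated annotation + probabilistic model.** Candidates per marker are
cells above the upper mixture-component mean (high-confidence bright
cells; a flat 95th-percentile rule was rejected because it floods the
candidate set with bright negatives whenever true positives are rarer than
5%), restricted to cells with a segmented nucleus and in-bounds nuclear
area; epithelial-vs-lineage double assertions keep the higher z-score;
markers with < 20 candidates, or no bimodal structure, are skipped with a
warning. Matched negatives come from below the lower component mean. The
probability model is per-marker class-conditional Gaussians on (log mean,
log SD) with pooled covariance (falling back to the diagonal with a warning
when singular) — the simplest family capturing "one probability model per
marker"; marker posteriors > 0.5 define positivity, classes come from the
gating table, and confidence is the product of the called-state posteriors.

## Scoring

Immune score: count of cells positive for any of CD45/CD3/CD4/CD8 and
negative for AE1 (counts, not area-normalized densities; area normalization
is an option the tables leave off by default). FOXP3 and PD1 are not immune
markers here — they subset CD3+ cells. Stroma score: 100 × (non-epithelial-
mask cells negative for AE1 and all immune markers) / (non-epithelial-mask
cells); a core with no non-epithelial cells gets NaN and a
`stroma_score_defined=False` flag rather than a silent zero. Percent-of-
total uses all QC-kept cells of the core as denominator, so the eight class
percentages partition 100 exactly. Patient averages are unweighted across
assessable cores (the operational reading of "average percent of the
assessable cores"); cell-count weighting is available but not default, and
a regression test documents that the two differ whenever core sizes differ.
Hot-spot selection is argmax of CD3+ count (single-marker mode) or summed
T-subtype count (multi-marker mode) over assessable cores, ties broken by
smallest core id for determinism. "Epithelial-associated" means inside the
epithelial segmentation mask; no distance halo.

## Statistics

* **Concordance:** Welch's unequal-variance one-way ANOVA (via pingouin)
  of automated scores across pathologist categories, plus pairwise Welch
  t-tests. No multiplicity adjustment anywhere, matching the source
  workflow's explicit choice; hypothesis tests are at 5%.
* **Heterogeneity:** a patient is heterogeneous for a score when their ≥ 2
  assessable cores disagree; three-core patients additionally report
  "all three different". Percentages are integers recomputed from the
  counts (half rounds away from zero).
* **Correlation / clustering:** Spearman matrix over per-patient subtype
  percents (constant columns flagged NaN); Ward agglomerative clustering on
  standardized percents cut at k = 2 or 3, relabelled so cluster 1 is the
  immune-hot one. The source legend's "Euclidean correlation distance" is
  self-contradictory; Euclidean (Ward's natural metric) is the default and
  correlation distance is available via `metric=`.
* **Median dichotomization:** low ≤ median (ties go low); if ties empty the
  high group the split falls back to strict-below with a warning;
  all-identical values are an error.
* **Cox models:** lifelines with Efron tie handling. Univariate rows report
  HR, 95% Wald CI and the likelihood-ratio p. The multivariate procedure on
  complete cases (missing differentiation drops the row): exact-collinear
  variables are screened out first (infinite VIF would crash any fit), then
  greedy backward elimination removes whichever variable's removal most
  decreases AIC until none does, then generalized VIFs (determinant
  formula, scaled per dimension for multi-column factors) are computed and
  variables with VIF > 2 are removed largest-first with re-elimination
  after each, and the final model reports per-variable LR p values
  (refitting without the variable), AIC and Harrell's C. The biomarker
  competes for elimination like any covariate. Clinical covariates are
  refit per biomarker. At least 10 events are required.

## Problem sizes and tolerances

Tests and the acceptance script size their simulations to make each check
sharp but cheap: classifier-recovery runs use ~10,000 cells (binomial SE on
an accuracy near 95% is ~0.2%, far finer than the ≥ 90% bound being
checked); hazard-ratio coverage uses 100 cohorts of n = 1000 (uncensored,
so the (0.4, 0.6) window is ~6 SEs wide); null calibration uses 500 cohorts
with the acceptance band the exact central 95% binomial interval at
p = 0.05. Binomial oracles in generator tests use 99.9% intervals so a
whole-cohort sweep has < 5% family-wise false-alarm probability. All
randomness flows from explicit integer seeds; two runs with the same seed
are bit-identical.

## Known limitations

* The probabilistic classifier's Gaussian family and the automated
  annotation rule are this package's own concrete renderings of a workflow
  whose published description is qualitative; accuracies on real data will
  depend on staining quality in ways the generator cannot probe.
* Published cohort-level effect estimates (e.g. Treg hazard ratios in real
  patients) are not reproduction targets: the underlying patient-level data
  are not public. The survival layer is validated by parameter recovery on
  simulated cohorts instead.
* The backward-elimination path explores greedily, not exhaustively; with
  heavily correlated covariates different removal orders can reach
  different local AIC optima (the VIF screen mitigates this).
* Percent-based hot-spot dominance holds for counts, not percents, when
  core sizes differ; the dominance invariant is asserted on counts.
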