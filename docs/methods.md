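# Methods

## Model

All inference is on the natural-log scale of concentration in ppb. For a
sample *i* taken by worker *j(i)*:

    ln C_i = x_i' β + b_{j(i)} + ε_i,   ε_i ~ N(0, σ_w²),   b_j ~ N(0, σ_b²)

A measurement below its per-sample limit of detection (LOD) contributes the
censored likelihood P(ln C_i < ln LOD_i). Lognormality, linearity of effects
on the log scale, homoscedasticity and independence across samples (given
the subject effect) are assumed throughout; non-linear dose patterns and
alternative error distributions are out of scope.

Two variants are provided. The **fixed-effect** form drops `b_j` and is used
where too few workers repeat (the rule is: strictly more than 5 subjects with
≥ 2 samples are required for the random-intercept form; this puts the
small QC and flavoring task groups on the fixed-effect form). Facility is
never a random effect — with ~17 facilities and few subjects per facility a
nested variance component is not estimable.

### Priors

* coefficients and intercept: Normal(0, 1 000 000) — effectively flat;
* fixed-effect residual variance: inverse-gamma(shape 0.1, scale 0.1);
* random-intercept model: independent uniform priors on both standard
  deviations σ_w, σ_b over [ln 1.01, ln 500] ≈ [0.00995, 6.215]. The bounds
  cover any plausible geometric standard deviation (GSD = exp σ from 1.01 to
  500) while excluding the degenerate σ = 0.

Consequence worth knowing: on data with very small spread, the
inverse-gamma(0.1, 0.1) prior keeps the fixed-effect σ_w near 0.1 (GSD
≈ 1.1); this is the stated prior doing its job, not a bug.

### Sampler

A data-augmentation Gibbs sampler written for this package:

1. censored rows: latent response drawn from Normal(x'β + b, σ_w²) truncated
   above at ln LOD. The truncated-normal primitive uses the inverse CDF for
   standardized bounds above −6 and an exponential rejection sampler
   (Robert-style) in the far tail, so bounds many SDs below the mean are
   exact and finite;
2. coefficient block: conjugate multivariate normal (Cholesky solve);
3. subject intercepts: independent normal conditionals (vectorised);
4. variances: inverse-gamma conditional in the fixed-effect model; in the
   random-effect model each SD is updated by shrinkage slice sampling on the
   bounded SD interval (the conditional density depends on σ only through a
   residual sum of squares, so slice evaluations are O(1)).

Initialisation: censored rows at their bound, coefficients at the ridge
least-squares solution, σ_w at the residual SD clipped to the prior bounds,
σ_b at half of it. Chains mix essentially immediately (first/second-half
posterior means agree within Monte-Carlo error after a few hundred
iterations on the bundled fixtures).

**Schedule.** Defaults follow the production-scale convention: 5 000 burn-in
iterations; covariate models keep 10 000 draws thinned by 60
(thin-then-keep: `burn_in + thin × kept` raw iterations, keeping every
thin-th, so the chain always has `kept` rows); descriptive intercept-only
models keep 20 000 unthinned draws. Tests and the acceptance script use
reduced schedules (hundreds of kept draws, thin 1–5) chosen so the full
suite runs in minutes; because the sampler is conjugate in the coefficients,
reduced chains already have thinned lag-1 autocorrelation < 0.2 on the
bundled fixtures. Every model derives its own seed from the run seed and the
model id via `numpy.random.SeedSequence`, so model spaces are reproducible
and parallelisable.

Diagnostics: batch-means Monte Carlo standard error (batch size ⌊√n⌋) per
parameter; a rank-deficient design triggers a warning (the wide prior keeps
the posterior proper, but the coefficients are not separately identifiable).
Single chains are the default; `n_chains` exists but no Gelman–Rubin
machinery is provided. Credible intervals are equal-tailed chain quantiles
(numpy's linear interpolation rule).

## Descriptive summaries

Per task (and instantaneous activity/source labels), an intercept-only fit
gives per-draw GM = exp(μ), GSD = exp(σ) and P95 = exp(μ + 1.645 σ); the
identity P95 = GM · GSD^1.645 holds on every draw by construction. Under the
random-intercept model σ is the **total** spread √(σ_w² + σ_b²): a task's
single published GSD is read as between- plus within-worker variability
(both components are exported separately). Groups with fewer than 3 records
or no uncensored value are reported as not estimable.

STEL exceedance counts samples whose duration is within ±1 minute of the
15-minute comparison duration; censored records count as eligible
non-exceedances (the LOD sits far below the limit), and imputed values are
never used, so the tabulation is deterministic given the records. Percentages
round half away from zero. The between-analyte association is the Spearman
rank correlation of log concentrations over pairs with both members
uncensored (excluded pair counts are logged; imputation-based alternatives
were deliberately not used).

## Screening and exclusions

Each determinant is fitted alone (per task group, model form chosen by the
repeated-measures rule). A determinant is *notable* at level L when any of
its coefficients' equal-tailed L-intervals excludes zero; 80% is the entry
gate to model averaging, with 90/95% reported for the heatmap. Pearson
correlations are computed between all expanded columns (each non-reference
category as a 0/1 indicator, continuous values as-is) on the same filtered
rows, pairwise-complete when values are missing. Any cross-determinant
column pair with |r| ≥ 0.5 marks the *pair of determinants* (whole
categorical blocks, never single categories) as collinear; declared nesting
(one determinant a subset of another) is excluded regardless of correlation.
The absolute value is used because negative collinearity inflates variance
just as positive does; the threshold is inclusive (r = 0.5 excludes).

## Model averaging

All subsets of the notable determinants containing no excluded pair are
enumerated (deterministic order, binary counting over determinant indices;
spaces beyond 2²⁴ candidate subsets are refused). The null model is fitted
for the GSD-reduction metric but excluded from membership counts and
averaging. Every admissible model is fitted with the same chain schedule;
a failed member is dropped from averaging with a loud warning.

**Averaging is restricted**: a determinant's averaged posterior uses only the
models containing it, deliberately avoiding shrinkage toward zero from
models where collinearity forced it out. The default, unweighted averaged
posterior is the **equal-weight mixture of the member posteriors** (pooled
kept draws). A per-iteration *mean* across independent member chains was
considered and rejected as the default: when member models agree it shrinks
the averaged SD by ~1/√M and drops 95%-interval coverage to ~83% in
simulation; it remains available (`method="iteration_mean"`) and is the form
used when explicit model weights are supplied (e.g. proportional to GSD
reduction — off by default, since weighting was found not to change
estimates materially when GSD reductions are small).

Effect sizes are percent changes `(exp(β · units) − 1) × 100` relative to
the reference category (units = 1) or per `unit_scale` raw units of a
continuous determinant (e.g. per 250 lbs of roaster capacity, per 20
percentage points of ground coffee). Continuous coefficients are *fitted*
per raw unit; the unit scale enters only at percent-change time. The
percent-change median and CI are the exact monotone transforms of the β-draw
median and quantiles, so notability (95% CI excluding zero; an endpoint
exactly at zero counts as containing it) agrees between scales by
construction. Model fit is summarised by GSD reduction — the posterior
median overall GSD of the null model minus that of the covariate model — in
place of R², which misbehaves when censored values are imputed.

The reference GM reported with each averaged table is exp(median) of the
intercept draws averaged iteration-wise over all fitted models (the
intercept appears in every model, so restricted and full averaging coincide).

## Synthetic studies

The generator exists because the original survey data are restricted; it
emulates the *structure* the analysis assumes, with known ground truth for
recovery testing:

* 17 facilities, 606 task samples allocated to the 10 task categories by
  largest-remainder quotas of the task mix, so the default reproduces the
  design counts (189 roasting / 74 grinding / 203 packaging / 44 QC /
  15 flavoring / …) exactly; subjects per facility U{4..12}, samples per
  subject U{1..8} adjusted to the exact total;
* log-concentrations from the analysis model itself: intercept + task
  effects + optional process effects + subject intercept + noise. Default
  task effects are the log GM ratios between tasks (reference roasting)
  taken from the emulated study's descriptive table; the total spread is
  ln GSD 1.4 split as σ_b = 0.4, σ_w = 1.342 (the split is a convention —
  the source reports no variance components);
* per-sample LODs lognormal around the analyte median (0.9 ppb diacetyl,
  1.0 ppb 2,3-pentanedione; log-SD 0.1). The reference-task GM (1.3 /
  1.35 ppb) was calibrated analytically — a normal-CDF mixture over the task
  mix — so the expected overall censored fraction is ≈ 24% (diacetyl) and
  ≈ 27% (2,3-pentanedione), the study's reported censoring levels. The
  task-level GMs therefore sit below the published table's GMs while
  preserving their ratios; the published per-task %BDL values are not
  individually reproduced (they are inconsistent with a common-spread
  lognormal at the published GMs);
* process-level determinants (ventilation, open storage, capacities, percent
  ground coffee, flavoring indicators) are driven by one latent facility
  "production scale" factor with loading 0.9, so declared pairs (roaster vs
  grinder capacity) exceed |r| = 0.5 in-sample and the exclusion logic has
  something real to find; one nested pair (flavor_ground_coffee within
  flavoring_during_survey) exercises the nesting rule;
* default process *effects* are zero; `SimulationConfig.demo_effects()` adds
  known nonzero effects (GEV −0.9, open storage +0.5/+0.9, +0.02 per percent
  ground coffee) for end-to-end demonstrations and recovery tests;
* paired two-analyte generation shares the design and correlates log
  residuals at 0.70, which (after excluding censored pairs) yields a Spearman
  correlation near 0.5 between analytes, the reported association.

What the generator does **not** emulate: per-task GSD heterogeneity (a
common spread is used), instantaneous canister sampling, within-task
autocorrelation, missing-value patterns, and any real facility's coefficient
values. Passing recovery tests therefore shows the estimator is correct
under the assumed model, not that the published coefficients are
reproducible — they derive from restricted data.

## Numerical choices and edge cases

* Categories encode in declared order with the declared reference; a
  determinant with only its reference observed contributes no columns and is
  skipped with a warning; columns that become constant after task filtering
  are dropped likewise (different task models legitimately carry different
  determinant sets).
* Missing continuous values exclude the row from models selecting that
  determinant (count logged); categorical "unknown" is modelled only if
  declared as a category.
* Detected concentrations below the nominal LOD are accepted as uncensored
  values (the schema permits them; their original treatment is unknown).
* All-censored designs are refused with a pointer to descriptive-only
  treatment; all-censored *groups* are reported as not estimable.
* Chain caching (optional, used by the pipeline) keys on a SHA-1 of the
  design arrays, determinant set, schedule and seed, so regeneration never
  silently refits with different inputs.
* The pipeline writes a manifest (seeds, stages, warnings, timings) from
  which every numeric output is exactly re-executable; identical config and
  seed give byte-identical CSVs.

## Problem sizes used in the checks

The bundled test suite and `scripts/acceptance.py` run reduced
configurations chosen as sufficient for their purpose: chains of 200–2 000
kept draws (thin 1–5); Tobit-oracle comparison at n = 200 with 30%
censoring; variance-component recovery at 40 subjects × 5 repeats (averaged
over 5 replicates in the acceptance script, since a single 40×5 realisation
is weakly informative about σ_b); 95%-interval coverage over 100 univariate
and 50 model-averaging replicates; enumeration cross-checked against a
brute-force power-set filter up to p = 12.

## Known limitations

* Single-chain inference; convergence is asserted by stability and MCSE, not
  by multi-chain diagnostics.
* The model-space totals of the motivating study (483, 837, …) are not
  reconstructable without its unpublished correlation structure; totals here
  are defined as the count of non-null admissible subsets.
* Percent-change interpretation is relative to reference conditions; large
  percent increases on small reference GMs can be small absolute changes.
* The repeated-measures threshold (> 5 subjects with repeats) is one reading
  of an ambiguous rule; it reproduces the intended fixed-effect fallback for
  small task groups.
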