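# Methods

`oefish` implements an observed/expected (O/E) biomonitoring index for
riverine fish assemblages, together with the synthetic river network used to
test it.  This note documents the models, the parameters that matter, the
numerical choices, and what the synthetic world does and does not emulate.

## The O/E index

For each river reach, per-species boosted regression trees (BRTs) predict
the probability that a species would be captured by a standard survey.  Two
predictions are made per species and reach: one from the reach's current
covariates, and one from the same covariates transformed to a *reference
condition* — a declared near-natural state, not a reconstruction of the
pre-human landscape.  Presence calls come from a per-species probability
threshold (below), giving two species sets per reach:

- **E** (expected): species called present under reference covariates;
- **O** (observed): species called present under *current* covariates,
  restricted to E.  Species present today but not expected under reference
  do not count toward O, so O ⊆ E and O/E ∈ [0, 1] by construction.

`ratio = |O| / |E|` where E is non-empty; reaches with E = ∅ carry an
undefined flag and are excluded from all downstream fits.  A ratio near 1
means the current assemblage resembles the reference assemblage; low ratios
flag reaches whose expected species are missing today.

Only native species enter O/E.  Exotic species are modelled with the same
machinery but feed exclusively into the pressure-attribution stage.

## Reference-condition transform

The default scenario applies three kinds of rule, all configurable via YAML:

| rule | covariates | semantics |
|---|---|---|
| `set_to` | upstream native cover → 1.0, upstream pasture → 0.0, riparian native cover → 100 | overwrite everywhere |
| `cap_at` | nitrate-N → 0.11 mg/L, DRP → 0.006 mg/L | reduce **only where exceeded** (never raised) |
| `substitute_from` | riparian shade ← pre-human shade column | replace from companion column |

The nutrient ceilings are the upper range of enrichment observed in rivers
of high ecological health.  The transform is idempotent, never mutates its
input, and leaves all other columns bit-identical.  Rule key sets must be
disjoint; a missing companion column is a schema error.

## Survey filtering

The analysis set is built by a fixed, audited rule sequence: unparseable
date → sampled before 2000 → outside the summer window (December–March
inclusive; each record is charged to the first rule it violates) →
non-electric method → less than 150 m of surveyed reach.  All boundaries are
inclusive ("at least").  Where a site retains several records, exactly one
is kept, chosen uniformly at random keyed by (seed, site id) — the choice is
reproducible and independent of input order.  Species present at fewer than
150 distinct sites are dropped, as are river classes with fewer than 1,000
survey sites; model fitting *and all prediction* are restricted to retained
classes to avoid extrapolating into unsurveyed environments.  Every filter
stage reports removed-per-rule counts that reconcile exactly with its input.

A pairwise Pearson collinearity screen (r and two-sided p for every
covariate pair) is produced as a report only; no variables are removed.

## Boosted-tree occurrence models

Each species is modelled independently by stagewise gradient boosting on
Bernoulli deviance with the regime: tree complexity 5 (five splits per tree,
the `gbm` `interaction.depth` convention — trees are capped at six leaves
and depth five), bag fraction 0.15 (per-tree row subsampling), 10-fold
cross-validation, and a learning rate chosen so the cross-validation-optimal
tree count is at least 1,000: starting from 0.01, the rate is halved (at
most 6 times) until the floor is reached, after which the model is refitted
to all data at the optimal count.  The tree count explored per fold is
capped at 2.5x the floor; if the CV deviance is still falling at the cap,
the cap is accepted (it already satisfies the floor).  LightGBM supplies the
trees (and native routing of missing covariate values); the fold
construction, deviance curves, tree-count selection, halving protocol and
influence normalisation are implemented here.

Skill is reported as cross-validated AUC — the Mann–Whitney probability
that a random presence outscores a random absence, ties half — computed on
pooled out-of-fold predictions (per-fold AUCs are reported alongside; the
pooled value is the headline).  Relative influence is each covariate's
percentage share of the ensemble's total split-gain, normalised to sum
to 100.

## Kappa-optimal thresholds

Probabilities become presence calls at a per-species threshold chosen by
exhaustive search: every threshold in {0, 0.005, …, 1.0} (201 values,
endpoints included) is evaluated against the training presence/absence
labels and the threshold maximising Cohen's Kappa wins; ties break toward
the smallest threshold (favouring sensitivity, deterministic).  Calls are
inclusive: present iff probability ≥ threshold.  Kappa uses the standard
closed form (p_o − p_e)/(1 − p_e), returning 0 when p_e = 1.  Thresholds
are selected on the same data used for fitting (an out-of-fold mode exists
but is off by default).

## Attribution and ordination

Defined-O/E reaches are modelled against anthropogenic pressure covariates
(downstream-dam indicator, nutrient concentrations, a riparian O/E proxy,
and per-exotic-species predicted presence) with the same boosting regime
under squared-error loss, O/E being continuous.  The reported
`cv_correlation` is the Pearson correlation between pooled out-of-fold
predictions and O/E — the natural reading of a "cross-validated correlation
coefficient".

Species are ordinated by their influence profiles: each species keeps its
five largest relative influences (other covariates zeroed), Euclidean
distances between these vectors are embedded in two dimensions by non-metric
multidimensional scaling — alternating isotonic (monotone) regression of
configuration distances on the input dissimilarities with Guttman-transform
updates, minimising Kruskal stress-1, best of 20 seeded random starts.  The
iteration stops as soon as stress fails to improve, so reported stress is
non-increasing within a run.  Coordinates are identifiable only up to
rotation/reflection/translation; comparisons against other NMDS
implementations are made at the stress level.

## The synthetic world

The generator emulates the statistical structure the analysis assumes,
without bundling any survey database:

- **Reaches.**  Two latent gradients drive correlated covariates: an
  upland/geographic gradient (slope, January air temperature, flood
  frequency, distance to coast) and a development gradient concentrated in
  the lowlands (pasture — hence nutrients — riparian loss, downstream dams).
  Pasture and native cover are negatively correlated by construction;
  nutrients rise nonlinearly with pasture.  Riparian shade is generated at
  or below its pre-human companion value.  River classes are assigned by
  mixing proportions.  Extra pure-noise covariates are appended so influence
  estimates can be checked against known irrelevance.
- **Species.**  Each species' true occurrence probability is logistic in a
  handful of standardised natural covariates with a quadratic temperature
  optimum and one pairwise interaction, minus a nonnegative-weighted sum of
  pressure terms (pasture, nutrient excess above the reference ceilings,
  dams, riparian and shade loss) scaled by `impact_strength`.  With
  `impact_strength = 0` the world is pristine and true O/E = 1 wherever
  E > 0.  Natives' responses are monotonically non-increasing in every
  pressure, so the reference transform can only raise their probability;
  exotics get the opposite sign and never enter O/E.  A per-species
  sharpness multiplier (U(1.2, 3.5)) spreads generating-process
  separability across the realistic range for fish distribution models
  (Bayes AUC ≈ 0.79–0.99).  Pressure sensitivities are set so the majority
  of reaches deviate from reference (true O/E mean ≈ 0.7, roughly a third
  of reaches fully intact) — the regime an O/E indicator exists for.
  Intercepts are calibrated against the *reference* world (target reference
  prevalence U(0.75, 0.95)): the species that survive a prevalence filter
  are by construction the common ones, which are broadly expected under
  near-natural conditions.
- **Surveys.**  Each surveyed site yields one or more records with year,
  month, method and surveyed reach length; a configurable fraction of
  records violates each filter rule, and a fraction of sites receives
  repeat visits, so the ingest stage has real work to do.  Presences are
  Bernoulli draws of the true current probability times a detection
  probability.  Detection defaults to 1.0: the models' target is capture
  probability itself, so detection is folded into the modelled quantity;
  the knob exists for sensitivity studies.
- **Truth oracle.**  `true_oe` applies the pipeline's exact counting rules
  to the *true* probabilities at given thresholds, for recovery testing.

What the synthetic world does **not** emulate: spatial network topology and
flow routing (reaches are exchangeable rows), migration/diadromy dynamics,
observer skill and conductivity effects on electric fishing, and
geomorphic/physical-habitat change.  Passing recovery tests therefore show
that the pipeline recovers a known signal under the stated statistical
structure — not that any of these field complications are handled.

## Problem sizes and known limitations

The demo world is 2,000 reaches, 8 species (6 native, 2 exotic), all
reaches surveyed, seed 42.  At this scale the prevalence and class-size
filters are scaled proportionally (150 presence sites; 150 class sites) —
the absolute thresholds of the full-scale analysis would empty a
2,000-reach world.  Full-regime fitting of the demo (8 species x 10-fold
CV with learning-rate halving) takes a few minutes on one CPU.

The O/E *ratio* at 6 native species is coarse: each reach's index is built
from at most 12 presence calls, so single near-threshold call flips move
the ratio by 1/E.  E and O counts recover the truth at Spearman ≈ 0.9 in
the demo world, while the ratio itself recovers at ≈ 0.75 — an inherent
granularity limit at this species count, not a fitting failure; real
applications with ~24 native species produce a much finer-grained index.
Counterfactual (reference-state) predictions are extrapolations beyond the
covariate support of degraded landscapes; boosted trees clamp at the edge
of the training hull, which biases reference predictions conservatively.
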