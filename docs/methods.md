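# Methods

## The ensemble and its assumptions

The package implements a bagging-based ensemble feature-selection
framework for wide, partially missing visit-level cohort tables with a
binary outcome derived from BMI. Its core assumptions:

* records are exchangeable — repeated visits by one child are treated as
  independent records, so no longitudinal structure is modelled;
* the outcome is defined *within* the data: a visit is positive when its
  BMI strictly exceeds the empirical 90th percentile of its (age-year,
  sex) stratum, computed by the nearest-rank rule in a first streaming
  pass (an external growth-reference threshold table can be supplied
  instead);
* heterogeneous selectors make partially independent errors, so a
  weighted vote over their ranked lists is more stable and interpretable
  than any single list.

The bagging layer exists for scale and stability, not for prediction: the
final output is a feature *ranking*, and the classical
majority-vote-of-classifiers aggregation is deliberately replaced by the
weighted feature vote.

## Pipeline stages and the parameters that matter

| parameter | default | meaning |
|---|---|---|
| `chunk_size` | 10,000 rows | streaming block size; chunks are the unit of splitting/bootstrap |
| `split_ratio` | 0.8 | per-chunk train share; test size = round(0.2 · n) |
| `bootstrap_frac` | 0.1 | bootstrap sample size = floor(0.1 · train size), drawn with replacement, uniform over rows |
| `M` | 5 | number of selectors = number of bootstrap sets per chunk |
| `K` | 10 | list length per selector and final output length |
| `percentile` | 90 | outcome threshold percentile |
| w1 | K + 1 − rank | rank weight ladder (rank 1 → 10 … rank 10 → 1); configurable |
| w2 ladder | 1 / 0.5 / 0.2 | tier weights; tiers set explicitly or automatically from (accuracy, F-score) |

Rounding conventions are fixed so the size laws are exact: test size uses
round-half-up, bootstrap size uses floor. Every random draw derives from
the master seed plus a stage-local key (chunk index for the map stage,
selector index for the reduce stage), which makes runs reproducible and
chunk/sid processing order irrelevant.

The w1 ladder is linear because the printed tally it reproduces is
consistent with it cell-for-cell; a Borda-style 1/k alternative can be
passed as any positive non-increasing mapping. In voting, weights are
converted to exact rationals (`fractions.Fraction`), so tallies like
9 + 9 + 7·0.2 = 19.4 are exact, not floating-point near-misses.

### Selector conventions

* **filter_mi** — kNN mutual-information estimate (3 neighbors) between
  each feature and the label; the estimator's internal seeded jitter
  breaks duplicate-value degeneracy, and constant columns are forced to
  MI 0. Signs come from point-biserial correlation. Because a filter has
  no model, its test-set predictor is an OLS fit on its selected features.
* **svm_rfe** — linear SVM (C = 1, squared hinge, standardized inputs),
  eliminating the smallest-|coefficient| feature one per iteration until
  K remain; survivors are ranked by |coefficient| of the final fit (this
  also covers the no-elimination boundary where the input has exactly K
  features). Ties in elimination break by column order.
* **lasso / ridge** — penalized least squares on the 0/1 outcome
  (standardized features), penalty chosen by cross-validation over a
  log-spaced grid; importance = |coefficient|. The linear-probability
  form is the default because the reference analysis reports signed
  regression coefficients; logistic variants would slot in behind the
  same interface. If the selected penalty zeroes every lasso coefficient,
  ranking falls back to activation order along the path, with a warning.
* **random_forest** — 50 Gini trees; importance is the mean decrease in
  accuracy over 5 permutations per feature, scored on an internal 80/20
  validation split of the selector's own sample set rather than on its
  training rows, to reduce training-set bias; negative permutation means
  are clipped to zero in reports.
* All predictors that are regressions are thresholded at 0.5 for
  accuracy/F-score; the F-score's positive class defaults to the
  overweight label and is configurable, since a majority-class positive
  convention changes F dramatically at 10% prevalence.

### Aggregation conventions

The union feature space is formed after an alias merge (encoded dummy →
canonical feature, e.g. folding a negatively-signed "adequate" level into
its "inadequate" complement). If aliasing makes one list contain a
canonical feature twice, both entries keep their rank weights. Effect
signs are carried through for reporting but never enter the vote. Equal
scores are broken by (number of supporting lists, then name) — a
documented, deterministic rule. K larger than |F| returns all of F with a
warning.

## The synthetic cohort generator

The generator emulates the statistical shape of a pediatric primary-care
extraction at desk scale: visits from `n_children` children aged 1–18
(sex fixed per child), eight numeric and four categorical features,
missing-completely-at-random cells at per-feature rates mirroring the
real blocks (≈0–5% for vitals, 30–60% for lifestyle questions, 85% for a
rarely-completed form), and BMI built as

    BMI = 13.5 + 0.45·age + 0.3·sex + η + ε,  ε ~ N(0, 2.0²) kg/m²

with η the planted linear predictor. Thresholding at the stratum 90th
percentile then yields ≈10% prevalence and label–feature associations
whose signs equal the planted signs. The default plants are
`screen_time` +3.0 and `exercise_hours` −2.8 kg/m² per SD and the
`snack_freq` "daily" level +3.5 kg/m²; "strongly planted" here means the
planted predictor's sd (≈2.3) is on par with the noise sd (2.0), the
regime in which the outcome is genuinely learnable above the
majority-class baseline and every selector is expected to recover every
plant. Recovery tests run the selectors on the 80% train split of
n = 30,000 cohorts over 10 seeds — the scale at which stable recovery is
expected of the method, and which keeps a full suite run in minutes.

What the generator does **not** emulate: visit-motivation-driven
missingness (the real mechanism is closer to missing-not-at-random),
within-child correlation of repeated visits, realistic covariance between
lifestyle variables, or external growth-reference thresholds. Passing
recovery tests therefore demonstrate the machinery is correct under MCAR
and independence, not that the method is robust to informative
missingness.

## Numerical and degenerate-input choices

* Nearest-rank percentile (smallest order statistic at or above the
  target rank): deterministic and tie-robust; strata under 10 records
  fall back to the pooled threshold with a warning.
* Imputation: per-chunk median for numerics (one pass, bounded memory),
  all-zero dummy row for missing categoricals; both overridable per
  column in the schema. Unseen categorical levels after the registry
  freeze encode as all-zeros and are counted in the log.
* Chunks smaller than M + 1 rows are skipped with a warning; single-class
  training sets raise; a single-class or empty test pool raises.
* Standardization uses population sd with zero-sd columns mapped to
  divisor 1 (constant columns pass through rather than producing NaNs).

## Known limitations

* The two-pass ingest reads the input file twice (three times counting
  level discovery); acceptable at the scales tested, wasteful on slow
  storage.
* Merged sets are held in memory; the optional per-sid spill-to-disk
  writer covers larger runs but selectors still load one set at a time.
* Parallelism is a contract (identical results regardless of execution
  order), not an implementation — stages run sequentially in-process.
* Auto-tiering of model weights uses a greedy gap rule on mean(accuracy,
  F-score) with a 0.01 tolerance; with near-tied selectors the explicit
  tier map is the reliable path.
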