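# Methods

## Problem setting

Real tabular datasets in biostatistics and epidemiology routinely contain
missing values, and the way an analyst handles them changes every
downstream result. This package provides a controlled test-bed for that
question: starting from a *complete* table, it deliberately introduces
missing values (amputation), applies competing missing-data handlers, and
measures two things against the known ground truth — how close the imputed
values are to the true ones, and how much the set of features judged
relevant by standard selectors drifts away from the set obtained on the
untouched table.

The handlers compared are:

* **Chained-equation multiple imputation** (fully conditional
  specification): the method under study.
* **Mean/mode replacement** (and median as a variant): the common quick
  fix.
* **Listwise deletion**: drop every row containing a missing cell.
* **Dropping variables**: drop every feature column containing a missing
  cell.

## Data model

A `TypedTable` couples a column schema (categorical or numeric, exactly one
target column) with a cell grid in which missingness is explicit: NaN in
float columns, `None` in categorical columns, so a missing cell is
distinguishable from every observed value including the empty string.
Categorical level domains are frozen at construction; imputation can only
produce levels from the frozen domain, which keeps mode pooling and
accuracy scoring well defined. CSV (with configurable missing tokens,
`{"?", "NA", ""}` by default for UCI-style files) plus a YAML sidecar
schema is the interchange format; ARFF is not supported.

Source files that already contain missing markers can be reduced to a
complete ground-truth table with the `drop_preexisting_missing` flag of
`read_table`; the package takes no position on how pre-existing missingness
should otherwise be treated.

## Amputation

MCAR amputation removes an **exact count** `round(rate x n_feature_cells)`
of feature cells, drawn uniformly without replacement, so each replicate
realises the nominal rate exactly rather than only in expectation. The
choice of exact-count sampling over per-cell Bernoulli or per-row schemes
is an interpretation; it matches reporting missingness as fixed percentage
levels. Two guards apply: the target column is never amputed (the
feature-selection experiment needs labels), and a draw that would empty an
entire feature column is rejected and redrawn (bounded at 100 attempts) —
conditional models need at least one observed value per column to train
on. The redraw perturbs per-cell inclusion probabilities only in
pathologically small tables.

MAR amputation makes each non-driver cell's loss probability proportional
to `expit(steepness * z)` of a standardised, fully observed numeric driver
feature, rescaled so the expected overall rate equals the nominal one
(probabilities are clipped at 1, which can bias the realised rate downward
only at extreme rate/steepness combinations). `steepness = 0` reduces to a
Bernoulli MCAR mechanism. MNAR is out of scope.

Per-instance seeds derive from `(master_seed, rate in basis points,
replicate_id)` through `numpy.random.SeedSequence`, so grids are
reproducible cell-by-cell regardless of execution order.

## Chained-equation engine

One chain runs as: (1) basic fill — observed column mean for numeric,
observed column mode for categorical (mode ties break to the
lexicographically smallest level everywhere in the package); (2) for each
feature with originally-missing cells, in schema column order (optionally
ascending-missingness order), set those cells aside, fit a conditional
model on the rows where the feature was observed — ridge-stabilised linear
regression (`alpha = 1e-6` by default, guarding collinear one-hot designs)
for numeric features, multinomial logistic regression for categorical
features — with all other features as predictors (categoricals one-hot
encoded over their frozen domains; the class target is excluded by default
and included with `include_target_as_predictor`); overwrite the cells with
the model's predictions; (3) repeat the sweep for `n_iterations` cycles
(default 10) and keep the final table. A response that is degenerate on
its observed rows (zero variance, single level) falls back to the basic
fill with a logged warning.

Predictions are deterministic conditional means/classes: no posterior
draws, no added noise, no predictive-mean matching, and numeric
predictions are not clipped to the observed range unless `clip_numeric`
is set. Because chains would otherwise be identical, multiple imputation
(`m_imputations`, default 5) decorrelates them by shuffling the feature
visit order of every chain after the first under per-chain derived seeds;
this is the package's explicit design choice and is recorded in the run
metadata. The m completed tables are pooled value-wise — arithmetic mean
for numeric cells, mode with lexicographic tie-break for categorical
cells; cells on which all chains agree (in particular every observed
cell) pass through bit-exactly. Pooling operates on data values, not on
downstream model estimates, so Rubin's rules for variance pooling are out
of scope.

## Quality metrics

Metrics are computed strictly on the cells the mask marks as amputed.
Numeric features are min-max normalised to [0, 1] using the complete
original column's range before MAE/RMSE (on by default), making errors
comparable across features of different scales; accuracy for categorical
features is the fraction of imputed cells equal to the true level (the
complement of a misclassification rate). Metrics of an empty cell set are
NaN, never 0. Overall (cross-feature) values pool the normalised cells of
all features of the applicable kind, so overall MAE equals the
cell-count-weighted combination of per-feature MAEs. Deletion handlers
impute nothing and receive no quality metrics.

Distribution shift is summarised as the total-variation distance between
a column's marginal in the original and the imputed table: level
frequencies for categorical columns, histograms over 20 equal-width bins
spanning the original range (out-of-range imputations fall into the edge
bins) for numeric columns.

## Feature selection

Five selectors produce named feature sets against the target:

* **SKB chi-squared**: Pearson's contingency statistic of feature levels
  against target classes, no continuity correction, authored here and
  cross-checked against `scipy.stats.chi2_contingency` in the tests.
  Continuous features are discretised into at most 10 equal-frequency bins
  first — a saturated unique-value table would score ~n for any continuous
  feature regardless of association.
* **SKB F-value**: regression F statistic of each feature against the
  target's integer class code treated as continuous.
* **SKB ANOVA F**: one-way classification F across target classes. The
  F-value/ANOVA-F distinction is an interpretation; the two coincide for
  binary targets.
* **RFE**: recursive elimination (step 1) around an L2-penalised logistic
  model on standardised predictors.
* **Tree importance**: Gini importances of a 100-tree random forest;
  importances form a probability vector (uniform if the forest makes no
  informative split).

Categorical features are integer-coded over their frozen domains for the
scorers that need numeric input. Score ties break to the earlier schema
column. Set sizes are per-algorithm configuration (`k_map`) and are
clipped to the number of available features so column-reduced tables
remain selectable. Selections are row-order invariant for the univariate
scorers and numerically so for RFE; forest importances are row-order
invariant only in distribution, because bootstrap resampling indexes rows.

## Benchmarks

The quality experiment runs a rates x replicates MCAR grid and scores
each imputing handler per instance; the stability experiment draws one
instance per rate, applies all four handlers, runs the five selectors on
the handled table and compares each selected set against the
complete-table reference by intersection size, Jaccard index and
symmetric-difference count. Both emit tidy data frames (CSV via the CLI)
with every configured cell present.

At rates of 25% and above, uniform cell amputation hits every column of
any realistically sized table with probability near 1, so dropping
variables (and occasionally listwise deletion, or a deletion-reduced
table left with a single target class) cannot produce a usable table.
Such cells are recorded with status `failed`, an empty selected set and
Jaccard 0: a handler that leaves nothing to select from is scored as
total instability rather than silently dropped.

## Synthetic data

The generator draws all features from a single-latent-factor Gaussian
model: latent `j` is `sqrt(rho) * Z + sqrt(1 - rho) * eps_j`, giving every
pair of latents correlation `rho` (`dependency_strength`) in expectation —
a closed form the tests assert against. Numeric features expose their
latent; categorical features cut theirs at fixed standard-normal quantiles
(balanced levels). The class target follows a multinomial logit on the
*idiosyncratic* components `eps_j` of the planted relevant features, with
per-feature coefficient rows normalised to class-contrast magnitude
`effect_size` (default 1.5) plus logit noise of sd `noise_sd` (default
0.5). Loading on `eps` rather than the full latent keeps the planted
structure clean: irrelevant features correlate with relevant ones through
`Z` but carry no target signal of their own, so selector recovery of the
planted set is well defined even under strong dependence. At the pinned
design point (n = 500, effect 1.5, dependency 0.6) ANOVA-F SKB at
k = |relevant| recovers the planted set in well over 80% of seeds.

Replication presets mirror the column-type mix of four classic UCI
benchmark shapes: 286 x 9 all-categorical, 2000 x 16 all-numeric with a
26-class target (rows scaled down 10x from the original 20000 to keep the
grid desk-scale; scale factors recorded in run metadata), 269 rows of
7 categorical + 6 numeric (dependency 0.8), and 1000 x 57 all-numeric
(scaled down from 4601). The generator emulates shape, type mix,
dependence and planted relevance — not the actual distributions of those
datasets — so passing benchmarks demonstrate the machinery and the
qualitative orderings under known ground truth, not dataset-specific
numbers.

## Numerical and degenerate-input choices

* Mode ties: lexicographically smallest level, everywhere.
* Score ties in selection: earlier schema column wins.
* `f_regression` can underflow `1 - r^2` below zero for a perfectly
  correlated feature, returning a huge negative F; negative F values are
  mapped to +inf (maximal relevance).
* NaN univariate scores (constant features) rank below every finite
  score.
* Fully missing columns are an error for every imputing handler.
* A table with no missing cells is a fixed point of the entire engine.

## Problem sizes

The default experiment sizes used by the bundled benchmark script (three
rates x five replicates for the quality grid; three rates, single
replicate, 500 x 12 table for the stability comparison; chains with
n_iterations = 10, m_imputations = 5) are chosen as desk-scale stand-ins
for the full 10-rate x 100-replicate design, which the grid machinery
supports unchanged.

## Known limitations

* Chains differ only through visit order, so between-imputation variance
  understates imputation uncertainty relative to engines that draw from
  predictive distributions; pooled point predictions are the object of
  study here.
* MAR calibration is in expectation, not exact-count; extreme
  rate/steepness combinations clip probabilities and undershoot.
* The chi-squared binning rule for continuous features (10 equal-frequency
  bins) is a convention; other discretisations reorder borderline
  features.
* No MNAR mechanism, no pairwise deletion, no hot-deck/kNN/EM imputers,
  no significance testing between handlers.
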