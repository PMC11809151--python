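# Methods

## The synthesis model

`cohortsynth` generates wholly synthetic stand-ins for rectangular
cohort datasets by sequential conditional synthesis. Given an observed
table with columns \(x_1, \dots, x_p\) in a chosen *visit order*, the
synthetic table is built one column at a time:

* \(x_1\) is drawn by resampling its observed marginal with
  replacement, uniform over rows (missing markers included);
* each later \(x_j\) is modelled as \(x_j \mid x_{1},\dots,x_{j-1}\)
  on the observed data, and synthetic values are *sampled* from that
  model at the already-synthesised predictor rows.

The default per-column model is CART donor-sampling: a decision tree
(squared-error regression tree for continuous targets, Gini
classification tree otherwise) partitions the observed rows; each
synthetic row is routed to a leaf and its value drawn uniformly from
the observed target values in that leaf. The factorisation
\(P(x_1)\,P(x_2\mid x_1)\cdots P(x_p \mid x_{<p})\) means the joint
distribution is approximated without any causal assumptions; the
scheme is the fully-synthetic analogue of chained-equation imputation.
Parametric alternatives are available per column: `norm` (least-squares
linear fit plus Gaussian residual noise), `logit`/`polytomous`
(multinomial logistic fit, values drawn from predicted class
probabilities; a separated or singular fit falls back to CART
donor-sampling with a warning).

Because donors are observed values, a synthetic column's support is
contained in the observed support (exactly — this is asserted as a
property test), which is what makes disclosure control necessary.

### Missing data

Missingness is synthesised alongside values so that relations between
missingness and other variables survive:

* categorical columns treat the missing marker as an ordinary level of
  the column model;
* continuous columns are synthesised in two stages — a binary
  missing/observed indicator by the column's method first, then values
  modelled on the observed non-missing rows. This keeps the value
  models well-defined while reproducing "NA" bars in marginal
  comparisons.
* a binary column containing missing values under the `logit` method
  is effectively three-class and is fitted multinomially over
  levels + NA rather than through a separate indicator.

### Rules and smoothing

Deterministic consistency rules (e.g. *never smokers get 0 cigarettes
per day*) are conjunctions of conditions over columns earlier in the
visit order. They fire immediately after their target column is
generated, so later columns condition on rule-consistent values. A row
whose predicate variable is missing never satisfies a condition.

Optional smoothing jitters continuous synthetic values with Gaussian
kernel noise, bandwidth from the normal-reference rule
\(0.9\,\min(s,\mathrm{IQR}/1.34)\,n^{-1/5}\), clipped to the observed
min/max. Rule-forced cells are exempt from smoothing — this is the one
coherent ordering: rules must see and produce exact forced values
(an exact 0 would otherwise be jittered away), while smoothing is a
disclosure-control perturbation of model-generated values only.
Flagging of replicated uniques runs after smoothing, so flags reflect
the released values.

### Determinism

One pseudo-random stream per column, derived from `(plan.seed, column
index)`; tree fits carry a seed-derived `random_state` for split
tie-breaks. Identical (observed table, plan, seed) gives a bit-identical
release, and changing the plan downstream of a column leaves that
column's stream untouched.

### Tunable parameters

| parameter | default | why |
|---|---|---|
| visit order | input column order | order matters; `--outcome-last` moves exposure/outcome to the end, which can preserve their mutual relations more faithfully |
| predictors | all earlier columns | the standard sequential-synthesis default |
| CART `min_leaf` | 5 rows | leaves small enough for faithful conditional donor pools, large enough that a leaf is never a single record |
| CART `complexity` | 1e-8 | effectively unpruned trees; conditional fidelity over parsimony |
| smoothing bandwidth | normal-reference rule | no bandwidth is canonical for donor jitter; the normal-reference rule is the standard default |
| synthetic n | observed n | like-for-like comparisons |

## Disclosure control

A *replicated unique* is a synthetic row whose full value combination
(missing markers included) occurs exactly once in the observed table.
Flagging uses exact row equality after canonicalisation (labels as
strings, floats compared bitwise), the same equality a manual
spot-check would use. The share is reported against the observed
sample size. `apply_sdc` removes flagged rows and optionally
top/bottom-codes continuous columns at stated quantiles; because
censoring can itself mint new replicates, flagging is re-run until the
released table contains none (asserted on every pipeline run). The
manual spot check draws rows unique within the observed table and
counts exact matches among rows unique within the synthetic table —
note this intra-table-uniqueness rule differs from the flagging rule
(uniqueness in the observed table only); we implement both as stated,
and after SDC the check must return 0.

Out of scope by design: k-anonymity, l-diversity, differential
privacy, attribute-disclosure modelling, and formal utility indices
(pMSE and relatives).

## Utility comparison

Marginals are compared cell-by-cell on definitions computed from the
observed table (categorical levels; quartile breaks for continuous
columns) and applied to both tables, with missing tallied as an `NA`
category; a synthetic category absent from the observed levels is
reported with observed count 0 as a synthesis-bug signal. Model-based
utility refits one GLM specification (Gaussian or binomial) separately
to the complete cases of each table and reports per-coefficient
estimates, SEs, z = estimate/SE (a shared scale across coefficients),
Wald 95% CIs and a symmetrised CI overlap:
overlap = mean(shared/width₁, shared/width₂), 1 for identical and 0
for disjoint intervals. Zero-width intervals compare as points.

## Longitudinal validation

Repeated measures are synthesised strictly in **wide** format (one row
per individual); long-format input is refused with an explanatory
error, because synthesising long rows independently destroys the
within-individual covariance. The synthetic wide table is reshaped to
long form and both tables are fitted with the same multilevel model:

height = β₀ + β₁(age−12) + β₂(age−12)² [+ female offsets on all three]
  + b₀ᵢ + b₁ᵢ(age−12) + b₂ᵢ(age−12)² + ε

with individual random effects (b₀,b₁,b₂) under an unstructured 3×3
covariance and independent residuals. Age is centred at 12 years so
the intercept is the expected height at 12. Estimation is maximum
likelihood (not REML) so fits on tables of different size are
comparable; CIs are Wald-type.

Numerical notes: the squared-age regressor is rescaled by 10
internally — the random-effect variances then have comparable
magnitudes, without which the quasi-Newton optimiser reliably stalls
in a poor local optimum (verified against an independent lme4 fit on
the same data). The optimiser is L-BFGS with iterated warm restarts
until the log-likelihood changes by < 1e-4, then a Powell fallback.
Degenerate noise-free fits can yield non-finite SEs; these are
reported as 0 (point intervals). Random-effect (co)variance SEs are
delta-method approximations (profiled bse × residual variance) and the
residual variance is reported without an SE. Variance estimates are
floored at 0.

## Fixture generators

The fixture generators define the study conditions under which the
pipeline is tested; their parameters are the package's own choices of
realistic magnitudes, not estimates taken from any restricted dataset.

*Cross-sectional cohort* (default n = 5000): 15 variables shaped like
a perinatal-cohort analysis file — child sex, birthweight ~ N(3.4,
0.55²) kg, gestation ~ N(39.4, 1.9²) weeks, maternal age ~ N(28, 5²)
years (clipped 16–45), parental education and social class, housing
tenure, marital status, ethnicity, parity, pregnancy size. The
exposure is an EPDS-like maternal depression score, Binomial(30, p)
with logit(p) depending on education, tenure, ethnicity and age
(marginal mean ≈ 5–6); the outcome is a binary offspring depression
diagnosis from a logistic model (log-odds 0.08 per exposure point;
prevalence ≈ 10%). MAR missingness (~5–12% per column) depends only on
always-complete covariates (tenure, maternal age). MNAR mechanisms are
rejected by construction.

*Height panel* (default n = 2000): 8 occasions at target ages 7.5–17.5
years with N(0, 0.25²) jitter; growth truth 150 + 5.6a − 0.15a²
(a = age − 12) with female offsets (−0.5, −1.0, −0.25), random-effect
covariance diag ≈ (45, 0.4, 0.02) with modest covariances, residual sd
2.5 cm, 10% occasion-wise missingness of height cells (ages remain
observed — the visit schedule is known even when a measurement is
missed).

What the fixtures do **not** emulate: real cohort attrition patterns
(missingness here is a simple MAR logit), measurement error structure,
within-family clustering, secular trends, or the long-tailed and
heaped distributions of real questionnaire scores. Passing tests
demonstrate that the pipeline preserves the relations it models under
known truth at these scales; they do not certify fidelity on any
specific real dataset, which always requires the comparison tools to
be re-run on that dataset.

## Release packaging and audit

Releases carry a constant `FALSE_DATA` marker column first, a
provenance JSON (seed, plan digest, pre-SDC n, rows removed,
timestamp) and a plain-text disclaimer stating the data are synthetic
and unsuitable for research use. The release audit checks: fewer than
50 variables (and notes columns beyond the stated analysis model);
zero replicated uniques plus a clean manual check; marginal and model
comparisons generated; the marker column; the disclaimer; and recorded
provenance. A failed audit blocks writing unless forced, and the
refusal is logged. Stata output is written as version-117 .dta with
value labels (the marker as a plain string column; a labelled numeric
column would be an equivalent alternative).

## Problem sizes used in the checks

The automated checks run the cross-sectional pipeline at n = 5000 (20
synthesis seeds for the fidelity property), the growth-model recovery
at n = 2000 × 8 occasions over 20 replicates, and brute-force CART
oracles on 6–10-row toys. These sizes give binomial/Wald tolerances
tight enough to detect meaningful distortions while keeping the whole
suite runnable on a laptop.

## Known limitations

* Single-table synthesis only; no linked/hierarchical multi-table
  plans and no multiple synthetic replicates per call.
* Random-forest and copula column methods are not implemented.
* CART trees split on one-hot indicators for categorical predictors,
  so multi-way categorical splits are expressed as indicator chains.
* Growth-mixture / latent-class trajectory modelling is out of scope;
  the longitudinal module validates data preparation and the quadratic
  mixed model only.
* Chained rules (a rule target feeding a later rule's predicate) are
  supported but flagged in validation, since their semantics depend on
  rule order.
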