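# Methods

`alsurv` predicts an *individual survival distribution* (ISD) — a full
survival function S(t | x) — for each ALS patient, targeting the time to a
composite respiratory-failure event (death, tracheostomy, or non-invasive
ventilation > 23 h/day), and evaluates predictions with censoring-aware
statistics.  This note records the models, the estimation and evaluation
conventions, the synthetic-data design, and the numerical choices, so that
every number the package produces is reproducible from this document and
the code.

## Survival curves

A curve is a knot sequence (t_0 = 0, S_0 = 1), …, (t_k, S_k) with
non-increasing S.  Two interpolation conventions coexist:

* **step** (right-continuous): Kaplan–Meier estimates, Cox baselines and
  forest leaves, which are defined as step functions;
* **linear**: discrete-time model output (MTLR) and parametric curves
  sampled onto a grid, where linear interpolation keeps the median
  well-defined on coarse grids.

**Tail extension.** Medians and conditional tail means must exist even
when a curve never reaches zero.  When S_k > 0 the curve is extended
linearly beyond t_k with the slope of its last two knots; if that slope is
flat or rising, the slope of the chord from (0, 1) to (t_k, S_k) is used
instead.  The extension is capped at 3 t_k, where the curve drops to 0.
This is a deliberately low-assumption rule; it is applied identically to
model curves and Kaplan–Meier curves, so comparisons are not biased by the
convention.  Curves whose knots stop early (heavy censoring) therefore get
finite medians, at the price of an extrapolation that the data cannot
check — one reason evaluation prefers pooled statistics over per-patient
tails.

**Kaplan–Meier.** `km_fit` wraps the lifelines product-limit estimator;
ties between events and censorings at one timestamp process events first.
Curves keep a final flat knot at the last observed time so that the
no-event stretch after the last event is represented explicitly.

**Conditional tail mean.** `conditional_mean_beyond(curve, c)` returns
c + (∫_c^T S dt) / S(c) with T the time the extended curve reaches 0,
computed by exact piecewise integration (rectangles for step segments,
trapezoids for linear ones and the extension).

## Base learners

All four learners share one surface — `fit(X, y)` /
`predict_curves(X)` — and z-score features internally with training-fold
statistics, which makes a single regularization constant meaningful across
features of very different scales (ALSFRS-R points vs cortical thickness
in millimetres).

**AFT** (`aft.py`): log event time linear in features plus σ·noise;
lognormal (default) or Weibull.  The right-censored likelihood is
maximized directly by L-BFGS with analytic gradients; standard errors come
from the observed information.  Lognormal is the default because ALS
progression heterogeneity is large and log-symmetric residuals are a
common default for survival-time regression in this disease.

**Cox–Kalbfleisch-Prentice** (`cox.py`): coefficients maximize the Breslow
partial likelihood (damped Newton, step-norm tolerance 1e-10, max 50
iterations; coefficient magnitudes above 20 on z-scored features are
treated as separation and raised as errors).  The baseline is the
Kalbfleisch–Prentice product estimator: at each distinct event time the
factor α solves Σ_{i∈D} w_i/(1−α^{w_i}) = Σ_{j∈R} w_j (closed form when
the event is untied; Brent otherwise).  With all coefficients zero this
reproduces the Kaplan–Meier curve exactly, knot for knot.

**MTLR** (`mtlr.py`): time is discretized by m = ⌈√(#events)⌉ edges at
empirical quantiles of the uncensored event times (deduplicated; the last
edge is the largest event time).  The model is a distribution over the
m + 1 monotone label sequences; the sequence with the event in interval k
scores Σ_{j≥k}(θ_j·x + b_j).  A censored patient's likelihood sums the
sequences consistent with survival past the censoring time.  The ridge
penalty (C/2)(‖θ‖² + ‖b‖²) covers the biases as well as the coefficients:
with quantile-placed bins the uniform distribution over sequences is the
natural fully-regularized limit, and a single constant C remains the only
tuned hyperparameter.  The concave objective is maximized by L-BFGS
(analytic gradient, relative-objective tolerance 1e-8, 500 iterations;
non-convergence raises).  Predicted curves evaluate S at the grid edges
and interpolate linearly.

**Random survival forest** (`rsf.py`): trees grown on bootstrap resamples;
at each node the split maximizes the two-sample log-rank statistic over
`mtry` (default ⌈√d⌉) randomly drawn features, computed vectorized over
all candidate thresholds; both children must retain at least
`min_leaf_events` = 3 events.  Leaves predict exp(−Nelson–Aalen cumulative
hazard) of their sample on a common grid (the distinct training event
times); the forest averages tree curves.  Defaults: 100 trees, unlimited
depth.  All randomness derives from the constructor seed, so refits are
bit-identical.

## Feature selection

`cox_select` fits one multivariate Cox model on z-scored features with a
ridge stabilizer (1e-4, doubled up to 1.0 until convergence — necessary
when 182 features meet ~138 training rows) and keeps features with Wald
p < α (default 0.05).  If nothing is significant the ten largest |z| are
kept; a single significant feature is padded to two.  The selection is a
deterministic function of the training fold only.

## Evaluation

**MAE-margin.**  The predicted event time is the median of the predicted
curve.  For an event patient the target is the observed time; for a
censored patient it is the *margin time* — the mean of the training-fold
Kaplan–Meier curve conditioned on surviving past the censoring time
(always ≥ the censoring time; if the training curve is exhausted at c the
censoring time itself is used).  The reported value is the unweighted mean
absolute difference in months.  With no censoring this is exactly plain
MAE.  A confidence-weighted variant exists in the metric's source
literature; this package reports the unweighted form.  Note a structural
property: margin targets are themselves KM-derived, so the covariate-free
KM baseline is a strong competitor under heavy censoring (see
"Synthetic studies" below).

**C-index.**  Harrell's concordance over predicted times: pairs (i, j)
with i's event observed and t_i < t_j; ties in predicted time count 1/2.

**Horizon accuracy.**  Classification of "survives past h" for
h = 12, 24, 36 months; a patient censored before h is excluded (status
unknown); predicted survival means S(h) ≥ 0.5, consistent with the
median-based point prediction.

**Uncertainty.**  The 95% interval half-width of the MAE-margin is the
percentile bootstrap (default 1000 resamples) over pooled per-patient
absolute errors, seeded.

## SuperLearner

The grid is algorithm × feature-selection × feature-set =
{AFT, Cox-KP, MTLR, RSF} × {cox, none} × {clinical, image, both} — 24
cells.  Internal stratified 5-fold cross-validation of the training set
scores each cell by mean MAE-margin; per inner fold the pipeline is:
restrict to the feature set → mean-impute with inner-train means →
optionally `cox_select` on inner-train → fit (models z-score internally)
→ predict inner-test curves → MAE-margin against inner-train KM margin
times.  MTLR's C is tuned in the same inner loop over
{0.01, 0.1, 1, 10, 100} (ties prefer the larger, more regularized C).
The winner minimizes mean MAE-margin; exact ties break by a fixed
precedence (Cox-KP < AFT < MTLR < RSF, then no-selection < selection, then
clinical < image < both: simpler pipelines first).  Cells whose pipeline
raises a model error on any fold are excluded and logged, not fatal.  The
winner is refit on the full training set (imputation, selection and
scaling all refit).  External stratified 5-fold cross-validation nests
this whole procedure for reporting; folds stratify on the event indicator,
and the KM baseline (training-fold KM curve and median for every test
patient) is evaluated on identical folds and margin times.

Leakage discipline: imputation means, scalers, selected features and the
margin-time KM are functions of the training side of every split; this is
asserted by mutation tests (corrupting test rows changes nothing on the
training side).

## Preprocessing

From a visit-level table with ISO-8601 dates: the observed time is
event−recruitment for event patients, MAID−recruitment (censored) for
patients who chose medical assistance in dying — treated as censoring
independent of disease course — and last-contact−recruitment otherwise;
days convert at 30.44 days/month.  Patients with time 0 (no record after
the first visit) are removed; features missing in > 80% of patients are
dropped; remaining gaps are mean-imputed.  Imputation scope is a switch:
`cohort` imputes once on the whole table (the single-pass order of the
original pipeline); the default `fold_safe` leaves gaps for the CV engine
to impute per training fold, avoiding test leakage.

## Synthetic cohorts

`simulate_cohort` emulates the structure the pipeline assumes: default 172
patients, 114 clinical + 68 image features with single-factor within-block
correlation (loading 0.4, pairwise r = 0.16 — a one-parameter stand-in for
correlated cortical-thickness regions), event times from a lognormal AFT
(baseline median 30 months, σ = 0.6), and independent censoring from a
uniform administrative window calibrated by root-finding so the expected
realized censoring fraction hits the target (default 45%).  A random 10%
of censored patients carry a MAID date; missingness is injected completely
at random (default 5%).  By default the prognostic signal lives entirely
in the clinical block (10 alternating-sign coefficients of 0.2); the image
block is correlated pure noise.

What the generator does *not* emulate: real ALSFRS-R trajectories,
informative censoring, site effects, non-linear effects, and anatomically
plausible thickness maps.  Passing tests therefore demonstrate the
pipeline's statistical machinery, not clinical validity on real
multi-centre cohort data.

## Synthetic study sizes

The verification studies run the full nested machinery, so their cohorts
are scaled down from the default; sizes were fixed from runtime and
structural considerations:

* **Selection-sanity study** (does internal CV prefer the clinical block
  when only it carries signal?): 130 patients, 24 clinical (8 informative,
  |β| = 0.25) + 20 pure-noise image features.  The image block is kept
  large relative to the training-fold size because the property under
  test is precisely the cost of carrying an uninformative block of that
  relative size; full 24-cell grid with MTLR C ∈ {0.1, 1, 10} and
  20-tree, depth-6 forests.
* **Baseline-comparison study** (does the learned pipeline beat the
  covariate-free KM estimator on MAE-margin?): 172 patients (the default),
  10 clinical (6 informative, |β| = 0.3, giving nested-CV C-index ≈ 0.70,
  the discrimination level reported for the full-scale tool) + 6 image
  features; grid restricted to AFT (the generator's true family) and
  Cox-KP to keep 20 nested runs tractable.  Because margin targets are
  KM-derived, the KM baseline is structurally favored under 45% censoring
  and the model's expected advantage is of the order of one month —
  comparable to its across-seed spread — so in these conditions the
  pipeline beats the baseline in a majority of replicates, not in nearly
  all of them.
* The acceptance script's end-to-end run uses 150 patients, 24 + 20
  features and the same reduced grid.

## Known limitations

* The tail-extension rule is a convention; medians of curves that remain
  above 0.5 at their last knot inherit it.
* MAE-margin's margin times presume independent censoring — the same
  assumption under which MAID censoring is handled.
* The KP baseline and KM curves are step functions; their medians move in
  whole event-time steps on small folds.
* High-dimensional no-selection Cox/AFT cells can legitimately fail on
  small folds; the SuperLearner skips and logs them rather than aborting.
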