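# Methods

## The estimation problem

The package estimates a person's cognitive state from how they type.
Inputs are raw keystroke session tensors — press/release timestamps,
keyboard zones, key-type categories, touchscreen tap offsets, and
assisted-typing events from four semi-controlled tasks (two on a
mechanical keyboard, two on a touchscreen). Outputs are associations
between typing-derived model scores and clinical reference targets:
nine cognitive-subdomain scores derived from MoCA, DRS-2, FAB and ADLQ
items, and the MoCA total. No typed content (letter identities) ever
enters the data model, so the analysis is content-agnostic by
construction.

## Clinical outcomes scoring

Every scale item x_i with maximum max(x_i) is normalized to an
impairment scale: norm(x_i) = x_i/max(x_i) when a higher raw score means
more impairment, and 1 − x_i/max(x_i) when it means better function (the
unique affine map preserving [0, 1] and the two anchors). A subdomain
score is the plain mean of the normalized values of the M valid
(non-missing) items mapped to that subdomain; it is reported only when
M ≥ `min_items` (default 1). Summation uses `math.fsum`, so scores are
exactly invariant to item order. All item weights are 1; the mapping
schema reserves a weight field for forward compatibility.

The shipped mapping covers nine subdomains (verbal memory, non-verbal
memory, visual motor ability, language/verbal skills, executive
function, perception, attention and concentration, visuospatial
function, mental tracking/monitoring) fed by MoCA grouped sections
(standard maxima 5/3/6/3/2/5/6, summing to 30), DRS-2 subscales
(37/37/6/39/25), FAB items (max 3) and the ADLQ self-care subscale
(0–3, higher = worse). DRS-2 and FAB enter as raw (not age-corrected)
scores. The item-level catalogue is a documented approximation at the
instrument-subscale granularity; finer mappings load from YAML and are
validated against the canonical subdomain names. The MoCA total is the
raw sum of the seven section scores in natural orientation (higher =
better); by default it is missing unless all seven sections are present.

## Typing features

Each session reduces to fixed-catalogue statistics (order pinned by a
SHA-256 hash in the test suite):

* **keystroke** — mean/median/SD/IQR/5th/95th percentiles of hold times
  (release − press) and flight times (next press − release; negative
  under rollover and deliberately retained), fraction of flights above
  the pause threshold (default 500 ms, a common convention,
  configurable), fraction of negative flights, and keystrokes per second
  over the first-press→last-release span (so all timing features are
  invariant to uniform time translation).
* **language** — word statistics from key-type runs: words are maximal
  alphanumeric runs closed by space/enter/punctuation; a backspace
  removes the most recent character from the current word count (floor
  0); modifier and emoji keys are transparent. Reported: word count,
  mean/SD/max word length, punctuation per word, enter count, delimiter
  fraction.
* **precision** — backspace fraction on all tasks; on touchscreen tasks
  also mean/SD of tap-offset magnitude √(Eₓ² + E_y²) in key-width units
  and autocorrect/word-suggestion events per 100 keystrokes.
  Touchscreen-only statistics have no catalogue slot on mechanical
  tasks, so they can never be confused with missing data.

Statistics needing at least two values (SD, IQR, flight statistics on a
one-event session) are missing when undersized. A subject's feature
vector concatenates the applicable families over the four tasks
(~100 slots); absent tasks produce missing slots, and the vector length
is identical for every subject regardless of missingness. Keyboard zones
are carried in the data model but no zone-derived feature is in the
default catalogue; the catalogue is the extension point.

## Models and cross-validation

Three variants, all trees (hence no feature scaling), all with 100
estimators and squared-error loss, all at library-default
hyperparameters to avoid tuning-induced overfitting:

* **independently optimized** — one LightGBM GOSS boosted regressor per
  target. Missing features are routed natively by the trees; subjects
  missing a target are dropped from that target's training set only, so
  per-target n varies with item missingness.
* **jointly optimized** — one multi-output ExtraTreesRegressor over all
  targets, exploiting their correlation. Features are mean-imputed with
  training-fold means (re-applied unchanged to test folds); subjects
  with any missing target are dropped (complete-case), so n is uniform
  across targets.
* **single-output** — the independent architecture trained on the MoCA
  total, as the conventional one-score reference.

Evaluation uses 10 repetitions of a randomized 3-fold cross-validation
grouped by subject: each repetition permutes the subjects into three
near-equal folds, and no subject's data ever appears on both sides of a
split — violations raise an internal leakage error rather than passing
silently. Fold permutations derive from (seed, repetition); model seeds
from (variant, target, repetition, fold); the generator derives child
streams per subject and per (subject, task), so adding a subject never
perturbs another's draws and every output is byte-identical under a
fixed seed. Folds are not stratified by diagnosis group (plain random
grouping); stratification is not implemented.

The reported association uses the per-subject mean of the 10 out-of-fold
predictions (one stable estimate per subject); the per-repetition table
is also available. Metrics: Pearson r and Spearman ρ with two-sided
t-approximation p-values, R² and p from the OLS of the target on the
prediction (identical to Pearson's p in the simple regression), and MSE.
Stars: p < 0.001 (***), < 0.01 (**), < 0.05 (*), else n.s., with the
0.05 boundary strictly non-significant. Zero-variance inputs yield an
explicitly flagged undefined result rather than NaN propagation. No
multiple-testing correction is applied; reports state the number of
tests run.

Confounder screening: a₀ is the OLS slope of the target on the model
score; a_adj is the score's slope after adding the covariate (age in
years, or sex coded 0/1); change = |a₀ − a_adj|/|a_adj|, flagged when
strictly above 10%. A near-zero a_adj is reported as degenerate instead
of an infinite change.

Attributions use the additive TreeSHAP decomposition built into the
boosted models (`pred_contrib`), computed on each iteration's test-fold
subjects, absolute values averaged per feature, summed within feature
family × task, and normalized to fractions per target. The joint
extra-trees variant exposes no additive attribution and raises an
explicit unsupported error. All-constant features yield a flagged
uniform attribution.

## Synthetic cohort generator

The generator emulates the two-group study design so the whole chain is
testable end to end. Each subject carries a latent global severity g
drawn per group (defaults: impaired mean 0.55, normal mean 0.15, SD
0.12, truncated to [0, 1]) and per-subdomain impairment
θ_d = clip(g·loading_d + ε_d), ε_d ~ N(0, 0.08). The shared g
reproduces the positive inter-subdomain correlation that motivates
joint multi-output modelling. Demographics are drawn per group to match
the documented cohort (ages 73.6 ± 6.4 vs 71.1 ± 7.3, education
16.8 ± 2.7 vs 16.4 ± 2.1 years, sex ratios 23/38 vs 20/39) with no
pathway from age or sex to typing, so the confounder analysis is
null by construction.

Scale items: the expected normalized impairment of an item is the mean
θ over its mapped subdomains, mixed with uniform noise at weight
(1 − item_reliability) (default reliability 0.9), and realized as a
binomial draw over the item's integer range, stored in the item's
natural orientation; items go missing at rate 0.03, whole task sessions
at rate 0.03.

Typing: hold and flight times are log-normal, parameterized directly by
arithmetic mean and coefficient of variation (so a +30% mean effect
scales the sample mean by exactly 1.3); flights mix in a log-normal
pause component and bounded negative rollover overlaps; key-type
streams are geometric-length words with space/punctuation/enter
delimiters and per-keystroke backspace-plus-retype corrections;
touchscreen tasks add Gaussian tap offsets and Poisson assisted-typing
events. Copy tasks are longer (420/340 events) than description and
conversation tasks (260/160) — sizes chosen as realistic for 5-minute
tasks while keeping simulation fast. An explicit effect matrix maps each
subdomain's θ to parameter shifts; the default calibration plants
strong effects on verbal memory (hold +35%, flight +50%, pauses +0.15
at θ = 1) and executive function (flight CV +60%, backspaces +0.10,
word length −1.5, tap scatter +50%, autocorrect +2/100). These defaults
are calibration knobs for a plausible, recoverable signal, not
estimates of any real cohort — no published effect sizes link
impairment to these parameters.

Two named scenarios support calibration studies: a **null**
configuration (empty effect matrix: typing carries no information about
cognition) and an **independent-subdomain** configuration (one group,
g fixed at 0.5, subdomain noise SD 0.25) in which the θ_d are mutually
independent, so effects planted on some subdomains must not surface in
others.

What the generator does *not* emulate: real text content or passage
semantics, learning/fatigue within a session, device-specific timing
quirks, and any direct demographic influence on typing. Passing tests
therefore demonstrate the pipeline's correctness and statistical
behaviour under a known generative model, not clinical validity on real
cohorts.

## Numerical and design choices

* Backspace is its own key-type category: the precision family needs it
  counted content-agnostically, and it must not distort language word
  lengths (it participates in corrections, and word counting subtracts
  it).
* Timestamps are milliseconds relative to session start; absolute start
  time lives in the session context, which keeps features
  device-clock-independent.
* Tap offsets are in key-width units for device-resolution independence.
* SDs use ddof = 1; percentiles use the default linear interpolation.
* LightGBM ≥ 4 requests GOSS via `data_sample_strategy="goss"` (the
  algorithm previously selected by `boosting_type="goss"`);
  `deterministic=True` and `force_row_wise=True` are pinned so results
  are reproducible across thread counts.
* Signal-recovery experiments evaluate predictions against the latent
  θ: item-derived scores share items across subdomains (every
  verbal-memory item also maps to non-verbal memory), so only θ is a
  clean per-subdomain ground truth.
* Test and acceptance problem sizes: null calibration uses 20 seeds at
  n = 120; signal recovery and the subdomain-over-item comparison use
  10 seeds at n = 200; these sizes give stable Monte-Carlo estimates
  while keeping a full suite run in a few minutes on one CPU.

## Known limitations

* **Anticonservative null p-values.** Out-of-fold predictions pooled
  across folds share trained models between subjects, so correlation
  p-values computed under an independence assumption are
  anticonservative: under a pure null at n = 120 the pooled aggregated
  Spearman ρ has SD ≈ 0.15 (vs 0.092 for independent pairs) and a small
  negative bias ≈ −0.08 (models predict approximately the training-fold
  target mean, which anti-correlates with the held-out fold's own
  targets), yielding a ~25–30% nominal star rate at p < 0.05. The same
  mechanism produces occasional |ρ| ≈ 0.2–0.3 negative correlations on
  genuinely unpredictable targets. This is a property of the evaluation
  design itself — the acceptance suite measures it honestly rather than
  masking it — and is worth keeping in mind when reading significance
  stars on small cohorts.
* Binomial item discretization bounds how well subdomain scores can
  track the latent state: with perfectly reliable items the attainable
  correlation is ≈ 0.94–0.95 for item-rich subdomains but only ≈ 0.78
  for the single max-6-item subdomain; the test suite checks observed
  correlations against this analytic ceiling.
* Default LightGBM regularization (≥ 20 samples per leaf, GOSS) caps
  self-fit resolution on small cohorts; a model trained on an exact
  copy of a feature reaches r ≈ 0.98, not 1.0, at n = 200.
* The item catalogue approximates instrument content at subscale
  granularity; per-item mappings, alternative maxima and directions are
  configurable through the YAML mapping schema.
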