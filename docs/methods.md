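# Methods

`typeage` estimates a behavioral "brain age" from smartphone keystroke
metadata and asks whether people at elevated risk of bipolar disorder (a
positive screen on the Mood Disorders Questionnaire, MDQ) are systematically
predicted older or younger than their chronological age. This note documents
the models, the estimators, the synthetic-data generator and the numerical
choices, in that order.

## From keypresses to features

The atomic record is a keypress event: subject id, timestamp in seconds, and
a type in {alphanumeric, backspace, autocorrect, other}. No content is ever
represented. Each subject's stream is tokenized into **sessions**: maximal
runs in which consecutive events are separated by strictly less than 5
seconds. A gap of exactly 5.000 s therefore splits (the joining rule is
strict `<`), identical timestamps join, and single-keypress sessions are
kept; their handling is deferred to the feature layer. Tokenization refuses
unsorted input rather than silently re-sorting, because silent reordering
can mask ingestion bugs.

Six metrics are computed per session: keypress count, mean and median
interkey time (successive timestamp differences within the session; missing
for single-keypress sessions), autocorrect rate, backspace rate (type count
over all keypresses of the session), and session length (last minus first
timestamp). Interkey times deliberately include transitions into and out of
backspace/autocorrect events; distinguishing transition types is a separate
modeling question this package does not address.

Each subject's chronological session series is then summarised five ways —
mean, median, sample standard deviation (n−1), **unscaled** median absolute
deviation (no 1.4826 consistency factor; a robust-dispersion summary, not a
normal-sd estimate), and sample entropy — giving 6 × 5 = 30 typing features
in a fixed canonical column order.

### Sample entropy

SampEn(m, r, τ) = −ln(A/B), where B counts pairs of length-m delay templates
within Chebyshev distance r (self-matches excluded) and A the same for
length-(m+1) templates. Defaults m = 2, r = 0.2 · sd(series), τ = 1.
Choices worth noting:

* r uses the population (ddof = 0) standard deviation, the convention of
  common SampEn implementations; because r is proportional to the series'
  own sd, SampEn(a·x + b) = SampEn(x) exactly for a > 0.
* Both template lengths use the same count of N − m·τ templates, so A/B is a
  proper conditional-probability estimate.
* Matches use `distance ≤ r`, so a constant series gives A/B = 1 → SampEn 0.
* Series shorter than `min_len` = 10 sessions, or with A = 0 or B = 0,
  return a missing value rather than ±∞ or a wild small-sample estimate;
  missing features are median-imputed downstream from training data only.
  With m = 2 the estimator is defined from 4 points; 10 is a pragmatic floor
  and is configurable.

### Inclusion filter

Analysis is restricted to subjects with "enough" typing: the cohort median
of per-subject daily keypress rates defines a typical day, and a subject is
included iff their total keypress count is at least `min_weeks × 7` (default
12 weeks) of typical days. The boundary is inclusive. The exact functional
form of such a rule is a judgment call; it is isolated in
`filter_participants` so alternatives can be swapped without touching
anything else. Under the simulator's defaults (everyone observed for exactly
84 days, lognormal activity spread) this rule excludes roughly the
below-median half of the cohort — a faithful consequence of tying the
threshold to the cohort median when observation windows are equal.

## Age models

Two stepwise random-forest regressions predict chronological age: Model 1
from the 30 typing features, Model 2 from those plus a binary gender
indicator (`not_male`, mirroring how cohort composition is usually reported
for this instrument) and MDQ screen status (positive ⇔ symptom score ≥ 7).
Forests tolerate the strong collinearity among the summaries of a common
session metric, which is why they are used here.

* Split: simple random 75:25 (train gets ⌈0.75 n⌉), seeded, unstratified. A
  stratified option (age decile × screen status) exists but is off by
  default.
* Tuning: mtry (features tried per split) grid-searched over 1–30 under
  repeated k-fold CV (default 10-fold × 3). The score is the **mean of fold
  RMSEs** (not pooled residuals); ties resolve to the smallest mtry. Grid
  values exceeding the predictor count are skipped with a warning.
  Fold-level median imputation avoids leaking validation information.
* Forest: 500 trees by default, terminal-node size 5 (the classic regression
  default of the R forest implementation), bootstrap on, out-of-bag
  predictions retained.
* Imputation: training-set medians, stored in the fitted bundle and reused
  verbatim at prediction time.
* Errors: raw error = predicted − actual (positive = predicted older);
  absolute error = |raw error|.

## Evaluation and group comparisons

Performance: RMSE, Breiman's pseudo R² = 1 − MSE/Var(actual) (population
variance, so pseudo-R² = 1 − RMSE²/Var exactly), and median absolute error.
Model 1 vs Model 2 is a paired two-sided Wilcoxon signed-rank test on
absolute errors; the reported statistic V is the positive-rank sum and zero
differences are dropped. Screen-positive vs screen-negative contrasts are
two-sided Wilcoxon rank-sum tests on raw and absolute validation errors; the
statistic W is the first (screen-negative) group's Mann–Whitney U. The exact
null is used when the pooled sample is ≤ 50 without ties, otherwise the
normal approximation with continuity correction. Holm–Bonferroni is applied
over the two screen-status tests (that two-test family only); the model
comparison is reported unadjusted. α defaults to 0.05, two-sided.

## Interpretation

**Permutation importance** follows the OOB convention: per tree, the MSE on
that tree's out-of-bag observations is compared before and after permuting
one feature's values among those observations; deltas are averaged over
trees and over 5 permutation repeats (seeded). A feature independent of the
target has importance → 0; duplicated features share credit.

**Accumulated Local Effects (ALE)** are computed natively against any
`predict_fn`, with quantile (equal-count) bins and duplicate edges
collapsed. First order: per-bin mean of f(upper edge) − f(lower edge) over
the bin's observations, accumulated, then centered so the count-weighted
mean of the interpolated effect over the data is zero. ALE's local finite
differences make it honest under correlated features — a linear predictor's
slope is recovered exactly regardless of correlation, which partial
dependence cannot promise. Second order: per-cell mean second differences
accumulated over the 2-D grid (empty cells borrow the nearest occupied
cell's local effect); each cell takes the four-corner average of the
accumulated surface; then the count-weighted additive row/column structure
is removed by an exact weighted least-squares projection. This projection is
a deliberate refinement of the usual marginal-subtraction estimator: under
unbalanced cell counts it leaves the count-weighted row and column means
zero to machine precision, which is the defining property of a pure
interaction surface, and it coincides with the usual estimator when counts
are balanced.

## The synthetic cohort

No raw keystroke streams ship with this package, so a generator produces
cohorts with the statistical structure the analysis assumes. Defaults
describe the study conditions the pipeline is designed for: 344 subjects,
ages 18–88, two-thirds screening positive (score ≥ 7 for positives, ≤ 6 for
negatives), 84 days of observation, ~4 sessions/day, and per-subject
lognormal activity multipliers (log-sd 0.6) that land the median total near
~10,000 keypresses over 12 weeks while producing the heavy right tail
(mean ≫ median) typical of passive-sensing totals.

Mechanisms, each the simplest that produces the intended association:

* **Typing speed**: mean interkey time rises linearly with *effective typing
  age* (0.25 s at 18 + 0.003 s/year by default), with lognormal subject
  (log-sd 0.15) and session/keypress (log-sd 0.10) fluctuations. Interkey
  draws are clipped below 98% of the gap threshold and sessions are laid out
  ≥ 5 s apart, so tokenization recovers the generated session boundaries
  exactly — a round-trip the tests assert.
* **Session length**: target mean duration grows linearly with age (8 s +
  0.08 s/year); the keypress count per session is geometric with mean
  matching the target duration at the subject's speed, so session length
  emerges rather than being imposed.
* **Error-key behavior**: per-session backspace/autocorrect probabilities
  fluctuate on the log scale following an AR(1) process whose coefficient
  rises with effective age (0 at the youngest age up to 0.8 at the oldest by
  default). Older subjects' rate series are therefore smoother — lower
  sample entropy. Serial correlation, not variance, has to carry this
  effect: because SampEn's tolerance tracks the series' own sd, merely
  shrinking the variance of an i.i.d. series would change its entropy not
  at all.
* **Brain-age offset**: screen-positive subjects' effective typing age is
  their true age plus a single scalar δ (default 0). This is the minimal
  mechanism for "types older than their years" and is the planted truth the
  gap statistics must recover.
* **Gender** has no effect on typing in the default generator; the profile
  plumbing provides the hook should one ever be wanted.

What the generator does **not** emulate: language content, diurnal
typing-speed cycles, day-to-day mood autocorrelation, device changes, or any
dependence between activity level and age or screen status. Passing tests
therefore demonstrate that the estimators and the pipeline recover planted
structure of the assumed form — not that real cohorts satisfy those
assumptions.

A compact `strong_signal_params` preset (steeper slopes 0.008 s/yr and 0.30
s/yr, subject noise 0.05, 14 days) exists for validation studies where the
age signal should dominate sampling noise.

## Validation experiment sizes

The simulation-backed checks run at sizes chosen to make their conclusions
stable while keeping the suite quick: signal recovery uses one n = 400
strong-signal cohort with the full mtry 1–30 grid under 5-fold × 1 CV and
150-tree forests; offset recovery uses 20 replicates of n = 120 cohorts
(validation ≈ 30, giving the rank-sum test high power at δ = 6); null
calibration uses 200 replicates of n = 80 cohorts with 60-tree forests. The
δ-recovery replicates use the typing-only model: a gap analysis should
compare groups on a prediction that is blind to group membership, and Model
2's access to the screen flag lets the forest partially absorb the planted
offset (it still detects it, with reduced power — the mixed-cohort analogue
of training a normative model on patients).

The acceptance script runs the full default-condition protocol (n = 344
enrolled, 12-week filter, grid 1–30, 10-fold × 3 CV) with 250-tree forests.

## Degenerate inputs and tie-breaks

Empty event streams tokenize to zero sessions; subjects without sessions are
dropped at featurization. Constant prediction targets fit to a constant
forest. A feature that is missing for every training subject is an error; a
subject missing every feature predicts from the all-median vector. The
paired test on identical error vectors raises (no information), as do
empty groups, empty cohorts and zero-variance targets in pseudo-R².
Millisecond timestamps are detected by magnitude (> 10^11) and converted to
seconds with a log message. Ages implied by birth year outside [18, 120] are
rejected with a warning rather than silently kept.

## Known limitations

* The inclusion rule is one defensible reading of a cohort-median
  criterion; others (per-day medians, distinct-active-day thresholds) are
  plausible and would change who is analyzed.
* SampEn on ~50–300-session series is a noisy estimator; the `min_len`
  floor avoids the worst of it but short observation windows still produce
  missing entropy features that fall back to median imputation.
* The generator's δ mechanism shifts the whole typing phenotype coherently;
  real neuroprogression would likely affect features unevenly.
* Exact rank-sum p-values are used only in tie-free pooled samples ≤ 50;
  elsewhere the continuity-corrected normal approximation is standard but
  approximate at small n with many ties.
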