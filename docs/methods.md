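# Methods

`oddsearch` analyzes trial tables from *urgent* four-alternative oddball
search: the go signal precedes the color cue by a Gap of 0–225 ms, a valid
response must occur within 450 ms of the go signal, and the processing time
PT = RT − Gap measures how long the cue could inform the choice (negative
PTs are legitimate — the saccade left before the cue appeared). This note
records the models, the numerical conventions, and the design choices made
where the procedure was genuinely open.

## Tachometric curves and their summaries

Accuracy versus PT is estimated in 50-ms bins sliding in 1-ms steps. Each
bin is half-open, `[c − w/2, c + w/2)`, so every PT value is counted the
same number of times across the sliding grid and results are
bit-reproducible. Empty bins are carried as missing, never as zero, and are
not interpolated.

Two summaries are independent of any binning: **floor accuracy** is the
proportion correct over trials with PT < 100 ms (uninformed guesses; chance
is 0.25) and **ceiling accuracy** over trials with PT > 150 ms (informed
choices). Both inequalities are strict as real-number comparisons; the
100–150 ms transition band belongs to neither. Binomial proportions carry
Agresti–Coull 95% intervals (add-z² adjusted Wald, clipped to [0, 1]).
Between-condition comparisons use a trial-level percentile bootstrap
(default 10,000 resamples, stratified by group, mandatory seed); the
two-sided p-value is add-one smoothed.

S−D difference curves subtract two curves bin by bin with the binomial
standard errors combined in quadrature. Because neighboring sliding bins
share up to 49 of 50 ms of data, pointwise exceedance of an SE band on the
sliding grid has an n-independent false-positive rate; *decisions* about
the presence of an effect in a PT regime are therefore taken on the
binning-independent floor/ceiling aggregates (`analysis.region_contrast`),
with the band drawn at 2.5 combined standard errors (two-sided ≈ 99%).

## Selection-history labels

Histories are computed within sessions only; a trial with fewer than the
required predecessors belongs to no condition. Two schemes coexist because
both are needed:

- **run mode**: the N immediately preceding trials form a homogeneous run
  (all same / all different color or quadrant; all correct / all errors).
  "At least N" semantics hold, so (N+1)-deep membership nests inside
  N-deep. For location, "different" constrains each predecessor relative
  to the current target only — predecessors may repeat among themselves.
- **sequence mode**: each of the H preceding trials carries its own
  relation letters (4^H color×location sequences, 8^H with outcome). The
  schemes coincide at depth 1 and differ for H ≥ 2.

Lagged single events (1S(k−1)x / 1D(k−1)x) constrain only the trial k
positions back, leaving intervening trials free; they trace the decay of a
single repeat or switch. By default histories are computed over the same
RT-filtered trial set that enters analysis; a caller can classify before
filtering if the alternative convention is wanted.

Quadrants are half-open 90° sectors anchored counter-clockwise on the
axes (positive x axis → right, positive y axis → up, …), which covers the
plane without gaps or overlaps; the origin has no quadrant.

## Curve alignment and pooling

Two subjects' curves are aligned by z(j) = g·y2(j+δ) + b, minimizing the
mean absolute deviation per overlapping bin. The L1 objective is piecewise
linear, so the optimum is found by exhaustive grid search: δ at the grid's
step resolution (coarse pass over the full range, fine pass within ±5
steps), g ∈ [0.5, 1.5] (step 0.01) and b ∈ [−0.25, 0.25] (step 0.005) in a
coarse-to-fine nest. Ties break toward smallest |δ|, then |b|, then g
nearest 1. Bins estimated from fewer than 25 trials are masked from the
objective: sparse tail bins are individually so noisy that pushing them
out of the overlap would otherwise be rewarded more than any true
alignment. Normalizing per overlapping bin prevents the complementary
failure (rewarding small overlaps). Only δ propagates to the data, as an
RT shift applied before pooling; g and b are diagnostics.

## The conditional-independence interaction test

For history variables A and B and outcome C, conditional independence
P(A,B|C) = P(A|C)·P(B|C) plus Bayes' rule yields the no-interaction
benchmark

    P(C=1|A,B) = pa·pb / (pa·pb + (1−pa)(1−pb)·π/(1−π)),

with pa = P(C=1|A), pb = P(C=1|B), π = P(C=1). The package measures the
left side directly from jointly conditioned trials and predicts it from the
right; the analysis is restricted to informed trials (PT > 150 ms), and the
prior π defaults to the informed-trial proportion correct of the full set
(a flag switches to the all-PT proportion — the informed-trial version is
the one consistent with the components it combines). Points whose measured
CI spans ≥ 15 percentage points are flagged unreliable; the β₂ summary is
the OLS slope of predicted (y) on measured (x) over reliable points, with a
percentile bootstrap CI over points (10,000 resamples, seeded) as primary
and the closed-form OLS interval reported alongside. β₂ ≈ 1 indicates
independent contributions; interactions shrink the predicted range relative
to the measured one and flatten the slope.

The reliability rule is applied to the measured CI (the quantity plotted on
x); requiring reliable components as well is a caller-side filter, not the
default, so that the flag keeps a single meaning.

## The synthetic session generator

No generative model of this task is given anywhere, so the generator is the
package's own construction, built to have exactly the statistical structure
the analyses assume and fully known ground truth:

- target color ~ uniform{red, green} and quadrant ~ uniform{4 quadrants},
  independent across trials (repetition priors 0.5 and 0.25);
- Gap uniform on {0, 25, …, 225} ms (the task reports a 0–225 ms range
  without its sampling grid; a 25-ms grid is the package default and is
  configurable); RT ~ Normal(275, 60) truncated to (0, 450]; PT = RT − Gap;
- the choice arbitrates between an informed route, taken with probability
  q(PT) = logistic((PT − center)/width), and a guess route (softmax over
  four location weights). Informed choices hit the target with probability
  p_ceil and otherwise pick a uniform distracter.
- history enters through two leaky integrators updated after every trial
  and gated by its outcome (reward → +κ on the trial's target
  quadrant/color, error → −κ; all traces decay by exp(−1/τ) per trial):
  per-quadrant guess weights (location priming, τ = 9 trials) and a
  per-color gain added to the logit of p_ceil (color priming, τ = 5
  trials). Probabilities are kept in (0, 1) by the logistic link, never by
  clipping. An optional interaction term couples the two traces; at its
  default of 0 the generator satisfies the conditional-independence
  structure the interaction test assumes under the null.

Defaults: floor 0.25, ceiling 0.70, center 125 ms, width 6 ms,
κ_color = 0.7 (logit units), κ_location = 0.8 (softmax-weight units). The
width makes the informed probability effectively 0 below PT = 100 ms
(q(100) ≈ 0.015) and effectively 1 above 150 ms (q(150) ≈ 0.985), so the
generator's true floor over the PT < 100 region is 0.2505 and its ceiling
0.6997 under the default Gap/RT distributions — consistent with the
chance-below-100 / ceiling-above-150 structure the floor and ceiling
summaries presuppose. A wider rise (e.g. 15 ms) leaks informed choices
into the floor region and biases its accuracy above chance by ~1.4
percentage points, which is why the steeper default was chosen. The κ
values produce outcome-conditioned accuracy swings of roughly 15–25
percentage points and unconditioned S−D effects of a few points,
magnitudes typical of reward-gated priming of pop-out.

Two generator properties are worth knowing when interpreting tests:

- With symmetric ±κ updates and an overall accuracy near 50%, the
  *unconditioned* S−D effects are strongly diluted relative to the
  outcome-conditioned ones, and the color ceiling effect can even reverse
  sign through outcome-selection feedback (informed trials reinforce high
  gains, guessing trials punish them). Magnitude-based checks are
  therefore used for unconditioned contrasts.
- The generator emulates accuracy modulation only; history effects on RT
  itself are not modeled, and real data features such as session drift,
  fatigue, and between-subject parameter differences are absent. Passing
  tests show the pipeline recovers the structure the generator puts in —
  not that real data contain that structure.

All latent trajectories and the uniform draws consumed by the choice rule
are logged, so emitted choices can be replayed deterministically from the
log; with all couplings at zero the simulation takes a vectorized path
that consumes the identical random stream, so the two code paths are
draw-for-draw interchangeable.

## Parameter recovery

The history-free accuracy model p(correct|PT) = floor + (ceiling −
floor)·logistic((PT − center)/width) is fitted by direct Bernoulli
maximum likelihood: a deterministic grid over center/width start values
(floor/ceiling started at the region means), then bounded L-BFGS-B.
Standard errors come from the numerically differentiated observed
information with the width parameterized on the log scale — a positive
scale parameter has a right-skewed sampling distribution, and the
symmetric interval on log(width), exponentiated, restores near-nominal
coverage where the naive Wald interval undercovers. Estimates pinned at a
bound (e.g. ceiling → 1 on all-correct data) are flagged and their Wald
intervals are not to be trusted; a singular information matrix (e.g.
PT-shuffled data, where width is unidentifiable) flags the width as
uninformative.

## Problem sizes used in the shipped checks

The package's own test battery uses simulations of 20,000–200,000 trials
per check (100 replicates for CI-coverage properties, 50 for alignment
recovery, 1,000 random sessions for the label-oracle comparison) — sizes
at which the Monte-Carlo error of each asserted quantity is several times
smaller than its assertion margin.

## Known limitations

- Alignment is pairwise only; aligning several subjects means aligning
  each to a common reference.
- The β₂ bootstrap resamples points, not trials; with very few reliable
  points the interval is wide and the OLS interval is the more stable
  companion readout.
- The loader derives `correct` from the quadrant comparison and treats a
  contradicting `correct` column as a hard error by default; data coded
  with chosen-location conventions other than the four-quadrant scheme
  must be mapped before loading.
- Eye-movement processing (saccade detection, calibration) is upstream of
  the trial table and out of scope.
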