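# Methods

`cpgait` re-implements, as a tested pipeline, the probabilistic
classification of joint-motion gait patterns in children with cerebral
palsy (CP), together with a synthetic gait-data generator that stands
in for the clinical database such studies are built on.  This note
documents the models, the generator, the numerical choices, and what
the tests do and do not establish.

## Problem and data model

Three-dimensional gait analysis yields joint-angle curves over the
gait cycle.  Each curve is time-normalized to 51 samples (0–100% in 2%
steps; initial contact at 0%).  Nine angle tracks are modeled (pelvis
and hip in three planes, sagittal knee and ankle, foot progression
angle).  Eleven *joint motions* are classified independently: pelvis,
hip and foot-progression motions on the full cycle, and the sagittal
knee and ankle separately during stance (`[0, toe_off]`) and swing
(`[toe_off, 100]`), each phase re-normalized to its own 51 samples.
Every joint motion has 3–6 expert-defined pattern classes (46 total;
the two stance-knee patterns that differ only in kinetics are merged
because the pipeline is kinematic).  Left/right side is not modeled; a
trial is one limb's cycle.

A *normative band* — pointwise mean ± SD curves plus cycle-mean
summaries from a typically developing (TD) reference cohort — anchors
all "deviates from normal" features.  Zero SDs in a degenerate
reference are floored at 0.5° (configurable, logged) so band features
stay defined.

## Expert features and discretization

The 24 expert features comprise 18 continuous quantities (extrema,
timings, ranges of motion, band-exceedance percentages, angles at
fixed cycle points, and the second-rocker excursion) and 6 composite
features, each a pair of mutually exclusive above/below band flags
mapping to three states.  Bins are left-closed with the last bin
closed; values outside the printed outer bounds clamp to the outer
bins with a warning, since those bounds are observed data ranges.

Operational definitions that the consensus literature leaves implicit
are configurable parameters with these defaults:

* second-rocker window: 20–80% of stance; the feature is the net
  dorsiflexion excursion over the window in degrees (the printed bin
  range of roughly −21° to 31° suggests degrees, not deg/%);
* early/mid-stance knee-flexion peak: searched in 0–50% of stance,
  timing reported as % of stance;
* terminal-swing ankle angle: read at 90% of the gait cycle;
* band flags: a trial's cycle-averaged angle against the cohort's
  cycle-mean mean ± 1 cycle-mean SD.  The foot-progression flag names
  carry a stance prefix in the consensus table; the cycle-average rule
  is used uniformly here and the stance-window reading is noted as an
  alternative interpretation.

The registry keeps 24 rows although the source text counts 23
expert-defined features; the discrepancy is documented rather than
resolved.

The full battery (default 1047 features) contains every curve sample
of every track/domain (13 curves × 51 samples) plus 12 derived
statistics (min, max, ROM, their timings, above/below band
percentages, values at 0/50/90/100% of the window, and the 20→80%
excursion) per curve window — whole cycle plus stance/swing windows
for full-cycle tracks, the full phase for knee/ankle phase curves, and
the early-stance window for the stance knee.  The 18 continuous expert
features are each identical to one battery column by construction,
which the tests assert.  Matching a particular printed feature count
is a non-goal; the count is config-reported.

## Classifiers

**Categorical Naïve Bayes.**  Class priors are empirical relative
frequencies; conditional probability tables are learned by counting
with a Laplace pseudo-count α (default 1).  α = 0 reproduces pure
maximum-likelihood counting, in which a feature bin unseen for every
class zeroes all likelihoods; that case falls back to the class prior
(logged).  Posteriors are computed in log space; hard assignments take
the maximum a posteriori class with ties resolved to the first
declared class.

**Multinomial logistic regression.**  Softmax likelihood (the
multinomial generalization of the sigmoid model; the binary case
reduces to it exactly) with an L2 penalty λ on non-intercept weights.
The source prints the penalty without a square; L2 is used as the
standard convex choice.  Minimization is quasi-Newton (L-BFGS) from a
zero start, making fits deterministic; the objective is convex, which
the tests verify by matching optima from random starts.  λ is chosen
per training fold from the grid {0.01, 0.1, 1, 10} by inner
patient-grouped 3-fold cross-validation on macro accuracy (ties prefer
stronger regularization).  A fixed λ can be configured instead; the
grid is the default because a fixed λ = 1 cannot give rare classes
(1% prevalence) enough weight against dominant classes even on
noise-free separable data.

**Encodings per approach.**  Approach 1: expert bins (NB directly, LR
one-hot).  Approach 2a: the full battery — MDL-discretized per
training fold for NB (features in which no cut passes the criterion
carry no class information and are dropped), standardized continuous
for LR.  Approach 2b: as 2a plus CFS subset selection on the binned
training fold; NB uses the selected bins, LR the selected continuous
columns.  Approach 3: expert features — MDL bins for NB, standardized
continuous for LR; composite (boolean) features pass through unchanged
as 3-state categoricals (one-hot for LR), so for the two flag-only
joint motions approach 3 coincides with approach 1.  The source
specifies the encodings only for approach 3; the rest are this
package's choices.

## MDL discretization

Recursive binary splitting on class entropy: candidate cuts are
midpoints between adjacent sorted values with differing values and
labels (with a secondary sort on the label so duplicates are handled
order-independently); the best cut by information gain (ties to the
smallest cut) is accepted only if the gain exceeds the
minimum-description-length threshold
`(log2(N−1) + log2(3^k − 2) − (k·Ent(S) − k1·Ent(S1) − k2·Ent(S2)))/N`.
Outer cuts are the observed min/max; no accepted cut yields a
single-bin scheme.  Discretization runs on training folds only and is
cached per (fold, feature).

## Feature selection

CFS merit `k·r_cf / sqrt(k + k(k−1)·r_ff)` with symmetrical
uncertainty `SU = 2·I(x;y)/(H(x)+H(y))` on discretized features as the
correlation measure (the standard CFS formulation; the source names
CFS but not the measure).  Search is forward best-first from the empty
set, expanding by single-feature additions, stopping after five
consecutive expansions without improving the global best; ties break
on the lexicographically smallest subset, making selection
deterministic.  Selection runs per training fold by default (leak-free);
a single whole-dataset run is available via configuration for
comparison with reports that selected once.

## Evaluation

Patient-grouped stratified k-fold cross-validation (default k = 10):
all trials of a patient share one fold.  Folds are built greedily —
patients in decreasing order of trial count, each placed where it
least increases the chi-square-weighted deviation between fold class
counts and a 1/k share of the global counts — followed by local
move-refinement passes; ties break from the seed.  The same fold
assignment is reused across every approach × classifier cell.

Metrics per joint motion, pooled over folds: *macro accuracy* (mean
per-class recall), *macro f-score* (mean per-class F1, 0 when
undefined), and plain percent-correct; the overall row is the
unweighted mean over the 11 joint motions.  The source is ambiguous
about whether its per-motion "accuracy" is macro or plain; both are
emitted and macro is the headline, honoring its macro-averaging
definition.  Confusion matrices (row-normalized) and average-posterior
matrices (row i = mean posterior over trials of true class i)
accompany every cell.  Trials are the classification unit.  When a
training fold lacks a class (possible for 1%-prevalence classes at
small cohort sizes), the model is fitted on the present classes and
that fold's trials of the missing class are necessarily misclassified;
this is reported, not hidden.

## Synthetic generator

The generator emulates the study conditions: 11 joint motions with 46
pattern classes at the printed prevalences; patients with 1–3 sessions
(probabilities 275/356, 67/356, 14/356) and 2–15 trials per session
with mean 4 (truncated geometric, solved numerically for the mean); a
56-child TD reference cohort; per-trial toe-off ~ N(60, 2)% clipped to
[55, 65]%.

Every track has an analytic normative template (shape-preserving
cubics through physiologic knots for knee and ankle — double-bump knee
profile, three-rocker ankle profile — and low-order sinusoids for
pelvis, hip and foot progression).  Each pattern class deforms its
source template by offsets, ROM scaling about the mean (which
preserves the cycle average and therefore the band flags), localized
bumps/dips, or replacement knots, calibrated so that each noise-free
expert-feature value sits at the midpoint of the bin named by the
pattern's clinical description (for localized deformations, at a
margin-maximizing point ≥3 noise SDs inside the bin).  Distinct
classes of a joint motion therefore occupy distinct bin combinations
and are exactly separable without noise.

Variability (all smooth in time; magnitudes are this package's
calibration, chosen by margin analysis): TD cohort between-subject
offset SD 5° plus harmonic shape SD 0.8° (this fixes the band width);
patient effect offset SD 1.5° plus shape SD 0.3°; trial noise offset
SD 0.5° plus up to three random harmonics of total SD 0.8°.  Knee and
ankle full-cycle curves are assembled from the (noisy) phase curves at
the trial's toe-off, so phase and full-cycle features stay consistent.

Pattern codes are assigned per session (fixed across a session's
trials — a child's pattern does not flip between consecutive trials)
and independently across joint motions.  Codes are *quota-sampled*
(largest-remainder apportionment of the prior over the session count,
then shuffled) rather than drawn i.i.d.: empirical prevalences then
match the printed ones at any cohort size, and a 1%-prevalence class
is represented by more than one patient in a 200-patient study — under
i.i.d. draws such a class is regularly carried by a single patient,
which makes its patient-grouped CV recall structurally zero for any
classifier.

**What the generator does not emulate.**  Real gait correlates
patterns across joints and sides; here they are independent, because
the classifiers are per-joint-motion.  Curve shapes are analytic
stand-ins, not biomechanically validated trajectories; kinetics,
spatiotemporal parameters and left/right asymmetry are absent; the
within-pattern spread of CP trials is narrower than the TD cohort's
between-subject spread by construction.  Passing tests therefore show
that the pipeline recovers labels whose generative structure matches
the expert rules — they do not certify clinical performance, and the
clinical study's headline numbers are not reproducible from synthetic
data at desk scale.

## Study sizes used by the checks

The automated checks run the default synthetic study at 200 patients
(≈900 trials): label recovery with expert features ≥90% macro accuracy
per joint motion (100% noise-free), and the naive-vs-selected ordering
(NB on the full battery without selection loses to NB with CFS) over
three replicate seeds.  Oracle-equivalence checks (NB vs joint
enumeration, MDL vs exhaustive recursion, best-first vs exhaustive
subset search) use small instances where brute force is exact.

## Known limitations

* Exact operational definitions of a few features (second-rocker
  excursion, early-stance peak search, flag windows) follow documented
  interpretations of the pattern descriptions, each behind one
  configuration parameter.
* The greedy fold builder approximates stratification; with
  whole-patient assignment, per-fold proportions of very small classes
  can deviate by more than a patient's worth of trials.
* Logistic regression on the full battery (~1000 standardized
  columns) is fit jointly; no sparsity is induced, matching the naive
  approach's intent.
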