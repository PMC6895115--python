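# Methods

## The task

The simulator reproduces a criterion-driven spatial-discrimination
serial reversal session as run in rodent operant chambers. Two response
apertures (left, right) are available; exactly one is correct at any
time and choosing it always delivers reward (deterministic
contingency). A session opens with a *retention* phase (the side
rewarded on the previous day remains correct) and then reverses the
contingency three times. A phase ends on the first trial at which at
least 9 of the subject's last 10 responses in that phase were correct;
before a full window has elapsed the criterion is evaluated over all
trials so far, so nine straight correct responses complete a phase at
trial nine. The 1 h session limit is represented by a per-phase trial
cap (default 400); a session that hits the cap is flagged a
non-completer and excluded from fitting by default, mirroring the
study-design exclusion of animals that failed to finish three
reversals. Reversals are silent: the agent's Q values and
previous-choice indicator carry over phase boundaries unchanged.

## The models

Four nested model-free learners. All update the chosen option's value
by the Rescorla–Wagner delta rule

    Q(c) <- Q(c) + alpha_eff * (r - Q(c)),     r in {0, 1}

with the unchosen option untouched, and choose through a softmax over
the two values with a *temperature* convention — Q is divided by beta,
so larger beta means more exploration — plus a choice-autocorrelation
("stickiness") bonus kappa for the side chosen on the previous trial:

    P(L) = exp(Q(L)/beta + kappa*L_prev) /
           [exp(Q(L)/beta + kappa*L_prev) + exp(Q(R)/beta + kappa*R_prev)]

kappa is added outside the 1/beta scaling. The variants are M1 (alpha,
beta; kappa = 0), M2 (separate alpha_reward / alpha_noreward selected
by the trial's outcome), M3 (single alpha plus free kappa) and M4 (dual
rates plus kappa). M1/M2 are exactly the kappa = 0 special case of
M3/M4 and all four share one likelihood code path, which the tests
exploit (nested reductions agree to < 1e-12 per trial).

Parameter ranges: learning rates in [0, 1]; beta > 0 with the fitted
grid spanning [0.005, 5]; kappa in [-1, 1]. Q values start at q0
(default 0; any symmetric value yields P = 0.5 on trial 1, where both
previous-choice indicators are 0).

## Fitting

The log-likelihood of a session factorizes over trials. Model space is
treated as discrete: axes alpha 0.001:0.08:1 (13 points), beta
0.005:0.08:5 (63 points), kappa -1:0.08:1 (26 points), dual rates
sharing the alpha axis; every combination is evaluated exhaustively and
the maximizer returned. Because the Q trajectory depends only on the
learning rate(s), the search computes, per learning-rate point, the
whole (beta, kappa) plane in one broadcast expression; per-element
arithmetic and the trial-axis reduction are the same operations the
scalar likelihood performs, so a naive nested loop over grid points
reproduces `grid_fit` exactly (bit for bit), which the acceptance suite
asserts. Ties — common in short sessions — are broken deterministically
by scan order (rates ascending, reward rate outermost, then beta, then
kappa). Natural logarithms throughout.

The kappa axis as published (-1 upward in steps of 0.08) does not
contain 0, so grid-restricted sticky fits can come out marginally below
a nested smaller model; `ParameterGrid.augmented()` inserts the neutral
point for nesting property tests, and a negative likelihood-ratio
statistic is clamped to zero with a warning, since nesting is a
property of the continuous models.

## Model comparison

* Likelihood-ratio test: d = 2·(logL_big − logL_small), chi-square with
  df = difference in free parameter counts; at df = 1 the p = 0.05
  boundary on a 0.001 grid is d = 3.842.
* pseudo-r²: the chance-normalized log-likelihood 1 − logL/(m·ln 0.5),
  0 at coin-flip performance and 1 at perfect prediction. A historical
  variant that normalizes by the raw chance probability 0.5^m instead
  of its log is kept behind a flag for audit only; it is not on the 0–1
  scale and is used nowhere.
* BIC in the larger-is-better convention logL − (k/2)·ln m (m = trials,
  k = free parameters); multiply by −2 for the textbook scale.
* Cohort selection: mean BIC per model on a designated primary subset
  (default the post-exposure high-escalation cell, the cell the sticky
  model exists to explain), with per-subject LRTs as supporting output.

## Behavioral statistics

* **Win-stay / lose-shift**: over consecutive trial pairs pooled across
  the session (boundary-straddling and retention pairs included by
  default — the subject cannot observe a reversal — with exclusion
  flags), the probability of repeating after a reward and of switching
  after a non-reward. Undefined (flagged, not raised) when a
  denominator is empty.
* **Trials to criterion**: per phase, the 1-based index of the
  criterion-satisfying trial; total summed over retention + three
  reversals; non-completer phases contribute their capped count plus a
  flag.
* **Perseverative errors** ("7 of the last 10 incorrect"): for each
  reversal phase, errors are counted from phase onset up to the first
  trial at which the count of incorrect responses over the last
  min(t, 10) trials drops below 7 *after having reached 7 at least
  once*; if the condition never holds the phase contributes zero.
  Counting stops permanently at the first release. This is the reading
  under which an animal that switches within its first few
  post-reversal trials scores zero while ten straight errors followed
  by recovery score exactly ten.
* **Escalation ratio**: mean intake on long-access days 6–7 (calendar
  days 12–13) divided by intake on the first long-access day (day 7);
  undefined and flagged when day 7 is zero. The cohort **median split**
  labels ratio ≥ median as high-escalation (HE), below as LE; with an
  odd cohort the median element joins HE, so 19 subjects split 9/10.
  Ties at the median all go to HE (logged).

## Synthetic cohort

No animal data ship with this package; the generator emulates the
study design so that every downstream stage is exercised end to end.
Three groups (control n = 23, LE n = 9, HE n = 10) × two timepoints;
each subject's session is generated by an M3 agent with parameters
drawn from truncated normal distributions per cell, plus a 13-day
infusion series for drug-group subjects (6 flat short-access days, 7
long-access days ramping linearly so that the noise-free escalation
ratio equals the subject's target; Poisson count noise; group targets
1.2 ± 0.13 for LE and 2.1 ± 0.60 for HE). Everything derives from one
base seed through `numpy.random.SeedSequence.spawn`, and ground-truth
parameters accompany every session.

All parameter magnitudes are this package's choices — the source data
report fitted group contrasts only graphically — constrained to sit
inside the fitted grid and to encode the qualitative finding the cohort
exists to carry: baseline cells alpha ~ N(0.70, 0.10), beta ~ N(0.30,
0.08), kappa ~ N(0, 0.05); the HE-post cell shifts to beta ~ N(1.00,
0.20) and kappa ~ N(0.85, 0.08) with alpha deliberately matched (no
learning-rate effect). A point worth recording: in a *deterministic*
reversal task, raising beta alone *increases* measured lose-shift —
exploration errors occur while the agent still values the correct side,
so the trial after such a loss usually returns to it, which counts as a
shift — and the lose-shift decrease must therefore be carried by
stickiness. The kappa-only contrast test isolates exactly this
mechanism. The defaults reproduce the full qualitative signature
(HE-post: higher fitted beta, higher fitted kappa, lower lose-shift
than both other post cells) in ≈ 39 of 40 base seeds.

What the generator does **not** emulate: latencies and inter-trial
dynamics, satiation, session-to-session carryover other than the
retention rule, any pharmacokinetics, and real rats' deviations from
Q-learning (e.g. side biases, heuristic win-stay/lose-shift layers).
Passing tests therefore certify the pipeline's internal correctness and
sensitivity, not the biological claims.

## Recovery studies and identifiability

Parameter recovery uses fixed-length 300-trial serial-reversal sessions
(reversing on criterion indefinitely) so estimation quality is
comparable across subjects; the task's natural criterion-driven
sessions (~40–140 trials) give noisier but sign-consistent recovery and
remain available. Generating draws cover the behaviorally plausible
sub-ranges alpha ∈ [0.10, 0.95], beta ∈ [0.05, 1.5], kappa ∈ [−0.6,
0.6] rather than the full grid span: beta near its 5.0 bound is
near-random responding where no estimator is informative. At this scale
fitted beta and kappa track the generating values with Spearman rho ≈
0.9 and alpha's median absolute error stays within two grid steps.

Model identification per subject is intrinsically limited in this task.
Dual learning rates buy a median log-likelihood gain of only ≈ 3 nats
over 300 trials even at maximal rate separation, against a BIC penalty
of (1/2)·ln 300 ≈ 2.85 per extra parameter, so roughly half of even
the most separated dual-rate subjects classify as M1, and the
4-parameter model rarely survives two penalties — consonant with the
source analysis, where the 4-parameter variant failed to improve on the
sticky 3-parameter model and was dropped. Identifiability also requires
moderate temperatures (near-greedy agents reveal neither alpha nor
kappa) and kappa away from 0 (a sticky agent with kappa = 0 *is* a
plain Q-learner). The model-recovery utilities therefore draw their
generating parameters from those identifiable regimes, and recovery is
asserted where it is decidable: near-perfect identification of M1,
selections confined to the generating model's nested family, and
cohort-level mean-BIC selection recovering the M3 generator in ≥ 90% of
replicates.

## Numerical choices

* Choice probabilities are computed through the logistic of the softmax
  argument difference (`-logaddexp(0, -z)`), so log-likelihoods stay
  finite even where the probability itself rounds to 1.0 in double
  precision.
* Grid axes are generated as lower + step·k while ≤ upper within 1e−9,
  giving 13/63/26 points for the published ranges.
* Degenerate inputs: empty sessions raise; undefined probabilities and
  ratios return flagged `None`; non-completion is a flag, not an
  exception; all-equal median splits warn and label everything HE.
* Problem sizes in tests and the acceptance script (100 subjects per
  model for recovery, 20 base seeds for the cohort signature, 300-trial
  sessions) are the package's chosen study scales for stable
  statistics on a single CPU.

## Known limitations

* The discrete grid caps attainable precision at half a step and the
  published kappa axis excludes the neutral point (see above).
* Only the chosen option's value is updated; no decay/forgetting of the
  unchosen option, no eligibility traces, no model-based component.
* Deterministic rewards make several parameter pairs partially
  confounded (beta with alpha at low beta; kappa with exploitation);
  conclusions about dual learning rates in particular should rest on
  cohort-level comparison, not per-subject classification.
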