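# Methods

This note documents the models and procedures `autcage` implements, the
choices made where the design was genuinely open, and what the synthetic
subjects do and do not emulate.

## Protocol schedule

The 50-step schedule is data plus a few deterministic rules. The distractor
areas for steps 31–50 are a hand-chosen printed table (they follow no
closed form) and are stored verbatim; step 50's distractor equals the
42.25 cm² target, so the size cue carries no information there. Where the
protocol description leaves gaps, the schedule fills them explicitly:

- **Step 1 (warm-up).** Its content is unspecified upstream of milestone
  *size*; we use a full-screen trigger (side = screen height, default
  22 cm) with no sound, guaranteeing that any touch initiates a trial and
  first contact is rewarded.
- **Trigger sizes, steps 3–14.** Only the endpoints (20 cm at step 2, 6 cm
  at step 15) are fixed; intermediate values are linear interpolation
  rounded to 0.1 cm — the simplest monotone schedule through the endpoints.
- **Loudness ramp.** "30 to 72 dB SPL in 10-dB steps over steps 16–22" is
  arithmetically over-determined; we use nominal levels 30, 40, 50, 60, 70,
  72, 72 dB SPL, honoring both endpoints and the 10-dB increment as far as
  it goes, constant at 72 afterwards.
- **Maximum eccentricity.** The target steps outward 1 cm per step "until
  the screen edge"; the edge depends on the device. The screen half-width
  is configurable (default 15 cm) and eccentricity clamps at half-width
  minus half the target side (11.75 cm by default), reached at step 28.
- **Inter-trial intervals.** Correct: 2–4 s (1–2 s at the acoustic-test
  step, which uses a shorter post-reward timeout). Error: with a distractor
  present, the wrong-choice gray screen is a fixed 8 s; before step 31 an
  error is an off-target touch penalized 5–7 s. All per-trial draws from
  these ranges happen in the caller; the schedule stores the ranges.

One upstream inconsistency is left unresolved by design: step 31's
distractor is described both as 0.3 cm × 0.3 cm (0.09 cm²) and as 0.9 cm²
in the printed area list. The printed list is taken as authoritative for
all of steps 31–50. Both the area difference (42.25 − area) and the
side-length difference are exposed; the psychometric axis is the area
difference.

## Trial engine

A trial is a pure function of a step specification and a time-ordered
touch script, which keeps every behavioral path unit-testable. Phase-1
touches outside the trigger are non-trial events (the device is self-paced;
un-initiated trials simply do not appear in the log). After initiation the
cue plays and the target appears following the sound-to-target delay;
touches landing before target onset are never classified. The first touch
at or after onset decides the trial: target → `correct`, anything else on
screen → `wrong`, nothing within 8 s → `ignored`.

Classifying a background touch as `wrong` (not just distractor touches) is
a deliberate extension: in the milestones without a distractor an error can
only be an off-target touch, and the off-target penalty interval exists in
the protocol; without this rule no scored error could occur before step 31
and the staircase could never step down there. Gray-screen penalty
behavior (touches during the timeout reset it) is applied uniformly across
milestones.

## Staircase controller

The window holds the 10 most recent *scored* outcomes at the current step;
`ignored` trials and trials whose start/end identity labels disagree are
excluded (an aborted trial says nothing about discrimination, and a
mislabeled trial would credit the wrong subject). Evaluation happens only
at a full window — there is no early step-up after 8 straight corrects,
the conservative reading of "8 of 10". On an actual step change (up or
down) the window clears, preventing stale outcomes from double-stepping;
a move suppressed at the clamp boundaries (up at step 50, down at step 1)
leaves the window sliding, treated symmetrically at both ends. Whether the
original device slid its window across step boundaries is unknowable from
the protocol description; clearing is the documented choice here and the
brute-force oracle in the tests pins the exact semantics.

## Identification model

The image classifier is abstracted as a row-stochastic confusion matrix
P(label | true subject) over the subjects plus a `null` label. Start and
end captures are drawn independently given the subject — defensible
because running the classifier twice is reported upstream to improve
performance only marginally, consistent with near-independent errors — so
the expected exclusion rate of the consistency check is
1 − Σ_label P(label|s)², which the tests verify by Monte Carlo. Mismatched
trials are withheld from the controller but remain in the log and in the
engagement/turn-taking analyses under their true identity (the simulator
knows the truth; the consistency check exists to protect progression, not
the descriptive statistics).

## Synthetic subjects

Agent defaults encode the study conditions the analyses assume:

| parameter | default | meaning |
|---|---|---|
| m, w | 25, 10 cm² | psychometric threshold and 0.5→0.95 width on the size-difference axis |
| λ, γ | 0.02, 0.5 | lapse rate; 2 AC guessing floor |
| acoustic_weight | 0.0 | mixture weight of the acoustic channel (0 = sound ignored, the empirically observed regime) |
| p_acoustic | 0.95 | accuracy of the acoustic channel when used |
| motor_accuracy | 0.9 | P(touching the intended region) at steps without a distractor |
| engagement anchors | 0.90/0.55 after correct, 0.25/0.40 after wrong | P(initiating within 30 s) at hit rate 1.0 / 0.5 |
| latency | median 1 s, σ = 0.5 | log-normal response latency |
| p_ignore | 0.05 | per-trial abort probability |

The acoustic channel is a probabilistic mixture, not cue fusion: with
weight a, P(correct) = (1−a)·ψ(Δ) + a·p_acoustic. A single interpretable
knob spans the observed regimes (a = 0: chance at step 50; a = 1: the task
is solvable acoustically). Engagement interpolates linearly in the recent
hit rate (last 20 scored trials; window length is a smoothing choice)
between the chance and perfect anchors; aborted trials use the after-wrong
anchors. `p_ignore` is an addition to the upstream parameter list — real
logs contain `ignored` outcomes and the analyses must be exercised against
them.

Group sessions alternate in bouts: the next subject is drawn from a Markov
turn matrix (uniform off-diagonal by default), between-bout gaps are
log-normal with median 100 s, and a bout ends when the engagement draw
fails. Sessions default to 3 h.

What the simulator does **not** emulate: dominance hierarchies or spatial
cage dynamics beyond the turn matrix, circadian/satiation drift within a
session, learning (psychometric parameters are stationary), and any real
image statistics behind the confusion matrix. Passing tests therefore
demonstrate that the pipeline recovers what the generative model puts in —
they do not validate the behavioral assumptions against real animals.

## Statistical procedures

- **Hit rate** is correct/(correct+wrong) everywhere; `ignored` trials are
  excluded from scoring but keep timestamps for engagement measures.
- **Initiation likelihood**: a response is "followed" if the same subject
  initiates its next trial within 30 s, never across session boundaries;
  the response moment is initiation time plus response latency.
- **Balanced blocks**: scored trials are drawn without replacement into
  blocks with an equal per-step quota (block size // number of steps);
  steps with fewer trials truncate the number of blocks — nothing is
  upsampled. Per-block hit rate and initiation likelihood are correlated
  by Pearson.
- **Partial correlation** residualizes both variables on the covariates
  (with intercept) by least squares and correlates the residuals; p from
  the t distribution on n−k−2 df, CI by Fisher z with effective size
  n−k−3. With zero covariates it is exactly plain Pearson (tested against
  pingouin as an independent implementation).
- **Psychometric fit**: binomial MLE with L-BFGS-B from three starts;
  bounds keep λ ∈ [0, 0.1] and γ ∈ [0.4, 0.6] because the task's lower
  asymptote is guessing — unconstrained asymptotes degenerate on small
  data. The width convention is the 0.5→0.95 span of S (not the more
  common 0.05→0.95). The 95% CI on m is a parametric bootstrap (500
  refits from the fitted ψ, percentile interval, widened if necessary to
  contain the point estimate). Fits with data stuck at an asymptote are
  flagged `converged=False` rather than raising.
- **Latency test**: Kruskal–Wallis between cue types per subject,
  Bonferroni-corrected across subjects.
- **Turn-taking**: trial sequences collapse to bouts; transitions are
  counted between consecutive distinct subjects within sessions (counting
  across session boundaries is a flag, off by default — whether the
  original count crossed sessions is ambiguous). The permutation null
  preserves each subject's per-session bout count *and* the realizability
  of the order: a plain label shuffle places equal bouts adjacent, which a
  real log cannot contain, and systematically destroys transitions —
  measured here to inflate the false-positive rate by an order of
  magnitude. Realizable re-orderings are sampled uniformly by generating
  memoryless next-differs-from-current walks (each realizable arrangement
  is equally likely under such a walk) and keeping those matching the
  observed composition; for compositions too skewed for this rejection
  step, remaining replicates fall back to plain shuffles whose surplus
  self-adjacencies simply do not count. P-values use
  2·min(P(perm ≥ obs), P(perm ≤ obs)) with the (r+1)/(n+1) correction —
  slightly conservative under the discreteness of small counts.
- **Time-to-half-trials** is the earliest session time by which at least
  half of all pooled trials had been initiated (lower median of initiation
  times).

## Numerical and testing choices

Problem sizes in the test suite were chosen to make each statistical check
decisive at desk scale: the controller oracle runs 1,000 random sequences
of 500 outcomes; psychometric recovery uses 200 trials per level across
the 20 distractor-step size differences with 50 replicates (coverage of
the bootstrap CI ≥ 90%); chance-level acoustic-test performance uses 1,500
trials against the binomial 95% band; permutation calibration uses 200
simulated exchangeable bout sequences of 150 bouts with 1,000 permutations
each, requiring the per-pair rejection rate at α = 0.05 to land in
[0.02, 0.09]. Seeds are fixed throughout; identical seeds reproduce
simulator output byte for byte.

## Known limitations

- The identity model is trial-level only; it does not model within-session
  drift of classifier accuracy or retraining events.
- The conditional-walk permutation sampler needs a roughly balanced bout
  composition; heavily skewed groups fall back to a conservative shuffle.
- The engagement model reacts instantaneously to the recent hit rate; how
  fast real engagement anchors shift across milestones is not quantified
  upstream, so no lag is modeled.
- Bootstrap CIs are percentile-based; no bias correction is applied.
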