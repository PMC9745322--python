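# autcage

Autonomous home-cage staircase training and analysis for two-alternative
choice (2 AC) touchscreen tasks in socially housed animals.

## What problem this addresses

Training non-human primates on psychophysical tasks traditionally requires
a human trainer shaping one animal at a time. Home-cage devices replace the
trainer with an automated protocol: animals initiate trials at their own
pace on a touchscreen attached to their enclosure, a camera-based classifier
attributes each trial to an individual, and a staircase controller adjusts
task difficulty per subject from its recent performance — across sessions,
without food or fluid restriction, and without separating animals from
their group.

`autcage` is a tested, reusable implementation of such a pipeline for a
visuo-acoustic 2 AC task, aimed at researchers who want to prototype
protocol variants, validate analysis code against synthetic ground truth,
or analyze trial logs from a real device:

- **Protocol schedule** — a 50-step shaping sequence in three milestones:
  *size* (steps 2–15, the central trigger shrinks 20 → 6 cm), *location-sound*
  (16–30, a cue sound precedes a 6.5 cm target stepping 1 cm per step toward
  the screen edge, loudness ramping 30 → 72 dB SPL), and *distractor* (31–49,
  a second stimulus grows from 0.9 cm² until it equals the 42.25 cm² target
  at step 50, where only the sound disambiguates).
- **Trial engine** — a deterministic two-phase state machine (trigger touch →
  cued choice) producing one record per trial: `correct`, `wrong`, or
  `ignored` (no response within 8 s).
- **Staircase controller** — a sliding window of the 10 most recent scored
  outcomes at the current step; ≥ 8 correct steps up, ≤ 2 correct steps
  down; per-subject state persists across sessions in a JSON store.
- **Identification** — a row-stochastic confusion matrix stands in for the
  image classifier (including a `null` label for unidentifiable captures);
  start/end captures are compared and mismatched trials are withheld from
  the controller. Per-label precision and per-subject recall quantify
  classifier quality.
- **Synthetic subjects** — agents with a psychometric visual channel, an
  optional acoustic channel, outcome-dependent engagement, log-normal
  latencies, and Markov turn-taking across group members, so simulated
  session logs have the statistical structure the analyses assume.
- **Statistics** — hit rate by step, milestone summaries, initiation
  likelihood within 30 s of a response (with step-balanced block
  resampling), partial Pearson correlation, psychometric fitting, rank
  latency tests, and a turn-taking transition matrix with a permutation
  null.

## The model at the core

The probability of a correct choice as a function of the target−distractor
size difference *x* (cm²) is a cumulative-normal psychometric function

ψ(x; m, w, λ, γ) = γ + (1 − λ − γ) · S(x; m, w)

where S is a normal CDF scaled so that S(m) = 0.5 and S(m + w) = 0.95:
*m* is the threshold (the level at the midpoint of the sigmoid span), *w*
the width between the 0.5 and 0.95 levels of S, γ the guess rate (0.5 in a
2 AC task), and λ the lapse rate. `fit_psychometric` maximizes the binomial
likelihood of per-level correct counts with λ ∈ [0, 0.1] and γ ∈ [0.4, 0.6],
and puts a parametric-bootstrap 95% CI on *m*.

Turn-taking is summarized by the Markov matrix of transitions between
consecutive bouts (runs of trials by one subject). Significance per ordered
pair comes from a permutation null that re-orders each session's bouts
uniformly among realizable bout sequences (same per-subject bout counts,
no adjacent repeats), with two-sided p = 2·min(P(perm ≥ obs), P(perm ≤ obs))
and the (r+1)/(n+1) correction.

## Worked example

Simulate three 3-hour sessions of a four-subject group and analyze
engagement and turn-taking:

```sh
$ aut-cage simulate --sessions 3 --seed 7 --out demo
wrote 3 session log(s) to demo
$ aut-cage analyze engagement --in demo --seed 1
{
 "analysis": "engagement",
 "initiation_likelihood": {
  "correct": 0.8349514563106796,
  "wrong": 0.21621621621621623
 },
 "iqr_trials": 25.25,
 "median_trials": 64.5,
 "n_trials": 728,
 "time_to_half_trials": 5320.364417118009
}
$ aut-cage analyze turntaking --in demo --seed 1
{
 "analysis": "turntaking",
 "median_interval_s": 106.33268612661186,
 "n_permutations": 1000,
 "n_trials": 728,
 "total_transitions": 184
}
```

Reading the numbers: subjects performed a median of 64.5 trials per session
(IQR 25.25) and re-engaged within 30 s after 83% of correct responses but
only 22% of errors — the outcome-dependent engagement built into the
default agents. Half of all trials occurred within the first ~89 minutes.
The device changed hands 184 times, a median of ~106 s apart (the turn
matrices and per-pair permutation p-values are written as CSVs next to the
summary).

Fitting the psychometric function to an agent whose true threshold is
m = 25 cm² (200 trials at each of the 20 distractor-step size differences):

```python
import numpy as np
from autcage import schedule, analysis
from autcage.agents import AgentParams, simulate_trials

rng = np.random.default_rng(0)
sch = schedule.build_schedule()
agent = AgentParams("B", m=25.0, w=10.0, lapse=0.02, acoustic_weight=0.0)

levels, k, n = [], [], []
for step in range(31, 51):
    recs = simulate_trials(agent, sch[step - 1], 200, rng)
    levels.append(schedule.size_difference(step))
    k.append(sum(r.outcome == "correct" for r in recs))
    n.append(len(recs))

fit = analysis.fit_psychometric(levels, k, n, rng=rng)
print(f"threshold m = {fit.m:.2f} cm2  (95% CI {fit.ci95_m[0]:.2f}-{fit.ci95_m[1]:.2f})")
print(f"width w = {fit.w:.2f} cm2, lapse = {fit.lam:.3f}, guess = {fit.gam:.3f}")
```

prints

```
threshold m = 25.44 cm2  (95% CI 24.43-26.43)
width w = 9.63 cm2, lapse = 0.017, guess = 0.503
```

The true threshold falls inside the bootstrap CI; because this agent has
`acoustic_weight=0`, its hit rate at step 50 (size difference 0) sits at
the γ ≈ 0.5 guessing floor.

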