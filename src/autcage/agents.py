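"""Synthetic subjects and group sessions.

Agents emulate the behavioral regularities the analyses assume, without
claiming to model real macaque cognition:

* perception — at the distractor steps, the probability of choosing the
  larger stimulus follows a cumulative-normal psychometric function of the
  target-distractor area difference; an optional acoustic channel is mixed
  in with weight ``acoustic_weight`` (0 reproduces the empirical pattern of
  animals ignoring the sound, so step 50 sits at chance);
* engagement — the probability of initiating another trial shortly after a
  response depends on the last outcome and the recent hit rate, high after
  corrects when performance is good and converging as performance falls to
  chance;
* turn-taking — within a session the device is occupied in bouts; which
  subject takes over follows a Markov transition matrix, with log-normal
  gaps between bouts.

``simulate_session`` composes the whole stack: trials run through the real
trial engine, identity labels come from the confusion-matrix identity
model, and step progression goes through the real staircase controller, so
a simulated log is structurally indistinguishable from a device log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import staircase as _staircase
from .analysis import psi
from .engine import TouchEvent, TrialRecord, draw_trial_randomization, run_trial
from .identification import IdentityModel, sample_label
from .io import SessionLog
from .schedule import StepSpec, size_difference
from .staircase import ProgressStore, SubjectState

__all__ = [
    "AgentParams",
    "GroupSchedule",
    "p_correct",
    "p_initiate",
    "simulate_trials",
    "simulate_session",
]

#: Scored trials over which an agent judges its own recent hit rate.
HIT_RATE_WINDOW = 20


@dataclass(frozen=True)
class AgentParams:
    """Perception, engagement, and timing model of one synthetic subject.

    Psychometric parameters (m, w in cm² of size difference; lapse λ; guess
    γ = 0.5 for a two-alternative choice) govern the visual channel at the
    distractor steps.  ``acoustic_weight`` mixes in an acoustic channel of
    accuracy ``p_acoustic``; 0 means the sound is ignored.  Engagement
    anchors give the probability of initiating another trial within 30 s
    after a correct/wrong response at hit rate 1.0 (``*_hi``/``*_lo`` for
    correct, reversed for wrong) and at chance (0.5).  Latency is
    log-normal with ``latency_median`` seconds and shape ``latency_sigma``.
    """

    subject_id: str
    m: float = 25.0
    w: float = 10.0
    lapse: float = 0.02
    guess: float = 0.5
    acoustic_weight: float = 0.0
    p_acoustic: float = 0.95
    motor_accuracy: float = 0.9
    engage_after_correct_hi: float = 0.90
    engage_after_correct_lo: float = 0.55
    engage_after_wrong_lo: float = 0.25
    engage_after_wrong_hi: float = 0.40
    latency_median: float = 1.0
    latency_sigma: float = 0.5
    p_ignore: float = 0.05

    def __post_init__(self) -> None:
        for name in ("acoustic_weight", "p_acoustic", "motor_accuracy",
                     "engage_after_correct_hi", "engage_after_correct_lo",
                     "engage_after_wrong_lo", "engage_after_wrong_hi",
                     "lapse", "guess", "p_ignore"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.w <= 0:
            raise ValueError("psychometric width w must be positive")


@dataclass(frozen=True)
class GroupSchedule:
    """Who shares the device, how they alternate, and for how long."""

    subjects: tuple[str, ...]
    turn_matrix: Optional[np.ndarray] = None   # row-stochastic, rows = from
    bout_gap_median: float = 100.0             # s between bouts of different animals
    bout_gap_sigma: float = 0.8                # log-normal shape
    session_duration: float = 3.0 * 3600.0     # s

    def __post_init__(self) -> None:
        if len(self.subjects) == 0:
            raise ValueError("group needs at least one subject")
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        if self.bout_gap_median <= 0:
            raise ValueError("bout_gap_median must be positive")
        if self.turn_matrix is not None:
            tm = np.asarray(self.turn_matrix, dtype=float)
            n = len(self.subjects)
            if tm.shape != (n, n):
                raise ValueError("turn_matrix shape must match the subject count")
            if (tm < 0).any() or not np.allclose(tm.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("turn_matrix rows must be non-negative and sum to 1")
            object.__setattr__(self, "turn_matrix", tm)

    def default_matrix(self) -> np.ndarray:
        """Uniform off-diagonal transitions (or self-loop for a singleton)."""
        n = len(self.subjects)
        if n == 1:
            return np.ones((1, 1))
        tm = np.full((n, n), 1.0 / (n - 1))
        np.fill_diagonal(tm, 0.0)
        return tm


def p_correct(agent: AgentParams, spec: StepSpec) -> float:
    """Probability of a correct choice at one protocol step.

    Steps without a distractor only require touching the target, so the
    probability is the agent's motor accuracy.  At distractor steps the
    visual channel follows ψ of the size difference and is mixed with the
    acoustic channel at ``acoustic_weight``.
    """
    if not spec.has_distractor:
        return agent.motor_accuracy
    delta = size_difference(spec.step_index)
    p_vis = float(psi(delta, agent.m, agent.w, agent.lapse, agent.guess))
    return (1.0 - agent.acoustic_weight) * p_vis + agent.acoustic_weight * agent.p_acoustic


def p_initiate(agent: AgentParams, last_outcome: str, recent_hit_rate: float) -> float:
    """Probability of initiating another trial within 30 s of a response.

    Linear in the recent hit rate between the chance (0.5) and perfect
    (1.0) anchors: after a correct it falls from ``engage_after_correct_hi``
    toward ``engage_after_correct_lo`` as performance drops to chance;
    after a wrong (or aborted) trial it rises from ``engage_after_wrong_lo``
    toward ``engage_after_wrong_hi``.
    """
    if not 0.0 <= recent_hit_rate <= 1.0:
        raise ValueError("recent_hit_rate must lie in [0, 1]")
    frac = (min(max(recent_hit_rate, 0.5), 1.0) - 0.5) / 0.5
    if last_outcome == "correct":
        lo, hi = agent.engage_after_correct_lo, agent.engage_after_correct_hi
        return lo + frac * (hi - lo)
    lo_hr, hi_hr = agent.engage_after_wrong_hi, agent.engage_after_wrong_lo
    # hi_hr applies at hit rate 1.0, lo_hr at chance
    return lo_hr + frac * (hi_hr - lo_hr)


def _synthesize_touches(agent: AgentParams, spec: StepSpec, target_side: str,
                        correct: bool, ignored: bool, delay: float,
                        rng: np.random.Generator) -> list[TouchEvent]:
    """Script the touch events realizing an intended trial outcome."""
    touches = [TouchEvent(0.0, 0.0, 0.0)]  # trigger touch at screen center
    if ignored:
        return touches
    latency = float(rng.lognormal(math.log(agent.latency_median), agent.latency_sigma))
    t = delay + max(latency, 1e-3)
    if t > delay + spec.response_timeout:
        t = delay + spec.response_timeout  # respond at the deadline, not past it
    sign = {"left": -1.0, "right": 1.0, "center": 0.0}[target_side]
    tx = sign * spec.eccentricity
    if correct:
        touches.append(TouchEvent(t, tx, 0.0))
    elif spec.has_distractor:
        touches.append(TouchEvent(t, -tx, 0.0))
    else:
        # an off-target touch just outside the target's corner
        off = spec.target_side / 2 + 1.0
        touches.append(TouchEvent(t, tx + off, off))
    return touches


def simulate_trials(agent: AgentParams, spec: StepSpec, n: int,
                    rng: np.random.Generator, *,
                    subject_id: Optional[str] = None,
                    session_id: str = "sim",
                    allow_ignored: bool = False) -> list[TrialRecord]:
    """Run ``n`` independent trials of one agent at a fixed step.

    A convenience for psychometric-style sampling: outcomes are drawn from
    :func:`p_correct`, realized as touch sequences, and executed through the
    trial engine.  Aborts are off by default so every trial is scored.
    """
    records = []
    t = 0.0
    pc = p_correct(agent, spec)
    for i in range(n):
        center = spec.eccentricity == 0.0
        sound_kind, side = draw_trial_randomization(rng, center=center)
        ignored = allow_ignored and rng.random() < agent.p_ignore
        correct = (not ignored) and rng.random() < pc
        delay = (float(rng.uniform(spec.sound_delay_min, spec.sound_delay_max))
                 if spec.has_sound else 0.0)
        touches = _synthesize_touches(agent, spec, side, correct, ignored, delay, rng)
        rec = run_trial(spec, touches, sound_kind, side, start_time=t,
                        session_id=session_id, trial_index=i,
                        subject_id=subject_id or agent.subject_id,
                        sound_delay=delay)
        records.append(rec)
        t = rec.initiation_time + delay + (rec.response_latency or spec.response_timeout) + 3.0
    return records


def _recent_hit_rate(outcomes: list[str]) -> float:
    scored = [o for o in outcomes[-HIT_RATE_WINDOW:]]
    if not scored:
        return 1.0
    return sum(1 for o in scored if o == "correct") / len(scored)


def simulate_session(
    group: GroupSchedule,
    agents: dict[str, AgentParams] | Sequence[AgentParams],
    schedule: Sequence[StepSpec],
    store: ProgressStore,
    identity: IdentityModel,
    rng: np.random.Generator,
    *,
    session_id: str = "S001",
    group_id: str = "G1",
    start_time: float = 0.0,
) -> SessionLog:
    """Simulate one home-cage session of a group sharing the device.

    Bouts alternate between subjects following the group's turn matrix with
    log-normal between-bout gaps; within a bout, trials are generated from
    the agent's perception and engagement model, executed through the trial
    engine, labeled by the identity model, and fed to the staircase
    controller — mismatched start/end labels block the controller update
    but the trial stays in the log.  The final per-subject states are
    persisted to ``store``.
    """
    if isinstance(agents, dict):
        agent_map = dict(agents)
    else:
        agent_map = {a.subject_id: a for a in agents}
    missing = [s for s in group.subjects if s not in agent_map]
    if missing:
        raise ValueError(f"agents missing for subjects {missing}")

    tm = group.turn_matrix if group.turn_matrix is not None else group.default_matrix()
    subjects = list(group.subjects)
    states: dict[str, SubjectState] = {s: store.resume(s) for s in subjects}
    recent: dict[str, list[str]] = {s: [] for s in subjects}

    records: list[TrialRecord] = []
    t = 0.0
    trial_index = 0
    current: Optional[int] = None

    while True:
        # hand the device over
        if current is None:
            current = int(rng.integers(len(subjects)))
        else:
            current = int(rng.choice(len(subjects), p=tm[current]))
        t += float(rng.lognormal(math.log(group.bout_gap_median), group.bout_gap_sigma))
        if t >= group.session_duration:
            break
        sid = subjects[current]
        agent = agent_map[sid]

        # one bout of self-paced trials
        while t < group.session_duration:
            state = states[sid]
            spec = schedule[state.current_step - 1]
            center = spec.eccentricity == 0.0
            sound_kind, side = draw_trial_randomization(rng, center=center)
            ignored = rng.random() < agent.p_ignore
            correct = (not ignored) and rng.random() < p_correct(agent, spec)
            delay = (float(rng.uniform(spec.sound_delay_min, spec.sound_delay_max))
                     if spec.has_sound else 0.0)
            touches = _synthesize_touches(agent, spec, side, correct, ignored,
                                          delay, rng)
            rec = run_trial(spec, touches, sound_kind, side, start_time=t,
                            session_id=session_id, trial_index=trial_index,
                            subject_id=sid, sound_delay=delay)
            rec.label_start = sample_label(identity, sid, rng)
            rec.label_end = sample_label(identity, sid, rng)
            rec.consistent = rec.label_start == rec.label_end
            records.append(rec)
            trial_index += 1

            if rec.consistent:
                states[sid] = _staircase.update(state, rec.outcome)
            if rec.outcome in ("correct", "wrong"):
                recent[sid].append(rec.outcome)

            # advance the clock through the response and the inter-trial interval
            if rec.outcome == "correct":
                iti = float(rng.uniform(spec.iti_correct_min, spec.iti_correct_max))
            elif rec.outcome == "wrong":
                iti = float(rng.uniform(spec.iti_wrong_min, spec.iti_wrong_max))
            else:
                iti = spec.response_timeout
            responded = rec.response_latency is not None
            t = (rec.initiation_time + delay
                 + (rec.response_latency if responded else spec.response_timeout)
                 + iti)

            # stay engaged?
            hr = _recent_hit_rate(recent[sid])
            if rng.random() >= p_initiate(agent, rec.outcome, hr):
                break
            t += float(rng.uniform(0.5, 8.0))  # self-paced gap to the next trigger touch

    for s in subjects:
        store.put(states[s])

    end = start_time + group.session_duration
    return SessionLog(session_id=session_id, group_id=group_id,
                      start_time=start_time, end_time=end, records=records)
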