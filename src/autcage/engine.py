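"""Deterministic single-trial state machine.

A trial unfolds in two phases on a screen-centered, metric coordinate
frame (x rightward, y upward, cm):

* phase 1 — the subject touches the central trigger square to initiate the
  trial.  Touches outside the trigger are non-trial events: they delay
  initiation but are not scored.
* phase 2 — if the step has a sound phase, the cue plays and the target
  appears after the sound-to-target delay; a distractor of the step's area
  appears on the opposite side at the same eccentricity when the step has
  one.  The first touch at or after target onset is classified: inside the
  target → ``correct`` (rewarded), inside the distractor or anywhere else
  on screen → ``wrong`` (gray penalty interval), no touch within the
  response timeout → ``ignored``.

The engine is purely a function of the step specification and a scripted
touch sequence, which makes every behavioral path unit-testable; randomness
(cue identity, target side, delays) lives with the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .schedule import StepSpec

__all__ = [
    "TouchEvent",
    "TrialRecord",
    "TrialNotInitiated",
    "hit_region",
    "run_trial",
    "draw_trial_randomization",
    "SOUND_KINDS",
    "TARGET_FOR_SOUND",
]

#: Cue identities and the visual target each one predicts.
SOUND_KINDS = ("vocalization", "tone")
TARGET_FOR_SOUND = {"vocalization": "macaque_face", "tone": "geometric_pattern"}

_SIDE_SIGN = {"left": -1.0, "right": 1.0, "center": 0.0}


class TrialNotInitiated(RuntimeError):
    """No touch ever landed in the trigger; no trial record exists."""


@dataclass(frozen=True)
class TouchEvent:
    """One screen touch: time in seconds since trial start, position in cm."""

    time: float
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("touch time must be non-negative")


@dataclass
class TrialRecord:
    """One completed trial as written to the session log."""

    session_id: str
    trial_index: int
    subject_true_id: str
    step: int
    milestone: str
    sound_kind: str                       # vocalization | tone | none
    target_side_of_screen: str            # left | right | center
    outcome: str                          # correct | wrong | ignored
    initiation_time: float                # s since session start
    response_latency: Optional[float]     # s from target onset; None if ignored
    reward_volume: float                  # ml; 0 unless correct
    label_start: str = ""
    label_end: str = ""
    consistent: bool = True

    def __post_init__(self) -> None:
        if self.outcome == "correct" and self.reward_volume <= 0:
            raise ValueError("correct trials must carry a positive reward")
        if self.outcome == "ignored" and self.response_latency is not None:
            raise ValueError("ignored trials have no response latency")


def _in_square(x: float, y: float, cx: float, cy: float, side: float) -> bool:
    h = side / 2.0
    return abs(x - cx) <= h and abs(y - cy) <= h


def hit_region(spec: StepSpec, phase: int, point: tuple[float, float],
               target_side_of_screen: str = "center") -> str:
    """Classify a touch point into trigger/target/distractor/background.

    Phase 1 knows only the trigger square.  Phase 2 places the target square
    (side ``spec.target_side``) at ``(±eccentricity, 0)`` and, when the step
    has one, the distractor square (side ``sqrt(distractor_area)``) at the
    mirrored position.  Boundaries are inclusive.
    """
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase}")
    x, y = point
    if phase == 1:
        return "trigger" if _in_square(x, y, 0.0, 0.0, spec.trigger_side) else "background"
    sign = _SIDE_SIGN[target_side_of_screen]
    tx = sign * spec.eccentricity
    if _in_square(x, y, tx, 0.0, spec.target_side):
        return "target"
    if spec.has_distractor and _in_square(x, y, -tx, 0.0, spec.distractor_side):
        return "distractor"
    return "background"


def run_trial(
    spec: StepSpec,
    touches: Sequence[TouchEvent],
    sound_kind: str = "none",
    target_side: str = "center",
    start_time: float = 0.0,
    *,
    session_id: str = "",
    trial_index: int = 0,
    subject_id: str = "",
    sound_delay: Optional[float] = None,
) -> TrialRecord:
    """Run one trial over a scripted, time-ordered touch sequence.

    ``sound_delay`` fixes the sound-to-target interval for steps with a
    sound phase (default: midpoint of the step's range); touches landing
    between initiation and target onset are never classified.

    Raises :class:`TrialNotInitiated` when no touch enters the trigger.
    """
    times = [t.time for t in touches]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("touches must be sorted by time")
    if target_side not in _SIDE_SIGN:
        raise ValueError(f"unknown target side {target_side!r}")

    t_init = None
    for touch in touches:
        if hit_region(spec, 1, (touch.x, touch.y)) == "trigger":
            t_init = touch.time
            break
    if t_init is None:
        raise TrialNotInitiated("no touch entered the trigger region")

    if spec.has_sound:
        delay = sound_delay if sound_delay is not None else (
            0.5 * (spec.sound_delay_min + spec.sound_delay_max))
    else:
        delay = sound_delay if sound_delay is not None else 0.0
    onset = t_init + delay
    deadline = onset + spec.response_timeout

    outcome = "ignored"
    latency: Optional[float] = None
    for touch in touches:
        if touch.time <= t_init or touch.time < onset:
            continue
        if touch.time > deadline:
            break
        region = hit_region(spec, 2, (touch.x, touch.y), target_side)
        outcome = "correct" if region == "target" else "wrong"
        latency = touch.time - onset
        break

    return TrialRecord(
        session_id=session_id,
        trial_index=trial_index,
        subject_true_id=subject_id,
        step=spec.step_index,
        milestone=spec.milestone,
        sound_kind=sound_kind if spec.has_sound else "none",
        target_side_of_screen=target_side,
        outcome=outcome,
        initiation_time=start_time + t_init,
        response_latency=latency,
        reward_volume=spec.reward_volume if outcome == "correct" else 0.0,
    )


def draw_trial_randomization(rng: np.random.Generator,
                             center: bool = False) -> tuple[str, str]:
    """Draw the per-trial cue identity and target side.

    The cue is a fair draw between the vocalization and the pure tone (each
    deterministically mapped to its visual target); the side is a fair draw
    between left and right, or ``center`` while the target has not yet moved
    off-center (steps ≤ 16).
    """
    sound_kind = SOUND_KINDS[int(rng.integers(2))]
    side = "center" if center else ("left", "right")[int(rng.integers(2))]
    return sound_kind, side
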