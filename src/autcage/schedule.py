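"""The 50-step visuo-acoustic shaping schedule.

The protocol trains a subject toward a two-alternative choice (2 AC)
discrimination in three milestones plus a warm-up step and a final
acoustic-only test step:

* step 1 — warm-up: a full-screen trigger guarantees first contact.
* steps 2–15 — ``size``: the central trigger shrinks from 20 cm to 6 cm,
  training touch precision.
* steps 16–30 — ``location_sound``: a sound (conspecific vocalization or a
  4 kHz tone train) precedes a 6.5 cm visual target that steps away from the
  screen center by 1 cm per step; sound level ramps from 30 to 72 dB SPL.
* steps 31–49 — ``distractor``: a second visual stimulus appears on the
  opposite side and grows in area until, at step 50, it matches the
  42.25 cm² target, leaving only the acoustic cue informative.
* step 50 — ``acoustic_test``: target and distractor are identical in size;
  performance above chance requires using the sound.

All geometry is in centimetres on a screen-centered coordinate frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "MILESTONES",
    "ProtocolConfig",
    "StepSpec",
    "ConfigurationError",
    "milestone_of",
    "trigger_side",
    "sound_level",
    "distractor_area",
    "size_difference",
    "eccentricity",
    "build_schedule",
    "TARGET_SIDE_CM",
    "TARGET_AREA_CM2",
    "N_STEPS",
]

N_STEPS = 50

#: Side of the visual target from step 16 onward, cm.
TARGET_SIDE_CM = 6.5
#: Area of the visual target, cm².
TARGET_AREA_CM2 = TARGET_SIDE_CM * TARGET_SIDE_CM  # 42.25

#: Milestone labels in protocol order with their (first, last) step.
MILESTONES = {
    "warmup": (1, 1),
    "size": (2, 15),
    "location_sound": (16, 30),
    "distractor": (31, 49),
    "acoustic_test": (50, 50),
}

# Distractor area per step, cm².  These are the protocol's printed values;
# they are not derivable from a closed form (the side lengths were chosen by
# hand) and must be treated as data.
_DISTRACTOR_AREA = {
    31: 0.9, 32: 1.8, 33: 2.56, 34: 4.84, 35: 8.41,
    36: 11.55, 37: 13.69, 38: 15.21, 39: 17.64, 40: 20.25,
    41: 22.09, 42: 25.0, 43: 28.09, 44: 32.49, 45: 34.81,
    46: 36.0, 47: 38.44, 48: 39.69, 49: 40.96, 50: 42.25,
}

# Nominal sound level per step of the loudness ramp, dB SPL.  The ramp rises
# in 10-dB increments from 30 dB SPL at step 16 and is clamped at the final
# level of 72 dB SPL reached on step 22.
_SOUND_RAMP = {16: 30.0, 17: 40.0, 18: 50.0, 19: 60.0, 20: 70.0, 21: 72.0, 22: 72.0}
_SOUND_FINAL = 72.0


class ConfigurationError(ValueError):
    """Raised for an invalid protocol configuration."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Device geometry and policy knobs the schedule depends on.

    Parameters
    ----------
    screen_half_width_cm
        Half the usable screen width; bounds the target eccentricity.
    screen_half_height_cm
        Half the usable screen height; sets the warm-up trigger size.
    warmup_policy
        Only ``"full_screen"`` is supported: step 1 shows a trigger whose
        side equals the screen height so any touch initiates a trial.
    """

    screen_half_width_cm: float = 15.0
    screen_half_height_cm: float = 11.0
    warmup_policy: str = "full_screen"

    def __post_init__(self) -> None:
        if self.screen_half_width_cm <= TARGET_SIDE_CM / 2:
            raise ConfigurationError(
                f"screen_half_width_cm={self.screen_half_width_cm} cannot fit "
                f"a {TARGET_SIDE_CM} cm target"
            )
        if self.screen_half_height_cm <= 0:
            raise ConfigurationError("screen_half_height_cm must be positive")
        if self.warmup_policy != "full_screen":
            raise ConfigurationError(f"unknown warmup_policy {self.warmup_policy!r}")

    @property
    def max_eccentricity_cm(self) -> float:
        """Largest target eccentricity that keeps the target on screen."""
        return self.screen_half_width_cm - TARGET_SIDE_CM / 2


@dataclass(frozen=True)
class StepSpec:
    """Full stimulus and timing parameterization of one protocol step."""

    step_index: int
    milestone: str
    trigger_side: float            # cm
    target_side: float             # cm; equals trigger_side before step 16
    distractor_area: float         # cm²; 0 when no distractor is shown
    eccentricity: float            # cm from screen center
    sound_level: Optional[float]   # dB SPL; None before step 16
    sound_delay_min: float         # s between sound onset and target onset
    sound_delay_max: float
    response_timeout: float        # s; no phase-2 touch within it => ignored
    reward_volume: float           # ml per correct trial
    iti_correct_min: float         # s
    iti_correct_max: float
    iti_wrong_min: float           # s; penalty interval after an error
    iti_wrong_max: float

    @property
    def has_sound(self) -> bool:
        return self.sound_level is not None

    @property
    def has_distractor(self) -> bool:
        return self.distractor_area > 0

    @property
    def distractor_side(self) -> float:
        """Side of the (square) distractor, cm."""
        return math.sqrt(self.distractor_area)


def _check_step(step: int, lo: int = 1, hi: int = N_STEPS) -> None:
    if not isinstance(step, (int,)) or isinstance(step, bool):
        raise TypeError(f"step must be an integer, got {step!r}")
    if not lo <= step <= hi:
        raise ValueError(f"step {step} outside valid range {lo}–{hi}")


def milestone_of(step: int) -> str:
    """Return the milestone label owning ``step``."""
    _check_step(step)
    for name, (lo, hi) in MILESTONES.items():
        if lo <= step <= hi:
            return name
    raise AssertionError("unreachable: milestones partition 1–50")


def trigger_side(step: int, config: Optional[ProtocolConfig] = None) -> float:
    """Side of the square trigger stimulus at ``step``, cm.

    Linearly interpolated from 20 cm at step 2 to 6 cm at step 15 (rounded
    to 0.1 cm), constant at 6 cm afterwards.  Step 1 fills the screen.
    """
    _check_step(step)
    config = config or ProtocolConfig()
    if step == 1:
        return 2.0 * config.screen_half_height_cm
    if step >= 15:
        return 6.0
    return round(20.0 - (step - 2) * (14.0 / 13.0), 1)


def sound_level(step: int) -> float:
    """Nominal sound level at ``step``, dB SPL (steps 16–50 only)."""
    _check_step(step)
    if step < 16:
        raise ValueError(f"step {step} has no sound phase (sound starts at step 16)")
    return _SOUND_RAMP.get(step, _SOUND_FINAL)


def distractor_area(step: int) -> float:
    """Distractor area at ``step``, cm² (steps 31–50 only)."""
    _check_step(step, 31, 50)
    return _DISTRACTOR_AREA[step]


def size_difference(step: int) -> float:
    """Target-minus-distractor area at ``step``, cm².

    This is the stimulus level on the abscissa of the psychometric fit;
    it shrinks to exactly 0 at step 50.
    """
    return TARGET_AREA_CM2 - distractor_area(step)


def eccentricity(step: int, config: Optional[ProtocolConfig] = None) -> float:
    """Horizontal distance of the target from the screen center, cm.

    0 through step 16, then +1 cm per step until the target reaches the
    screen edge, where it is clamped; constant at the maximum from there on.
    """
    _check_step(step)
    config = config or ProtocolConfig()
    if step <= 16:
        return 0.0
    return min(float(min(step, 30) - 16), config.max_eccentricity_cm)


def build_schedule(config: Optional[ProtocolConfig] = None) -> tuple[StepSpec, ...]:
    """Construct the full ordered 50-step schedule.

    Purely a function of ``config``; no randomness is involved.  Timing
    entries that the device draws per trial (sound-to-target delay,
    inter-trial intervals) are stored as (min, max) ranges.
    """
    config = config or ProtocolConfig()
    steps = []
    for s in range(1, N_STEPS + 1):
        has_sound = s >= 16
        final = s == 50
        steps.append(
            StepSpec(
                step_index=s,
                milestone=milestone_of(s),
                trigger_side=trigger_side(s, config),
                target_side=TARGET_SIDE_CM if s >= 16 else trigger_side(s, config),
                distractor_area=_DISTRACTOR_AREA.get(s, 0.0),
                eccentricity=eccentricity(s, config),
                sound_level=sound_level(s) if has_sound else None,
                sound_delay_min=1.0 if has_sound else 0.0,
                sound_delay_max=1.5 if has_sound else 0.0,
                response_timeout=8.0,
                reward_volume=0.5,
                # the acoustic test step uses a shorter post-reward timeout
                iti_correct_min=1.0 if final else 2.0,
                iti_correct_max=2.0 if final else 4.0,
                # before a distractor exists, an error is an off-target touch
                # penalized with a 5–7 s gray interval; with a distractor the
                # wrong choice turns the screen gray for a fixed 8 s
                iti_wrong_min=8.0 if s >= 31 else 5.0,
                iti_wrong_max=8.0 if s >= 31 else 7.0,
            )
        )
    return tuple(steps)
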