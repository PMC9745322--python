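"""Sliding-window staircase controller for step-wise shaping.

The controller watches the most recent 10 scored outcomes at the current
step.  Once the window is full it moves one step up when at least 8 of the
10 were correct and one step down when at most 2 were correct, clamped to
the protocol's step range.  Aborted ("ignored") trials and trials whose
identity labels disagreed between the start and end captures never enter
the window, so the controller only ever reacts to committed choices it can
attribute to the right subject.

Per-subject state survives sessions through :class:`ProgressStore`, a JSON
file keyed by subject id, so an animal resumes at the step it left.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

from .schedule import N_STEPS

__all__ = [
    "WINDOW_SIZE",
    "STEP_UP_MIN_CORRECT",
    "STEP_DOWN_MAX_CORRECT",
    "SubjectState",
    "ProgressStore",
    "StoreIntegrityError",
    "update",
    "resume",
]

WINDOW_SIZE = 10
#: Minimum correct trials in a full window that advances one step.
STEP_UP_MIN_CORRECT = 8
#: Maximum correct trials in a full window that retreats one step.
STEP_DOWN_MAX_CORRECT = 2

_SCORED = ("correct", "wrong")
_OUTCOMES = ("correct", "wrong", "ignored")


class StoreIntegrityError(RuntimeError):
    """A persisted subject entry is corrupt; never silently reset."""


@dataclass(frozen=True)
class SubjectState:
    """A subject's position in the protocol and its current outcome window."""

    subject_id: str
    current_step: int = 1
    window: tuple[str, ...] = ()
    totals: dict = field(default_factory=lambda: {o: 0 for o in _OUTCOMES})

    def __post_init__(self) -> None:
        if not 1 <= self.current_step <= N_STEPS:
            raise ValueError(f"current_step {self.current_step} outside 1–{N_STEPS}")
        if len(self.window) > WINDOW_SIZE:
            raise ValueError("window longer than 10 outcomes")
        if any(o not in _SCORED for o in self.window):
            raise ValueError("window may only hold scored outcomes")


def update(state: SubjectState, outcome: str) -> SubjectState:
    """Feed one trial outcome into the controller and return the new state.

    ``ignored`` outcomes only increment the totals.  Scored outcomes are
    appended to the window (evicting the oldest beyond 10 entries); when
    the window holds exactly 10, the 8-up/2-down rule is evaluated.  The
    window is cleared whenever the step actually changes; a move suppressed
    at a clamp boundary (up at step 50, down at step 1) leaves the window
    sliding.
    """
    if outcome not in _OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    totals = dict(state.totals)
    totals[outcome] = totals.get(outcome, 0) + 1
    if outcome == "ignored":
        return replace(state, totals=totals)

    window = (state.window + (outcome,))[-WINDOW_SIZE:]
    step = state.current_step
    if len(window) == WINDOW_SIZE:
        n_correct = sum(1 for o in window if o == "correct")
        if n_correct >= STEP_UP_MIN_CORRECT and step < N_STEPS:
            return replace(state, current_step=step + 1, window=(), totals=totals)
        if n_correct <= STEP_DOWN_MAX_CORRECT and step > 1:
            return replace(state, current_step=step - 1, window=(), totals=totals)
    return replace(state, window=window, totals=totals)


def _state_to_json(state: SubjectState) -> dict:
    return {
        "current_step": state.current_step,
        "window": list(state.window),
        "totals": dict(state.totals),
    }


def _state_from_json(subject_id: str, entry: object) -> SubjectState:
    try:
        assert isinstance(entry, dict)
        step = entry["current_step"]
        window = tuple(entry["window"])
        totals = dict(entry["totals"])
        return SubjectState(subject_id, step, window, totals)
    except (AssertionError, KeyError, TypeError, ValueError) as exc:
        raise StoreIntegrityError(
            f"corrupt progress entry for subject {subject_id!r}: {exc}"
        ) from exc


class ProgressStore:
    """Durable per-subject progress, serialized as a JSON file.

    Unknown subjects resume fresh at step 1; a corrupt entry raises
    :class:`StoreIntegrityError` rather than resetting the subject.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._states: dict[str, SubjectState] = {}
        if os.path.exists(self.path):
            self._load()

    def _load(self) -> None:
        try:
            with open(self.path) as fh:
                raw = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise StoreIntegrityError(f"unreadable progress store {self.path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise StoreIntegrityError(f"progress store {self.path} is not a mapping")
        self._states = {sid: _state_from_json(sid, entry) for sid, entry in raw.items()}

    def save(self) -> None:
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump({sid: _state_to_json(s) for sid, s in self._states.items()},
                      fh, indent=1, sort_keys=True)
        os.replace(tmp, self.path)

    def resume(self, subject_id: str) -> SubjectState:
        """Return the persisted state, or a fresh step-1 state if unknown."""
        if subject_id in self._states:
            return self._states[subject_id]
        return SubjectState(subject_id)

    def put(self, state: SubjectState) -> None:
        self._states[state.subject_id] = state

    def subjects(self) -> list[str]:
        return sorted(self._states)


def resume(subject_id: str, store: ProgressStore) -> SubjectState:
    """Module-level convenience mirroring :meth:`ProgressStore.resume`."""
    return store.resume(subject_id)
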