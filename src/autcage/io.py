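"""Versioned session-log serialization (CSV and JSON-lines).

A session log is the unit of storage: session metadata plus the ordered
trial records.  Both formats carry the same schema version tag and round
trip losslessly, so the analysis pipeline runs unchanged on simulator
output and user-supplied logs.  Timestamps inside records are seconds since
session start; the absolute session start lives in the metadata.
"""

from __future__ import annotations

import csv
import hashlib
import json
import os
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional

import pandas as pd

from .engine import TrialRecord

__all__ = [
    "SCHEMA_VERSION",
    "SessionLog",
    "LogValidationError",
    "write_log",
    "read_log",
    "logs_to_frame",
    "read_log_dir",
    "config_hash",
]

SCHEMA_VERSION = "autcage-log/1"

_COLUMNS = [
    "session_id", "trial_index", "subject_true_id", "label_start", "label_end",
    "consistent", "step", "milestone", "sound_kind", "target_side_of_screen",
    "outcome", "initiation_time", "response_latency", "reward_volume",
]
_OUTCOMES = {"correct", "wrong", "ignored"}


class LogValidationError(ValueError):
    """One or more rows of a session log failed validation."""

    def __init__(self, path: str, row_errors: list[tuple[int, str]]):
        self.path = path
        self.row_errors = row_errors
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in row_errors[:10])
        more = "" if len(row_errors) <= 10 else f" (+{len(row_errors) - 10} more)"
        super().__init__(f"{path}: {len(row_errors)} invalid row(s): {detail}{more}")


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SessionLog:
    """One session's metadata and ordered trial records."""

    session_id: str
    group_id: str
    start_time: float                     # absolute, seconds since epoch
    end_time: float
    records: list[TrialRecord] = field(default_factory=list)
    device_config_hash: str = ""

    def __post_init__(self) -> None:
        times = [r.initiation_time for r in self.records]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("records must be sorted by initiation_time")
        if times and self.end_time - self.start_time < times[-1]:
            raise ValueError("end_time precedes the last trial initiation")


def _meta(log: SessionLog) -> dict:
    return {
        "schema": SCHEMA_VERSION,
        "session_id": log.session_id,
        "group_id": log.group_id,
        "start_time": log.start_time,
        "end_time": log.end_time,
        "device_config_hash": log.device_config_hash,
    }


def _record_row(r: TrialRecord) -> dict:
    d = asdict(r)
    return {c: d[c] for c in _COLUMNS}


def _parse_row(row: dict, line_no: int, errors: list) -> Optional[TrialRecord]:
    try:
        lat = row.get("response_latency")
        if lat in ("", None):
            lat = None
        else:
            lat = float(lat)
        cons = row["consistent"]
        if isinstance(cons, str):
            if cons not in ("True", "False", "true", "false"):
                raise ValueError(f"bad consistent flag {cons!r}")
            cons = cons in ("True", "true")
        outcome = row["outcome"]
        if outcome not in _OUTCOMES:
            raise ValueError(f"bad outcome {outcome!r}")
        return TrialRecord(
            session_id=str(row["session_id"]),
            trial_index=int(row["trial_index"]),
            subject_true_id=str(row["subject_true_id"]),
            label_start=str(row["label_start"]),
            label_end=str(row["label_end"]),
            consistent=bool(cons),
            step=int(row["step"]),
            milestone=str(row["milestone"]),
            sound_kind=str(row["sound_kind"]),
            target_side_of_screen=str(row["target_side_of_screen"]),
            outcome=outcome,
            initiation_time=float(row["initiation_time"]),
            response_latency=lat,
            reward_volume=float(row["reward_volume"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        errors.append((line_no, str(exc)))
        return None


def write_log(log: SessionLog, path: str | os.PathLike, format: str = "csv") -> None:
    """Serialize a session log losslessly as ``csv`` or ``jsonl``."""
    path = os.fspath(path)
    try:
        if format == "csv":
            with open(path, "w", newline="") as fh:
                fh.write(f"# {json.dumps(_meta(log))}\n")
                writer = csv.DictWriter(fh, fieldnames=_COLUMNS)
                writer.writeheader()
                for r in log.records:
                    row = _record_row(r)
                    if row["response_latency"] is None:
                        row["response_latency"] = ""
                    writer.writerow(row)
        elif format == "jsonl":
            with open(path, "w") as fh:
                fh.write(json.dumps(_meta(log)) + "\n")
                for r in log.records:
                    fh.write(json.dumps(_record_row(r)) + "\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    except OSError as exc:
        raise OSError(f"cannot write session log to {path}: {exc}") from exc


def read_log(path: str | os.PathLike) -> SessionLog:
    """Read and validate a session log written by :func:`write_log`.

    The format is detected from the first line.  Malformed rows are
    aggregated into a single :class:`LogValidationError` naming their line
    numbers; an unrecognized schema version is rejected up front.
    """
    path = os.fspath(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first.startswith("# "):
            meta = json.loads(first[2:])
            body_format = "csv"
        else:
            meta = json.loads(first)
            body_format = "jsonl"
        if meta.get("schema") != SCHEMA_VERSION:
            raise LogValidationError(path, [(1, f"unsupported schema {meta.get('schema')!r}, "
                                                f"expected {SCHEMA_VERSION!r}")])
        errors: list[tuple[int, str]] = []
        records: list[TrialRecord] = []
        if body_format == "csv":
            reader = csv.DictReader(fh)
            for line_no, row in enumerate(reader, start=3):
                rec = _parse_row(row, line_no, errors)
                if rec is not None:
                    records.append(rec)
        else:
            for line_no, line in enumerate(fh, start=2):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    errors.append((line_no, f"unparseable JSON: {exc}"))
                    continue
                rec = _parse_row(row, line_no, errors)
                if rec is not None:
                    records.append(rec)
    if errors:
        raise LogValidationError(path, errors)
    return SessionLog(
        session_id=str(meta["session_id"]),
        group_id=str(meta["group_id"]),
        start_time=float(meta["start_time"]),
        end_time=float(meta["end_time"]),
        records=records,
        device_config_hash=str(meta.get("device_config_hash", "")),
    )


def logs_to_frame(logs: Iterable[SessionLog]) -> pd.DataFrame:
    """Concatenate session logs into the tidy frame the analyses consume."""
    rows = []
    for log in logs:
        for r in log.records:
            rows.append(_record_row(r))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    if len(df):
        df["response_latency"] = df["response_latency"].astype(float)
    return df


def _is_session_log(path: str) -> bool:
    """Cheap sniff: does the file open with this schema's version tag?"""
    try:
        with open(path) as fh:
            first = fh.readline()
    except OSError:
        return False
    return SCHEMA_VERSION in first


def read_log_dir(directory: str | os.PathLike) -> list[SessionLog]:
    """Read every ``*.csv`` / ``*.jsonl`` session log in a directory.

    Files without the session-log schema tag on their first line (e.g.
    analysis outputs living alongside the logs) are skipped.
    """
    directory = os.fspath(directory)
    logs = []
    for name in sorted(os.listdir(directory)):
        path = os.path.join(directory, name)
        if (name.endswith((".csv", ".jsonl")) and not name.startswith(".")
                and _is_session_log(path)):
            logs.append(read_log(path))
    return logs
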