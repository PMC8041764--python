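"""Data model and file I/O for raw assessment sessions and cohort tables.

A session log is a versioned JSON document holding the complete trial-level
record of one OCS-Plus administration: per-subtask event streams with
response identity, correctness, millisecond timestamps (relative to session
start) and optional tap coordinates (screen pixels, origin top-left,
y increasing downward).  Skipped subtasks carry a reason and contribute
"not assessed", never zero, downstream.

Cohort score tables are UTF-8 CSVs whose header names resolve against the
canonical measure registry; empty cells are explicit missing values.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .registry import MEASURE_NAMES, REGISTRY, SUBTASK_ORDER

SCHEMA_VERSION = "ocsplus-session/1"


class SessionValidationError(ValueError):
    """Structured validation failure naming the offending field/block."""


class TrialEvent(BaseModel):
    model_config = ConfigDict(extra="forbid")

    trial_index: int
    stimulus_id: str
    response_value: Optional[str] = None
    correct: Optional[bool] = None          # None = unscored event
    timestamp_ms: int
    tap_xy: Optional[tuple[float, float]] = None

    @field_validator("timestamp_ms")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("timestamp_ms must be >= 0")
        return v


class SubtaskBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")

    subtask_id: str
    events: list[TrialEvent] = []
    skipped: bool = False
    skip_reason: Optional[str] = None
    condition_flags: list[str] = []         # interruption / fatigue / technical

    @field_validator("subtask_id")
    @classmethod
    def _known_subtask(cls, v: str) -> str:
        if v not in SUBTASK_ORDER:
            raise ValueError(
                f"unknown subtask id {v!r}; expected one of {', '.join(SUBTASK_ORDER)}"
            )
        return v

    @model_validator(mode="after")
    def _consistency(self) -> "SubtaskBlock":
        if self.skipped:
            if self.events:
                raise ValueError(
                    f"block {self.subtask_id!r}: skipped block must have no events"
                )
            if not self.skip_reason:
                raise ValueError(
                    f"block {self.subtask_id!r}: skipped block needs a skip_reason"
                )
        ts = [e.timestamp_ms for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"block {self.subtask_id!r}: timestamps must be non-decreasing"
            )
        idx = [e.trial_index for e in self.events]
        if len(set(idx)) != len(idx):
            raise ValueError(
                f"block {self.subtask_id!r}: trial_index values must be unique"
            )
        return self


class SessionLog(BaseModel):
    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    participant_id: str
    age: float
    education_band: str = "standard"        # standard | higher
    sex: Optional[str] = None
    site: Optional[str] = None
    session_datetime: Optional[str] = None
    audio_reference: Optional[str] = None   # optional pointer, no payload
    blocks: list[SubtaskBlock] = []

    @field_validator("age")
    @classmethod
    def _age_pos(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("age must be > 0")
        return v

    @field_validator("education_band")
    @classmethod
    def _edu(cls, v: str) -> str:
        if v not in ("standard", "higher"):
            raise ValueError("education_band must be 'standard' or 'higher'")
        return v

    @model_validator(mode="after")
    def _block_order(self) -> "SessionLog":
        ids = [b.subtask_id for b in self.blocks]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subtask block")
        order = {t: i for i, t in enumerate(SUBTASK_ORDER)}
        ranks = [order[i] for i in ids]
        if ranks != sorted(ranks):
            raise ValueError(
                "blocks must follow the administration order "
                f"{' -> '.join(SUBTASK_ORDER)}"
            )
        return self

    def block(self, subtask_id: str) -> Optional[SubtaskBlock]:
        for b in self.blocks:
            if b.subtask_id == subtask_id:
                return b
        return None


def read_session(path: str | Path) -> SessionLog:
    """Read and validate a session-log JSON file."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SessionValidationError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise SessionValidationError(f"{path}: top level must be a JSON object")
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SessionValidationError(
            f"{path}: unsupported schema_version {version!r} (expected {SCHEMA_VERSION})"
        )
    try:
        return SessionLog.model_validate(payload)
    except ValueError as exc:
        raise SessionValidationError(f"{path}: {exc}") from exc


def write_session(log: SessionLog, path: str | Path) -> Path:
    """Write a session log as JSON; ``read_session`` round-trips exactly.

    Optional fields that are absent are omitted rather than null-filled.
    """
    path = Path(path)
    payload = log.model_dump(exclude_none=True)
    path.write_text(
        json.dumps(payload, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )
    return path


DEMOGRAPHIC_COLUMNS = ("participant_id", "age", "education_band", "sex", "site")


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort score CSV into a DataFrame.

    The header must consist of demographic columns plus canonical measure
    names.  Empty cells become NaN (explicit missing, never zero).  Scores
    outside a measure's registered range raise, naming row and measure.
    """
    path = Path(path)
    df = pd.read_csv(path, encoding="utf-8")
    unknown = [
        c for c in df.columns if c not in DEMOGRAPHIC_COLUMNS and c not in MEASURE_NAMES
    ]
    if unknown:
        raise SessionValidationError(
            f"{path}: unregistered column(s) {unknown}; "
            f"measure columns must be drawn from the canonical registry"
        )
    if "participant_id" not in df.columns:
        raise SessionValidationError(f"{path}: missing participant_id column")
    for name in df.columns:
        if name not in MEASURE_NAMES:
            continue
        mdef = REGISTRY[name]
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.notna() & (
            (col < mdef.lo) | (False if mdef.hi is None else col > mdef.hi)
        )
        if bad.any():
            row = int(bad.idxmax())
            raise SessionValidationError(
                f"{path}: row {row}, measure {name!r}: value {col[row]} outside "
                f"range [{mdef.lo}, {mdef.hi}]"
            )
        df[name] = col
    return df


def write_cohort(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False, encoding="utf-8")
    return path
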