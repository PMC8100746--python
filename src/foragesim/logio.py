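"""Interchange formats for trial logs.

Two formats are supported:

* JSONL -- one trial per line, lossless (config, events, outcome, eye
  schedule); the canonical archive format.
* flat CSV -- one row per selection event with the trial and participant
  keys repeated; the interchange table consumed by the metrics stage.
  Times are milliseconds, distances/coordinates pixels, everywhere.

``write_logs`` then ``read_logs`` is the identity on every analyzed field.
Schema violations on read raise :class:`SchemaError` naming the offending
column.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from .environment import (
    EyeSchedule,
    Outcome,
    SelectionEvent,
    TrialConfig,
    TrialLog,
)

__all__ = ["write_logs", "read_logs", "to_event_table", "SchemaError",
           "EVENT_COLUMNS", "TRIAL_COLUMNS"]


class SchemaError(ValueError):
    """An interchange file does not match the event-table schema."""


TRIAL_COLUMNS = [
    "participant_id",
    "trial_index",
    "experiment",
    "role",
    "target_condition",
    "wolf_behavior",
    "wolf_speed",
    "outcome",
    "points_earned",
    "duration_ms",
    "policy_label",
]
EVENT_COLUMNS = [
    "tick",
    "time_ms",
    "item_id",
    "category",
    "x",
    "y",
    "serial_index",
    "nearest_wolf_distance",
    "during_danger",
    "patch_index",
]
REQUIRED = TRIAL_COLUMNS[:8] + EVENT_COLUMNS[:7]

_CONFIG_KEYS = {
    "experiment": "variant",
    "role": "predation_role",
    "target_condition": "target_condition",
    "wolf_behavior": "wolf_behavior",
    "wolf_speed": "wolf_speed",
}


def _log_to_dict(log: TrialLog) -> dict:
    d = {
        "config": {k: (v.value if hasattr(v, "value") else v)
                   for k, v in asdict(log.config).items()},
        "events": [asdict(e) for e in log.events],
        "outcome": log.outcome.value,
        "duration_ms": log.duration_ms,
        "points_earned": log.points_earned,
        "participant_id": log.participant_id,
        "trial_index": log.trial_index,
        "policy_label": log.policy_label,
        "eye_schedule": None,
    }
    if log.eye_schedule is not None:
        s = log.eye_schedule
        d["eye_schedule"] = {
            "intervals": [list(iv) for iv in s.intervals],
            "inert": s.inert,
            "countdown_range_s": list(s.countdown_range_s),
            "danger_range_s": list(s.danger_range_s),
            "grace_s": s.grace_s,
        }
    return d


def _log_from_dict(d: dict) -> TrialLog:
    cfg = dict(d["config"])
    for key in ("canvas", "grid", "redirect_range_s", "countdown_range_s",
                "danger_range_s"):
        if key in cfg and isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    config = TrialConfig(**cfg)
    events = [SelectionEvent(**e) for e in d["events"]]
    sched = None
    if d.get("eye_schedule") is not None:
        s = d["eye_schedule"]
        sched = EyeSchedule(
            intervals=[tuple(iv) for iv in s["intervals"]],
            inert=s["inert"],
            countdown_range_s=tuple(s["countdown_range_s"]),
            danger_range_s=tuple(s["danger_range_s"]),
            grace_s=s["grace_s"],
        )
    return TrialLog(
        config=config,
        events=events,
        outcome=Outcome(d["outcome"]),
        duration_ms=d["duration_ms"],
        eye_schedule=sched,
        points_earned=d["points_earned"],
        participant_id=d.get("participant_id"),
        trial_index=d.get("trial_index"),
        policy_label=d.get("policy_label", ""),
    )


def to_event_table(logs: Sequence[TrialLog]) -> pd.DataFrame:
    """Flat event table: one row per selection event, trial keys repeated.

    Trials without events contribute a single row with NaN event fields so
    that outcomes (e.g. early eaten trials) survive the round trip.
    """
    rows = []
    for log in logs:
        base = {
            "participant_id": log.participant_id,
            "trial_index": log.trial_index,
            "experiment": log.config.variant.value,
            "role": log.config.predation_role.value,
            "target_condition": log.config.target_condition.value,
            "wolf_behavior": log.config.wolf_behavior.value,
            "wolf_speed": log.config.wolf_speed,
            "outcome": log.outcome.value,
            "points_earned": log.points_earned,
            "duration_ms": log.duration_ms,
            "policy_label": log.policy_label,
        }
        if log.events:
            for e in log.events:
                rows.append({**base, **asdict(e)})
        else:
            rows.append({**base, **{c: None for c in EVENT_COLUMNS}})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS + EVENT_COLUMNS)


def _table_to_logs(df: pd.DataFrame) -> list[TrialLog]:
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    logs = []
    keys = ["participant_id", "trial_index"]
    for _, g in df.groupby(keys, dropna=False, sort=False):
        first = g.iloc[0]
        config = TrialConfig(
            variant=first["experiment"],
            predation_role=first["role"],
            target_condition=first["target_condition"],
            wolf_behavior=first["wolf_behavior"],
            wolf_speed=float(first["wolf_speed"]),
        )
        events = []
        for _, row in g.iterrows():
            if pd.isna(row["item_id"]):
                continue
            events.append(
                SelectionEvent(
                    tick=int(row["tick"]),
                    time_ms=float(row["time_ms"]),
                    item_id=int(row["item_id"]),
                    category=str(row["category"]),
                    x=float(row["x"]),
                    y=float(row["y"]),
                    serial_index=int(row["serial_index"]),
                    nearest_wolf_distance=float(row["nearest_wolf_distance"]),
                    during_danger=bool(row.get("during_danger", False)),
                    patch_index=int(row.get("patch_index", 0) or 0),
                )
            )
        pid = first["participant_id"]
        tix = first["trial_index"]
        logs.append(
            TrialLog(
                config=config,
                events=events,
                outcome=Outcome(first["outcome"]),
                duration_ms=float(first["duration_ms"]),
                eye_schedule=None,
                points_earned=int(first["points_earned"]),
                participant_id=None if pd.isna(pid) else str(pid),
                trial_index=None if pd.isna(tix) else int(tix),
                policy_label=str(first.get("policy_label", "") or ""),
            )
        )
    return logs


def write_logs(logs: Sequence[TrialLog], path, format: str = "jsonl") -> Path:
    """Serialize logs to JSONL (lossless) or flat CSV (event table)."""
    path = Path(path)
    if format == "jsonl":
        with open(path, "w") as fh:
            for log in logs:
                fh.write(json.dumps(_log_to_dict(log)) + "\n")
    elif format == "csv":
        to_event_table(logs).to_csv(path, index=False, float_format="%.6f")
    else:
        raise ValueError(f"unknown format {format!r} (use 'jsonl' or 'csv')")
    return path


def read_logs(path, format: str | None = None) -> list[TrialLog]:
    """Read logs written by :func:`write_logs`; format inferred from suffix."""
    path = Path(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format == "jsonl":
        logs = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.strip()
                if not line:
                    continue
                try:
                    logs.append(_log_from_dict(json.loads(line)))
                except (KeyError, TypeError, ValueError) as exc:
                    raise SchemaError(f"line {i + 1}: {exc}") from exc
        return logs
    if format == "csv":
        return _table_to_logs(pd.read_csv(path))
    raise ValueError(f"unknown format {format!r}")
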