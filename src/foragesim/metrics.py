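"""Per-trial dependent variables of the foraging task.

All measures operate on the ordered selection events of a single trial:

* ``count_runs`` -- number of maximal same-category selection blocks (the
  primary foraging variable; 2..40 on a completed 20+20 trial).
* ``inter_target_stats`` -- inter-target times (ms) and distances (px)
  between successive target selections.
* ``best_r`` -- search-organization index: the larger of |r1| and |r2|,
  where r1 (r2) is the Pearson correlation between the selected items'
  x (y) coordinates and selection order.
* ``wolf_distance`` -- mean distance from the cursor to the nearest
  predator, sampled at selection events.
* ``selection_order`` -- mean 1-based serial position at which a category's
  items were collected (lower = earlier prioritization).
* ``segment_patches`` -- temporal feeding patches separated by big-eye
  danger periods (freeze variant).

Distractor-error selections are excluded from all sequence statistics and
counted separately.  Undefined metrics are returned as NaN sentinels, never
raised, so that tables of heterogeneous trials assemble cleanly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .environment import (
    EyeSchedule,
    PredationRole,
    SelectionEvent,
    TrialLog,
)

__all__ = [
    "TrialMetrics",
    "count_runs",
    "inter_target_stats",
    "best_r",
    "wolf_distance",
    "selection_order",
    "segment_patches",
    "trial_metrics",
    "metrics_table",
]


@dataclass
class TrialMetrics:
    n_runs: Optional[int]
    itt: list[float]
    itd: list[float]
    itt_mean: float
    itd_mean: float
    r1: float
    r2: float
    best_r: float
    wolf_distance_mean: float
    selection_order_a: float
    selection_order_b: float
    n_patches: Optional[int]
    targets_per_patch: list[int] = field(default_factory=list)
    n_selection_errors: int = 0
    n_selected: int = 0
    n_cat_a: int = 0
    n_cat_b: int = 0
    outcome: str = ""


def count_runs(categories: Sequence[str]) -> Optional[int]:
    """Number of maximal same-category blocks; None for an empty sequence."""
    if len(categories) == 0:
        return None
    changes = sum(
        1 for a, b in zip(categories[:-1], categories[1:]) if a != b
    )
    return 1 + changes


def inter_target_stats(
    events: Sequence[SelectionEvent],
) -> tuple[list[float], list[float]]:
    """First differences of selection times (ms) and positions (px)."""
    if len(events) < 2:
        return [], []
    itt = [
        events[i + 1].time_ms - events[i].time_ms for i in range(len(events) - 1)
    ]
    itd = [
        math.hypot(events[i + 1].x - events[i].x, events[i + 1].y - events[i].y)
        for i in range(len(events) - 1)
    ]
    return itt, itd


def _pearson_vs_order(values: np.ndarray) -> float:
    order = np.arange(1.0, len(values) + 1.0)
    if np.ptp(values) == 0:
        return float("nan")
    return float(np.corrcoef(values, order)[0, 1])


def best_r(events: Sequence[SelectionEvent]) -> tuple[float, float, float]:
    """(r1, r2, best_r): selection order vs x, vs y, and max |.|.

    A zero-variance coordinate yields NaN for that coefficient; best_r falls
    back to the other, or NaN when both degenerate or fewer than 3 events.
    """
    if len(events) < 3:
        return (float("nan"),) * 3
    xs = np.array([e.x for e in events])
    ys = np.array([e.y for e in events])
    r1 = _pearson_vs_order(xs)
    r2 = _pearson_vs_order(ys)
    cands = [abs(r) for r in (r1, r2) if not math.isnan(r)]
    return r1, r2, (max(cands) if cands else float("nan"))


def wolf_distance(events: Sequence[SelectionEvent]) -> float:
    """Mean nearest-wolf distance over selection events (px); NaN if absent."""
    d = [
        e.nearest_wolf_distance
        for e in events
        if not math.isnan(e.nearest_wolf_distance)
    ]
    return float(np.mean(d)) if d else float("nan")


def selection_order(events: Sequence[SelectionEvent], category: str) -> float:
    """Mean 1-based serial position of the category's selections; NaN if absent."""
    pos = [e.serial_index for e in events if e.category == category]
    return float(np.mean(pos)) if pos else float("nan")


def segment_patches(
    events: Sequence[SelectionEvent],
    schedule: Optional[EyeSchedule],
    role: PredationRole = PredationRole.HUNTED,
) -> tuple[Optional[int], list[int]]:
    """Partition selections into temporal patches between danger periods.

    Patches are maximal selection subsequences between consecutive big-eye
    intervals relevant to the role (wolf intervals for hunted, sheep
    intervals for distracted); inert or absent schedules give a single patch.
    Empty patches are dropped.  Returns (n_patches, targets per patch).
    """
    if len(events) == 0:
        return None, []
    role = PredationRole(role)
    if schedule is None or schedule.inert or not schedule.intervals:
        return 1, [len(events)]
    want_sheep = role is PredationRole.DISTRACTED
    ends = sorted(
        iv[1]
        for iv in schedule.intervals
        if (iv[2] == "sheep") == want_sheep
    )
    if not ends:
        return 1, [len(events)]
    counts: dict[int, int] = {}
    for e in events:
        k = sum(1 for end in ends if end <= e.tick)
        counts[k] = counts.get(k, 0) + 1
    per_patch = [counts[k] for k in sorted(counts)]
    return len(per_patch), per_patch


def trial_metrics(log: TrialLog) -> TrialMetrics:
    """All per-trial measures of one log.

    Distractor-error events are excluded from the run / ITT / ITD / best-r /
    selection-order computations and counted in ``n_selection_errors``.
    """
    tevents = log.target_events()
    errors = len(log.events) - len(tevents)
    cats = [e.category for e in tevents]
    itt, itd = inter_target_stats(tevents)
    r1, r2, br = best_r(tevents)
    n_patches, per_patch = (
        segment_patches(tevents, log.eye_schedule, log.config.predation_role)
        if log.config.variant.value == "E2_freeze"
        else (None, [])
    )
    return TrialMetrics(
        n_runs=count_runs(cats),
        itt=itt,
        itd=itd,
        itt_mean=float(np.mean(itt)) if itt else float("nan"),
        itd_mean=float(np.mean(itd)) if itd else float("nan"),
        r1=r1,
        r2=r2,
        best_r=br,
        wolf_distance_mean=wolf_distance(tevents),
        selection_order_a=selection_order(tevents, "A"),
        selection_order_b=selection_order(tevents, "B"),
        n_patches=n_patches,
        targets_per_patch=per_patch,
        n_selection_errors=errors,
        n_selected=len(tevents),
        n_cat_a=sum(1 for c in cats if c == "A"),
        n_cat_b=sum(1 for c in cats if c == "B"),
        outcome=log.outcome.value,
    )


def metrics_table(logs: Sequence[TrialLog]) -> pd.DataFrame:
    """Tidy per-trial metrics table (one row per trial).

    Includes the trial keys and condition columns needed by the
    classification stage; list-valued fields are summarized (means/counts).
    """
    rows = []
    for log in logs:
        m = trial_metrics(log)
        rows.append(
            {
                "participant_id": log.participant_id,
                "trial_index": log.trial_index,
                "experiment": log.config.variant.value,
                "role": log.config.predation_role.value,
                "target_condition": log.config.target_condition.value,
                "wolf_behavior": log.config.wolf_behavior.value,
                "wolf_speed": log.config.wolf_speed,
                "outcome": m.outcome,
                "n_selected": m.n_selected,
                "n_cat_a": m.n_cat_a,
                "n_cat_b": m.n_cat_b,
                "n_runs": m.n_runs,
                "itt_mean": m.itt_mean,
                "itd_mean": m.itd_mean,
                "r1": m.r1,
                "r2": m.r2,
                "best_r": m.best_r,
                "wolf_distance_mean": m.wolf_distance_mean,
                "selection_order_high": m.selection_order_a,
                "selection_order_low": m.selection_order_b,
                "n_patches": m.n_patches,
                "n_selection_errors": m.n_selection_errors,
                "duration_ms": log.duration_ms,
                "points_earned": log.points_earned,
            }
        )
    return pd.DataFrame(rows)
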