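"""Synthetic foragers: parameterized selection and motion policies.

These agents stand in for human players.  They are deliberately simple --
the goal is to generate trial logs whose *statistical* structure spans the
behavioural phenotypes the analysis pipeline must detect (random vs
run-focused category selection, reward prioritization, predator avoidance,
freeze compliance), not to model human cognition or motor control.

Category selection works in two regimes:

* ``switch_prob is None`` (the unbiased forager): the next target is drawn
  from *all* remaining targets, weighted by proximity and value.  With
  neutral weights this makes the category sequence exchangeable, so the
  expected number of runs equals the Wald-Wolfowitz null 2*n1*n2/N + 1.
* ``switch_prob = s``: a category-first process -- with probability ``s``
  the agent switches away from the previously selected category (forced
  stay/switch once a category is exhausted), then picks an item within the
  chosen category.  This gives direct experimental control over run
  structure for calibration studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .environment import (
    Item,
    TargetCondition,
    TrialConfig,
    TrialLog,
    Variant,
    WolfBehavior,
    run_block,
    split_streams,
)

__all__ = [
    "AgentPolicy",
    "choose_next_target",
    "plan_motion",
    "preset",
    "PRESET_NAMES",
    "simulate_participant",
    "sample_category_sequence",
    "sample_category_sequences",
    "e1_grid",
    "e2_grid",
    "e3_grid",
]

_DIST_FLOOR = 10.0  # px; distance floor so proximity weights stay finite


@dataclass
class AgentPolicy:
    """Parameter bundle controlling one synthetic forager.

    switch_prob
        Probability of switching target category between consecutive
        selections, or None for the unbiased (uniform-over-remaining)
        forager; see the module docstring.
    proximity_weight
        Exponent >= 0 biasing item choice toward items near the cursor
        (weight ~ 1/distance^proximity_weight).
    value_bias
        Exponent biasing choice toward high-value items
        (weight ~ value^value_bias); only meaningful in the reward variant.
        Positive prefers high value, 0 is value-blind; negative values are
        admitted for value-averse probe agents.
    error_rate
        Per-selection probability of mistakenly selecting the distractor
        nearest the intended target (which ends the trial).
    cursor_speed / selection_pause_ms / pause_jitter_sigma
        Motion tempo: straight-line cursor movement in px/s, plus a
        lognormal dwell before each selection registers (median
        ``selection_pause_ms``, log-sd ``pause_jitter_sigma``).
    avoidance_radius / flee_speed
        Predator avoidance in the avoidance variant: when the nearest wolf
        is closer than the radius, the agent flees directly away at
        ``flee_speed`` until clear.  Radius 0 disables avoidance.
    freeze_compliance
        Probability (per danger period) of withholding selections while a
        relevant big-eye period is active in the freeze variant.
    conjunction_switch_drop
        Amount subtracted from switch_prob on conjunction trials, emulating
        the longer runs seen under harder selection.  For the unbiased
        forager this converts it to a category-first process with
        ``switch_prob = 0.5 - drop`` when the drop is positive.
    """

    switch_prob: Optional[float] = None
    proximity_weight: float = 0.0
    value_bias: float = 0.0
    error_rate: float = 0.0
    cursor_speed: float = 300.0
    selection_pause_ms: float = 350.0
    pause_jitter_sigma: float = 0.25
    avoidance_radius: float = 0.0
    flee_speed: float = 420.0
    freeze_compliance: float = 1.0
    conjunction_switch_drop: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("error_rate", "freeze_compliance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.switch_prob is not None and not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1] or None")
        if self.cursor_speed <= 0 or self.flee_speed <= 0:
            raise ValueError("speeds must be positive")
        if self.proximity_weight < 0:
            raise ValueError("proximity_weight must be >= 0")

    def with_(self, **kw) -> "AgentPolicy":
        return replace(self, **kw)

    def for_condition(self, config: TrialConfig) -> "AgentPolicy":
        """Condition-adjusted copy (conjunction lowers switching, slows pace)."""
        if (
            config.target_condition is TargetCondition.CONJUNCTION
            and self.conjunction_switch_drop > 0
        ):
            base = 0.5 if self.switch_prob is None else self.switch_prob
            return self.with_(
                switch_prob=max(0.0, base - self.conjunction_switch_drop),
                selection_pause_ms=self.selection_pause_ms * 1.3,
            )
        return self

    # -- selection ---------------------------------------------------------

    def choose_next_target(
        self,
        items: Sequence[Item],
        cursor: tuple[float, float],
        prev_category: Optional[str],
        config: TrialConfig,
        rng: np.random.Generator,
        hazard: Optional[tuple[list[tuple[float, float]], float]] = None,
    ) -> int:
        return choose_next_target(
            self, items, cursor, prev_category, config, rng, hazard=hazard
        )

    def draw_pause_ticks(
        self, config: TrialConfig, rng: np.random.Generator
    ) -> int:
        """Lognormal dwell before a selection registers, in ticks (>= 1)."""
        ms = self.selection_pause_ms * math.exp(
            rng.normal(0.0, self.pause_jitter_sigma)
        )
        return max(1, int(round(ms / 1000.0 * config.tick_rate)))


def _item_weights(
    policy: AgentPolicy,
    cands: list[Item],
    cursor: tuple[float, float],
    hazard: Optional[tuple[list[tuple[float, float]], float]] = None,
) -> np.ndarray:
    w = np.ones(len(cands))
    if policy.proximity_weight > 0:
        d = np.array(
            [
                max(_DIST_FLOOR, math.hypot(it.position[0] - cursor[0], it.position[1] - cursor[1]))
                for it in cands
            ]
        )
        w *= (1.0 / d) ** policy.proximity_weight
    if policy.value_bias != 0:
        w *= np.array([max(it.value, 1) for it in cands], dtype=float) ** policy.value_bias
    if hazard is not None:
        # strongly downweight (never hard-exclude) items close to a predator
        positions, radius = hazard
        for i, it in enumerate(cands):
            if any(
                math.hypot(it.position[0] - hx, it.position[1] - hy) < radius
                for hx, hy in positions
            ):
                w[i] *= 0.01
    return w


def choose_next_target(
    policy: AgentPolicy,
    items: Sequence[Item],
    cursor: tuple[float, float],
    prev_category: Optional[str],
    config: TrialConfig,
    rng: np.random.Generator,
    hazard: Optional[tuple[list[tuple[float, float]], float]] = None,
) -> int:
    """Pick the id of the next item to select.

    With probability ``error_rate`` the distractor nearest the intended
    target is substituted; ``hazard`` (predator positions + radius) lets a
    hunted agent deprioritize items close to a wolf.  Raises ValueError
    when no targets remain.
    """
    remaining = [it for it in items if it.role == "target" and it.collected_at is None]
    if not remaining:
        raise ValueError("choose_next_target called with no remaining targets")

    if policy.switch_prob is None:
        cands = remaining
    else:
        cats = sorted({it.category for it in remaining})
        if prev_category is None or prev_category not in cats:
            # value bias may steer the initial / forced category choice
            if policy.value_bias != 0 and len(cats) > 1:
                mv = np.array(
                    [
                        np.mean([it.value for it in remaining if it.category == c])
                        for c in cats
                    ]
                )
                p = np.maximum(mv, 1.0) ** policy.value_bias
                cat = cats[rng.choice(len(cats), p=p / p.sum())]
            else:
                cat = cats[int(rng.integers(len(cats)))]
        elif len(cats) == 1:
            cat = cats[0]  # forced stay (or forced switch) -- one category left
        else:
            others = [c for c in cats if c != prev_category]
            if policy.value_bias != 0:
                # switch/stay base probabilities re-weighted by category value
                base = {prev_category: 1.0 - policy.switch_prob}
                for c in others:
                    base[c] = policy.switch_prob / len(others)
                vals = {
                    c: np.mean([it.value for it in remaining if it.category == c])
                    for c in cats
                }
                w = np.array(
                    [base[c] * max(vals[c], 1.0) ** policy.value_bias for c in cats]
                )
                cat = cats[rng.choice(len(cats), p=w / w.sum())]
            else:
                if rng.random() < policy.switch_prob:
                    cat = others[int(rng.integers(len(others)))]
                else:
                    cat = prev_category
        cands = [it for it in remaining if it.category == cat]

    w = _item_weights(policy, cands, cursor, hazard)
    chosen = cands[int(rng.choice(len(cands), p=w / w.sum()))]

    if policy.error_rate > 0 and rng.random() < policy.error_rate:
        distractors = [
            it for it in items if it.role == "distractor" and it.collected_at is None
        ]
        if distractors:
            tx, ty = chosen.position
            chosen = min(
                distractors,
                key=lambda it: math.hypot(it.position[0] - tx, it.position[1] - ty),
            )
    return chosen.id


def plan_motion(
    policy: AgentPolicy,
    cursor: tuple[float, float],
    target_pos: tuple[float, float],
    nearest_wolf_pos: Optional[tuple[float, float]] = None,
    hunted: bool = False,
) -> tuple[float, float]:
    """Cursor velocity vector (px/s): pursuit of the target, or flight.

    Hunted agents with a wolf closer than ``avoidance_radius`` override
    pursuit with a flee vector pointing directly away from that wolf.
    """
    if (
        hunted
        and policy.avoidance_radius > 0
        and nearest_wolf_pos is not None
        and math.hypot(nearest_wolf_pos[0] - cursor[0], nearest_wolf_pos[1] - cursor[1])
        < policy.avoidance_radius
    ):
        ang = math.atan2(
            cursor[1] - nearest_wolf_pos[1], cursor[0] - nearest_wolf_pos[0]
        )
        return (
            policy.flee_speed * math.cos(ang),
            policy.flee_speed * math.sin(ang),
        )
    dx, dy = target_pos[0] - cursor[0], target_pos[1] - cursor[1]
    d = math.hypot(dx, dy)
    if d == 0:
        return (0.0, 0.0)
    return (policy.cursor_speed * dx / d, policy.cursor_speed * dy / d)


# ---------------------------------------------------------------------------
# Presets


_PRESETS = {
    # Category-random forager: uniform over remaining targets.
    "random_switcher": AgentPolicy(switch_prob=None, label="random_switcher"),
    # Long runs: strong category perseveration plus nearest-item habit.
    "run_focused": AgentPolicy(
        switch_prob=0.05, proximity_weight=1.0, label="run_focused"
    ),
    # Category-random but spatially organized forager.
    "switch_focused": AgentPolicy(
        switch_prob=None, proximity_weight=1.0, label="switch_focused"
    ),
    # Prioritizes high-value targets (reward variant).
    "reward_focused": AgentPolicy(
        switch_prob=None, proximity_weight=1.0, value_bias=3.0,
        label="reward_focused",
    ),
    # Predator-wary: wide avoidance radius, no value bias, high compliance.
    "wolf_focused": AgentPolicy(
        switch_prob=None, proximity_weight=1.0, avoidance_radius=150.0,
        freeze_compliance=0.98, label="wolf_focused",
    ),
    # Ignores all dynamic objects (baseline phenotype).
    "baseline_ignorer": AgentPolicy(
        switch_prob=None, proximity_weight=1.0, avoidance_radius=0.0,
        label="baseline_ignorer",
    ),
    # Keeps feeding through danger periods; small avoidance radius.
    "food_focused": AgentPolicy(
        switch_prob=None, proximity_weight=1.0, avoidance_radius=60.0,
        freeze_compliance=0.94, label="food_focused",
    ),
}
PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> AgentPolicy:
    """Return a documented parameter bundle for a behavioural phenotype."""
    try:
        return replace(_PRESETS[name])
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Selection-level (kinematics-free) simulation
#
# For large calibration studies only the category sequence matters.  This
# sampler runs the same choose_next_target policy against a static layout,
# teleporting the cursor to each selected item, and is orders of magnitude
# faster than the tick-level simulator.  Wolf-dependent behaviour
# (avoidance, freezing) plays no role here.


def sample_category_sequence(
    policy: AgentPolicy,
    config: TrialConfig,
    rng: np.random.Generator,
    stop_at_goal: Optional[bool] = None,
) -> list[str]:
    """Category sequence of one trial under the selection policy alone.

    ``stop_at_goal`` defaults to True for the reward variant (stop at the
    point goal) and False otherwise (exhaustive).  Selection errors are not
    simulated here.
    """
    from .environment import layout_trial

    if stop_at_goal is None:
        stop_at_goal = config.variant is Variant.E3_REWARD
    items = layout_trial(config, rng)
    cursor = (config.canvas[0] / 2.0, config.canvas[1] / 2.0)
    seq: list[str] = []
    prev = None
    points = 0
    pol = policy.with_(error_rate=0.0)
    n_targets = sum(1 for it in items if it.role == "target")
    for _ in range(n_targets):
        iid = choose_next_target(pol, items, cursor, prev, config, rng)
        it = next(x for x in items if x.id == iid)
        it.collected_at = 0
        seq.append(it.category)
        prev = it.category
        cursor = it.position
        points += it.value
        if stop_at_goal and points >= config.point_goal:
            break
    return seq


def _policy_is_uniform(policy: AgentPolicy) -> bool:
    return (
        policy.switch_prob is None
        and policy.proximity_weight == 0
        and policy.value_bias == 0
        and policy.error_rate == 0
    )


def sample_category_sequences(
    policy: AgentPolicy,
    config: TrialConfig,
    n_trials: int,
    rng: np.random.Generator,
    stop_at_goal: Optional[bool] = None,
) -> list[list[str]]:
    """n_trials independent category sequences under the policy.

    The fully uniform policy (no switch, proximity, value or error biases)
    is dispatched to a vectorized permutation sampler -- mathematically
    identical to the per-item path, since uniform selection over remaining
    targets makes the sequence a uniform random permutation.
    """
    if stop_at_goal is None:
        stop_at_goal = config.variant is Variant.E3_REWARD
    if _policy_is_uniform(policy) and not stop_at_goal:
        cats = [
            spec[1] for spec in _category_roster_targets(config)
        ]
        arr = np.array(cats)
        out = []
        for _ in range(n_trials):
            out.append(list(arr[rng.permutation(len(arr))]))
        return out
    return [
        sample_category_sequence(policy, config, rng, stop_at_goal)
        for _ in range(n_trials)
    ]


def _category_roster_targets(config: TrialConfig):
    from .environment import _category_roster

    return [s for s in _category_roster(config) if s[0] == "target"]


# ---------------------------------------------------------------------------
# Factorial condition grids and participant-level simulation


def e1_grid(
    role="hunted",
    wolf_behavior="pack",
    speeds: Sequence[float] = (30, 42, 54, 66, 78),
    **overrides,
) -> list[tuple[TrialConfig, int]]:
    """Avoidance-variant cells: 2 target conditions x len(speeds) velocities.

    Returns (config, n_correct) pairs; 3 correct trials per velocity cell so
    each target-condition block totals 15 correct trials.
    """
    cells = []
    for cond in (TargetCondition.FEATURE, TargetCondition.CONJUNCTION):
        for v in speeds:
            cells.append(
                (
                    TrialConfig(
                        variant=Variant.E1_AVOID,
                        predation_role=role,
                        target_condition=cond,
                        wolf_behavior=wolf_behavior,
                        wolf_speed=float(v),
                        **overrides,
                    ),
                    3,
                )
            )
    return cells


def e2_grid(role="hunted", n_correct: int = 10, **overrides):
    """Freeze-variant cells: feature and conjunction, 10 correct each."""
    return [
        (
            TrialConfig(
                variant=Variant.E2_FREEZE,
                predation_role=role,
                target_condition=cond,
                wolf_behavior=WolfBehavior.PACK,
                wolf_speed=78.0,
                **overrides,
            ),
            n_correct,
        )
        for cond in (TargetCondition.FEATURE, TargetCondition.CONJUNCTION)
    ]


def e3_grid(role="hunted", n_correct: int = 20, **overrides):
    """Reward-variant cell: 20 correct trials, lone wolf at 78 px/s."""
    return [
        (
            TrialConfig(
                variant=Variant.E3_REWARD,
                predation_role=role,
                target_condition=TargetCondition.REWARD,
                wolf_behavior="lone",
                wolf_speed=78.0,
                **overrides,
            ),
            n_correct,
        )
    ]


def simulate_participant(
    grid: Sequence[tuple[TrialConfig, int]],
    policy: AgentPolicy,
    seed,
    participant_id: str = "sim",
    max_attempts_per_cell: Optional[int] = None,
) -> list[TrialLog]:
    """Run every cell of a factorial grid for one synthetic participant.

    Failed trials are retained.  The policy is adjusted per cell via
    ``policy.for_condition`` (conjunction difficulty).
    """
    streams = split_streams(seed, len(grid))
    logs: list[TrialLog] = []
    for (config, n_correct), rng in zip(grid, streams):
        cell_logs = run_block(
            config,
            policy.for_condition(config),
            n_correct,
            rng,
            max_attempts=max_attempts_per_cell,
        )
        for log in cell_logs:
            log.participant_id = participant_id
        logs.extend(cell_logs)
    return logs
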