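"""Discrete-time simulation of the foraging world.

The task world is a grey canvas (800 x 600 px by default) holding a regular
10 x 8 grid of selectable items, a cursor rendered as a sheep, and four
predator ("wolf") objects whose motion follows multiple-object-tracking
conventions: constant speed, straight-line segments, specular reflection at
the display edges.  Three task variants are supported:

``E1_avoid``
    Wolves are physically dangerous to *hunted* players: bounding-box contact
    between sheep and wolf ends the trial.  Wolves move either as a "pack"
    (independent linear trajectories, redirected at random intervals) or with
    one "lone" wolf that continuously re-aims at the sheep at 20 Hz.
``E2_freeze``
    Wolves are spatially harmless but periodically become "hungry" (big
    eyes).  Selections made during such danger periods (after a short grace
    window) end the trial for hunted players; for *distracted* players the
    sheep's own eyes change instead and selections are silently ignored while
    they are big; a *baseline* group sees inert eye changes.
``E3_reward``
    Two target categories with unequal value (10 x 2 points, 30 x 1 point);
    the trial ends when the score reaches the point goal.

Everything is deterministic given a configuration and a seed.  Time advances
in ticks of 1/tick_rate seconds (60 Hz by default, matching the capped
display update rate of the original task).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard for typing only
    from .agents import AgentPolicy

__all__ = [
    "Variant",
    "PredationRole",
    "TargetCondition",
    "WolfBehavior",
    "ConfigError",
    "TrialConfig",
    "Item",
    "WolfState",
    "SheepState",
    "EyeSchedule",
    "SelectionEvent",
    "TrialLog",
    "cell_center",
    "layout_trial",
    "init_wolves",
    "step_wolves",
    "schedule_eyes",
    "check_termination",
    "run_trial",
    "run_block",
    "split_streams",
]

# Sprite geometry (pixels).  Items are 20 px disks; sprite rectangles are the
# full rendered size of the original assets.
CANVAS = (800, 600)
GRID = (10, 8)
WOLF_SIZE = (70.0, 94.0)
SHEEP_SIZE = (64.0, 80.0)
ITEM_SIZE = 20.0
E1_WOLF_SPEEDS = (30.0, 42.0, 54.0, 66.0, 78.0)


class Variant(str, Enum):
    E1_AVOID = "E1_avoid"
    E2_FREEZE = "E2_freeze"
    E3_REWARD = "E3_reward"


class PredationRole(str, Enum):
    HUNTED = "hunted"
    DISTRACTED = "distracted"
    BASELINE = "baseline"


class TargetCondition(str, Enum):
    FEATURE = "feature"
    CONJUNCTION = "conjunction"
    REWARD = "reward"


class WolfBehavior(str, Enum):
    PACK = "pack"
    LONE = "lone"


class Outcome(str, Enum):
    COMPLETED = "completed"
    EATEN = "eaten"
    DISTRACTOR_ERROR = "distractor_error"
    DANGER_ERROR = "danger_error"
    TIMEOUT = "timeout"


class ConfigError(ValueError):
    """Raised when a trial configuration is internally inconsistent."""


@dataclass
class TrialConfig:
    """Full parameterization of a single trial.

    Defaults reproduce the standard task: 800 x 600 canvas, 10 x 8 item grid,
    40 targets + 40 distractors, four wolves starting at the grid corners,
    60 Hz clock.  ``wolf_speed`` is one of (30, 42, 54, 66, 78) px/s in the
    avoidance variant and fixed at 78 px/s in the freeze and reward variants.
    """

    variant: Variant = Variant.E1_AVOID
    predation_role: PredationRole = PredationRole.HUNTED
    target_condition: TargetCondition = TargetCondition.FEATURE
    wolf_behavior: WolfBehavior = WolfBehavior.PACK
    wolf_speed: float = 78.0
    canvas: tuple[int, int] = CANVAS
    grid: tuple[int, int] = GRID
    n_targets: int = 40
    n_distractors: int = 40
    point_goal: int = 30
    tick_rate: float = 60.0
    seed: Optional[int] = None
    # Wolf kinematics
    redirect_range_s: tuple[float, float] = (1.7, 3.3)
    lone_retarget_every: int = 3  # ticks; 3 @ 60 Hz = 20 Hz re-aiming
    edge_mode: str = "reflect"  # "reflect" | "reverse"
    # Freeze-variant timing
    countdown_range_s: tuple[float, float] = (1.5, 5.0)
    danger_range_s: tuple[float, float] = (1.5, 3.0)
    grace_s: float = 0.5
    # Freeze-variant wolf repulsion from the sheep
    sheep_avoid_radius: float = 100.0
    boost_factor: float = 1.5
    boost_duration_s: float = 0.5
    # Safety net against non-terminating policies
    max_ticks: int = 60 * 240

    def __post_init__(self) -> None:
        self.variant = Variant(self.variant)
        self.predation_role = PredationRole(self.predation_role)
        self.target_condition = TargetCondition(self.target_condition)
        self.wolf_behavior = WolfBehavior(self.wolf_behavior)
        ncells = self.grid[0] * self.grid[1]
        if self.n_targets + self.n_distractors != ncells:
            raise ConfigError(
                f"grid capacity {ncells} != n_targets + n_distractors "
                f"({self.n_targets} + {self.n_distractors})"
            )
        if self.wolf_speed <= 0 or self.tick_rate <= 0:
            raise ConfigError("wolf_speed and tick_rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.tick_rate

    @property
    def n_cells(self) -> int:
        return self.grid[0] * self.grid[1]

    def with_(self, **kw) -> "TrialConfig":
        return replace(self, **kw)


@dataclass
class Item:
    id: int
    role: str  # "target" | "distractor"
    category: str  # targets: "A"/"B"; distractors: "C"/"D"
    value: int
    cell: tuple[int, int]
    position: tuple[float, float]
    collected_at: Optional[int] = None


@dataclass
class WolfState:
    x: float
    y: float
    heading: float  # radians
    speed: float  # px/s, constant within a trial
    mode: WolfBehavior = WolfBehavior.PACK
    eyes: str = "normal"
    next_redirect_at: int = -1  # tick; -1 = not yet scheduled
    boost_until: int = -1  # tick until which the transient speed boost lasts
    size: tuple[float, float] = WOLF_SIZE

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class SheepState:
    x: float
    y: float
    eyes: str = "normal"
    size: tuple[float, float] = SHEEP_SIZE

    @property
    def position(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class EyeSchedule:
    """Alternating countdown / big-eye periods for the freeze variant.

    ``intervals`` holds ``(start_tick, end_tick, bearer)`` triples with
    half-open tick spans ``[start, end)``; the bearer is a wolf index or the
    string ``"sheep"``.  ``inert=True`` marks baseline schedules whose eye
    changes carry no task consequence.
    """

    intervals: list[tuple[int, int, object]] = field(default_factory=list)
    inert: bool = False
    countdown_range_s: tuple[float, float] = (1.5, 5.0)
    danger_range_s: tuple[float, float] = (1.5, 3.0)
    grace_s: float = 0.5

    def active(self, tick: int):
        """Return the interval covering ``tick``, or None."""
        for iv in self.intervals:
            if iv[0] <= tick < iv[1]:
                return iv
            if iv[0] > tick:
                break
        return None

    def n_ended_before(self, tick: int) -> int:
        return sum(1 for iv in self.intervals if iv[1] <= tick)


@dataclass
class SelectionEvent:
    tick: int
    time_ms: float
    item_id: int
    category: str
    x: float
    y: float
    serial_index: int  # 1-based order of *target* selections within the trial
    nearest_wolf_distance: float
    during_danger: bool = False
    patch_index: int = 0  # number of relevant danger periods ended before tick


@dataclass
class TrialLog:
    config: TrialConfig
    events: list[SelectionEvent]
    outcome: Outcome
    duration_ms: float
    eye_schedule: Optional[EyeSchedule] = None
    points_earned: int = 0
    participant_id: Optional[str] = None
    trial_index: Optional[int] = None
    policy_label: str = ""

    @property
    def completed(self) -> bool:
        return self.outcome is Outcome.COMPLETED

    def target_events(self) -> list[SelectionEvent]:
        return [e for e in self.events if e.category in ("A", "B")]


# ---------------------------------------------------------------------------
# RNG plumbing


def split_streams(seed, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent child generators from a seed.

    Accepts an int, a SeedSequence, or an existing Generator (whose bit
    generator seed sequence is spawned from, keeping streams reproducible).
    """
    if isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq
    elif isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Layout


def cell_center(config: TrialConfig, col: int, row: int) -> tuple[float, float]:
    """Center of grid cell (col, row); lattice inset half a cell from edges."""
    cw = config.canvas[0] / config.grid[0]
    ch = config.canvas[1] / config.grid[1]
    return ((col + 0.5) * cw, (row + 0.5) * ch)


def _category_roster(config: TrialConfig) -> list[tuple[str, str, int]]:
    """(role, category, value) for every item, in a fixed canonical order."""
    if config.target_condition is TargetCondition.REWARD:
        n_high = config.n_targets // 4  # 10 of 40 by default
        n_low = config.n_targets - n_high
        targets = [("target", "A", 2)] * n_high + [("target", "B", 1)] * n_low
    else:
        half = config.n_targets // 2
        targets = [("target", "A", 0)] * half + [("target", "B", 0)] * (
            config.n_targets - half
        )
    dhalf = config.n_distractors // 2
    distractors = [("distractor", "C", 0)] * dhalf + [("distractor", "D", 0)] * (
        config.n_distractors - dhalf
    )
    return targets + distractors


def layout_trial(config: TrialConfig, rng: np.random.Generator) -> list[Item]:
    """Assign the item roster to grid cells by a uniformly random bijection."""
    cols, rows = config.grid
    cells = [(c, r) for r in range(rows) for c in range(cols)]
    roster = _category_roster(config)
    if len(roster) != len(cells):  # defensive; __post_init__ already checks
        raise ConfigError("grid capacity does not match item count")
    perm = rng.permutation(len(cells))
    items = []
    for item_id, (spec_, cell_idx) in enumerate(zip(roster, perm)):
        role, cat, val = spec_
        cell = cells[cell_idx]
        items.append(
            Item(
                id=item_id,
                role=role,
                category=cat,
                value=val,
                cell=cell,
                position=cell_center(config, *cell),
            )
        )
    return items


# ---------------------------------------------------------------------------
# Wolves


def init_wolves(config: TrialConfig) -> list[WolfState]:
    """Four wolves at the grid corners, initially heading for the center.

    In lone mode the first wolf is the pursuer; the other three behave as
    pack wolves.  The freeze variant has no lone wolf.
    """
    cols, rows = config.grid
    corners = [(0, 0), (cols - 1, 0), (0, rows - 1), (cols - 1, rows - 1)]
    cx, cy = config.canvas[0] / 2.0, config.canvas[1] / 2.0
    wolves = []
    lone = (
        config.wolf_behavior is WolfBehavior.LONE
        and config.variant is not Variant.E2_FREEZE
    )
    for i, cell in enumerate(corners):
        x, y = cell_center(config, *cell)
        heading = math.atan2(cy - y, cx - x)
        wolves.append(
            WolfState(
                x=x,
                y=y,
                heading=heading,
                speed=config.wolf_speed,
                mode=WolfBehavior.LONE if (lone and i == 0) else WolfBehavior.PACK,
            )
        )
    return wolves


def _bounds(config: TrialConfig, size: tuple[float, float]):
    # Anchor (sprite center) is confined to the canvas rectangle; sprites may
    # overhang the edge, matching the corner starting positions.
    return 0.0, float(config.canvas[0]), 0.0, float(config.canvas[1])


def _reflect_axis(v: float, lo: float, hi: float) -> tuple[float, bool]:
    """Fold v into [lo, hi]; True if a boundary was crossed."""
    crossed = False
    # segment lengths are << span, so a couple of folds suffice; loop for safety
    while v < lo or v > hi:
        crossed = True
        v = 2 * lo - v if v < lo else 2 * hi - v
    return v, crossed


def _move_with_reflection(
    wolf: WolfState, dist: float, config: TrialConfig
) -> None:
    xlo, xhi, ylo, yhi = _bounds(config, wolf.size)
    nx = wolf.x + math.cos(wolf.heading) * dist
    ny = wolf.y + math.sin(wolf.heading) * dist
    nx, cx = _reflect_axis(nx, xlo, xhi)
    ny, cy = _reflect_axis(ny, ylo, yhi)
    vx, vy = math.cos(wolf.heading), math.sin(wolf.heading)
    if config.edge_mode == "reverse" and (cx or cy):
        vx, vy = -vx, -vy
    else:
        if cx:
            vx = -vx
        if cy:
            vy = -vy
    wolf.x, wolf.y = nx, ny
    wolf.heading = math.atan2(vy, vx)


def _wolf_radius(wolf: WolfState) -> float:
    return math.hypot(wolf.size[0] / 2.0, wolf.size[1] / 2.0)


def _point_segment_distance(
    px: float, py: float, ax: float, ay: float, bx: float, by: float
) -> float:
    vx, vy = bx - ax, by - ay
    L2 = vx * vx + vy * vy
    if L2 == 0.0:
        return math.hypot(px - ax, py - ay)
    t = max(0.0, min(1.0, ((px - ax) * vx + (py - ay) * vy) / L2))
    return math.hypot(px - (ax + t * vx), py - (ay + t * vy))


def step_wolves(
    wolves: Sequence[WolfState],
    sheep: SheepState,
    config: TrialConfig,
    tick: int,
    rng: np.random.Generator,
) -> None:
    """Advance all wolves by one tick, in place.

    Pack wolves hold a straight course, resampling the heading uniformly on
    [0, 2pi) at intervals drawn U(1.7, 3.3) s.  A lone wolf re-aims at the
    sheep every ``lone_retarget_every`` ticks.  Edges reflect motion while
    preserving the per-tick path length exactly.  The freeze variant adds
    wolf-wolf heading exchange on contact and active repulsion (with a
    transient speed boost) when a wolf comes within ``sheep_avoid_radius`` px
    of the sheep.
    """
    dt = config.dt
    lo_s, hi_s = config.redirect_range_s
    for wolf in wolves:
        if wolf.mode is WolfBehavior.LONE:
            if tick % config.lone_retarget_every == 0:
                wolf.heading = math.atan2(sheep.y - wolf.y, sheep.x - wolf.x)
        else:
            if wolf.next_redirect_at < 0:
                wolf.next_redirect_at = tick + int(
                    round(rng.uniform(lo_s, hi_s) * config.tick_rate)
                )
            elif tick >= wolf.next_redirect_at:
                wolf.heading = rng.uniform(0.0, 2.0 * math.pi)
                wolf.next_redirect_at = tick + int(
                    round(rng.uniform(lo_s, hi_s) * config.tick_rate)
                )

    if config.variant is Variant.E2_FREEZE:
        # Repulsion from the sheep, with a brief acceleration.
        for wolf in wolves:
            d = math.hypot(wolf.x - sheep.x, wolf.y - sheep.y)
            if d < config.sheep_avoid_radius:
                wolf.heading = math.atan2(wolf.y - sheep.y, wolf.x - sheep.x)
                if wolf.boost_until < tick:
                    wolf.boost_until = tick + int(
                        round(config.boost_duration_s * config.tick_rate)
                    )
        # Wolf-wolf bounce: exchange headings on circle overlap, only when
        # converging (prevents re-swapping every tick while overlapped).
        for i in range(len(wolves)):
            for j in range(i + 1, len(wolves)):
                a, b = wolves[i], wolves[j]
                dx, dy = b.x - a.x, b.y - a.y
                if math.hypot(dx, dy) < _wolf_radius(a) + _wolf_radius(b):
                    rel_vx = math.cos(b.heading) - math.cos(a.heading)
                    rel_vy = math.sin(b.heading) - math.sin(a.heading)
                    if rel_vx * dx + rel_vy * dy < 0:
                        a.heading, b.heading = b.heading, a.heading

    for wolf in wolves:
        speed = wolf.speed
        if config.variant is Variant.E2_FREEZE and tick < wolf.boost_until:
            speed *= config.boost_factor
        _move_with_reflection(wolf, speed * dt, config)


# ---------------------------------------------------------------------------
# Eye-change scheduling (freeze variant)


def schedule_eyes(
    config: TrialConfig,
    first_selection_tick: Optional[int],
    rng: np.random.Generator,
    horizon_ticks: Optional[int] = None,
) -> EyeSchedule:
    """Build the alternating countdown / big-eye schedule.

    Armed by the first selection: countdown durations are drawn U(1.5, 5.0) s
    and big-eye (danger) durations U(1.5, 3.0) s.  Each danger period's
    bearer is a uniformly drawn wolf (hunted role) or the sheep (distracted);
    baseline schedules are flagged inert.  Outside the freeze variant, or
    when no selection was ever made, the schedule is empty.
    """
    sched = EyeSchedule(
        countdown_range_s=config.countdown_range_s,
        danger_range_s=config.danger_range_s,
        grace_s=config.grace_s,
        inert=config.predation_role is PredationRole.BASELINE,
    )
    if config.variant is not Variant.E2_FREEZE or first_selection_tick is None:
        return sched
    if horizon_ticks is None:
        horizon_ticks = config.max_ticks
    tr = config.tick_rate
    t = first_selection_tick
    while t < horizon_ticks:
        t += int(round(rng.uniform(*config.countdown_range_s) * tr))
        if t >= horizon_ticks:
            break
        dur = int(round(rng.uniform(*config.danger_range_s) * tr))
        if config.predation_role is PredationRole.DISTRACTED:
            bearer: object = "sheep"
        else:
            bearer = int(rng.integers(4))
        sched.intervals.append((t, t + dur, bearer))
        t += dur
    return sched


# ---------------------------------------------------------------------------
# Termination rules


def sprites_overlap(
    a_pos: tuple[float, float],
    a_size: tuple[float, float],
    b_pos: tuple[float, float],
    b_size: tuple[float, float],
) -> bool:
    """Axis-aligned bounding-box overlap of two centered sprites."""
    return (
        abs(a_pos[0] - b_pos[0]) < (a_size[0] + b_size[0]) / 2.0
        and abs(a_pos[1] - b_pos[1]) < (a_size[1] + b_size[1]) / 2.0
    )


def check_termination(
    config: TrialConfig,
    *,
    selected_item: Optional[Item] = None,
    points: int = 0,
    n_collected: int = 0,
    sheep_wolf_overlap: bool = False,
    wolf_danger_active: bool = False,
    within_grace: bool = False,
    sheep_eyes_big: bool = False,
):
    """Apply the trial-ending rules; return an Outcome, "ignored", or None.

    Rules, in order of precedence: sheep-wolf contact eats hunted players in
    the avoidance variant; a distractor selection always ends the trial; a
    selection during a wolf big-eye period (grace window excepted) ends a
    hunted freeze trial; a selection while the sheep's eyes are big is
    silently ignored for distracted freeze players; completion is all targets
    collected (avoidance/freeze) or reaching the point goal (reward).
    """
    if (
        config.variant is Variant.E1_AVOID
        and config.predation_role is PredationRole.HUNTED
        and sheep_wolf_overlap
    ):
        return Outcome.EATEN
    if selected_item is not None:
        if (
            config.variant is Variant.E2_FREEZE
            and config.predation_role is PredationRole.DISTRACTED
            and sheep_eyes_big
        ):
            return "ignored"
        if selected_item.role == "distractor":
            return Outcome.DISTRACTOR_ERROR
        if (
            config.variant is Variant.E2_FREEZE
            and config.predation_role is PredationRole.HUNTED
            and wolf_danger_active
            and not within_grace
        ):
            return Outcome.DANGER_ERROR
        points = points + selected_item.value
        n_collected = n_collected + 1
    if config.variant is Variant.E3_REWARD:
        if points >= config.point_goal:
            return Outcome.COMPLETED
    elif n_collected >= config.n_targets:
        return Outcome.COMPLETED
    return None


# ---------------------------------------------------------------------------
# Trial driver


def run_trial(
    config: TrialConfig,
    policy: "AgentPolicy",
    seed,
    monitor=None,
) -> TrialLog:
    """Simulate one complete trial of the task with a synthetic forager.

    The root seed is split into independent child streams for layout, wolf
    motion, the eye schedule, and the agent policy, so that changing the
    policy never perturbs the world's randomness.  Deterministic given
    (config, policy, seed).
    """
    from .agents import AgentPolicy  # local import to avoid a cycle

    assert isinstance(policy, AgentPolicy)
    layout_rng, wolf_rng, sched_rng, pol_rng = split_streams(seed, 4)

    items = layout_trial(config, layout_rng)
    by_id = {it.id: it for it in items}
    wolves = init_wolves(config)
    sheep = SheepState(x=config.canvas[0] / 2.0, y=config.canvas[1] / 2.0)
    is_e2 = config.variant is Variant.E2_FREEZE
    hunted_e1 = (
        config.variant is Variant.E1_AVOID
        and config.predation_role is PredationRole.HUNTED
    )
    schedule: Optional[EyeSchedule] = None
    grace_ticks = int(round(config.grace_s * config.tick_rate))

    events: list[SelectionEvent] = []
    outcome: Optional[Outcome] = None
    points = 0
    n_collected = 0
    prev_category: Optional[str] = None
    target_id: Optional[int] = None
    select_at = -1  # tick at which the pending selection registers
    comply_current: Optional[bool] = None  # compliance draw for active danger
    reach = ITEM_SIZE / 2.0
    flee_heading = 0.0
    flee_until = -1  # tick until which the current escape dash is committed
    flee_d0 = math.inf  # nearest-wolf distance when the dash was chosen
    hold_ticks = 0  # ticks spent waiting for a blocked approach to clear

    def nearest_wolf() -> float:
        return min(math.hypot(w.x - sheep.x, w.y - sheep.y) for w in wolves)

    tick = 0
    for tick in range(config.max_ticks):
        step_wolves(wolves, sheep, config, tick, wolf_rng)

        if hunted_e1:
            hit = any(
                sprites_overlap(sheep.position, sheep.size, w.position, w.size)
                for w in wolves
            )
            if check_termination(config, sheep_wolf_overlap=hit) is Outcome.EATEN:
                outcome = Outcome.EATEN
                break

        # Danger bookkeeping (freeze variant)
        active = schedule.active(tick) if schedule is not None else None
        if active is None:
            comply_current = None
        wolf_danger = active is not None and not schedule.inert and active[2] != "sheep"
        sheep_big = active is not None and not schedule.inert and active[2] == "sheep"
        within_grace = active is not None and tick < active[0] + grace_ticks

        # --- sheep control -------------------------------------------------
        fleeing = False
        if hunted_e1 and policy.avoidance_radius > 0:
            dists = [math.hypot(w.x - sheep.x, w.y - sheep.y) for w in wolves]
            dmin = min(dists)
            if dmin < policy.avoidance_radius:
                # Dodge: head away from the nearest wolf, but consider
                # sideways escapes too and pick the direction that leaves
                # the largest clearance from *all* wolves (so flight does
                # not run into a second predator or pin against a wall).
                fleeing = True
                step = policy.flee_speed * config.dt
                xlo, xhi, ylo, yhi = _bounds(config, sheep.size)
                # re-decide when the dash commitment expires, or early if the
                # current dash is losing ground (a retargeting pursuer can
                # turn a committed dash stale within a few ticks)
                if tick >= flee_until or dmin < flee_d0 - 10.0:
                    # Commit to an escape heading for a short dash rather
                    # than re-deciding every tick: a myopic per-tick dodge
                    # dithers at walls while a pursuer ratchets in.  Score
                    # full-circle directions by the clearance from the
                    # wolves' positions projected half a second ahead,
                    # penalizing directions blocked by a wall.
                    w = wolves[dists.index(dmin)]
                    ang = math.atan2(sheep.y - w.y, sheep.x - w.x)
                    horizon = 0.5 * config.tick_rate
                    # plan over a long dash so that slipping through a gap
                    # between converging wolves outscores lingering inside a
                    # pocket that is about to close
                    dash = 0.6 * config.tick_rate * step
                    proj = [
                        (
                            ww.x
                            + math.cos(ww.heading) * ww.speed * config.dt * horizon,
                            ww.y
                            + math.sin(ww.heading) * ww.speed * config.dt * horizon,
                        )
                        for ww in wolves
                    ]
                    hazards = [(ww.x, ww.y) for ww in wolves] + proj
                    best = None
                    for k in range(12):
                        a = ang + k * math.pi / 6.0
                        tx = min(max(sheep.x + math.cos(a) * dash, xlo), xhi)
                        ty = min(max(sheep.y + math.sin(a) * dash, ylo), yhi)
                        # path clearance keeps the dash from brushing a wolf;
                        # endpoint clearance rewards ending in open space
                        path_clear = min(
                            _point_segment_distance(
                                px, py, sheep.x, sheep.y, tx, ty
                            )
                            for px, py in hazards
                        )
                        end_clear = min(
                            math.hypot(tx - px, ty - py) for px, py in hazards
                        )
                        moved = math.hypot(tx - sheep.x, ty - sheep.y)
                        score = path_clear + 0.5 * end_clear + 0.3 * moved
                        if best is None or score > best[0]:
                            best = (score, a)
                    flee_heading = best[1]
                    flee_until = tick + int(round(0.25 * config.tick_rate))
                    flee_d0 = dmin
                sheep.x = min(max(sheep.x + math.cos(flee_heading) * step, xlo), xhi)
                sheep.y = min(max(sheep.y + math.sin(flee_heading) * step, ylo), yhi)
                # flight preempts selection; re-plan afterwards
                target_id = None
                select_at = -1

        if monitor is not None:
            monitor(tick, sheep, wolves, fleeing)

        if not fleeing:
            if target_id is None:
                hazard = None
                if hunted_e1 and policy.avoidance_radius > 0:
                    hazard = (
                        [(w.x, w.y) for w in wolves],
                        policy.avoidance_radius,
                    )
                target_id = policy.choose_next_target(
                    items, sheep.position, prev_category, config, pol_rng,
                    hazard=hazard,
                )
                select_at = -1
            tgt = by_id[target_id]
            dx, dy = tgt.position[0] - sheep.x, tgt.position[1] - sheep.y
            d = math.hypot(dx, dy)
            step = policy.cursor_speed * config.dt
            if d > reach and select_at < 0:
                blocked = False
                if hunted_e1 and policy.avoidance_radius > 0:
                    # hold rather than walk into a predator: check the next
                    # stretch of the straight path for wolf clearance
                    look = min(d, 150.0)
                    lx, ly = sheep.x + dx / d * look, sheep.y + dy / d * look
                    blocked = any(
                        _point_segment_distance(w.x, w.y, sheep.x, sheep.y, lx, ly)
                        < 120.0
                        for w in wolves
                    )
                if blocked:
                    hold_ticks += 1
                    if hold_ticks % 30 == 0:
                        target_id = None  # re-plan toward a safer item
                elif step >= d:
                    sheep.x, sheep.y = tgt.position
                else:
                    sheep.x += dx / d * step
                    sheep.y += dy / d * step
            if select_at < 0 and math.hypot(
                tgt.position[0] - sheep.x, tgt.position[1] - sheep.y
            ) <= reach:
                select_at = tick + policy.draw_pause_ticks(config, pol_rng)

            if select_at >= 0 and tick >= select_at:
                # Freeze compliance: withhold the selection during a relevant
                # danger period (per-period draw).
                relevant_danger = (
                    wolf_danger
                    if config.predation_role is PredationRole.HUNTED
                    else sheep_big
                )
                if is_e2 and relevant_danger:
                    if comply_current is None:
                        comply_current = (
                            pol_rng.random() < policy.freeze_compliance
                        )
                    if comply_current:
                        select_at = tick + 1  # wait out the danger period
                        relevant_danger = None  # sentinel: skip selection
                if not (is_e2 and relevant_danger is None):
                    item = by_id[target_id]
                    res = check_termination(
                        config,
                        selected_item=item,
                        points=points,
                        n_collected=n_collected,
                        wolf_danger_active=wolf_danger,
                        within_grace=within_grace,
                        sheep_eyes_big=sheep_big,
                    )
                    if res == "ignored":
                        # selection swallowed; retry once eyes are normal
                        select_at = tick + 1
                    else:
                        during = wolf_danger or sheep_big
                        n_rel = (
                            schedule.n_ended_before(tick)
                            if schedule is not None and not schedule.inert
                            else 0
                        )
                        ev = SelectionEvent(
                            tick=tick,
                            time_ms=tick / config.tick_rate * 1000.0,
                            item_id=item.id,
                            category=item.category,
                            x=item.position[0],
                            y=item.position[1],
                            serial_index=n_collected + 1,
                            nearest_wolf_distance=nearest_wolf(),
                            during_danger=during,
                            patch_index=n_rel,
                        )
                        events.append(ev)
                        if res in (Outcome.DISTRACTOR_ERROR, Outcome.DANGER_ERROR):
                            outcome = res
                            break
                        item.collected_at = tick
                        points += item.value
                        n_collected += 1
                        prev_category = item.category
                        target_id = None
                        select_at = -1
                        if is_e2 and schedule is None:
                            schedule = schedule_eyes(
                                config, tick, sched_rng, config.max_ticks
                            )
                        if res is Outcome.COMPLETED:
                            outcome = Outcome.COMPLETED
                            break
    if outcome is None:
        outcome = Outcome.TIMEOUT
    return TrialLog(
        config=config,
        events=events,
        outcome=outcome,
        duration_ms=(tick + 1) / config.tick_rate * 1000.0,
        eye_schedule=schedule,
        points_earned=points,
        policy_label=policy.label,
    )


def run_block(
    config: TrialConfig,
    policy: "AgentPolicy",
    n_correct: int,
    seed,
    max_attempts: Optional[int] = None,
) -> list[TrialLog]:
    """Repeat trials until ``n_correct`` completed logs exist.

    Failed trials are retained in the returned list (they feed the
    eaten-count analyses).  Aborts with RuntimeError after ``max_attempts``
    (default ``20 * n_correct``) if the policy cannot reach the quota.
    """
    if n_correct < 1:
        raise ValueError("n_correct must be >= 1")
    if max_attempts is None:
        max_attempts = 20 * n_correct
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif isinstance(seed, np.random.Generator):
        ss = seed.bit_generator.seed_seq
    else:
        ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max_attempts)
    logs: list[TrialLog] = []
    n_done = 0
    for attempt in range(max_attempts):
        log = run_trial(config, policy, child_seeds[attempt])
        log.trial_index = attempt
        logs.append(log)
        if log.completed:
            n_done += 1
            if n_done >= n_correct:
                return logs
    raise RuntimeError(
        f"policy failed to reach {n_correct} completed trials "
        f"in {max_attempts} attempts ({n_done} completed)"
    )
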