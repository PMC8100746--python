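# Methods

## The simulated task

One trial places 80 items (40 targets in categories A/B, 40 distractors in
categories C/D) on a uniformly random bijection onto the cell centers of a
10 x 8 grid inset half a cell from the edges of an 800 x 600 px canvas.
Time advances in ticks of 1/60 s.  A sheep-shaped cursor (64 x 80 px
sprite) starts at the canvas center; four wolf sprites (70 x 94 px) start
at the grid's corner cells, initially heading for the canvas center.

Three variants:

* **Avoidance** (`E1_avoid`): wolves move at one of 30/42/54/66/78 px/s.
  Pack wolves travel in straight lines, resampling their heading uniformly
  on [0, 2π) at intervals drawn U(1.7, 3.3) s; a lone wolf re-aims at the
  sheep every 3 ticks (20 Hz).  For hunted players, axis-aligned
  bounding-box contact between the sheep and any wolf ends the trial
  ("eaten").  Selecting a distractor always ends the trial.  Completion =
  all 40 targets collected.
* **Freeze** (`E2_freeze`): wolves move at 78 px/s, bounce off each other
  (heading exchange on circle overlap while converging), and actively
  avoid the sheep (within 100 px they turn directly away with a 1.5x speed
  boost for 0.5 s; both configurable — the magnitude and duration of the
  "brief acceleration" are free parameters of this implementation).  After
  the first selection an alternating schedule of countdown periods
  U(1.5, 5.0) s and big-eye danger periods U(1.5, 3.0) s begins.  For
  hunted players one uniformly drawn wolf per period bears the big eyes
  and any selection during the period — beyond a 500 ms grace window after
  onset — ends the trial; for distracted players the sheep's own eyes
  change and selections are silently ignored while they are big; for the
  baseline group the schedule is generated but inert.
* **Reward** (`E3_reward`): targets are 10 high-value (2 pt, category A)
  and 30 low-value (1 pt, category B) items; the trial completes when the
  score reaches 30 points (so completed trials end on 30 or 31 points).
  Wolves: lone pursuer at 78 px/s.

Edge behaviour: wolf anchor points (sprite centers) reflect specularly at
the canvas rectangle, with the position folded across the boundary so the
per-tick path length is exactly speed/tick_rate even on reflection ticks
(the Euclidean chord on a folded tick is shorter by construction).  A
literal `edge_mode="reverse"` (full 180° heading reversal at contact) is
available; specular reflection is the default because strict reversal
traps wolves on wall-normal trajectories.  Sprites may overhang the canvas
edge; this matches the corner starting positions.

Coordinates: origin top-left, x right, y down, CSS-pixel units.

## Synthetic foragers

Agents are parameter bundles (`AgentPolicy`), not cognitive models.  Item
selection has two regimes:

* `switch_prob=None` — the *unbiased* forager draws the next target from
  all remaining targets with weight
  (1/distance)^proximity_weight × value^value_bias.  With neutral weights
  the category sequence is exchangeable, so E[runs] equals the
  Wald–Wolfowitz null 2n₁n₂/N + 1 exactly.  (A fixed switch probability of
  0.5 does *not* reproduce the exchangeable null: forced stays after
  category exhaustion — a Banach-matchbox tail of ≈7 selections on 20+20
  trials — depress the mean run count to ≈18.9.)
* `switch_prob=s` — a category-first process: switch away from the
  previous category with probability s (forced once a category is
  exhausted), then draw an item within the chosen category.  This gives
  direct experimental control of run structure; the conditional estimator
  described below inverts it.

Motion is straight-line pursuit at `cursor_speed` (default 300 px/s) with
a lognormal dwell before each selection registers (median 350 ms, log-sd
0.25; defaults chosen so that simulated inter-target times land above the
600 ms floor reported for cursor foraging).  Hunted agents with
`avoidance_radius > 0` (i) deprioritize targets within the radius of a
wolf (weight x0.01), (ii) hold position rather than walk a path that
passes within 120 px of a wolf, re-planning after half a second, and
(iii) when the nearest wolf is inside the radius, flee at `flee_speed`
(default 420 px/s) along an escape heading chosen from 12 candidate
directions by scoring a committed 0.25 s dash: path clearance to all
wolves (current and half-second-projected positions), endpoint clearance,
and displacement.  Flight preempts selection; the dash is re-decided when
it expires or starts losing ground.  In the freeze variant,
`freeze_compliance` is the per-danger-period probability of withholding
selections until the period ends.

Presets encode the phenotypes the classifier must separate:
`random_switcher` (uniform), `switch_focused` (uniform + proximity),
`run_focused` (s = 0.05 + proximity), `reward_focused` (value_bias 3),
`wolf_focused` (avoidance 150 px, compliance 0.98), `baseline_ignorer`,
and `food_focused` (compliance 0.94, small radius).  The two compliance
values were set from the reported eaten-event phenotypes of the freeze
task (≈21% vs ≈43% of trials failed), assuming ≈10 danger periods per
trial.  `value_bias` may be negative for value-averse probe agents (used
to force the 30-selection low-first economy bound).

Large calibration studies use a selection-level sampler
(`sample_category_sequences`) that runs the same choice policy on a static
layout with a teleporting cursor; the fully uniform case dispatches to a
vectorized permutation sampler, which is distributionally identical.

## Dependent variables

Per trial (distractor-error selections excluded from sequence statistics
and counted separately; undefined values are NaN sentinels):

* **runs** — 1 + number of adjacent category changes.
* **ITT / ITD** — first differences of selection times (ms) and positions
  (px); the interval from trial start to the first selection is excluded.
* **best-r** — max(|r₁|, |r₂|), Pearson correlations of item x and y with
  1-based selection order; signed r₁, r₂ are preserved.  Requires ≥3
  events and at least one non-degenerate coordinate.
* **wolf distance** — mean center-to-center distance from the sheep to the
  nearest wolf, sampled at selection events (the sampling moment is a
  convention of this implementation).
* **selection order** — mean 1-based serial position per category; serial
  indices are not consumed by distractor errors.
* **temporal patches** — selections partitioned by the ends of the danger
  periods relevant to the player's role; inert schedules give one patch;
  empty patches are dropped.

## Runs test and classification

The runs test uses the exact enumeration of the null distribution of R for
N ≤ 20 (two-sided p = probability of a run count at least as far from μ_R
as observed) and the normal approximation with a 0.5 continuity correction
otherwise (the correction clamps at the mode: |R − μ_R| ≤ 0.5 gives p = 1).
The continuity correction is on by default; it leaves the type-I rate of
the 20/20 case unchanged (0.036 by enumeration) and makes the approximate
tail probabilities track the exact ones to ≤ 0.04 for all splits with both
counts ≥ 5 and N ≤ 20.  Two-sided p-values of discrete and continuous
methods necessarily disagree near the distribution mode (by roughly the
modal probability, ~0.2); agreement claims are therefore stated — and
tested — on tail probabilities, which is where classification decisions
are made.

Classification conventions:

* *Strategy*: per-trial tests on a participant's conjunction trials at the
  Bonferroni-corrected level α/n_trials (α = 0.05 default); a trial is
  "random" iff not rejected; switch_focused iff > 50% random.  The rule is
  applied literally, so consistent over-alternation (R ≫ μ_R) is also
  "non-random" and lands in run_focused; raw test results are exposed.
* *Reward focus*: reward_focused iff the participant's mean high-value
  selection-order score is strictly below the low-value mean.
* *Survival focus*: median split on eaten counts; strictly above the
  median is food_focused, ties go to the lower (wolf_focused) group.

Switch-probability recovery: E[R] = 1 + s·(number of transitions where
both categories remain), so s is estimated as the fraction of switches
among such *eligible* transitions.  The unconditional closed-form
inversion s = (E[R] − 1)/(N − 1) is also provided; it is biased low by up
to ≈0.04 at mid-range s because forced stays generate no switches.

## A note on the reward-variant stopping rule

For value-blind agents the *selection process* is exchangeable, so
high- and low-value selection-order scores are equal in expectation on
unstopped sequences (verified to within Monte-Carlo error at n = 10,000).
The 30-point stopping rule breaks this symmetry: conditioning on reaching
the goal and on both categories being sampled biases the high-value score
upward by ≈ +0.42 serial positions at the default economy.  Reported
selection-order gaps near zero on *completed* reward trials therefore
indicate a mild high-value preference, not none.  The package computes
both quantities (`scripts/acceptance.py` reports the unstopped gap and the
stopped-trial bias separately).

## Randomness and reproducibility

Each trial splits its root seed into independent child streams for layout,
wolf motion, the eye schedule, and the agent policy, so policy changes
never perturb the world's randomness.  (config, policy, seed) determines
the trial log byte-for-byte; the CLI writes identical files for identical
seeds, and small golden fixtures are committed under `tests/data/`.

## Problem sizes

Calibration checks run at 10,000 sequences (null run level, type-I rate,
exchangeability), 200 simulated participants x 15 trials per strategy
preset, 100 trials per agent for parameter recovery, and 10,000 scheduled
danger periods; kinematic property checks use hundreds to thousands of
ticks and tens of full trials.  These sizes put Monte-Carlo standard
errors well below the decision thresholds they feed.

## Known limitations

* Perception is not modeled: conjunction difficulty enters only as a
  configurable reduction in switching plus a longer selection pause;
  distractor confusability only as a per-selection error probability.
* No learning or adaptation across trials, and no fitting of policies to
  human data.
* The reactive flee heuristic underperforms human players against a fast
  *continuous pursuer* in long exhaustive trials: with the lone wolf at
  78 px/s, avoidant agents complete only ~10% of avoidance-variant trials
  (~40% at 30 px/s), dying in multi-wolf pockets near walls.  Pack-wolf
  trials (~95% completion) and the short reward-variant trials (lone wolf,
  ~100%) are unaffected.  Lone-wolf avoidance cohorts should budget
  generous retry limits in `run_block`.
* Wolf Distance is sampled at selection events; a continuous per-tick
  variant would differ for strongly avoidant agents.
* Passing the simulated calibrations demonstrates the correctness of the
  measures and classifiers under the generator's assumptions (exchangeable
  or category-first selection, lognormal pauses, reactive avoidance); it
  does not certify claims about human foraging data.
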