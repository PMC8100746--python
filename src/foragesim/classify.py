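"""Randomness testing and participant-level strategy classification.

The trial-level tool is the Wald-Wolfowitz one-sample runs test of sequence
exchangeability.  For a two-category sequence with counts n1 and n2
(N = n1 + n2) the number of runs R has null mean and variance

    mu_R    = 2 n1 n2 / N + 1
    sigma_R^2 = 2 n1 n2 (2 n1 n2 - N) / (N^2 (N - 1))

The normal approximation standardizes R with a 0.5 continuity correction by
default; for short sequences (N <= 20) the exact null distribution of R is
enumerated in closed form and the two-sided p is the probability of a run
count at least as far from mu_R as observed.  (Two-sided p-values of the
exact and approximate methods necessarily disagree near the mode of the
discrete distribution; the approximations track each other in the tails,
which is where classification decisions are made.)

Participant-level labels:

* strategy: a participant is *switch focused* when more than 50% of their
  conjunction trials are random (runs test not rejected at a Bonferroni-
  corrected level), else *run focused*.
* reward focus: *reward focused* when high-value targets have a strictly
  lower mean selection-order score than low-value targets, else
  *wolf focused*.
* survival focus: a median split on how often a participant was eaten;
  above the median is *food focused*, at or below is *wolf focused*.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RunsTestResult",
    "ParticipantClassification",
    "runs_pmf",
    "runs_test",
    "runs_test_counts",
    "classify_strategy",
    "classify_reward_focus",
    "median_split_survival",
    "estimate_switch_prob",
    "invert_expected_runs",
    "expected_runs",
    "classify_participants",
    "strategy_frequency_table",
]

EXACT_N_MAX = 20


@dataclass
class RunsTestResult:
    n1: int
    n2: int
    R: int
    mu_R: float
    sigma_R: float
    z: float
    p: float
    method: str  # "normal_approx" | "exact" | "degenerate"

    @property
    def random(self) -> bool:
        """Convenience: not rejected at 0.05 (accept-the-null convention)."""
        return not (self.p < 0.05)


@dataclass
class ParticipantClassification:
    participant_id: Optional[str]
    strategy: Optional[str]  # "switch_focused" | "run_focused"
    fraction_random_trials: float
    n_trials: int
    reward_focus: Optional[str] = None  # "reward_focused" | "wolf_focused"
    survival_focus: Optional[str] = None  # "food_focused" | "wolf_focused"
    eaten_count: Optional[int] = None


def run_moments(n1: int, n2: int) -> tuple[float, float]:
    N = n1 + n2
    mu = 2.0 * n1 * n2 / N + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - N) / (N * N * (N - 1.0)) if N > 1 else 0.0
    return mu, math.sqrt(max(var, 0.0))


def expected_runs(n1: int, n2: int) -> float:
    """Wald-Wolfowitz null expectation 2 n1 n2 / N + 1."""
    return run_moments(n1, n2)[0]


def runs_pmf(n1: int, n2: int) -> dict[int, float]:
    """Exact null pmf of the number of runs for counts (n1, n2)."""
    N = n1 + n2
    tot = comb(N, n1)
    pmf: dict[int, float] = {}
    for R in range(2, N + 1):
        if R % 2 == 0:
            k = R // 2
            p = 2 * comb(n1 - 1, k - 1) * comb(n2 - 1, k - 1) / tot
        else:
            k = (R - 1) // 2
            p = (
                comb(n1 - 1, k - 1) * comb(n2 - 1, k)
                + comb(n1 - 1, k) * comb(n2 - 1, k - 1)
            ) / tot
        if p > 0:
            pmf[R] = p
    return pmf


def runs_test_counts(
    n1: int,
    n2: int,
    R: int,
    method: str = "auto",
    continuity: bool = True,
) -> RunsTestResult:
    """Runs test from the sufficient statistics (n1, n2, R).

    ``method``: "auto" picks the exact enumeration for N <= 20, the normal
    approximation otherwise.  With one category absent the test is
    degenerate (z = 0, p = NaN sentinel).
    """
    N = n1 + n2
    if min(n1, n2) == 0 or N < 2:
        mu, sd = run_moments(max(n1, 1), max(n2, 1)) if N else (float("nan"), 0.0)
        return RunsTestResult(n1, n2, R, float(R), 0.0, 0.0, float("nan"), "degenerate")
    mu, sd = run_moments(n1, n2)
    if method == "auto":
        method = "exact" if N <= EXACT_N_MAX else "normal_approx"
    if method == "exact":
        pmf = runs_pmf(n1, n2)
        d = abs(R - mu)
        p = min(1.0, sum(pr for r, pr in pmf.items() if abs(r - mu) >= d - 1e-12))
        z = (R - mu) / sd if sd > 0 else 0.0
        return RunsTestResult(n1, n2, R, mu, sd, z, p, "exact")
    if sd == 0:
        return RunsTestResult(n1, n2, R, mu, sd, 0.0, 1.0, "normal_approx")
    d = abs(R - mu)
    if continuity:
        d = max(0.0, d - 0.5)
    z = math.copysign(d / sd, R - mu)
    p = 2.0 * float(norm.sf(d / sd))
    return RunsTestResult(n1, n2, R, mu, sd, z, min(p, 1.0), "normal_approx")


def runs_test(
    categories: Sequence[str],
    method: str = "auto",
    continuity: bool = True,
) -> RunsTestResult:
    """Wald-Wolfowitz one-sample runs test of a two-category sequence."""
    cats = sorted(set(categories))
    if len(cats) > 2:
        raise ValueError(f"runs test requires <= 2 categories, got {cats}")
    n1 = sum(1 for c in categories if c == cats[0]) if cats else 0
    n2 = len(categories) - n1
    R = 1 + sum(1 for a, b in zip(categories[:-1], categories[1:]) if a != b)
    if len(categories) == 0:
        R = 0
    return runs_test_counts(n1, n2, R, method=method, continuity=continuity)


# ---------------------------------------------------------------------------
# Participant-level classification


def classify_strategy(
    trial_sequences: Sequence[Sequence[str]],
    alpha: float = 0.05,
    participant_id: Optional[str] = None,
) -> ParticipantClassification:
    """Label a participant switch- or run-focused from conjunction trials.

    Each trial is tested at the Bonferroni-corrected level alpha/n_trials; a
    trial counts as *random* when the test is not rejected.  The participant
    is switch_focused iff more than 50% of trials are random.
    """
    n = len(trial_sequences)
    if n == 0:
        raise ValueError("classify_strategy requires at least one trial")
    level = alpha / n
    random_flags = []
    for seq in trial_sequences:
        res = runs_test(seq)
        rejected = (not math.isnan(res.p)) and res.p < level
        random_flags.append(not rejected)
    frac = sum(random_flags) / n
    return ParticipantClassification(
        participant_id=participant_id,
        strategy="switch_focused" if frac > 0.5 else "run_focused",
        fraction_random_trials=frac,
        n_trials=n,
    )


def classify_reward_focus(
    high_orders: Sequence[float],
    low_orders: Sequence[float],
) -> Optional[str]:
    """reward_focused iff mean high-value order < mean low-value order.

    Per-trial selection-order scores are averaged per participant first;
    NaN trials (category never selected) are dropped.  Returns None when a
    category is entirely absent.
    """
    hi = [v for v in high_orders if not math.isnan(v)]
    lo = [v for v in low_orders if not math.isnan(v)]
    if not hi or not lo:
        return None
    return "reward_focused" if float(np.mean(hi)) < float(np.mean(lo)) else "wolf_focused"


def median_split_survival(eaten_counts: dict) -> dict:
    """Median split on eaten counts: above -> food_focused, else wolf_focused.

    Ties at the median fall in the lower (wolf_focused) group; fewer than two
    participants yields an empty mapping (sentinel).
    """
    if len(eaten_counts) < 2:
        return {}
    med = float(np.median(list(eaten_counts.values())))
    return {
        pid: ("food_focused" if c > med else "wolf_focused")
        for pid, c in eaten_counts.items()
    }


# ---------------------------------------------------------------------------
# Switch-probability recovery


def invert_expected_runs(mean_runs: float, n_selections: int) -> float:
    """Closed-form inversion s = (E[R] - 1) / (N - 1).

    Slightly biased low for mid-range switch probabilities because forced
    stays after category exhaustion generate no switches; see
    ``estimate_switch_prob`` for the unbiased conditional estimator.
    """
    return (mean_runs - 1.0) / (n_selections - 1.0)


def estimate_switch_prob(trial_sequences: Sequence[Sequence[str]]) -> float:
    """Recover the category-switch probability from observed sequences.

    The run expectation conditional on "eligible" transitions (those where
    both categories were still available) is 1 + s * n_eligible, so s is the
    fraction of switches among eligible transitions.  This conditioning
    removes the forced-stay bias of the naive closed-form inversion.
    """
    switches = 0
    eligible = 0
    for seq in trial_sequences:
        remaining: dict[str, int] = {}
        for c in seq:
            remaining[c] = remaining.get(c, 0) + 1
        for a, b in zip(seq[:-1], seq[1:]):
            remaining[a] -= 1
            if all(v > 0 for v in remaining.values()):
                eligible += 1
                if a != b:
                    switches += 1
    if eligible == 0:
        return float("nan")
    return switches / eligible


# ---------------------------------------------------------------------------
# Batch interface over the tidy metrics table


def classify_participants(
    metrics: pd.DataFrame,
    alpha: float = 0.05,
    strategy_condition: str = "conjunction",
) -> pd.DataFrame:
    """Per-participant classification from a tidy per-trial metrics table.

    Strategy labels use completed trials of ``strategy_condition`` via the
    sufficient statistics (n_cat_a, n_cat_b, n_runs); reward focus uses
    completed reward-variant trials; eaten counts come from failed trials
    with outcome "eaten" or "danger_error".
    """
    rows = []
    for pid, g in metrics.groupby("participant_id", dropna=False):
        done = g[g["outcome"] == "completed"]
        strat = g_frac = None
        conj = done[done["target_condition"] == strategy_condition]
        frac = float("nan")
        if len(conj):
            n = len(conj)
            level = alpha / n
            rand = []
            for _, row in conj.iterrows():
                res = runs_test_counts(
                    int(row["n_cat_a"]), int(row["n_cat_b"]), int(row["n_runs"])
                )
                rand.append(not ((not math.isnan(res.p)) and res.p < level))
            frac = sum(rand) / n
            strat = "switch_focused" if frac > 0.5 else "run_focused"
        reward = done[done["experiment"] == "E3_reward"]
        rf = None
        if len(reward):
            rf = classify_reward_focus(
                reward["selection_order_high"].tolist(),
                reward["selection_order_low"].tolist(),
            )
        eaten = int(
            g["outcome"].isin(["eaten", "danger_error"]).sum()
        )
        rows.append(
            {
                "participant_id": pid,
                "strategy": strat,
                "fraction_random_trials": frac,
                "n_strategy_trials": len(conj),
                "reward_focus": rf,
                "eaten_count": eaten,
            }
        )
    out = pd.DataFrame(rows)
    if len(out) >= 2 and out["eaten_count"].notna().any():
        labels = median_split_survival(
            dict(zip(out["participant_id"], out["eaten_count"]))
        )
        out["survival_focus"] = out["participant_id"].map(labels)
    else:
        out["survival_focus"] = None
    return out


def strategy_frequency_table(classified: pd.DataFrame, by: Sequence[str] = ()) -> pd.DataFrame:
    """Frequency table of strategy labels, optionally stratified."""
    cols = list(by) + ["strategy"]
    return (
        classified.groupby(cols, dropna=False)
        .size()
        .rename("count")
        .reset_index()
    )
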