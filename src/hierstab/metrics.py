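"""Daily ordinal ranks, the hierarchy-stability index S, and cross-method
rank-correlation summaries.

The stability index S condenses a daily rank table into one number in
[0, 1]: 1 means no individual's ordinal rank ever changed between
consecutive days; 0 means the complete rank order reversed every other day.
Between the two anchors, S discounts instability by how much of the
maximum attainable daily rank churn was realized, with changes near the
top of the hierarchy weighted more than changes near the bottom
(weight (N - r + 1) / N for rank r of N). Days whose only change is
renumbering after a demographic exit — relative order among the survivors
preserved — contribute nothing: passive departures are not rank reversals.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .elo_core import EloTrajectory, standardize_scores
from .io_formats import LifeHistoryRecord


@dataclass
class DailyRankTable:
    """Per-day rank orders: ``order[date]`` lists individuals from rank 1 down.

    Ranks on each date are a permutation of 1..N_present; ties in score are
    broken by entry-date seniority (earlier entrant ranks higher), then
    identifier, so the order is deterministic.
    """

    group_id: str
    order: dict[dt.date, list[str]]
    scores: dict[dt.date, dict[str, float]]
    method_label: str = "traditional"

    @property
    def dates(self) -> list[dt.date]:
        return sorted(self.order)

    def rank_of(self, individual_id: str, date: dt.date) -> int:
        return self.order[date].index(individual_id) + 1

    def present(self, date: dt.date) -> set[str]:
        return set(self.order[date])


@dataclass(frozen=True)
class StabilityResult:
    group_id: str
    S: float
    n_days: int
    n_rank_change_days: int
    method_label: str
    weighted: bool = True


def daily_ranks(
    trajectories: dict[str, EloTrajectory],
    life_history: list[LifeHistoryRecord],
    method_label: str = "traditional",
) -> DailyRankTable:
    """Rank every individual on every day of her presence window.

    Descending end-of-day score; ties broken by seniority (entry date,
    then identifier).
    """
    if not trajectories:
        raise ValueError("no trajectories given")
    records = {r.individual_id: r for r in life_history}
    group_id = next(iter(trajectories.values())).group_id
    start = min(t.start for t in trajectories.values())
    end = max(t.end for t in trajectories.values())

    order: dict[dt.date, list[str]] = {}
    scores: dict[dt.date, dict[str, float]] = {}
    date = start
    while date <= end:
        present = {
            ind: t.score_on(date)
            for ind, t in trajectories.items()
            if t.covers(date)
        }
        if present:
            ranked = sorted(
                present,
                key=lambda i: (
                    -present[i],
                    records[i].entry_date if i in records else dt.date.min,
                    i,
                ),
            )
            order[date] = ranked
            scores[date] = present
        date += dt.timedelta(days=1)
    return DailyRankTable(
        group_id=group_id, order=order, scores=scores, method_label=method_label
    )


def _restricted_positions(full_order: list[str], subset: set[str]) -> dict[str, int]:
    """1-based ranks within ``subset`` induced by the full order."""
    sub = [ind for ind in full_order if ind in subset]
    return {ind: i + 1 for i, ind in enumerate(sub)}


def compute_stability_index(
    rank_table: DailyRankTable, weighted: bool = True
) -> StabilityResult:
    """The stability index S over consecutive-day rank changes.

    For each consecutive day pair, ranks are recomputed among the
    individuals present on both days (so demographic renumbering after an
    exit or entry contributes nothing), the absolute rank changes are
    summed — weighted by (N - r + 1)/N at the earlier day's rank when
    ``weighted`` — and divided by the day's maximum attainable total (a
    complete reversal of the order). S is one minus the ratio of the summed
    observed churn to the summed maximum churn. An unweighted variant
    (all weights 1) is available for sensitivity checks.
    """
    dates = rank_table.dates
    if len(dates) < 2:
        raise ValueError("stability is undefined on fewer than 2 days")

    observed_total = 0.0
    max_total = 0.0
    n_change_days = 0
    comparable = False
    for d1, d2 in zip(dates, dates[1:]):
        if (d2 - d1).days != 1:
            continue
        common = rank_table.present(d1) & rank_table.present(d2)
        n = len(common)
        if n < 2:
            continue
        comparable = True
        pos1 = _restricted_positions(rank_table.order[d1], common)
        pos2 = _restricted_positions(rank_table.order[d2], common)

        def w(r: int) -> float:
            return (n - r + 1) / n if weighted else 1.0

        day_obs = sum(w(pos1[i]) * abs(pos2[i] - pos1[i]) for i in common)
        day_max = sum(w(r) * abs(n + 1 - 2 * r) for r in range(1, n + 1))
        observed_total += day_obs
        max_total += day_max
        if day_obs > 0:
            n_change_days += 1

    if not comparable or max_total == 0:
        raise ValueError("no comparable consecutive-day pairs with >= 2 individuals")
    s = 1.0 - observed_total / max_total
    return StabilityResult(
        group_id=rank_table.group_id,
        S=float(s),
        n_days=len(dates),
        n_rank_change_days=n_change_days,
        method_label=rank_table.method_label,
        weighted=weighted,
    )


def compare_methods(
    traj_a: dict[str, EloTrajectory],
    traj_b: dict[str, EloTrajectory],
    every_days: int = 1,
) -> tuple[float, float, int]:
    """Spearman rank correlation between two rating variants.

    Matches standardized scores at every (individual, day) point covered by
    both trajectory sets (optionally thinned to every ``every_days``-th
    day) and returns ``(rho, p_value, n_points)``.
    """
    if not traj_a or not traj_b:
        raise ValueError("empty trajectory set")
    start = max(min(t.start for t in traj_a.values()), min(t.start for t in traj_b.values()))
    end = min(max(t.end for t in traj_a.values()), max(t.end for t in traj_b.values()))
    xs: list[float] = []
    ys: list[float] = []
    date = start
    while date <= end:
        std_a = standardize_scores(traj_a, date)
        std_b = standardize_scores(traj_b, date)
        for ind in std_a.keys() & std_b.keys():
            xs.append(std_a[ind])
            ys.append(std_b[ind])
        date += dt.timedelta(days=every_days)
    if not xs:
        raise ValueError("no overlapping (individual, day) points")
    rho, p = spearmanr(xs, ys)
    return float(rho), float(p), len(xs)


def rank_order_at(
    rank_table: DailyRankTable,
    date: dt.date,
    subset: set[str] | None = None,
) -> list[str]:
    """Individuals in descending rank on ``date``; optionally restricted to a
    subset (e.g. the members of a later fission group), preserving order."""
    if date not in rank_table.order:
        raise KeyError(f"{date} not covered by the rank table")
    full = rank_table.order[date]
    if subset is None:
        return list(full)
    return [ind for ind in full if ind in subset]
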