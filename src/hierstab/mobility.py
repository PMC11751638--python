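"""Dyadic co-residence accounting, active rank reversals, and attribution of
rank changes to active (interaction-driven) versus passive (removal-driven)
mobility.

Active mobility is a rank change produced by agonistic interaction
outcomes; passive mobility is a rank change produced by the removal (death
or emigration) of a higher-ranking individual, with the relative order
among the survivors preserved. The unit at which rank reversals are counted
is the dyad: an unordered pair of co-resident females.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from itertools import combinations

from .io_formats import GroupDataset, LifeHistoryRecord
from .metrics import DailyRankTable, _restricted_positions

DAYS_PER_YEAR = 365.25


@dataclass
class DyadSummary:
    """A female-female pair's co-residence and dominance history."""

    individual_a: str
    individual_b: str
    group_id: str
    co_residence_start: dt.date
    co_residence_end: dt.date
    co_residence_years: float
    dominant_timeline: list[tuple[dt.date, dt.date, str]] = field(default_factory=list)
    n_active_reversals: int = 0
    n_unconfirmed_flips: int = 0
    decided: bool = False


@dataclass(frozen=True)
class MobilityEvent:
    """A dated ordinal-rank change for one individual, with its cause."""

    date: dt.date
    individual_id: str
    rank_before: int
    rank_after: int
    cause: str  # "active" | "passive"
    trigger: str


class ConsistencyError(RuntimeError):
    """A rank change with neither an interaction nor an exit to explain it."""


def enumerate_dyads(
    life_history: list[LifeHistoryRecord],
    group_id: str,
    study_end: dt.date,
) -> list[DyadSummary]:
    """One skeleton per unordered female pair with overlapping presence.

    Co-residence is the overlap of the two inclusive presence windows,
    reported in 365.25-day years; non-overlapping pairs are excluded.
    """
    recs = [r for r in life_history if r.group_id == group_id]
    out: list[DyadSummary] = []
    for ra, rb in combinations(sorted(recs, key=lambda r: r.individual_id), 2):
        start = max(ra.entry_date, rb.entry_date)
        end = min(ra.effective_exit(study_end), rb.effective_exit(study_end))
        if end < start:
            continue
        out.append(
            DyadSummary(
                individual_a=ra.individual_id,
                individual_b=rb.individual_id,
                group_id=group_id,
                co_residence_start=start,
                co_residence_end=end,
                co_residence_years=(end - start).days / DAYS_PER_YEAR,
            )
        )
    return out


def classify_mobility(
    rank_table: DailyRankTable, dataset: GroupDataset
) -> list[MobilityEvent]:
    """Attribute every between-day ordinal rank change to its cause.

    For each consecutive day pair the relative order among individuals
    present on both days is compared. A change in that relative order is
    active and must coincide with at least one interaction on the later day
    (under sequential rating nothing else can reorder co-present
    individuals; a violation raises :class:`ConsistencyError`). An absolute
    rank change that leaves the relative order intact is renumbering:
    passive when explained by the exit of a higher-ranked individual
    (trigger names the removed female), and silent when explained by an
    entrant slotting in above (entries are reported separately, in the
    entry-rank report). Mixed days resolve per individual to the minimal
    explanation: passive if her relative order among survivors is
    unchanged, active otherwise.
    """
    dates = rank_table.dates
    by_day: dict[dt.date, list] = {}
    for rec in dataset.interactions:
        by_day.setdefault(rec.date, []).append(rec)

    events: list[MobilityEvent] = []
    for d1, d2 in zip(dates, dates[1:]):
        if (d2 - d1).days != 1:
            continue
        o1, o2 = rank_table.order[d1], rank_table.order[d2]
        p1, p2 = set(o1), set(o2)
        common = p1 & p2
        if not common:
            continue
        pos1 = _restricted_positions(o1, common)
        pos2 = _restricted_positions(o2, common)
        day_inters = by_day.get(d2, [])
        exited = p1 - p2  # left at the end of d1
        rank1 = {ind: i + 1 for i, ind in enumerate(o1)}
        rank2 = {ind: i + 1 for i, ind in enumerate(o2)}

        for ind in sorted(common, key=lambda i: rank1[i]):
            if rank1[ind] == rank2[ind] and pos1[ind] == pos2[ind]:
                continue
            if pos1[ind] != pos2[ind]:  # relative order changed: active
                if not day_inters:
                    raise ConsistencyError(
                        f"{ind}: relative rank changed {d1} -> {d2} with no "
                        "interaction on that day"
                    )
                own = [
                    r
                    for r in day_inters
                    if ind in (r.winner_id, r.loser_id)
                ]
                trig = own[0] if own else day_inters[0]
                events.append(
                    MobilityEvent(
                        date=d2,
                        individual_id=ind,
                        rank_before=rank1[ind],
                        rank_after=rank2[ind],
                        cause="active",
                        trigger=f"interaction:{trig.winner_id}>{trig.loser_id}",
                    )
                )
            else:  # renumbering only
                if rank2[ind] < rank1[ind]:
                    above_exits = [e for e in exited if rank1[e] < rank1[ind]]
                    if not above_exits:
                        raise ConsistencyError(
                            f"{ind}: rank improved {d1} -> {d2} without an "
                            "exit above"
                        )
                    trigger = min(above_exits, key=lambda e: rank1[e])
                    events.append(
                        MobilityEvent(
                            date=d2,
                            individual_id=ind,
                            rank_before=rank1[ind],
                            rank_after=rank2[ind],
                            cause="passive",
                            trigger=f"removal:{trigger}",
                        )
                    )
                else:
                    entered_above = [
                        e for e in (p2 - p1) if rank2[e] < rank2[ind]
                    ]
                    if not entered_above:
                        raise ConsistencyError(
                            f"{ind}: rank worsened {d1} -> {d2} without an "
                            "entrant above"
                        )
                    # entry renumbering: not a mobility event
    return events


def detect_dyadic_reversals(
    rank_table: DailyRankTable,
    dataset: GroupDataset,
    dyads: list[DyadSummary],
) -> list[DyadSummary]:
    """Fill each dyad's dominance timeline and count its active reversals.

    The dominance direction on a day is the sign of the pair's score
    difference; zero-difference days carry the last nonzero direction
    forward (no phantom reversals from ties). A reversal is *counted* only
    when an interaction between the two (dummy records excluded) is won by
    the individual the established direction says is subordinate AND the
    outcome leaves the winner scored above the loser at the end of that
    day — the fight itself flipped the pair. Crossings induced purely by
    third-party score movements, or upsets that do not overturn the pair's
    order, appear in the timeline and are tallied as
    ``n_unconfirmed_flips`` but are not active reversals. ``decided`` marks
    dyads separated by at least one real interaction between the two.
    """
    dyadic_winner: dict[frozenset, dict[dt.date, str]] = {}
    for rec in dataset.interactions:
        if rec.is_dummy:
            continue
        pair = frozenset((rec.winner_id, rec.loser_id))
        # same-day repeats: the last outcome of the day stands
        dyadic_winner.setdefault(pair, {})[rec.date] = rec.winner_id

    for dyad in dyads:
        a, b = dyad.individual_a, dyad.individual_b
        pair = frozenset((a, b))
        winners_by_day = dyadic_winner.get(pair, {})
        dyad.decided = bool(winners_by_day)

        timeline: list[tuple[dt.date, dt.date, str]] = []
        current_dir: str | None = None
        seg_start: dt.date | None = None
        established: str | None = None
        n_rev = 0
        n_flips = 0
        prev_date: dt.date | None = None

        date = dyad.co_residence_start
        while date <= dyad.co_residence_end:
            day_scores = rank_table.scores.get(date)
            if day_scores is None or a not in day_scores or b not in day_scores:
                date += dt.timedelta(days=1)
                continue
            diff = day_scores[a] - day_scores[b]
            if diff > 0:
                direction = a
            elif diff < 0:
                direction = b
            else:
                direction = current_dir  # tie: carry last nonzero direction
            if direction is not None and direction != current_dir:
                if current_dir is not None:
                    timeline.append((seg_start, prev_date, current_dir))
                    n_flips += 1
                current_dir = direction
                seg_start = date
            day_winner = winners_by_day.get(date)
            if day_winner is not None:
                if established is None:
                    # the relationship is established by the first outcome
                    # consistent with the pair's score order (a lone opening
                    # upset does not define a direction to reverse from)
                    if direction == day_winner:
                        established = day_winner
                elif day_winner != established and direction == day_winner:
                    n_rev += 1
                    established = day_winner
            prev_date = date
            date += dt.timedelta(days=1)
        if current_dir is not None:
            timeline.append((seg_start, prev_date, current_dir))

        dyad.dominant_timeline = timeline
        dyad.n_active_reversals = n_rev
        dyad.n_unconfirmed_flips = max(n_flips - n_rev, 0)
    return dyads


@dataclass(frozen=True)
class EntryRankRecord:
    individual_id: str
    entry_date: dt.date
    entry_type: str
    entry_rank: int
    n_present: int
    bottom_entry: bool
    method_label: str


def entry_rank_report(
    rank_table: DailyRankTable,
    life_history: list[LifeHistoryRecord],
    study_start: dt.date,
) -> list[EntryRankRecord]:
    """Rank obtained on entry by every female who joined after study start.

    Under the traditional entry rule every entrant starts at the bottom by
    construction; under the fitted (maximum-likelihood) parameterization the
    entry rank is implied by the fitted initial score among the individuals
    present on the entrance day, so non-bottom entries become visible. The
    record carries the rank table's method label for exactly this reason.
    """
    out = []
    for rec in sorted(life_history, key=lambda r: (r.entry_date, r.individual_id)):
        if rec.entry_date <= study_start or rec.entry_type == "start":
            continue
        date = rec.entry_date
        if date not in rank_table.order or rec.individual_id not in rank_table.order[date]:
            continue  # not part of this hierarchy (e.g. excluded from the fit)
        order = rank_table.order[date]
        rank = order.index(rec.individual_id) + 1
        out.append(
            EntryRankRecord(
                individual_id=rec.individual_id,
                entry_date=date,
                entry_type=rec.entry_type,
                entry_rank=rank,
                n_present=len(order),
                bottom_entry=rank == len(order),
                method_label=rank_table.method_label,
            )
        )
    return out


def passive_improvements(events: list[MobilityEvent]) -> list[MobilityEvent]:
    """Passive events that improved a rank (moved the individual up)."""
    return [
        e for e in events if e.cause == "passive" and e.rank_after < e.rank_before
    ]


def mobility_summary(
    events: list[MobilityEvent], dyads: list[DyadSummary]
) -> dict:
    """Group-level totals used in reports.

    ``n_passive_improvements`` counts individual-level upward moves;
    ``n_passive_improvement_dyads`` counts (mover, removed) pairs once.
    """
    improvements = passive_improvements(events)
    dyad_pairs = {
        (e.individual_id, e.trigger.split(":", 1)[1])
        for e in improvements
        if e.trigger.startswith("removal:")
    }
    return {
        "n_dyads": len(dyads),
        "n_decided_dyads": sum(1 for d in dyads if d.decided),
        "n_active_reversal_dyads": sum(1 for d in dyads if d.n_active_reversals > 0),
        "n_active_reversals": sum(d.n_active_reversals for d in dyads),
        "n_unconfirmed_flips": sum(d.n_unconfirmed_flips for d in dyads),
        "n_active_events": sum(1 for e in events if e.cause == "active"),
        "n_passive_events": sum(1 for e in events if e.cause == "passive"),
        "n_passive_improvements": len(improvements),
        "n_passive_improvement_dyads": len(dyad_pairs),
        "mean_co_residence_years": (
            sum(d.co_residence_years for d in dyads) / len(dyads) if dyads else 0.0
        ),
        "max_co_residence_years": (
            max((d.co_residence_years for d in dyads), default=0.0)
        ),
    }
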