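"""Sequential (traditional) Elo rating with daily score trajectories.

Every decided agonistic interaction transfers score from loser to winner in
proportion to the pre-interaction upset probability: an expected win moves
scores little, an upset moves them a lot. Scores are carried forward
unchanged on days without interactions, giving a daily score (and hence a
daily ordinal rank) for every individual over her presence window.

Conventions follow the long-term-study usage of Elo rating for animal
dominance: all interactions share one intensity constant ``k`` (default
100); individuals present at study start receive a common initial score
(default 1000); individuals entering the hierarchy later (maturing natal
females and immigrants) receive the score of the lowest-ranking individual
on their entrance day, since entrants are typically subordinate at first.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import AgonisticInteraction, GroupDataset, LifeHistoryRecord

logger = logging.getLogger(__name__)

PROB_MODELS = ("logistic", "normal")
ENTRY_RULES = ("lowest_current", "fixed_value", "fitted")


@dataclass(frozen=True)
class EloParameters:
    """Parameters of the sequential rating.

    ``prob_model`` selects the winning-probability curve: ``logistic`` is the
    chess-style form 1/(1+10^(-d/400)), ``normal`` the Gaussian-CDF form
    Phi(d/(200*sqrt(2))); both give p=0.5 at equal scores and are
    complementary under swapping the opponents. ``entry_rule`` fixes how
    mid-study entrants are scored (``fitted`` is only meaningful for the
    maximum-likelihood variant).
    """

    k: float = 100.0
    initial_score_start: float = 1000.0
    prob_model: str = "logistic"
    entry_rule: str = "lowest_current"

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.prob_model not in PROB_MODELS:
            raise ValueError(f"prob_model must be one of {PROB_MODELS}")
        if self.entry_rule not in ENTRY_RULES:
            raise ValueError(f"entry_rule must be one of {ENTRY_RULES}")


def expected_win_prob(score_a: float, score_b: float, prob_model: str = "logistic") -> float:
    """Probability that the individual scored ``score_a`` wins.

    Satisfies p(a,b) + p(b,a) = 1 and p = 0.5 at equal scores.
    """
    d = score_a - score_b
    if prob_model == "logistic":
        return 1.0 / (1.0 + 10.0 ** (-d / 400.0))
    if prob_model == "normal":
        return 0.5 * (1.0 + math.erf((d / (200.0 * math.sqrt(2.0))) / math.sqrt(2.0)))
    raise ValueError(f"unknown prob_model {prob_model!r}")


def elo_update(
    score_winner: float,
    score_loser: float,
    k: float = 100.0,
    prob_model: str = "logistic",
) -> tuple[float, float]:
    """One rating update: winner gains k*(1 - p_winner), loser loses the same.

    The pair's total score is conserved; the gain shrinks as the winner's
    prior winning probability grows (expected outcomes barely move scores).
    """
    p_win = expected_win_prob(score_winner, score_loser, prob_model)
    delta = k * (1.0 - p_win)
    return score_winner + delta, score_loser - delta


def entry_score(
    current_scores: dict[str, float],
    rule: str = "lowest_current",
    params: EloParameters | None = None,
) -> float:
    """Score assigned to an individual entering an existing hierarchy.

    ``lowest_current`` (default): the minimum current score — entrants start
    at the bottom. Falls back to the fixed starting score, with a logged
    notice, when nobody is present yet.
    """
    params = params or EloParameters()
    if rule == "fixed_value":
        return params.initial_score_start
    if rule == "lowest_current":
        if not current_scores:
            logger.info(
                "entry into an empty hierarchy: falling back to initial score %.1f",
                params.initial_score_start,
            )
            return params.initial_score_start
        return min(current_scores.values())
    raise ValueError(f"unsupported entry rule {rule!r}")


@dataclass
class EloTrajectory:
    """Per-individual daily score series over her presence window.

    ``scores[i]`` is the end-of-day score on ``start + i`` days; scores are
    carried forward unchanged across days without interactions.
    """

    individual_id: str
    group_id: str
    start: dt.date
    scores: np.ndarray  # one entry per day, start..end inclusive
    parameters: EloParameters = field(default_factory=EloParameters)

    @property
    def end(self) -> dt.date:
        return self.start + dt.timedelta(days=len(self.scores) - 1)

    def covers(self, date: dt.date) -> bool:
        return self.start <= date <= self.end

    def score_on(self, date: dt.date) -> float:
        if not self.covers(date):
            raise KeyError(
                f"{self.individual_id}: {date} outside window "
                f"[{self.start}, {self.end}]"
            )
        return float(self.scores[(date - self.start).days])

    def to_series(self) -> pd.Series:
        idx = pd.date_range(self.start, self.end, freq="D")
        return pd.Series(self.scores, index=idx, name=self.individual_id)


def run_traditional_elo(
    dataset: GroupDataset, params: EloParameters | None = None
) -> dict[str, EloTrajectory]:
    """Replay the dated interaction sequence and return daily trajectories.

    Interactions are processed in date order (same-day ties in file order).
    Entrants are scored before any same-day interaction; exits take effect
    at the end of the exit day (inclusive presence window). Removing an
    individual never changes the others' scores.
    """
    return replay_elo(dataset, params)


def replay_elo(
    dataset: GroupDataset,
    params: EloParameters | None = None,
    entry_scores: dict[str, float] | None = None,
    include: set[str] | None = None,
) -> dict[str, EloTrajectory]:
    """Day-by-day Elo replay shared by the traditional and fitted variants.

    ``entry_scores`` overrides the entry rule per individual (used to replay
    under maximum-likelihood-fitted initial scores); ``include`` restricts
    the hierarchy to a subset of individuals, dropping the others and any
    interaction that involves them.
    """
    params = params or EloParameters()
    dataset.validate()

    start, end = dataset.study_start, dataset.study_end
    n_days = (end - start).days + 1
    records = {
        r.individual_id: r
        for r in dataset.life_history
        if include is None or r.individual_id in include
    }

    # per-day buckets of interactions, preserving file order within a day
    buckets: dict[int, list[AgonisticInteraction]] = {}
    for rec in dataset.interactions:
        if rec.winner_id in records and rec.loser_id in records:
            buckets.setdefault((rec.date - start).days, []).append(rec)

    entries: dict[int, list[LifeHistoryRecord]] = {}
    exits: dict[int, list[str]] = {}
    for rec in records.values():
        entries.setdefault(max((rec.entry_date - start).days, 0), []).append(rec)
        exits.setdefault(
            (rec.effective_exit(end) - start).days, []
        ).append(rec.individual_id)

    current: dict[str, float] = {}
    daily: dict[str, list[float]] = {r: [] for r in records}
    windows: dict[str, list[int]] = {}

    for day in range(n_days):
        for rec in sorted(entries.get(day, []), key=lambda r: r.individual_id):
            if entry_scores is not None and rec.individual_id in entry_scores:
                score = entry_scores[rec.individual_id]
            elif rec.entry_type == "start" or day == 0:
                score = params.initial_score_start
            else:
                score = entry_score(current, params.entry_rule, params)
            current[rec.individual_id] = score
            windows[rec.individual_id] = [day]
        for inter in buckets.get(day, []):
            for who in (inter.winner_id, inter.loser_id):
                if who not in current:
                    raise ValueError(
                        f"interaction on {inter.date} involves {who!r} "
                        "outside their presence window"
                    )
            w, l = elo_update(
                current[inter.winner_id],
                current[inter.loser_id],
                params.k,
                params.prob_model,
            )
            current[inter.winner_id] = w
            current[inter.loser_id] = l
        for ind, score in current.items():
            daily[ind].append(score)
        for ind in exits.get(day, []):
            if ind in current:
                del current[ind]
                windows[ind].append(day)

    out: dict[str, EloTrajectory] = {}
    for ind, rec in records.items():
        w = windows.get(ind)
        if w is None:
            continue
        first = w[0]
        out[ind] = EloTrajectory(
            individual_id=ind,
            group_id=dataset.group_id,
            start=start + dt.timedelta(days=first),
            scores=np.asarray(daily[ind], dtype=float),
            parameters=params,
        )
    return out


def scores_on(
    trajectories: dict[str, EloTrajectory], date: dt.date
) -> dict[str, float]:
    """Scores of all individuals whose window covers ``date``."""
    return {
        ind: t.score_on(date) for ind, t in trajectories.items() if t.covers(date)
    }


def standardize_scores(
    trajectories: dict[str, EloTrajectory], date: dt.date
) -> dict[str, float]:
    """Min–max standardization among individuals present on ``date``.

    The top-scoring individual maps to 1 and the bottom to 0. Degenerate
    days (a single individual, or all scores equal) map everyone to 1: with
    no spread there is no one to dominate, and the lone/tied individuals sit
    at the top of their own hierarchy.
    """
    present = scores_on(trajectories, date)
    if not present:
        return {}
    lo, hi = min(present.values()), max(present.values())
    if hi == lo:
        return {ind: 1.0 for ind in present}
    return {ind: (s - lo) / (hi - lo) for ind, s in present.items()}


def seniority_key(record: LifeHistoryRecord) -> tuple[dt.date, str]:
    """Tie-break key for equal scores: earlier entrant ranks higher, then id."""
    return (record.entry_date, record.individual_id)


def trajectories_to_frame(
    trajectories: dict[str, EloTrajectory],
    life_history: list[LifeHistoryRecord] | None = None,
) -> pd.DataFrame:
    """Long-format export: date, group, individual, score, standardized_score,
    ordinal_rank (unique ranks, descending score, seniority tie-break)."""
    records = {r.individual_id: r for r in (life_history or [])}
    rows = []
    if not trajectories:
        return pd.DataFrame(
            columns=["date", "group", "individual", "score", "standardized_score", "ordinal_rank"]
        )
    start = min(t.start for t in trajectories.values())
    end = max(t.end for t in trajectories.values())
    date = start
    while date <= end:
        present = scores_on(trajectories, date)
        if present:
            std = standardize_scores(trajectories, date)
            order = sorted(
                present,
                key=lambda i: (
                    -present[i],
                    records[i].entry_date if i in records else dt.date.min,
                    i,
                ),
            )
            ranks = {ind: r + 1 for r, ind in enumerate(order)}
            for ind in order:
                rows.append(
                    {
                        "date": date,
                        "group": trajectories[ind].group_id,
                        "individual": ind,
                        "score": present[ind],
                        "standardized_score": std[ind],
                        "ordinal_rank": ranks[ind],
                    }
                )
        date += dt.timedelta(days=1)
    return pd.DataFrame(rows)
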