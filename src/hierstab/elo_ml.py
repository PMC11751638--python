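"""Maximum-likelihood ("optimized") Elo rating.

The sequential rating has two arbitrary inputs: the intensity constant ``k``
and the scores assigned on hierarchy entry. This module fits both by
maximizing the Bernoulli likelihood of the observed winner sequence: the
interaction sequence is replayed from candidate initial scores at a
candidate ``k``, and each interaction contributes ``log p(observed winner
wins)`` evaluated from the pre-interaction scores.

Identifiability: the likelihood is invariant to adding a constant to all
initial scores, so fitted initial scores are constrained to sum to zero —
negative fitted scores for low-ranking individuals are expected and legal.
``k`` is optimized as ``exp(theta)`` so it can approach but never cross
zero; a boundary optimum ``k_hat`` below 1e-3 is summarized as "virtually
0" (the interaction sequence adds nothing beyond the entry scores), with
the raw value always retained.

Only individuals with at least one win and one loss are identifiable (a
never-winning individual's score would run to -infinity), so the fit
requires callers to exclude or augment the others first; see
:func:`list_excluded_individuals` and :func:`augment_dummy_interactions`.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .elo_core import EloParameters, EloTrajectory, replay_elo, run_traditional_elo
from .io_formats import AgonisticInteraction, GroupDataset

try:  # pragma: no cover - exercised implicitly when numba is present
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


_LOG10_OVER_400 = math.log(10.0) / 400.0


@njit(cache=True)
def _replay_loglik(
    winners: np.ndarray, losers: np.ndarray, scores0: np.ndarray, k: float, logistic: bool
) -> float:
    scores = scores0.copy()
    ll = 0.0
    for i in range(winners.size):
        d = scores[winners[i]] - scores[losers[i]]
        if logistic:
            p = 1.0 / (1.0 + 10.0 ** (-d / 400.0))
        else:
            p = 0.5 * (1.0 + math.erf(d / 400.0))
        if p < 1e-300:
            p = 1e-300
        ll += math.log(p)
        delta = k * (1.0 - p)
        scores[winners[i]] += delta
        scores[losers[i]] -= delta
    return ll


@dataclass
class MLFitResult:
    """Outcome of the maximum-likelihood fit for one group."""

    group_id: str
    k_hat: float
    initial_scores_hat: dict[str, float]
    log_likelihood: float
    converged: bool
    n_parameters: int
    n_interactions: int
    prob_model: str
    optimizer_report: dict = field(default_factory=dict)
    excluded_zero_interaction: list[str] = field(default_factory=list)

    @property
    def k_is_virtually_zero(self) -> bool:
        return self.k_hat < 1e-3

    def summary(self) -> dict:
        out = dataclasses.asdict(self)
        out["k_label"] = "virtually 0" if self.k_is_virtually_zero else f"{self.k_hat:.2f}"
        return out


def list_excluded_individuals(
    dataset: GroupDataset,
) -> tuple[list[str], list[str], list[str]]:
    """Partition individuals by interaction record, for exclusion/augmentation.

    Returns ``(zero_interaction, loss_only, win_only)`` over the real (non-
    dummy) interactions; individuals with both wins and losses appear in no
    list. Zero-interaction individuals cannot be placed in the hierarchy at
    all; loss-only individuals need a dummy winning interaction before the
    fit (win-only ones a dummy loss, which did not arise in practice).
    """
    wins: dict[str, int] = {ind: 0 for ind in dataset.individuals}
    losses: dict[str, int] = {ind: 0 for ind in dataset.individuals}
    for rec in dataset.interactions:
        if rec.is_dummy:
            continue
        wins[rec.winner_id] = wins.get(rec.winner_id, 0) + 1
        losses[rec.loser_id] = losses.get(rec.loser_id, 0) + 1
    zero = sorted(i for i in wins if wins[i] == 0 and losses[i] == 0)
    loss_only = sorted(i for i in wins if wins[i] == 0 and losses[i] > 0)
    win_only = sorted(i for i in wins if wins[i] > 0 and losses[i] == 0)
    return zero, loss_only, win_only


def sequence_log_likelihood(
    dataset: GroupDataset,
    k: float,
    initial_scores: dict[str, float],
    prob_model: str = "logistic",
) -> float:
    """Log-likelihood of the observed winner sequence under (k, initial scores).

    Replays the interactions in order from the given initial scores at the
    given ``k``; each interaction contributes log p(observed winner wins)
    from the pre-interaction scores. With ``k = 0`` the scores are static and
    the model reduces to a fixed latent-order Bernoulli model.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    ids = sorted(
        {r.winner_id for r in dataset.interactions}
        | {r.loser_id for r in dataset.interactions}
    )
    missing = [i for i in ids if i not in initial_scores]
    if missing:
        raise ValueError(f"no initial score for interacting individual(s) {missing}")
    index = {ind: i for i, ind in enumerate(ids)}
    winners = np.array([index[r.winner_id] for r in dataset.interactions], dtype=np.int64)
    losers = np.array([index[r.loser_id] for r in dataset.interactions], dtype=np.int64)
    scores0 = np.array([float(initial_scores[i]) for i in ids], dtype=np.float64)
    return float(
        _replay_loglik(winners, losers, scores0, float(k), prob_model == "logistic")
    )


# --- optimizer -------------------------------------------------------------

_SCORE_UNIT = 100.0  # optimize scores in units of 100 Elo points
_SCORE_BOUND = 60.0  # +/- 6000 Elo points; wide enough for separable data
_THETA_BOUNDS = (math.log(1e-6), math.log(5e3))
_TIE_TOL = 1e-3  # log-likelihood ties; broken by smallest k
_JITTER_SEED = 20211  # internal multi-start jitter; fixed for determinism


def _pack_scores(x: np.ndarray) -> np.ndarray:
    """Map n-1 free parameters to n sum-to-zero scores (Elo units)."""
    full = np.append(x, -np.sum(x))
    return full * _SCORE_UNIT


def fit_optimized_elo(
    dataset: GroupDataset,
    prob_model: str = "logistic",
    fit_init: bool = True,
    n_starts: int = 5,
) -> MLFitResult:
    """Fit ``k`` and (optionally) per-individual initial scores by maximum
    likelihood.

    Every individual appearing in the interactions must have at least one
    win and one loss (augment loss-only individuals with
    :func:`augment_dummy_interactions` first); zero-interaction individuals
    are recorded as excluded. The optimizer is quasi-Newton (L-BFGS-B,
    numeric gradients) with multi-start: one start from the traditional-Elo
    final scores, one from flat scores, one at near-zero ``k``, plus
    seeded jittered restarts. The best likelihood wins; likelihood ties
    (within 1e-3) are broken in favour of the smallest ``k``, so a ``k``
    that buys nothing is reported as (virtually) zero.

    With ``fit_init=False`` only ``k`` is fitted, from flat initial scores.
    """
    zero, loss_only, win_only = list_excluded_individuals(dataset)
    # dummies can repair loss-only individuals; recheck including dummies
    problem = []
    wins: dict[str, int] = {}
    losses: dict[str, int] = {}
    for rec in dataset.interactions:
        wins[rec.winner_id] = wins.get(rec.winner_id, 0) + 1
        losses[rec.loser_id] = losses.get(rec.loser_id, 0) + 1
    ids = sorted(set(wins) | set(losses))
    for ind in ids:
        if wins.get(ind, 0) == 0 or losses.get(ind, 0) == 0:
            problem.append(ind)
    if problem:
        raise ValueError(
            f"individual(s) without both a win and a loss: {problem}; "
            "augment with dummy interactions or exclude them first"
        )
    if len(ids) < 2:
        raise ValueError("need at least two interacting individuals to fit")

    index = {ind: i for i, ind in enumerate(ids)}
    winners = np.array([index[r.winner_id] for r in dataset.interactions], dtype=np.int64)
    losers = np.array([index[r.loser_id] for r in dataset.interactions], dtype=np.int64)
    logistic = prob_model == "logistic"
    n = len(ids)

    def negloglik(params: np.ndarray) -> float:
        k = math.exp(params[0])
        if fit_init:
            scores0 = _pack_scores(params[1:])
        else:
            scores0 = np.zeros(n)
        return -_replay_loglik(winners, losers, scores0, k, logistic)

    # start 1: traditional-Elo final scores, centered
    trad = run_traditional_elo(dataset)
    trad_final = np.array(
        [trad[i].scores[-1] if i in trad else 1000.0 for i in ids]
    )
    trad_centered = (trad_final - trad_final.mean()) / _SCORE_UNIT

    def free(x_full: np.ndarray) -> np.ndarray:
        return np.clip(x_full[:-1], -_SCORE_BOUND + 1, _SCORE_BOUND - 1)

    starts: list[np.ndarray] = []
    theta0 = math.log(100.0)
    if fit_init:
        starts.append(np.concatenate([[theta0], free(trad_centered)]))
        starts.append(np.concatenate([[theta0], np.zeros(n - 1)]))
        starts.append(np.concatenate([[math.log(1e-5)], free(trad_centered)]))
        rng = np.random.default_rng(_JITTER_SEED)
        while len(starts) < max(n_starts, 3):
            jit = free(trad_centered) + rng.normal(0.0, 2.0, n - 1)
            th = theta0 + rng.normal(0.0, 1.0)
            starts.append(np.concatenate([[th], jit]))
        bounds = [_THETA_BOUNDS] + [(-_SCORE_BOUND, _SCORE_BOUND)] * (n - 1)
    else:
        starts = [np.array([theta0]), np.array([math.log(1e-5)])]
        bounds = [_THETA_BOUNDS]

    candidates = []
    for x0 in starts:
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500},
        )
        candidates.append(
            {
                "ll": -float(res.fun),
                "k": math.exp(float(res.x[0])),
                "x": res.x,
                "success": bool(res.success),
                "nit": int(res.nit),
            }
        )

    best_ll = max(c["ll"] for c in candidates)
    tied = [c for c in candidates if c["ll"] >= best_ll - _TIE_TOL]
    chosen = min(tied, key=lambda c: c["k"])

    if fit_init:
        scores_hat = _pack_scores(chosen["x"][1:])
    else:
        scores_hat = np.zeros(n)
    return MLFitResult(
        group_id=dataset.group_id,
        k_hat=chosen["k"],
        initial_scores_hat={ind: float(scores_hat[i]) for i, ind in enumerate(ids)},
        log_likelihood=chosen["ll"],
        converged=chosen["success"],
        n_parameters=(1 + n - 1) if fit_init else 1,
        n_interactions=int(winners.size),
        prob_model=prob_model,
        optimizer_report={
            "n_starts": len(starts),
            "candidates": [
                {k: v for k, v in c.items() if k != "x"} for c in candidates
            ],
            "tie_tolerance": _TIE_TOL,
        },
        excluded_zero_interaction=zero,
    )


def run_optimized_elo(
    dataset: GroupDataset, fit: MLFitResult
) -> dict[str, EloTrajectory]:
    """Daily trajectories under the fitted parameterization.

    Each fitted individual starts at her fitted initial score on her entry
    date (no score before entry) and is updated with the fitted ``k``;
    individuals without fitted scores (zero-interaction) are left out.
    """
    params = EloParameters(
        k=fit.k_hat,
        initial_score_start=0.0,
        prob_model=fit.prob_model,
        entry_rule="fitted",
    )
    return replay_elo(
        dataset,
        params,
        entry_scores=dict(fit.initial_scores_hat),
        include=set(fit.initial_scores_hat),
    )


def augment_dummy_interactions(
    dataset: GroupDataset, params: EloParameters | None = None
) -> tuple[GroupDataset, list[dict]]:
    """Append one dummy winning interaction per loss-only individual.

    Two-pass procedure: (1) infer the hierarchy by traditional Elo with the
    one-sided (loss-only or win-only) individuals left out; (2) for each
    loss-only individual, append one dummy interaction, dated one day after
    the group's last real interaction, in which she beats the
    lowest-ranking female of the pass-1 hierarchy (herself excluded).
    Win-only individuals — the symmetric defect, which can arise when an
    alpha female is never observed losing — receive the mirror-image
    repair: one dummy loss against the pass-1 top-ranking female. Dummy
    records carry ``is_dummy=True`` and are listed in the returned audit
    log. Multiple dummies are ordered by the augmented individual's
    identifier, losses first. The dominance relations among all other
    females are unaffected — the dummies sit at the end of the sequence
    and only lift the one-sided females into admissibility.
    """
    params = params or EloParameters()
    _, loss_only, win_only = list_excluded_individuals(dataset)
    if not loss_only and not win_only:
        return dataset, []

    keep = set(dataset.individuals) - set(loss_only) - set(win_only)
    if len(keep) < 2:
        raise ValueError(
            "fewer than two two-sided individuals: cannot infer the pass-1 "
            "hierarchy for dummy augmentation"
        )
    pass1 = replay_elo(dataset, params, include=keep)
    real = [r for r in dataset.interactions if not r.is_dummy]
    if not real:
        raise ValueError("cannot augment a dataset with no real interactions")
    base_date = min(
        real[-1].date + dt.timedelta(days=1), dataset.study_end
    )

    audit: list[dict] = []
    new_records: list[AgonisticInteraction] = []
    for ind, side in [(i, "win") for i in sorted(loss_only)] + [
        (i, "loss") for i in sorted(win_only)
    ]:
        rec = dataset.record_for(ind)
        date = min(base_date, rec.effective_exit(dataset.study_end))
        candidates = {
            other: traj.score_on(date)
            for other, traj in pass1.items()
            if other != ind and traj.covers(date)
        }
        if not candidates:
            raise ValueError(
                f"no candidate opponent co-present with {ind!r} for a dummy "
                "interaction"
            )
        if side == "win":  # she beats the pass-1 bottom female
            other = min(candidates, key=lambda o: (candidates[o], o))
            winner, loser = ind, other
        else:  # she loses to the pass-1 top female
            other = max(candidates, key=lambda o: (candidates[o], o))
            winner, loser = other, ind
        dummy = AgonisticInteraction(
            date=date,
            winner_id=winner,
            loser_id=loser,
            group_id=dataset.group_id,
            interaction_type="displacement",
            is_dummy=True,
        )
        new_records.append(dummy)
        audit.append(
            {
                "augmented": ind,
                "side": side,
                "winner": winner,
                "loser": loser,
                "date": date.isoformat(),
                "opponent_pass1_score": candidates[other],
            }
        )

    augmented = GroupDataset(
        group_id=dataset.group_id,
        interactions=list(dataset.interactions) + new_records,
        life_history=list(dataset.life_history),
        study_start=dataset.study_start,
        study_end=dataset.study_end,
        species_label=dataset.species_label,
    )
    return augmented, audit
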