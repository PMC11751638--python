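import datetime as dt
import math

import numpy as np
import pytest

from hierstab import simulate
from hierstab.elo_core import EloParameters, run_traditional_elo
from hierstab.elo_ml import (
    augment_dummy_interactions,
    fit_optimized_elo,
    list_excluded_individuals,
    run_optimized_elo,
    sequence_log_likelihood,
)

from conftest import make_dataset, make_inter, make_life


def oracle_loglik(interactions, init, k, prob_model="logistic"):
    """Independent hand replay of the Bernoulli likelihood."""
    s = dict(init)
    ll = 0.0
    for rec in interactions:
        d = s[rec.winner_id] - s[rec.loser_id]
        if prob_model == "logistic":
            p = 1 / (1 + 10 ** (-d / 400))
        else:
            p = 0.5 * (1 + math.erf(d / 400))
        ll += math.log(p)
        delta = k * (1 - p)
        s[rec.winner_id] += delta
        s[rec.loser_id] -= delta
    return ll


def test_single_equal_score_interaction_gives_log_half(two_female_dataset):
    ll = sequence_log_likelihood(
        two_female_dataset, k=100, initial_scores={"A": 0.0, "B": 0.0}
    )
    assert ll == pytest.approx(math.log(0.5))


def test_k_zero_reduces_to_static_bernoulli():
    life = [make_life(i) for i in "AB"]
    inter = [make_inter(f"2000-01-{d:02d}", "A", "B") for d in range(1, 11)]
    ds = make_dataset(inter, life)
    init = {"A": 200.0, "B": -200.0}
    p = 1 / (1 + 10 ** (-400 / 400))
    assert sequence_log_likelihood(ds, 0.0, init) == pytest.approx(10 * math.log(p))


def test_loglik_matches_hand_replay_on_twenty_interactions():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=17, n_years=1, n_initial_females=4,
                                  interaction_rate_per_year=25)
    )
    init = {ind: s for ind, s in zip(ds.individuals, (300.0, 100.0, -100.0, -300.0))}
    for model in ("logistic", "normal"):
        got = sequence_log_likelihood(ds, 73.0, init, model)
        want = oracle_loglik(ds.interactions, init, 73.0, model)
        assert got == pytest.approx(want, abs=1e-9)


def test_loglik_requires_scores_for_all_participants(two_female_dataset):
    with pytest.raises(ValueError):
        sequence_log_likelihood(two_female_dataset, 100, {"A": 0.0})


def test_loglik_translation_invariance():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=19, n_years=2, n_initial_females=5,
                                  interaction_rate_per_year=20)
    )
    init = {ind: 100.0 * i for i, ind in enumerate(ds.individuals)}
    shifted = {ind: s + 777.7 for ind, s in init.items()}
    assert sequence_log_likelihood(ds, 50.0, init) == pytest.approx(
        sequence_log_likelihood(ds, 50.0, shifted), abs=1e-9
    )


def test_list_excluded_partition():
    life = [make_life(i) for i in "ABCD"]
    inter = [
        make_inter("2000-01-05", "A", "B"),
        make_inter("2000-02-05", "B", "A"),
        make_inter("2000-03-05", "A", "C"),
        make_inter("2000-04-05", "B", "C"),
    ]
    ds = make_dataset(inter, life)
    zero, loss_only, win_only = list_excluded_individuals(ds)
    assert zero == ["D"]
    assert loss_only == ["C"]
    assert win_only == []


def test_augment_noop_without_one_sided_individuals():
    life = [make_life(i) for i in "AB"]
    inter = [make_inter("2000-01-05", "A", "B"), make_inter("2000-02-05", "B", "A")]
    ds = make_dataset(inter, life)
    out, audit = augment_dummy_interactions(ds)
    assert out is ds and audit == []


def test_augment_adds_dummy_win_against_pass1_bottom():
    life = [make_life(i) for i in "ABCL"]
    inter = [
        make_inter("2000-01-05", "A", "B"),
        make_inter("2000-01-06", "B", "A"),
        make_inter("2000-02-05", "A", "C"),
        make_inter("2000-02-06", "C", "B"),
        make_inter("2000-03-05", "A", "L"),
        make_inter("2000-04-05", "B", "L"),
    ]
    ds = make_dataset(inter, life)
    out, audit = augment_dummy_interactions(ds)
    dummies = [r for r in out.interactions if r.is_dummy]
    assert len(dummies) == 1
    d = dummies[0]
    assert d.winner_id == "L"
    assert d.date == dt.date(2000, 4, 6)  # day after the last real interaction
    # loser is the bottom of the hierarchy fitted without L
    pass1 = run_traditional_elo(
        make_dataset(inter[:4], [make_life(i) for i in "ABC"])
    )
    bottom = min(pass1, key=lambda i: pass1[i].scores[-1])
    assert d.loser_id == bottom
    assert audit[0]["augmented"] == "L" and audit[0]["side"] == "win"


def test_augmentation_does_not_change_other_relations():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=23, n_years=5, n_initial_females=5,
                                  interaction_rate_per_year=20,
                                  latent_steepness=0.9)
    )
    zero, loss_only, win_only = list_excluded_individuals(ds)
    aug, audit = augment_dummy_interactions(ds)
    assert len(audit) == len(loss_only) + len(win_only)
    two_sided = [i for i in ds.individuals
                 if i not in zero + loss_only + win_only]
    if len(two_sided) >= 2 and audit:
        fit_no = fit_optimized_elo(
            make_dataset(
                [r for r in ds.interactions
                 if r.winner_id in two_sided and r.loser_id in two_sided],
                [r for r in ds.life_history if r.individual_id in two_sided],
                start=ds.study_start.isoformat(), end=ds.study_end.isoformat(),
            )
        )
        fit_with = fit_optimized_elo(aug)
        order_no = sorted(two_sided, key=lambda i: -fit_no.initial_scores_hat[i])
        order_with = [
            i for i in sorted(
                fit_with.initial_scores_hat,
                key=lambda i: -fit_with.initial_scores_hat[i],
            )
            if i in two_sided
        ]
        assert order_no == order_with


def test_fit_requires_win_and_loss():
    life = [make_life(i) for i in "AB"]
    inter = [make_inter("2000-01-05", "A", "B")]
    with pytest.raises(ValueError, match="without both"):
        fit_optimized_elo(make_dataset(inter, life))


def test_transitive_data_fit_is_boundary_k_zero():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=2, n_years=3, n_initial_females=4,
                                  interaction_rate_per_year=15,
                                  latent_steepness=1.0)
    )
    aug, _ = augment_dummy_interactions(ds)
    fit = fit_optimized_elo(aug)
    assert fit.converged
    assert fit.k_hat < 1e-3
    assert fit.k_is_virtually_zero
    # fitted order matches the latent order among non-augmented individuals
    order = sorted(fit.initial_scores_hat, key=lambda i: -fit.initial_scores_hat[i])
    assert order == sorted(ds.individuals)


def test_reversal_data_fit_needs_dynamics():
    cfg = simulate.SimulationConfig(
        seed=6, group_id="R", n_years=8, n_initial_females=5,
        interaction_rate_per_year=25, latent_steepness=1.0,
        injected_reversals=[simulate.ReversalEvent(year=4.0, position=3)],
    )
    ds, _ = simulate.simulate_group(cfg)
    aug, _ = augment_dummy_interactions(ds)
    fit = fit_optimized_elo(aug)
    assert fit.k_hat > 1e-3
    # dynamics must beat the best static (k ~ 0) candidate by a clear margin
    static_lls = [
        c["ll"] for c in fit.optimizer_report["candidates"] if c["k"] < 1e-3
    ]
    assert static_lls and fit.log_likelihood > max(static_lls) + 1e-3


def test_fit_is_deterministic():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=8, n_years=3, n_initial_females=4,
                                  interaction_rate_per_year=20,
                                  latent_steepness=0.9)
    )
    aug, _ = augment_dummy_interactions(ds)
    f1 = fit_optimized_elo(aug)
    f2 = fit_optimized_elo(aug)
    assert f1.k_hat == f2.k_hat
    assert f1.log_likelihood == f2.log_likelihood


def test_fit_beats_traditional_parameterization():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=31, n_years=4, n_initial_females=5,
                                  interaction_rate_per_year=20,
                                  latent_steepness=0.85)
    )
    aug, _ = augment_dummy_interactions(ds)
    fit = fit_optimized_elo(aug)
    ids = sorted(fit.initial_scores_hat)
    baseline = sequence_log_likelihood(aug, 100.0, {i: 0.0 for i in ids})
    assert fit.log_likelihood >= baseline
    # sum-to-zero identifiability constraint
    assert sum(fit.initial_scores_hat.values()) == pytest.approx(0.0, abs=1e-6)
    assert fit.log_likelihood <= 0.0


def test_optimized_trajectories_start_at_fitted_scores():
    ds, _ = simulate.simulate_group(
        simulate.SimulationConfig(seed=13, n_years=3, n_initial_females=4,
                                  interaction_rate_per_year=15,
                                  latent_steepness=0.9)
    )
    aug, _ = augment_dummy_interactions(ds)
    fit = fit_optimized_elo(aug)
    traj = run_optimized_elo(aug, fit)
    first_day = {r.winner_id for r in aug.interactions if r.date == aug.study_start}
    first_day |= {r.loser_id for r in aug.interactions if r.date == aug.study_start}
    for ind, t in traj.items():
        assert t.start == aug.record_for(ind).entry_date
        if t.start == aug.study_start and ind not in first_day:
            assert t.scores[0] == pytest.approx(fit.initial_scores_hat[ind])
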