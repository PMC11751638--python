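"""Shared builders for small hand-constructed datasets."""

from __future__ import annotations

import datetime as dt

import pytest

from hierstab.io_formats import (
    AgonisticInteraction,
    GroupDataset,
    LifeHistoryRecord,
)

D = dt.date


def make_life(
    individual,
    entry="2000-01-01",
    entry_type="start",
    exit=None,
    exit_reason="study_end",
    group="G",
    age=None,
):
    return LifeHistoryRecord(
        individual_id=individual,
        group_id=group,
        entry_date=dt.date.fromisoformat(entry),
        entry_type=entry_type,
        exit_date=dt.date.fromisoformat(exit) if exit else None,
        exit_reason=exit_reason,
        age_at_entry_years=age,
    )


def make_inter(date, winner, loser, group="G", itype="displacement", dummy=False):
    return AgonisticInteraction(
        date=dt.date.fromisoformat(date),
        winner_id=winner,
        loser_id=loser,
        group_id=group,
        interaction_type=itype,
        is_dummy=dummy,
    )


def make_dataset(
    interactions,
    life,
    start="2000-01-01",
    end="2000-12-31",
    group="G",
    species="mountain",
):
    return GroupDataset(
        group_id=group,
        interactions=list(interactions),
        life_history=list(life),
        study_start=dt.date.fromisoformat(start),
        study_end=dt.date.fromisoformat(end),
        species_label=species,
    )


@pytest.fixture
def two_female_dataset():
    """A and B present all year; one decided interaction in March."""
    life = [make_life("A"), make_life("B")]
    inter = [make_inter("2000-03-01", "A", "B")]
    return make_dataset(inter, life)
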