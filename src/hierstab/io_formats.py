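"""Reading, writing and validation of agonistic-interaction and life-history tables.

The two input tables are plain CSV (UTF-8, header row, ISO-8601 dates):

``interactions.csv``
    date,group,winner,loser,type[,is_dummy]

``life_history.csv``
    individual,group,entry_date,entry_type,exit_date,exit_reason[,age_at_entry]

Interaction types are restricted to the decided, low-intensity categories
used for dominance inference (``displacement`` and ``avoidance``); rows typed
``aggression`` are filtered out on read when ``type_filter`` is on, because
aggression is context-dependent and does not reliably express the hierarchy.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

ALLOWED_INTERACTION_TYPES = frozenset({"displacement", "avoidance"})
EXCLUDED_INTERACTION_TYPES = frozenset({"aggression"})
ENTRY_TYPES = frozenset({"start", "N", "IN", "IP"})
EXIT_REASONS = frozenset({"death", "emigration", "fission", "study_end", "censored"})

#: default column names for the two tables; override via ``schema_config``
DEFAULT_INTERACTION_COLUMNS = {
    "date": "date",
    "group": "group",
    "winner": "winner",
    "loser": "loser",
    "type": "type",
    "is_dummy": "is_dummy",
}
DEFAULT_LIFE_HISTORY_COLUMNS = {
    "individual": "individual",
    "group": "group",
    "entry_date": "entry_date",
    "entry_type": "entry_type",
    "exit_date": "exit_date",
    "exit_reason": "exit_reason",
    "age_at_entry": "age_at_entry",
}


class SchemaError(ValueError):
    """A required column is missing or a value class is unknown."""


class ValidationError(ValueError):
    """A row violates a dataset invariant (named by row where possible)."""


@dataclass(frozen=True)
class AgonisticInteraction:
    """One decided dyadic agonistic event; the atomic unit of rating updates."""

    date: dt.date
    winner_id: str
    loser_id: str
    group_id: str
    interaction_type: str
    is_dummy: bool = False

    def __post_init__(self) -> None:
        if self.winner_id == self.loser_id:
            raise ValidationError(
                f"interaction on {self.date}: winner and loser are both "
                f"{self.winner_id!r}"
            )
        if self.interaction_type not in ALLOWED_INTERACTION_TYPES:
            raise ValidationError(
                f"interaction on {self.date}: type {self.interaction_type!r} "
                f"not in {sorted(ALLOWED_INTERACTION_TYPES)}"
            )


@dataclass(frozen=True)
class LifeHistoryRecord:
    """An individual's presence window in a group, with how she entered and left.

    Entry classes: ``start`` (present at study start), ``N`` (natal
    maturation), ``IN`` (nulliparous immigrant), ``IP`` (parous immigrant).
    An open record (still present at study end) has ``exit_date=None`` and
    ``exit_reason`` of ``study_end`` or ``censored``.
    """

    individual_id: str
    group_id: str
    entry_date: dt.date
    entry_type: str
    exit_date: dt.date | None = None
    exit_reason: str = "study_end"
    age_at_entry_years: float | None = None
    sex: str = "F"

    def __post_init__(self) -> None:
        if self.entry_type not in ENTRY_TYPES:
            raise ValidationError(
                f"{self.individual_id}: entry_type {self.entry_type!r} "
                f"not in {sorted(ENTRY_TYPES)}"
            )
        if self.exit_reason not in EXIT_REASONS:
            raise ValidationError(
                f"{self.individual_id}: exit_reason {self.exit_reason!r} "
                f"not in {sorted(EXIT_REASONS)}"
            )
        if self.exit_date is not None and self.entry_date > self.exit_date:
            raise ValidationError(
                f"{self.individual_id}: entry {self.entry_date} after exit "
                f"{self.exit_date}"
            )

    def present_on(self, date: dt.date, study_end: dt.date | None = None) -> bool:
        """Inclusive presence window; open records run to ``study_end``."""
        if date < self.entry_date:
            return False
        end = self.exit_date if self.exit_date is not None else study_end
        return end is None or date <= end

    def effective_exit(self, study_end: dt.date) -> dt.date:
        return self.exit_date if self.exit_date is not None else study_end


@dataclass
class GroupDataset:
    """A group's full record: interactions, life history, and study window.

    Interactions are kept sorted by date with same-day ties in file order
    (daily timestamps carry no finer resolution, so file order is the only
    same-day order there is).
    """

    group_id: str
    interactions: list[AgonisticInteraction]
    life_history: list[LifeHistoryRecord]
    study_start: dt.date
    study_end: dt.date
    species_label: str = "mountain"

    def __post_init__(self) -> None:
        self.interactions = sorted(self.interactions, key=lambda r: r.date)

    @property
    def individuals(self) -> list[str]:
        return sorted({rec.individual_id for rec in self.life_history})

    @property
    def n_years(self) -> float:
        return ((self.study_end - self.study_start).days + 1) / 365.25

    def record_for(self, individual_id: str) -> LifeHistoryRecord:
        for rec in self.life_history:
            if rec.individual_id == individual_id:
                return rec
        raise KeyError(individual_id)

    def present_on(self, individual_id: str, date: dt.date) -> bool:
        return self.record_for(individual_id).present_on(date, self.study_end)

    def validate(self) -> None:
        """Check the cross-table invariants; raise ValidationError on failure."""
        by_id: dict[str, list[LifeHistoryRecord]] = {}
        for rec in self.life_history:
            by_id.setdefault(rec.individual_id, []).append(rec)
        for ind, recs in by_id.items():
            n_open = sum(1 for r in recs if r.exit_date is None)
            if n_open > 1:
                raise ValidationError(f"{ind}: more than one open presence record")
        for i, rec in enumerate(self.interactions):
            for who in (rec.winner_id, rec.loser_id):
                if who not in by_id:
                    raise ValidationError(
                        f"interaction {i} ({rec.date}): {who!r} has no "
                        "life-history record"
                    )
                if not any(
                    r.present_on(rec.date, self.study_end) for r in by_id[who]
                ):
                    raise ValidationError(
                        f"interaction {i} ({rec.date}): {who!r} not present "
                        "on that date"
                    )


def _parse_date(value: str, row: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(str(value).strip())
    except ValueError as exc:
        raise ValidationError(f"row {row}: cannot parse {column}={value!r}") from exc


def read_interactions(
    path: str | Path,
    schema_config: Mapping[str, str] | None = None,
    type_filter: bool = True,
) -> list[AgonisticInteraction]:
    """Read an interaction CSV into validated, date-sorted records.

    Parameters
    ----------
    path:
        CSV file with header.
    schema_config:
        Optional mapping from canonical names (``date``, ``group``,
        ``winner``, ``loser``, ``type``, ``is_dummy``) to the file's column
        names; unmapped names use the defaults.
    type_filter:
        When True (default), silently drop rows whose type is a known
        non-hierarchy category (``aggression``); unknown types always raise.
    """
    cols = dict(DEFAULT_INTERACTION_COLUMNS)
    if schema_config:
        cols.update(schema_config)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [cols[c] for c in ("date", "group", "winner", "loser", "type")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[AgonisticInteraction] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = row 1
        row_d = dict(zip(df.columns, row))
        itype = row_d[cols["type"]].strip()
        if itype in EXCLUDED_INTERACTION_TYPES:
            if type_filter:
                continue
            raise ValidationError(f"row {i}: excluded interaction type {itype!r}")
        is_dummy = False
        if cols["is_dummy"] in df.columns:
            is_dummy = row_d[cols["is_dummy"]].strip().lower() in {"true", "1", "yes"}
        try:
            rec = AgonisticInteraction(
                date=_parse_date(row_d[cols["date"]], i, "date"),
                winner_id=row_d[cols["winner"]].strip(),
                loser_id=row_d[cols["loser"]].strip(),
                group_id=row_d[cols["group"]].strip(),
                interaction_type=itype,
                is_dummy=is_dummy,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    records.sort(key=lambda r: r.date)  # stable: same-day ties keep file order
    return records


def read_life_history(
    path: str | Path, schema_config: Mapping[str, str] | None = None
) -> list[LifeHistoryRecord]:
    """Read a life-history CSV; empty exit_date means an open record."""
    cols = dict(DEFAULT_LIFE_HISTORY_COLUMNS)
    if schema_config:
        cols.update(schema_config)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [
        cols[c] for c in ("individual", "group", "entry_date", "entry_type")
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        row_d = dict(zip(df.columns, row))
        exit_raw = row_d.get(cols["exit_date"], "").strip()
        age_raw = row_d.get(cols["age_at_entry"], "").strip()
        try:
            rec = LifeHistoryRecord(
                individual_id=row_d[cols["individual"]].strip(),
                group_id=row_d[cols["group"]].strip(),
                entry_date=_parse_date(row_d[cols["entry_date"]], i, "entry_date"),
                entry_type=row_d[cols["entry_type"]].strip(),
                exit_date=_parse_date(exit_raw, i, "exit_date") if exit_raw else None,
                exit_reason=(row_d.get(cols["exit_reason"], "") or "study_end").strip(),
                age_at_entry_years=float(age_raw) if age_raw else None,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {i}: {exc}") from None
        records.append(rec)
    return records


def write_interactions(records: Iterable[AgonisticInteraction], path: str | Path) -> None:
    """Canonical serialization: read-write-read round-trips byte-stably."""
    rows = [
        {
            "date": r.date.isoformat(),
            "group": r.group_id,
            "winner": r.winner_id,
            "loser": r.loser_id,
            "type": r.interaction_type,
            "is_dummy": str(r.is_dummy).lower(),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["date", "group", "winner", "loser", "type", "is_dummy"]).to_csv(
        path, index=False
    )


def write_life_history(records: Iterable[LifeHistoryRecord], path: str | Path) -> None:
    rows = [
        {
            "individual": r.individual_id,
            "group": r.group_id,
            "entry_date": r.entry_date.isoformat(),
            "entry_type": r.entry_type,
            "exit_date": r.exit_date.isoformat() if r.exit_date else "",
            "exit_reason": r.exit_reason,
            "age_at_entry": "" if r.age_at_entry_years is None else f"{r.age_at_entry_years:g}",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "individual", "group", "entry_date", "entry_type",
            "exit_date", "exit_reason", "age_at_entry",
        ],
    ).to_csv(path, index=False)


def read_group_dataset(
    interactions_path: str | Path,
    life_history_path: str | Path,
    group_id: str,
    study_start: dt.date | None = None,
    study_end: dt.date | None = None,
    species_label: str = "mountain",
    schema_config: Mapping[str, Mapping[str, str]] | None = None,
) -> GroupDataset:
    """Assemble and validate a GroupDataset for one group from the two tables."""
    schema_config = schema_config or {}
    inter = [
        r
        for r in read_interactions(interactions_path, schema_config.get("interactions"))
        if r.group_id == group_id
    ]
    life = [
        r
        for r in read_life_history(life_history_path, schema_config.get("life_history"))
        if r.group_id == group_id
    ]
    if not life:
        raise ValidationError(f"no life-history records for group {group_id!r}")
    if study_start is None:
        study_start = min(r.entry_date for r in life)
    if study_end is None:
        dates = [r.exit_date for r in life if r.exit_date is not None]
        dates += [r.date for r in inter]
        study_end = max(dates) if dates else study_start
    ds = GroupDataset(
        group_id=group_id,
        interactions=inter,
        life_history=life,
        study_start=study_start,
        study_end=study_end,
        species_label=species_label,
    )
    ds.validate()
    return ds


# --- eligibility -----------------------------------------------------------

ADULT_AGE_DEFAULTS = {"mountain": 8.0, "western": 10.0}


def filter_eligible(
    dataset: GroupDataset,
    adult_age_mountain: float = 8.0,
    adult_age_western: float = 10.0,
    adult_age: float | None = None,
) -> GroupDataset:
    """Keep only adult females: the species-specific age threshold applies.

    Mountain gorilla females are adult from 8 years, western gorilla females
    from 10. Individuals whose age at entry is unknown are treated as adult
    when their entry class implies adulthood (parous immigrants ``IP``, and
    ``start`` individuals, whose age estimates are typically inaccurate);
    unknown-age ``N``/``IN`` entrants are retained, since hierarchy entry at
    maturation or immigration is itself the adulthood event. Interactions
    involving removed individuals are dropped. Idempotent.
    """
    if adult_age is not None:
        threshold = adult_age
    elif dataset.species_label in ("mountain",):
        threshold = adult_age_mountain
    elif dataset.species_label in ("western",):
        threshold = adult_age_western
    else:
        raise SchemaError(
            f"species_label {dataset.species_label!r} unrecognized and no "
            "explicit adult_age given"
        )

    keep: list[LifeHistoryRecord] = []
    for rec in dataset.life_history:
        if rec.age_at_entry_years is None:
            keep.append(rec)  # adulthood implied by entry class (see docstring)
            continue
        # age at final exit decides whether she is ever adult in-window
        exit_d = rec.effective_exit(dataset.study_end)
        years_in = (exit_d - rec.entry_date).days / 365.25
        if rec.age_at_entry_years + years_in >= threshold:
            keep.append(rec)
    kept_ids = {r.individual_id for r in keep}
    inter = [
        r
        for r in dataset.interactions
        if r.winner_id in kept_ids and r.loser_id in kept_ids
    ]
    return GroupDataset(
        group_id=dataset.group_id,
        interactions=inter,
        life_history=keep,
        study_start=dataset.study_start,
        study_end=dataset.study_end,
        species_label=dataset.species_label,
    )


@dataclass(frozen=True)
class InclusionReport:
    group_id: str
    include: bool
    n_interactions: int
    rate_per_year: float
    n_females: int
    n_years: float
    min_interactions: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def check_group_inclusion(
    dataset: GroupDataset, min_interactions: int = 50
) -> InclusionReport:
    """Decide whether a group has enough recorded interactions to infer a
    hierarchy at all; too-sparse groups (the low-rate regime of a few
    interactions per year) are excluded rather than given an unreliable fit.

    The threshold is always surfaced in the report and overridable.
    """
    n = len([r for r in dataset.interactions if not r.is_dummy])
    years = dataset.n_years
    return InclusionReport(
        group_id=dataset.group_id,
        include=n >= min_interactions,
        n_interactions=n,
        rate_per_year=n / years if years > 0 else 0.0,
        n_females=len(dataset.individuals),
        n_years=years,
        min_interactions=min_interactions,
    )
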