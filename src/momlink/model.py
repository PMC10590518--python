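"""Minimal claims data model: tables, invariants, CSV I/O, observation periods.

The schema is a thin slice of an OMOP-CDM-style claims database — just the
tables a mother-infant linkage algorithm touches:

* ``person``            — person_id, sex, year/month/day of birth, enrollment_id
* ``enrollment_span``   — raw insurance coverage intervals (may overlap)
* ``pregnancy_episode`` — dated pregnancy intervals with an outcome category
* ``clinical_event``    — condition/drug/procedure/measurement/visit records

All dates are whole-day, closed intervals, ISO-8601 on disk. Raw enrollment
spans are consolidated into *observation periods* by bridging short coverage
gaps (default: gaps of at most 30 uncovered days are bridged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEXES = ("female", "male")
OUTCOMES = ("live_birth", "stillbirth", "abortion", "ectopic")
DOMAINS = ("condition", "drug", "procedure", "measurement", "visit")
VISIT_TYPES = ("outpatient", "inpatient", "emergency")

PERSON_COLUMNS = [
    "person_id", "sex", "year_of_birth", "month_of_birth", "day_of_birth",
    "enrollment_id",
]
ENROLLMENT_COLUMNS = ["person_id", "start_date", "end_date"]
EPISODE_COLUMNS = ["episode_id", "person_id", "start_date", "end_date", "outcome"]
EVENT_COLUMNS = ["person_id", "event_date", "domain", "concept_code", "visit_type"]
OBSERVATION_COLUMNS = ["person_id", "start_date", "end_date", "ordinal"]

TABLE_COLUMNS: Mapping[str, list[str]] = {
    "person": PERSON_COLUMNS,
    "enrollment_span": ENROLLMENT_COLUMNS,
    "pregnancy_episode": EPISODE_COLUMNS,
    "clinical_event": EVENT_COLUMNS,
}

_DATE_COLUMNS = {"start_date", "end_date", "event_date"}


class SchemaError(ValueError):
    """A table violates the claims-schema invariants."""


def _parse_dates(df: pd.DataFrame, table: str) -> pd.DataFrame:
    for col in df.columns:
        if col in _DATE_COLUMNS:
            try:
                df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"{table}.{col}: unparseable date ({exc})") from exc
    return df


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


@dataclass
class ClaimsDataset:
    """In-memory bundle of the four claims tables.

    Observation periods are derived on demand (and cached per gap threshold)
    from the raw enrollment spans via :func:`merge_enrollment_spans`.
    """

    persons: pd.DataFrame
    enrollment_spans: pd.DataFrame
    pregnancy_episodes: pd.DataFrame
    clinical_events: pd.DataFrame
    _obs_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def validate(self) -> None:
        """Check every schema invariant; raise :class:`SchemaError` on the first
        violation, naming the offending rows."""
        p = self.persons
        _require_columns(p, "person")
        dup = p[p["person_id"].duplicated(keep=False)]
        if len(dup):
            raise SchemaError(
                f"person: duplicate person_id rows: {sorted(dup['person_id'].unique())[:10]}"
            )
        if p["year_of_birth"].isna().any():
            bad = p.loc[p["year_of_birth"].isna(), "person_id"].tolist()[:10]
            raise SchemaError(f"person: year_of_birth missing for {bad}")
        bad_sex = p.loc[~p["sex"].isin(SEXES), "person_id"].tolist()
        if bad_sex:
            raise SchemaError(f"person: invalid sex for {bad_sex[:10]}")
        day_no_month = p["day_of_birth"].notna() & p["month_of_birth"].isna()
        if day_no_month.any():
            bad = p.loc[day_no_month, "person_id"].tolist()[:10]
            raise SchemaError(f"person: day_of_birth without month_of_birth for {bad}")

        s = self.enrollment_spans
        _require_columns(s, "enrollment_span")
        bad = s[s["start_date"] > s["end_date"]]
        if len(bad):
            rows = bad[["person_id", "start_date", "end_date"]].head(10)
            raise SchemaError(f"enrollment_span: start_date > end_date:\n{rows}")

        e = self.pregnancy_episodes
        _require_columns(e, "pregnancy_episode")
        if e["episode_id"].duplicated().any():
            raise SchemaError("pregnancy_episode: duplicate episode_id")
        bad = e[e["start_date"] >= e["end_date"]]
        if len(bad):
            raise SchemaError(
                f"pregnancy_episode: start_date >= end_date for episodes "
                f"{bad['episode_id'].tolist()[:10]}"
            )
        bad_out = e.loc[~e["outcome"].isin(OUTCOMES), "episode_id"].tolist()
        if bad_out:
            raise SchemaError(f"pregnancy_episode: invalid outcome for {bad_out[:10]}")

        ev = self.clinical_events
        _require_columns(ev, "clinical_event")
        bad_dom = ev[~ev["domain"].isin(DOMAINS)]
        if len(bad_dom):
            raise SchemaError(
                f"clinical_event: invalid domain values {sorted(bad_dom['domain'].unique())}"
            )
        is_visit = ev["domain"] == "visit"
        if (is_visit & ev["visit_type"].isna()).any():
            raise SchemaError("clinical_event: visit rows must carry visit_type")
        if (~is_visit & ev["visit_type"].notna()).any():
            raise SchemaError("clinical_event: visit_type present on non-visit rows")

        # referential sanity (logged, not fatal: claims feeds routinely contain
        # orphan rows and downstream steps simply never select them)
        known = set(p["person_id"])
        for name, tbl in (
            ("enrollment_span", s), ("pregnancy_episode", e), ("clinical_event", ev),
        ):
            orphans = (~tbl["person_id"].isin(known)).sum()
            if orphans:
                logger.warning("%s: %d rows reference unknown person_id", name, orphans)
        logger.info(
            "dataset validated: %d persons, %d spans, %d episodes, %d events",
            len(p), len(s), len(e), len(ev),
        )

    def observation_periods(self, max_gap_days: int = 30) -> pd.DataFrame:
        """Gap-merged observation periods for every person (cached)."""
        if max_gap_days not in self._obs_cache:
            self._obs_cache[max_gap_days] = merge_enrollment_spans(
                self.enrollment_spans, max_gap_days=max_gap_days
            )
        return self._obs_cache[max_gap_days]


def merge_enrollment_spans(
    spans: pd.DataFrame,
    max_gap_days: int = 30,
    gap_rule: Literal["uncovered_days", "date_difference"] = "uncovered_days",
) -> pd.DataFrame:
    """Consolidate raw enrollment spans into disjoint observation periods.

    Two consecutive spans (after sorting by start date) fall into the same
    observation period when they overlap or when the gap between them does
    not exceed ``max_gap_days``. Under the default ``uncovered_days`` rule
    the gap is the number of uncovered days strictly between the spans
    (``next_start − prev_end − 1``); ``date_difference`` instead compares
    ``next_start − prev_end``. Overlapping or duplicate spans are legal and
    are unioned silently.

    Returns a frame with ``person_id, start_date, end_date, ordinal`` where
    ordinals rank a person's periods by start date (1-based).
    """
    if max_gap_days < 0:
        raise ValueError("max_gap_days must be >= 0")
    bad = spans[spans["start_date"] > spans["end_date"]]
    if len(bad):
        rows = bad[["person_id", "start_date", "end_date"]].head(10)
        raise SchemaError(f"enrollment_span: start_date > end_date:\n{rows}")
    if spans.empty:
        return pd.DataFrame(
            {
                "person_id": pd.Series([], dtype=object),
                "start_date": pd.Series([], dtype="datetime64[ns]"),
                "end_date": pd.Series([], dtype="datetime64[ns]"),
                "ordinal": pd.Series([], dtype=np.int64),
            }
        )

    s = spans.sort_values(
        ["person_id", "start_date", "end_date"], kind="mergesort"
    ).reset_index(drop=True)
    grp = s.groupby("person_id", sort=False)
    reach = grp["end_date"].cummax()  # furthest coverage end seen so far
    prev_reach = reach.groupby(s["person_id"], sort=False).shift(1)
    gap = (s["start_date"] - prev_reach).dt.days
    if gap_rule == "uncovered_days":
        gap = gap - 1
    elif gap_rule != "date_difference":
        raise ValueError(f"unknown gap_rule: {gap_rule!r}")
    new_period = prev_reach.isna() | (gap > max_gap_days)
    period_key = new_period.cumsum()

    out = (
        s.assign(_k=period_key)
        .groupby("_k", sort=True)
        .agg(
            person_id=("person_id", "first"),
            start_date=("start_date", "min"),
            end_date=("end_date", "max"),
        )
        .reset_index(drop=True)
    )
    out["ordinal"] = out.groupby("person_id", sort=False).cumcount() + 1
    return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _read_table(path: Path, table: str) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={
            "person_id": str,
            "episode_id": str,
            "enrollment_id": str,
            "concept_code": str,
            "sex": str,
            "outcome": str,
            "domain": str,
            "visit_type": str,
        },
        keep_default_na=True,
    )
    _require_columns(df, table)
    df = _parse_dates(df, table)
    for col in ("year_of_birth", "month_of_birth", "day_of_birth"):
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    return df


def read_dataset(
    paths: Mapping[str, Path] | str | Path, validate: bool = True
) -> ClaimsDataset:
    """Load a dataset bundle from CSV files.

    ``paths`` is either a directory containing ``person.csv``,
    ``enrollment_span.csv``, ``pregnancy_episode.csv`` and
    ``clinical_event.csv``, or an explicit table-name → file-path mapping.
    """
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {name: base / f"{name}.csv" for name in TABLE_COLUMNS}
    tables = {name: _read_table(Path(p), name) for name, p in paths.items()}
    ds = ClaimsDataset(
        persons=tables["person"],
        enrollment_spans=tables["enrollment_span"],
        pregnancy_episodes=tables["pregnancy_episode"],
        clinical_events=tables["clinical_event"],
    )
    if validate:
        ds.validate()
    return ds


def write_dataset(dataset: ClaimsDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the four tables as CSV (ISO dates, empty string for absent values).

    Rows are written in a canonical sort order so identical datasets produce
    byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "person": dataset.persons.sort_values("person_id"),
        "enrollment_span": dataset.enrollment_spans.sort_values(
            ["person_id", "start_date", "end_date"]
        ),
        "pregnancy_episode": dataset.pregnancy_episodes.sort_values("episode_id"),
        "clinical_event": dataset.clinical_events.sort_values(
            ["person_id", "event_date", "domain", "concept_code"],
            kind="mergesort",
        ),
    }
    for name, df in tables.items():
        df = df[TABLE_COLUMNS[name]].copy()
        for col in df.columns:
            if col in _DATE_COLUMNS:
                df[col] = df[col].dt.strftime("%Y-%m-%d")
        path = out / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written[name] = path
    return written
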