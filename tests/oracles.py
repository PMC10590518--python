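"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a pipeline quantity from first principles — day-level
bitmaps and nested loops over plain Python dates — deliberately sharing no
code with the implementation under test.
"""

from __future__ import annotations

import calendar
from datetime import date, timedelta

import pandas as pd


def bitmap_merge(spans: list[tuple[date, date]], max_gap_days: int) -> list[tuple[date, date]]:
    """Day-resolution oracle for observation-period merging: mark covered
    days, then join consecutive covered runs separated by at most
    ``max_gap_days`` uncovered days."""
    days: set[int] = set()
    for s, e in spans:
        days.update(range(s.toordinal(), e.toordinal() + 1))
    if not days:
        return []
    ordered = sorted(days)
    runs = [[ordered[0], ordered[0]]]
    for d in ordered[1:]:
        if d == runs[-1][1] + 1:
            runs[-1][1] = d
        else:
            runs.append([d, d])
    merged = [runs[0]]
    for s, e in runs[1:]:
        uncovered = s - merged[-1][1] - 1
        if uncovered <= max_gap_days:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [
        (date.fromordinal(s), date.fromordinal(e)) for s, e in merged
    ]


def _person_periods(dataset, person_id: str, max_gap_days: int) -> list[tuple[date, date]]:
    spans = dataset.enrollment_spans
    mine = spans[spans["person_id"] == person_id]
    return bitmap_merge(
        [
            (s.date(), e.date())
            for s, e in zip(mine["start_date"], mine["end_date"])
        ],
        max_gap_days,
    )


def _in_any(d: date, periods: list[tuple[date, date]]) -> bool:
    return any(s <= d <= e for s, e in periods)


def oracle_candidate_mothers(dataset, config) -> set[tuple[str, str]]:
    """Exhaustive filter over every (person, episode) pair."""
    persons = dataset.persons.set_index("person_id")
    out = set()
    for ep in dataset.pregnancy_episodes.itertuples():
        if ep.person_id not in persons.index:
            continue
        p = persons.loc[ep.person_id]
        if p["sex"] != "female" or ep.outcome != "live_birth":
            continue
        age = ep.start_date.year - int(p["year_of_birth"])
        lo, hi = config.mother_age_range
        if not lo <= age <= hi:
            continue
        periods = _person_periods(dataset, ep.person_id, config.max_gap_days)
        if config.episode_anchor == "full":
            ok = any(
                s <= ep.start_date.date() and ep.end_date.date() <= e
                for s, e in periods
            )
        else:
            ok = _in_any(ep.end_date.date(), periods)
        if ok:
            out.add((ep.person_id, ep.episode_id))
    return out


def oracle_inferred_dob(row, first_start: date) -> date:
    year = int(row["year_of_birth"])
    month = int(row["month_of_birth"]) if pd.notna(row["month_of_birth"]) else first_start.month
    day = int(row["day_of_birth"]) if pd.notna(row["day_of_birth"]) else first_start.day
    day = min(day, calendar.monthrange(year, month)[1])
    return date(year, month, day)


def oracle_candidate_infants(dataset, mothers: set[tuple[str, str]], config) -> dict[str, tuple[str, date]]:
    """person_id → (enrollment_id, inferred_dob) for every candidate infant."""
    mother_persons = {m for m, _ in mothers}
    mother_plans = set(
        dataset.persons.loc[
            dataset.persons["person_id"].isin(mother_persons), "enrollment_id"
        ]
    )
    out = {}
    for row in dataset.persons.to_dict("records"):
        pid = row["person_id"]
        if pid in mother_persons or row["enrollment_id"] not in mother_plans:
            continue
        periods = _person_periods(dataset, pid, config.max_gap_days)
        if not periods:
            continue
        first_start = periods[0][0]
        if int(row["year_of_birth"]) != first_start.year:
            continue
        out[pid] = (row["enrollment_id"], oracle_inferred_dob(row, first_start))
    return out


def oracle_candidate_links(dataset, config) -> set[tuple[str, str, str, int]]:
    """Nested-loop oracle over all mother × infant pairs: returns
    (mother, episode, infant, delta_days) tuples."""
    mothers = oracle_candidate_mothers(dataset, config)
    infants = oracle_candidate_infants(dataset, mothers, config)
    persons = dataset.persons.set_index("person_id")
    episodes = dataset.pregnancy_episodes.set_index("episode_id")
    out = set()
    for mother_id, episode_id in mothers:
        plan = persons.loc[mother_id, "enrollment_id"]
        periods = _person_periods(dataset, mother_id, config.max_gap_days)
        ep_end = episodes.loc[episode_id, "end_date"].date()
        for infant_id, (infant_plan, dob) in infants.items():
            if infant_plan != plan or not _in_any(dob, periods):
                continue
            out.add((mother_id, episode_id, infant_id, (dob - ep_end).days))
    return out


def oracle_covariate_matrix(cohort, dataset, specs, charlson, max_gap_days=30):
    """Per-row recount of every covariate with plain Python loops."""
    from momlink.cohorts import MOTHER_COHORTS

    direction = "pre" if cohort.cohort_id in MOTHER_COHORTS else "post"
    episodes = dataset.pregnancy_episodes.set_index("episode_id")
    persons = dataset.persons.set_index("person_id")
    events_by_person: dict[str, list] = {}
    for row in dataset.clinical_events.to_dict("records"):
        events_by_person.setdefault(row["person_id"], []).append(row)

    matrix = []
    for member in cohort.members.to_dict("records"):
        pid = member["person_id"]
        index = pd.Timestamp(member["index_date"]).date()
        if direction == "pre":
            lo, hi = index - timedelta(days=365), index
        else:
            lo, hi = index, index + timedelta(days=365)
        in_window = [
            ev for ev in events_by_person.get(pid, [])
            if lo <= ev["event_date"].date() <= hi
        ]
        ep_id = member["episode_id"]
        has_episode = pd.notna(ep_id)
        ep_end = episodes.loc[ep_id, "end_date"].date() if has_episode else None
        ep_len = (
            (episodes.loc[ep_id, "end_date"] - episodes.loc[ep_id, "start_date"]).days
            if has_episode else 0
        )

        periods = _person_periods(dataset, pid, max_gap_days)
        qual = ep_end if (direction == "pre" and has_episode) else index
        holding = [p for p in periods if p[0] <= index <= p[1]]
        if not holding:
            holding = [p for p in periods if p[0] <= qual <= p[1]]
        if not holding:
            holding = periods[:1]
        assert holding, f"no usable period for {pid}"
        pstart, pend = holding[0]
        prior = max(0, (index - pstart).days)
        post_anchor = ep_end if (direction == "post" and has_episode) else index
        post = max(0, (pend - post_anchor).days)

        row_vals = {}
        for spec in specs:
            src = spec.source
            if src == "age":
                v = index.year - int(persons.loc[pid, "year_of_birth"])
            elif src == "prior_obs":
                v = prior
            elif src == "post_obs":
                v = post
            elif src == "episode_length":
                v = ep_len
            elif src == "charlson":
                codes = {
                    ev["concept_code"] for ev in in_window
                    if ev["domain"] == "condition"
                }
                v = charlson.score(codes)
            elif src == "distinct_codes":
                v = len(
                    {
                        ev["concept_code"] for ev in in_window
                        if ev["domain"] == spec.domain
                    }
                )
            elif src == "visit_count":
                v = sum(
                    1 for ev in in_window
                    if ev["domain"] == "visit" and ev["visit_type"] == spec.visit_type
                )
            elif src == "code_presence":
                v = int(
                    any(
                        ev["domain"] == spec.domain
                        and ev["concept_code"] == spec.code
                        for ev in in_window
                    )
                )
            elif src == "index_year":
                v = int(index.year == spec.value)
            elif src == "index_month":
                v = int(index.month == spec.value)
            else:
                raise AssertionError(src)
            row_vals[spec.covariate_id] = float(v)
        matrix.append(row_vals)
    return pd.DataFrame(matrix, columns=[s.covariate_id for s in specs])
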