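from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from momlink import ClaimsDataset, SimulationConfig, simulate

PLAN_POOL = [f"PL{i:02d}" for i in range(10)]


def random_spans(rng: np.random.Generator, n: int, window_days: int = 365 * 5):
    """Random, possibly overlapping enrollment spans for one person."""
    base = date(2012, 1, 1)
    out = []
    for _ in range(n):
        start = base + timedelta(days=int(rng.integers(0, window_days)))
        out.append((start, start + timedelta(days=int(rng.integers(0, 400)))))
    return out


def random_dataset(rng: np.random.Generator, n_persons: int = 30) -> ClaimsDataset:
    """A small adversarial dataset built directly (not via the generator):
    mixed sexes, shared plans, episodes on males, absent spans, partial
    month/day of birth, overlapping coverage."""
    base = date(2012, 1, 1)
    persons, spans, episodes, events = [], [], [], []
    ep_counter = 0
    for i in range(n_persons):
        pid = f"P{i:03d}"
        sex = "female" if rng.random() < 0.6 else "male"
        yob = int(rng.integers(1960, 2018))
        month = int(rng.integers(1, 13)) if rng.random() < 0.3 else None
        day = (
            int(rng.integers(1, 29)) if (month is not None and rng.random() < 0.5)
            else None
        )
        plan = PLAN_POOL[int(rng.integers(0, len(PLAN_POOL)))]
        persons.append((pid, sex, yob, month, day, plan))

        for s, e in random_spans(rng, int(rng.integers(0, 4))):
            spans.append((pid, s, e))

        for _ in range(int(rng.integers(0, 3))):
            ep_counter += 1
            end = base + timedelta(days=int(rng.integers(200, 365 * 5)))
            start = end - timedelta(days=int(rng.integers(150, 311)))
            outcome = ["live_birth", "stillbirth", "abortion", "ectopic"][
                int(rng.integers(0, 4) if rng.random() < 0.5 else 0)
            ]
            episodes.append((f"E{ep_counter:04d}", pid, start, end, outcome))

        for _ in range(int(rng.integers(0, 12))):
            d = base + timedelta(days=int(rng.integers(0, 365 * 5)))
            domain = ["condition", "drug", "procedure", "measurement", "visit"][
                int(rng.integers(0, 5))
            ]
            if domain == "visit":
                vt = ["outpatient", "inpatient", "emergency"][int(rng.integers(0, 3))]
                events.append((pid, d, "visit", "VISIT", vt))
            else:
                events.append((pid, d, domain, f"K{int(rng.integers(0, 12)):02d}", None))

    ds = ClaimsDataset(
        persons=pd.DataFrame(
            persons,
            columns=["person_id", "sex", "year_of_birth", "month_of_birth",
                     "day_of_birth", "enrollment_id"],
        ),
        enrollment_spans=pd.DataFrame(
            spans, columns=["person_id", "start_date", "end_date"]
        ),
        pregnancy_episodes=pd.DataFrame(
            episodes,
            columns=["episode_id", "person_id", "start_date", "end_date", "outcome"],
        ),
        clinical_events=pd.DataFrame(
            events,
            columns=["person_id", "event_date", "domain", "concept_code",
                     "visit_type"],
        ),
    )
    for col in ("year_of_birth", "month_of_birth", "day_of_birth"):
        ds.persons[col] = pd.array(ds.persons[col], dtype="Int64")
    for frame, cols in (
        (ds.enrollment_spans, ("start_date", "end_date")),
        (ds.pregnancy_episodes, ("start_date", "end_date")),
        (ds.clinical_events, ("event_date",)),
    ):
        for c in cols:
            frame[c] = pd.to_datetime(frame[c])
    return ds


def tiny_dataset(
    persons: list[tuple],
    spans: list[tuple],
    episodes: list[tuple] = (),
    events: list[tuple] = (),
) -> ClaimsDataset:
    """Hand-built fixture helper; tuples follow the table column orders."""
    ds = ClaimsDataset(
        persons=pd.DataFrame(
            persons,
            columns=["person_id", "sex", "year_of_birth", "month_of_birth",
                     "day_of_birth", "enrollment_id"],
        ),
        enrollment_spans=pd.DataFrame(
            list(spans), columns=["person_id", "start_date", "end_date"]
        ),
        pregnancy_episodes=pd.DataFrame(
            list(episodes),
            columns=["episode_id", "person_id", "start_date", "end_date", "outcome"],
        ),
        clinical_events=pd.DataFrame(
            list(events),
            columns=["person_id", "event_date", "domain", "concept_code",
                     "visit_type"],
        ),
    )
    for col in ("year_of_birth", "month_of_birth", "day_of_birth"):
        ds.persons[col] = pd.array(ds.persons[col], dtype="Int64")
    for frame, cols in (
        (ds.enrollment_spans, ("start_date", "end_date")),
        (ds.pregnancy_episodes, ("start_date", "end_date")),
        (ds.clinical_events, ("event_date",)),
    ):
        for c in cols:
            frame[c] = pd.to_datetime(frame[c]) if len(frame) else pd.to_datetime(
                pd.Series([], dtype=object)
            )
    return ds


@pytest.fixture(scope="session")
def default_sim():
    """One moderately sized default-parameter simulation shared by tests."""
    ds, gt = simulate(SimulationConfig(n_families=500, seed=11))
    return ds, gt
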