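"""Synthetic claims generator with ground-truth mother-infant pairs.

Emulates the structures a family-plan commercial claims database exposes to a
mother-infant linkage algorithm: a shared insurance enrollment ID per family,
enrollment churn and coverage gaps, de-identified infant birth dates (month and
day redacted; enrollment typically starts on the first of the month after
birth), twins, and households with more than one woman of child-bearing age.
Every generated live birth is recorded in a ground-truth table, including the
pairs the algorithm is expected to miss (infant enrolled on another plan,
maternal coverage ending before delivery), so downstream sensitivity and PPV
are measurable.

Determinism: a single master seed; each family draws from its own substream
(``SeedSequence(seed, spawn_key=(family,))``), so increasing ``n_families``
extends the population without reshuffling earlier families.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy import stats

from .model import ClaimsDataset, DOMAINS

# pregnancy episode length model (days): truncated normal
EPISODE_LENGTH_MEAN = 273.0
EPISODE_LENGTH_SD = 18.0
EPISODE_LENGTH_BOUNDS = (150.0, 310.0)

CONDITION_CODES = [f"COND_{i:03d}" for i in range(1, 41)]
DRUG_CODES = [f"DRUG_{i:03d}" for i in range(1, 31)]
PROCEDURE_CODES = [f"PROC_{i:03d}" for i in range(1, 31)]
MEASUREMENT_CODES = [f"MEAS_{i:03d}" for i in range(1, 31)]
_DOMAIN_CODES = {
    "condition": CONDITION_CODES,
    "drug": DRUG_CODES,
    "procedure": PROCEDURE_CODES,
    "measurement": MEASUREMENT_CODES,
}
VISIT_TYPE_PROBS = {"outpatient": 0.75, "inpatient": 0.10, "emergency": 0.15}


class DelayDistribution(BaseModel):
    """Days from true birth to the infant's first enrollment start.

    ``first_of_next_month`` models de-identified commercial claims where
    enrollment begins on the first of the month following birth;
    ``same_day`` models databases with accurate birth-date enrollment;
    ``uniform_days`` draws an integer delay uniformly from [low, high].
    """

    kind: Literal["first_of_next_month", "same_day", "uniform_days"] = (
        "first_of_next_month"
    )
    low: int = 0
    high: int = 0

    @model_validator(mode="after")
    def _check_bounds(self):
        if self.kind == "uniform_days" and not 0 <= self.low <= self.high:
            raise ValueError("uniform_days requires 0 <= low <= high")
        return self


class SimulationConfig(BaseModel):
    """Parameters of the synthetic claims population."""

    n_families: int = Field(gt=0)
    seed: int = 0
    study_start: date = date(2000, 1, 1)
    study_end: date = date(2021, 12, 31)
    p_twin: float = 0.032
    p_infant_on_other_plan: float = 0.10
    p_mother_churn: float = 0.08
    p_multi_mother_household: float = 0.05
    p_enrollment_gap: float = 0.20
    p_mother_age_outlier: float = 0.02
    p_extra_infant: float = 0.25
    enrollment_delay: DelayDistribution = Field(default_factory=DelayDistribution)
    outcome_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "live_birth": 0.70,
            "abortion": 0.25,
            "ectopic": 0.035,
            "stillbirth": 0.015,
        }
    )
    event_rate_per_year: dict[str, float] = Field(
        default_factory=lambda: {
            "condition": 4.0,
            "drug": 3.0,
            "procedure": 4.0,
            "measurement": 3.0,
            "visit": 6.0,
        }
    )
    infant_dob_redacted: bool = True

    @field_validator(
        "p_twin", "p_infant_on_other_plan", "p_mother_churn",
        "p_multi_mother_household", "p_enrollment_gap", "p_mother_age_outlier",
        "p_extra_infant",
    )
    @classmethod
    def _prob(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check(self):
        if set(self.outcome_mix) - set(
            {"live_birth", "stillbirth", "abortion", "ectopic"}
        ):
            raise ValueError("outcome_mix has unknown outcome categories")
        total = sum(self.outcome_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"outcome_mix must sum to 1 (got {total})")
        if any(v < 0 for v in self.outcome_mix.values()):
            raise ValueError("outcome_mix probabilities must be >= 0")
        if set(self.event_rate_per_year) - set(DOMAINS):
            raise ValueError("event_rate_per_year has unknown domains")
        window = (self.study_end - self.study_start).days
        if window < EPISODE_LENGTH_BOUNDS[1]:
            raise ValueError(
                "degenerate config: study window shorter than one pregnancy"
            )
        return self

    @classmethod
    def noise_free(cls, n_families: int, seed: int) -> "SimulationConfig":
        """A fully clean configuration: same-plan infants, same-day enrollment,
        one woman per plan, no churn, no coverage gaps — every true pair is
        recoverable by construction."""
        return cls(
            n_families=n_families,
            seed=seed,
            p_twin=0.0,
            p_infant_on_other_plan=0.0,
            p_mother_churn=0.0,
            p_multi_mother_household=0.0,
            p_enrollment_gap=0.0,
            p_mother_age_outlier=0.0,
            p_extra_infant=0.0,
            enrollment_delay=DelayDistribution(kind="same_day"),
        )


@dataclass
class GroundTruth:
    """True mother-infant pairs keyed by pregnancy episode.

    One row per (mother, infant, episode); twins share an episode_id. The
    table includes pairs that are unlinkable by design (other-plan infants,
    churned mothers) — evaluation separates "recoverable" from "all" truth.
    """

    pairs: pd.DataFrame  # mother_person_id, infant_person_id, episode_id, true_birth_date

    def pair_set(self) -> set[tuple[str, str]]:
        return set(
            zip(self.pairs["mother_person_id"], self.pairs["infant_person_id"])
        )


def _truncnorm_lengths(rng: np.random.Generator, n: int) -> np.ndarray:
    lo, hi = EPISODE_LENGTH_BOUNDS
    a = (lo - EPISODE_LENGTH_MEAN) / EPISODE_LENGTH_SD
    b = (hi - EPISODE_LENGTH_MEAN) / EPISODE_LENGTH_SD
    draws = stats.truncnorm.rvs(
        a, b, loc=EPISODE_LENGTH_MEAN, scale=EPISODE_LENGTH_SD,
        size=n, random_state=rng,
    )
    return np.rint(draws).astype(int)


def _first_of_next_month(d: date) -> date:
    if d.month == 12:
        return date(d.year + 1, 1, 1)
    return date(d.year, d.month + 1, 1)


def _enrollment_start(rng: np.random.Generator, birth: date,
                      delay: DelayDistribution) -> date:
    if delay.kind == "same_day":
        return birth
    if delay.kind == "first_of_next_month":
        return _first_of_next_month(birth)
    return birth + timedelta(days=int(rng.integers(delay.low, delay.high + 1)))


def _maybe_split_span(
    rng: np.random.Generator, start: date, end: date, p_gap: float
) -> list[tuple[date, date]]:
    """Optionally cut one gap (1-45 days) into a coverage span. Gaps of at most
    30 days get re-bridged by observation-period merging; longer ones split the
    person's observation history."""
    n_days = (end - start).days
    if n_days < 120 or rng.random() >= p_gap:
        return [(start, end)]
    gap_len = int(rng.integers(1, 46))
    cut = int(rng.integers(30, n_days - gap_len - 30))
    first_end = start + timedelta(days=cut)
    second_start = first_end + timedelta(days=gap_len + 1)
    return [(start, first_end), (second_start, end)]


def _draw_events(
    rng: np.random.Generator,
    person_id: str,
    spans: list[tuple[date, date]],
    rates: dict[str, float],
    rows: list,
) -> None:
    for span_start, span_end in spans:
        n_days = (span_end - span_start).days + 1
        years = n_days / 365.25
        for domain, rate in rates.items():
            n = rng.poisson(rate * years)
            if n == 0:
                continue
            offsets = rng.integers(0, n_days, size=n)
            if domain == "visit":
                kinds = rng.choice(
                    list(VISIT_TYPE_PROBS), size=n, p=list(VISIT_TYPE_PROBS.values())
                )
                for off, kind in zip(offsets, kinds):
                    rows.append(
                        (person_id, span_start + timedelta(days=int(off)),
                         "visit", "VISIT", kind)
                    )
            else:
                codes = _DOMAIN_CODES[domain]
                picks = rng.integers(0, len(codes), size=n)
                for off, pick in zip(offsets, picks):
                    rows.append(
                        (person_id, span_start + timedelta(days=int(off)),
                         domain, codes[pick], None)
                    )


def simulate(config: SimulationConfig) -> tuple[ClaimsDataset, GroundTruth]:
    """Generate a claims dataset bundle and its ground-truth link table."""
    persons: list = []
    spans: list = []
    episodes: list = []
    events: list = []
    truth: list = []

    study_start, study_end = config.study_start, config.study_end
    study_days = (study_end - study_start).days

    for fam in range(config.n_families):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(fam,))
        )
        plan = f"PLAN{fam:07d}"
        n_women = 2 if rng.random() < config.p_multi_mother_household else 1
        infant_counter = 0

        for w in range(n_women):
            mother_id = f"F{fam:07d}_M{w + 1}"
            n_episodes = min(1 + rng.poisson(0.6), 3)

            # episode end (delivery/outcome) dates, spaced ~1-2.5 years apart
            first_end_offset = int(
                rng.integers(int(EPISODE_LENGTH_BOUNDS[1]), study_days + 1)
            )
            ends: list[date] = [study_start + timedelta(days=first_end_offset)]
            for _ in range(n_episodes - 1):
                nxt = ends[-1] + timedelta(days=int(rng.integers(330, 900)))
                if nxt > study_end:
                    break
                ends.append(nxt)

            lengths = _truncnorm_lengths(rng, len(ends))
            outcomes = rng.choice(
                list(config.outcome_mix), size=len(ends),
                p=list(config.outcome_mix.values()),
            )

            # mother demographics: age at first episode start within range,
            # occasionally an outlier to exercise the age filter
            first_start = ends[0] - timedelta(days=int(lengths[0]))
            if rng.random() < config.p_mother_age_outlier:
                age = int(rng.choice([10, 11, 56, 58, 60]))
            else:
                age = int(rng.integers(18, 41))
            yob = first_start.year - age
            persons.append((mother_id, "female", yob, None, None, plan))

            # mother coverage: from before first episode start to after last end
            cov_start = max(
                study_start,
                first_start - timedelta(days=int(rng.integers(200, 1200))),
            )
            last_end = ends[-1]
            churned = rng.random() < config.p_mother_churn
            if churned:
                cov_end = last_end - timedelta(days=int(rng.integers(10, 120)))
            else:
                cov_end = last_end + timedelta(days=int(rng.integers(200, 1500)))
            cov_end = max(cov_end, cov_start)
            mother_spans = _maybe_split_span(
                rng, cov_start, cov_end, config.p_enrollment_gap
            )
            for s, e in mother_spans:
                spans.append((mother_id, s, e))
            _draw_events(
                rng, mother_id, mother_spans, config.event_rate_per_year, events
            )

            for k, (end, length, outcome) in enumerate(zip(ends, lengths, outcomes)):
                episode_id = f"E{fam:07d}_{w + 1}_{k + 1}"
                start = end - timedelta(days=int(length))
                episodes.append((episode_id, mother_id, start, end, outcome))
                if outcome != "live_birth":
                    continue

                n_infants = 2 if rng.random() < config.p_twin else 1
                for _ in range(n_infants):
                    infant_counter += 1
                    infant_id = f"F{fam:07d}_I{infant_counter}"
                    sex = "male" if rng.random() < 0.513 else "female"
                    if rng.random() < config.p_infant_on_other_plan:
                        infant_plan = f"{plan}_EXT"
                    else:
                        infant_plan = plan
                    if config.infant_dob_redacted:
                        month = day = None
                    else:
                        month, day = end.month, end.day
                    persons.append(
                        (infant_id, sex, end.year, month, day, infant_plan)
                    )
                    enr_start = _enrollment_start(rng, end, config.enrollment_delay)
                    enr_end = enr_start + timedelta(
                        days=int(rng.integers(200, 2000))
                    )
                    infant_spans = _maybe_split_span(
                        rng, enr_start, enr_end, config.p_enrollment_gap
                    )
                    for s, e in infant_spans:
                        spans.append((infant_id, s, e))
                    _draw_events(
                        rng, infant_id, infant_spans,
                        config.event_rate_per_year, events,
                    )
                    truth.append((mother_id, infant_id, episode_id, end))

            # an age-0 entrant whose birth episode is not captured in the
            # data (e.g. delivery predates the family's enrollment): a
            # candidate infant by construction but never linkable, and not a
            # ground-truth pair of any recorded episode
            if rng.random() < config.p_extra_infant:
                birth = ends[-1] + timedelta(days=int(rng.integers(150, 400)))
                if birth <= study_end:
                    infant_counter += 1
                    infant_id = f"F{fam:07d}_X{infant_counter}"
                    sex = "male" if rng.random() < 0.513 else "female"
                    if config.infant_dob_redacted:
                        month = day = None
                    else:
                        month, day = birth.month, birth.day
                    persons.append((infant_id, sex, birth.year, month, day, plan))
                    enr_start = _enrollment_start(
                        rng, birth, config.enrollment_delay
                    )
                    enr_end = enr_start + timedelta(days=int(rng.integers(200, 2000)))
                    infant_spans = _maybe_split_span(
                        rng, enr_start, enr_end, config.p_enrollment_gap
                    )
                    for s, e in infant_spans:
                        spans.append((infant_id, s, e))
                    _draw_events(
                        rng, infant_id, infant_spans,
                        config.event_rate_per_year, events,
                    )

    dataset = ClaimsDataset(
        persons=pd.DataFrame(
            persons,
            columns=[
                "person_id", "sex", "year_of_birth", "month_of_birth",
                "day_of_birth", "enrollment_id",
            ],
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
            columns=["person_id", "event_date", "domain", "concept_code", "visit_type"],
        ),
    )
    for col in ("month_of_birth", "day_of_birth"):
        dataset.persons[col] = pd.array(dataset.persons[col], dtype="Int64")
    dataset.persons["year_of_birth"] = pd.array(
        dataset.persons["year_of_birth"], dtype="Int64"
    )
    for frame, cols in (
        (dataset.enrollment_spans, ("start_date", "end_date")),
        (dataset.pregnancy_episodes, ("start_date", "end_date")),
        (dataset.clinical_events, ("event_date",)),
    ):
        for col in cols:
            frame[col] = pd.to_datetime(frame[col])

    gt = pd.DataFrame(
        truth,
        columns=["mother_person_id", "infant_person_id", "episode_id",
                 "true_birth_date"],
    )
    gt["true_birth_date"] = pd.to_datetime(gt["true_birth_date"])
    return dataset, GroundTruth(pairs=gt)


def write_ground_truth(gt: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = gt.pairs.sort_values(
        ["mother_person_id", "infant_person_id", "episode_id"]
    ).copy()
    out["true_birth_date"] = out["true_birth_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(
        path,
        dtype={"mother_person_id": str, "infant_person_id": str, "episode_id": str},
    )
    df["true_birth_date"] = pd.to_datetime(df["true_birth_date"], format="%Y-%m-%d")
    return GroundTruth(pairs=df)
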