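"""Deterministic four-step mother-infant linkage with attrition accounting.

Step 1  identify candidate mothers (female, live-birth episode, age 12-55 at
        episode start, delivery during insurance coverage) and candidate
        infants (age 0 at first observation-period start, plan shared with a
        candidate mother, date of birth inferred from enrollment start when
        month/day are redacted).
Step 2  candidate links: same enrollment ID and the infant's inferred DOB
        falls inside one of the mother's observation periods.
Step 3  probable links: inferred DOB within ±window days (default 60) of the
        mother's pregnancy-episode end date; optional first-births-only
        restriction is applied here.
Step 4  ambiguity exclusion: any infant still linked to more than one
        distinct mother has ALL of its links removed (no nearest-wins).

Everything is deterministic and independent of input row order.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field, asdict
from typing import Literal

import pandas as pd

from .model import ClaimsDataset

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "mother_person_id", "episode_id", "infant_person_id", "delta_days", "status",
]


@dataclass(frozen=True)
class LinkageConfig:
    """Tunable parameters of the linkage algorithm.

    window_days:        correspondence window around the episode end date
                        (inclusive; sensitivity values 30 and 90).
    first_births_only:  restrict each mother to her earliest qualifying
                        episode (applied at Step 3).
    max_gap_days:       enrollment-gap threshold for observation periods.
    mother_age_range:   inclusive age bounds at episode start; age is
                        computed from calendar years (month/day of birth are
                        generally absent for adults).
    episode_anchor:     which part of the episode must lie inside a mother's
                        observation period: the end (delivery) date, or the
                        full episode.
    ambiguity_check:    whether Step-4 multi-mother ambiguity is assessed
                        after (default) or before within-mother episode
                        resolution.
    """

    window_days: int = 60
    first_births_only: bool = False
    max_gap_days: int = 30
    mother_age_range: tuple[int, int] = (12, 55)
    episode_anchor: Literal["end", "full"] = "end"
    ambiguity_check: Literal["after_resolution", "before_resolution"] = (
        "after_resolution"
    )

    def __post_init__(self):
        if self.window_days < 0:
            raise ValueError("window_days must be >= 0")
        if self.mother_age_range[0] > self.mother_age_range[1]:
            raise ValueError("mother_age_range must be (low, high)")


@dataclass
class AttritionReport:
    """Per-step record counts of one linkage run.

    ``probable_links`` counts links surviving Step 3 *and* within-mother
    episode resolution, so ``final_links = probable_links −
    ambiguous_links_removed`` holds exactly; ``within_mother_removed``
    records the episode-resolution drops separately.
    """

    candidate_mothers: int = 0            # distinct mother persons
    candidate_mother_episodes: int = 0    # distinct (mother, episode) pairs
    candidate_infants: int = 0
    candidate_links: int = 0
    probable_links: int = 0
    within_mother_removed: int = 0
    ambiguous_links_removed: int = 0
    final_links: int = 0
    linked_mothers: int = 0
    linked_infants: int = 0
    prop_mothers_linked: float = 0.0
    prop_infants_linked: float = 0.0

    def finalize(self) -> "AttritionReport":
        self.prop_mothers_linked = (
            self.linked_mothers / self.candidate_mothers
            if self.candidate_mothers else 0.0
        )
        self.prop_infants_linked = (
            self.linked_infants / self.candidate_infants
            if self.candidate_infants else 0.0
        )
        return self

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LinkageResult:
    """Final links plus the intermediate artifacts each step produced."""

    links: pd.DataFrame                 # LINK_COLUMNS, status == "final"
    attrition: AttritionReport
    candidate_mothers: pd.DataFrame     # person_id, episode_id, episode_start, episode_end
    candidate_infants: pd.DataFrame     # person_id, enrollment_id, inferred_dob, ...
    candidate_links: pd.DataFrame = field(default=None)


def _empty_links() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mother_person_id": pd.Series([], dtype=object),
            "episode_id": pd.Series([], dtype=object),
            "infant_person_id": pd.Series([], dtype=object),
            "delta_days": pd.Series([], dtype="int64"),
            "status": pd.Series([], dtype=object),
        }
    )


def identify_candidate_mothers(
    dataset: ClaimsDataset, config: LinkageConfig = LinkageConfig()
) -> pd.DataFrame:
    """Step 1a: (person, episode) pairs satisfying the candidate-mother rule.

    A pregnancy episode qualifies iff the person is female, the outcome is a
    live birth, the mother's age at episode start lies within the configured
    range (inclusive), and the episode's anchor (end date by default) lies
    inside one of her observation periods.
    """
    obs = dataset.observation_periods(config.max_gap_days)
    ep = dataset.pregnancy_episodes.merge(
        dataset.persons[["person_id", "sex", "year_of_birth"]], on="person_id"
    )
    ep = ep[(ep["sex"] == "female") & (ep["outcome"] == "live_birth")]
    age = ep["start_date"].dt.year - ep["year_of_birth"].astype("int64")
    lo, hi = config.mother_age_range
    ep = ep[(age >= lo) & (age <= hi)]

    cand = ep.merge(obs, on="person_id", suffixes=("", "_obs"))
    inside = (cand["end_date"] >= cand["start_date_obs"]) & (
        cand["end_date"] <= cand["end_date_obs"]
    )
    if config.episode_anchor == "full":
        inside &= cand["start_date"] >= cand["start_date_obs"]
    cand = cand[inside]
    out = (
        cand[["person_id", "episode_id", "start_date", "end_date"]]
        .drop_duplicates(["person_id", "episode_id"])
        .rename(columns={"start_date": "episode_start", "end_date": "episode_end"})
        .sort_values(["person_id", "episode_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def _clamped_date(year: int, month: int, day: int) -> pd.Timestamp:
    last = calendar.monthrange(year, month)[1]
    if day > last:
        logger.debug("clamping inferred DOB %d-%02d-%02d to month end", year, month, day)
        day = last
    return pd.Timestamp(year=year, month=month, day=day)


def identify_candidate_infants(
    dataset: ClaimsDataset,
    candidate_mothers: pd.DataFrame,
    config: LinkageConfig = LinkageConfig(),
) -> pd.DataFrame:
    """Step 1b: persons aged 0 at first observation-period start, on a plan
    shared with a candidate mother, with an inferred date of birth.

    Month and day of birth are used verbatim when present; otherwise they are
    taken from the first observation period's start (the de-identification
    convention of commercial claims, where most inferred days are the 1st).
    """
    obs = dataset.observation_periods(config.max_gap_days)
    first = obs[obs["ordinal"] == 1][["person_id", "start_date"]].rename(
        columns={"start_date": "first_obs_start"}
    )
    p = dataset.persons.merge(first, on="person_id", how="inner")
    yob = p["year_of_birth"].astype("int64")
    start_year = p["first_obs_start"].dt.year
    late = p[yob > start_year]
    if len(late):
        logger.info(
            "%d persons with year_of_birth after first observation year excluded",
            len(late),
        )
    p = p[yob == start_year].copy()

    mother_plans = dataset.persons.loc[
        dataset.persons["person_id"].isin(candidate_mothers["person_id"].unique()),
        "enrollment_id",
    ].unique()
    p = p[p["enrollment_id"].isin(set(mother_plans))].copy()
    # infants cannot be their own mother's record
    p = p[~p["person_id"].isin(set(candidate_mothers["person_id"]))]

    if p.empty:
        return pd.DataFrame(
            {
                "person_id": pd.Series([], dtype=object),
                "enrollment_id": pd.Series([], dtype=object),
                "inferred_dob": pd.Series([], dtype="datetime64[ns]"),
                "month_inferred": pd.Series([], dtype=bool),
                "day_inferred": pd.Series([], dtype=bool),
            }
        )

    month_inferred = p["month_of_birth"].isna()
    day_inferred = p["day_of_birth"].isna()
    month = p["month_of_birth"].astype("Float64").fillna(
        pd.Series(p["first_obs_start"].dt.month, index=p.index, dtype="Float64")
    )
    day = p["day_of_birth"].astype("Float64").fillna(
        pd.Series(p["first_obs_start"].dt.day, index=p.index, dtype="Float64")
    )
    dobs = [
        _clamped_date(int(y), int(m), int(d))
        for y, m, d in zip(p["year_of_birth"], month, day)
    ]
    out = pd.DataFrame(
        {
            "person_id": p["person_id"].to_numpy(),
            "enrollment_id": p["enrollment_id"].to_numpy(),
            "inferred_dob": pd.to_datetime(dobs),
            "month_inferred": month_inferred.to_numpy(dtype=bool),
            "day_inferred": day_inferred.to_numpy(dtype=bool),
        }
    ).sort_values("person_id", kind="mergesort").reset_index(drop=True)
    return out


def build_candidate_links(
    candidate_mothers: pd.DataFrame,
    candidate_infants: pd.DataFrame,
    dataset: ClaimsDataset,
    config: LinkageConfig = LinkageConfig(),
) -> pd.DataFrame:
    """Step 2: one candidate link per (mother, episode, infant) where the
    plans match and the infant's inferred DOB lies inside one of the mother's
    observation periods (closed interval)."""
    if candidate_mothers.empty or candidate_infants.empty:
        return _empty_links()
    obs = dataset.observation_periods(config.max_gap_days)
    mothers = candidate_mothers.merge(
        dataset.persons[["person_id", "enrollment_id"]], on="person_id"
    )
    pairs = mothers.merge(
        candidate_infants[["person_id", "enrollment_id", "inferred_dob"]],
        on="enrollment_id",
        suffixes=("_mother", "_infant"),
    )
    if pairs.empty:
        return _empty_links()

    # DOB-in-coverage check against the mother's periods
    mother_obs = obs.rename(
        columns={
            "person_id": "person_id_mother",
            "start_date": "obs_start",
            "end_date": "obs_end",
        }
    )
    dob_pairs = pairs[["person_id_mother", "person_id_infant", "inferred_dob"]].drop_duplicates()
    dob_cov = dob_pairs.merge(mother_obs, on="person_id_mother")
    dob_cov = dob_cov[
        (dob_cov["inferred_dob"] >= dob_cov["obs_start"])
        & (dob_cov["inferred_dob"] <= dob_cov["obs_end"])
    ][["person_id_mother", "person_id_infant"]].drop_duplicates()
    pairs = pairs.merge(dob_cov, on=["person_id_mother", "person_id_infant"])
    if pairs.empty:
        return _empty_links()

    out = pd.DataFrame(
        {
            "mother_person_id": pairs["person_id_mother"],
            "episode_id": pairs["episode_id"],
            "infant_person_id": pairs["person_id_infant"],
            "delta_days": (
                pairs["inferred_dob"] - pairs["episode_end"]
            ).dt.days.astype("int64"),
            "status": "candidate",
        }
    )
    return (
        out.drop_duplicates(["mother_person_id", "episode_id", "infant_person_id"])
        .sort_values(
            ["mother_person_id", "episode_id", "infant_person_id"], kind="mergesort"
        )
        .reset_index(drop=True)
    )


def _earliest_episode(candidate_mothers: pd.DataFrame) -> pd.DataFrame:
    """Each mother's earliest qualifying episode (min end date, tie → min id)."""
    cm = candidate_mothers.sort_values(
        ["person_id", "episode_end", "episode_id"], kind="mergesort"
    )
    return cm.drop_duplicates("person_id", keep="first")[["person_id", "episode_id"]]


def _resolve_within_mother(links: pd.DataFrame,
                           episode_end: pd.Series) -> pd.DataFrame:
    """One infant matching several episodes of one mother keeps the episode
    with the smallest |delta_days| (tie → earlier episode end, then id)."""
    df = links.copy()
    df["_abs"] = df["delta_days"].abs()
    df["_end"] = df["episode_id"].map(episode_end)
    df = df.sort_values(
        ["mother_person_id", "infant_person_id", "_abs", "_end", "episode_id"],
        kind="mergesort",
    )
    df = df.drop_duplicates(["mother_person_id", "infant_person_id"], keep="first")
    return df.drop(columns=["_abs", "_end"])


def _drop_ambiguous(links: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Remove every link of any infant associated with >1 distinct mother."""
    n_mothers = links.groupby("infant_person_id")["mother_person_id"].transform(
        "nunique"
    )
    ambiguous = n_mothers > 1
    return links[~ambiguous], int(ambiguous.sum())


def refine_links(
    candidates: pd.DataFrame,
    config: LinkageConfig = LinkageConfig(),
    candidate_mothers: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, AttritionReport]:
    """Steps 3-4: window restriction, optional first-births-only restriction,
    within-mother episode resolution, and multi-mother ambiguity exclusion.

    Returns the final links (status ``final``, one row per infant) and an
    :class:`AttritionReport`; counts for Step-1/2 stages are filled in when
    ``candidate_mothers`` is supplied (the pipeline driver always does).
    """
    report = AttritionReport(candidate_links=len(candidates))
    if candidate_mothers is not None:
        report.candidate_mothers = candidate_mothers["person_id"].nunique()
        report.candidate_mother_episodes = len(candidate_mothers)
    report.candidate_infants = candidates["infant_person_id"].nunique()

    probable = candidates[
        candidates["delta_days"].abs() <= config.window_days
    ].copy()

    if config.first_births_only:
        source = candidate_mothers if candidate_mothers is not None else None
        if source is not None:
            keep = _earliest_episode(source)
        else:
            # fall back to the episodes visible in the candidate links,
            # using the episode end implied by delta (end = dob − delta)
            tmp = probable.copy()
            tmp["episode_end"] = -tmp["delta_days"]
            keep = (
                tmp.sort_values(
                    ["mother_person_id", "episode_id"], kind="mergesort"
                )
                .drop_duplicates("mother_person_id")[
                    ["mother_person_id", "episode_id"]
                ]
                .rename(columns={"mother_person_id": "person_id"})
            )
        keep_pairs = set(zip(keep["person_id"], keep["episode_id"]))
        mask = [
            (m, e) in keep_pairs
            for m, e in zip(probable["mother_person_id"], probable["episode_id"])
        ]
        probable = probable[mask]

    if candidate_mothers is not None:
        episode_end = candidate_mothers.set_index("episode_id")["episode_end"]
    else:
        episode_end = pd.Series(dtype="datetime64[ns]")

    if config.ambiguity_check == "before_resolution":
        unambiguous, removed = _drop_ambiguous(probable)
        resolved = _resolve_within_mother(unambiguous, episode_end)
        report.within_mother_removed = len(unambiguous) - len(resolved)
        # keep final = probable − removed exact under this ordering too
        report.probable_links = len(resolved) + removed
        report.ambiguous_links_removed = removed
        final = resolved
    else:
        resolved = _resolve_within_mother(probable, episode_end)
        report.within_mother_removed = len(probable) - len(resolved)
        report.probable_links = len(resolved)
        final, removed = _drop_ambiguous(resolved)
        report.ambiguous_links_removed = removed

    final = final.copy()
    final["status"] = "final"
    final = final.sort_values(
        ["mother_person_id", "episode_id", "infant_person_id"], kind="mergesort"
    ).reset_index(drop=True)

    report.final_links = len(final)
    report.linked_mothers = final["mother_person_id"].nunique()
    report.linked_infants = final["infant_person_id"].nunique()
    report.finalize()
    logger.info(
        "linkage: %d candidate links -> %d probable -> %d final "
        "(%d ambiguous removed)",
        report.candidate_links, report.probable_links,
        report.final_links, report.ambiguous_links_removed,
    )
    return final, report


def link_mother_infants(
    dataset: ClaimsDataset, config: LinkageConfig = LinkageConfig()
) -> LinkageResult:
    """Run the full four-step pipeline on a dataset."""
    mothers = identify_candidate_mothers(dataset, config)
    infants = identify_candidate_infants(dataset, mothers, config)
    candidates = build_candidate_links(mothers, infants, dataset, config)
    final, report = refine_links(candidates, config, candidate_mothers=mothers)
    report.candidate_infants = len(infants)
    report.finalize()
    return LinkageResult(
        links=final,
        attrition=report,
        candidate_mothers=mothers,
        candidate_infants=infants,
        candidate_links=candidates,
    )
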