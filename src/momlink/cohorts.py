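"""The nine evaluation cohorts: linked, non-linked, and all candidates.

Mother cohorts are indexed at pregnancy-episode start or end; infant cohorts
at the inferred date of birth:

1/2  mothers linked to ≥1 infant, one row per linked episode, indexed at
     episode start / end
3    linked infants at inferred DOB (anchor episode = the linked episode)
7/8  all candidate mothers, one row per candidate episode, start / end
9    all candidate infants at inferred DOB
4/5/6  the non-linked complements: 7−1, 8−2, 9−3

Subtraction is person-level by default: a mother with one linked and one
non-linked episode is removed from cohorts 4/5 entirely. Person-level
disjoint-union identities (persons of 1 ⊎ persons of 4 = persons of 7, and
likewise for the other two triples) hold on every dataset; an episode-level
subtraction variant, under which the row-level identities are exact as well,
is available via ``subtraction="episode"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import pandas as pd

from .linkage import LinkageResult

MEMBER_COLUMNS = ["person_id", "index_date", "episode_id"]

DEFINITIONS = {
    1: "linked mothers @ episode start",
    2: "linked mothers @ episode end",
    3: "linked infants @ inferred DOB",
    4: "non-linked mothers @ episode start",
    5: "non-linked mothers @ episode end",
    6: "non-linked infants @ inferred DOB",
    7: "candidate mothers @ episode start",
    8: "candidate mothers @ episode end",
    9: "candidate infants @ inferred DOB",
}

MOTHER_COHORTS = frozenset({1, 2, 4, 5, 7, 8})
INFANT_COHORTS = frozenset({3, 6, 9})


@dataclass
class Cohort:
    cohort_id: int
    definition: str
    members: pd.DataFrame  # MEMBER_COLUMNS

    def __len__(self) -> int:
        return len(self.members)

    @property
    def persons(self) -> set:
        return set(self.members["person_id"])


def _mk(cohort_id: int, members: pd.DataFrame) -> Cohort:
    members = (
        members[MEMBER_COLUMNS]
        .drop_duplicates()
        .sort_values(MEMBER_COLUMNS, kind="mergesort")
        .reset_index(drop=True)
    )
    return Cohort(cohort_id, DEFINITIONS[cohort_id], members)


def build_cohorts(
    result: LinkageResult,
    subtraction: Literal["person", "episode"] = "person",
) -> dict[int, Cohort]:
    """Materialize all nine cohorts from a linkage run."""
    cm = result.candidate_mothers
    ci = result.candidate_infants
    links = result.links

    mothers_start = cm.rename(columns={"episode_start": "index_date"})
    mothers_end = cm.rename(columns={"episode_end": "index_date"})
    c7 = _mk(7, mothers_start)
    c8 = _mk(8, mothers_end)
    infants_all = ci.rename(columns={"inferred_dob": "index_date"}).assign(
        episode_id=pd.NA
    )
    c9 = _mk(9, infants_all)

    linked_episodes = set(zip(links["mother_person_id"], links["episode_id"]))
    linked_mask = [
        (p, e) in linked_episodes
        for p, e in zip(cm["person_id"], cm["episode_id"])
    ]
    c1 = _mk(1, mothers_start[linked_mask])
    c2 = _mk(2, mothers_end[linked_mask])

    infant_episode = links.set_index("infant_person_id")["episode_id"]
    linked_infants = infants_all[
        infants_all["person_id"].isin(infant_episode.index)
    ].copy()
    linked_infants["episode_id"] = linked_infants["person_id"].map(infant_episode)
    c3 = _mk(3, linked_infants)

    if subtraction == "person":
        c4 = _mk(4, mothers_start[~mothers_start["person_id"].isin(c1.persons)])
        c5 = _mk(5, mothers_end[~mothers_end["person_id"].isin(c2.persons)])
    elif subtraction == "episode":
        not_linked = [not m for m in linked_mask]
        c4 = _mk(4, mothers_start[not_linked])
        c5 = _mk(5, mothers_end[not_linked])
    else:
        raise ValueError(f"unknown subtraction mode: {subtraction!r}")
    c6 = _mk(6, infants_all[~infants_all["person_id"].isin(c3.persons)])

    return {c.cohort_id: c for c in (c1, c2, c3, c4, c5, c6, c7, c8, c9)}


def check_partition_identities(cohorts: dict[int, Cohort]) -> None:
    """Assert the person-level disjoint-union identities (1,4,7), (2,5,8),
    (3,6,9); raises AssertionError on violation."""
    for a, b, whole in ((1, 4, 7), (2, 5, 8), (3, 6, 9)):
        pa, pb, pw = cohorts[a].persons, cohorts[b].persons, cohorts[whole].persons
        assert pa.isdisjoint(pb), f"cohorts {a} and {b} share persons"
        assert pa | pb == pw, f"cohorts {a} ∪ {b} != cohort {whole}"


def write_cohorts(cohorts: dict[int, Cohort], path: str | Path) -> Path:
    """Write all cohorts to one CSV: cohort_id, person_id, index_date, episode_id."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for cid in sorted(cohorts):
        df = cohorts[cid].members.copy()
        df.insert(0, "cohort_id", cid)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["index_date"] = pd.to_datetime(out["index_date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, lineterminator="\n")
    return path
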