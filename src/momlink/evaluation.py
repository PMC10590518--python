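"""Ground-truth recovery metrics and correspondence-distribution statistics.

With simulated data the generator's ground truth makes linkage quality
directly measurable. Sensitivity is reported against two denominators:

* *all* true pairs — including pairs unlinkable by design (infant enrolled
  on another plan, maternal coverage churn, enrollment-start year rolling
  past the birth year), and
* *recoverable* pairs — those that satisfy the algorithm's own Step-1..3
  preconditions (candidate mother and infant, shared plan, DOB inside the
  mother's coverage, within the correspondence window), so the only possible
  losses are Step-4 ambiguity exclusions.

Correspondence statistics summarize the signed day offset between an
infant's inferred DOB and the linked mother's delivery date: the share of
links at |Δ| = 0 and within ±7/±14/±30 days, plus mean, SD and median of
the signed offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import (
    LinkageConfig,
    build_candidate_links,
    identify_candidate_infants,
    identify_candidate_mothers,
)
from .model import ClaimsDataset
from .simulate import GroundTruth


@dataclass
class CorrespondenceStats:
    n: int
    share_same_day: float | None
    share_within_7: float | None
    share_within_14: float | None
    share_within_30: float | None
    mean_delta: float | None
    sd_delta: float | None
    median_delta: float | None


@dataclass
class LinkageMetrics:
    n_true_pairs: int
    n_recoverable: int | None
    n_final_links: int
    n_correct: int
    n_episode_mismatch: int     # correct pair, different episode attributed
    sensitivity_all: float
    sensitivity_recoverable: float | None
    ppv: float | None
    correspondence: CorrespondenceStats
    prop_mothers_linked: float | None = None
    prop_infants_linked: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)

    def write_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")
        return path


def correspondence_stats(final_links: pd.DataFrame) -> CorrespondenceStats:
    """Distribution of the inferred-DOB − delivery-date offset over links."""
    n = len(final_links)
    if n == 0:
        return CorrespondenceStats(0, None, None, None, None, None, None, None)
    delta = final_links["delta_days"].to_numpy(dtype=float)
    adelta = np.abs(delta)
    sd = float(np.std(delta, ddof=1)) if n > 1 else 0.0
    return CorrespondenceStats(
        n=n,
        share_same_day=float(np.mean(adelta == 0)),
        share_within_7=float(np.mean(adelta <= 7)),
        share_within_14=float(np.mean(adelta <= 14)),
        share_within_30=float(np.mean(adelta <= 30)),
        mean_delta=float(np.mean(delta)),
        sd_delta=sd,
        median_delta=float(np.median(delta)),
    )


def recoverable_pairs(
    dataset: ClaimsDataset,
    truth: GroundTruth,
    config: LinkageConfig = LinkageConfig(),
) -> pd.DataFrame:
    """True pairs that satisfy the Step-1..3 preconditions on this dataset
    (same plan, candidate on both sides, DOB in coverage, within window)."""
    mothers = identify_candidate_mothers(dataset, config)
    infants = identify_candidate_infants(dataset, mothers, config)
    candidates = build_candidate_links(mothers, infants, dataset, config)
    in_window = candidates[candidates["delta_days"].abs() <= config.window_days]
    reachable = in_window[["mother_person_id", "infant_person_id"]].drop_duplicates()
    return truth.pairs.merge(
        reachable,
        on=["mother_person_id", "infant_person_id"],
    ).drop_duplicates(["mother_person_id", "infant_person_id"])


def score_links(
    final_links: pd.DataFrame,
    truth: GroundTruth,
    dataset: ClaimsDataset | None = None,
    config: LinkageConfig = LinkageConfig(),
    attrition=None,
) -> LinkageMetrics:
    """Score final links against ground truth.

    A link is correct iff its (mother, infant) pair is a true pair; a correct
    pair attributed to a different pregnancy episode stays correct but is
    counted in ``n_episode_mismatch``. Recoverable-denominator sensitivity is
    computed when the dataset is supplied.
    """
    true_pairs = truth.pairs[
        ["mother_person_id", "infant_person_id", "episode_id"]
    ].drop_duplicates(["mother_person_id", "infant_person_id"])
    n_truth = len(true_pairs)
    n_final = len(final_links)

    hits = final_links.merge(
        true_pairs,
        on=["mother_person_id", "infant_person_id"],
        suffixes=("", "_true"),
    )
    n_correct = len(hits)
    n_mismatch = int((hits["episode_id"] != hits["episode_id_true"]).sum())

    sensitivity_all = n_correct / n_truth if n_truth else 0.0
    ppv = n_correct / n_final if n_final else None

    n_recoverable = None
    sens_rec = None
    if dataset is not None:
        rec = recoverable_pairs(dataset, truth, config)
        n_recoverable = len(rec)
        rec_hits = hits.merge(
            rec[["mother_person_id", "infant_person_id"]],
            on=["mother_person_id", "infant_person_id"],
        )
        sens_rec = len(rec_hits) / n_recoverable if n_recoverable else None

    return LinkageMetrics(
        n_true_pairs=n_truth,
        n_recoverable=n_recoverable,
        n_final_links=n_final,
        n_correct=n_correct,
        n_episode_mismatch=n_mismatch,
        sensitivity_all=sensitivity_all,
        sensitivity_recoverable=sens_rec,
        ppv=ppv,
        correspondence=correspondence_stats(final_links),
        prop_mothers_linked=(
            attrition.prop_mothers_linked if attrition is not None else None
        ),
        prop_infants_linked=(
            attrition.prop_infants_linked if attrition is not None else None
        ),
    )
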