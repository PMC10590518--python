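"""Index-anchored covariate construction and standardized-mean-difference
comparison between linked and non-linked cohorts.

Covariates are measured in a one-year window around each cohort row's index
date, inclusive on both ends: mother cohorts look back (``[index−365,
index]``), infant cohorts look forward (``[index, index+365]``). For linked
infants, post-index observation time is measured from the linked mother's
delivery date (the true birth date) rather than the inferred DOB; event
windows stay anchored at the inferred DOB.

The standardized mean difference is reported as (non-linked − linked) in
units of a pooled standard deviation, so a covariate larger in the linked
cohort has a negative SMD. |SMD| > 0.1 is flagged as a meaningful imbalance.
Two denominator conventions are implemented:

* ``pooled_half`` — sqrt((s_a² + s_b²)/2), the textbook two-sample pooling;
* ``root_sum``   — sqrt(s_a² + s_b²).

Large claims-characterization tooling (e.g. the OHDSI feature-extraction
stack) pools binary prevalences with ``pooled_half`` but continuous
covariates with ``root_sum``; those are the defaults here so output is
comparable with published claims characterization tables. Both are
switchable per call.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .charlson import CharlsonMap, default_charlson_map
from .cohorts import Cohort, INFANT_COHORTS, MOTHER_COHORTS
from .model import ClaimsDataset, VISIT_TYPES

logger = logging.getLogger(__name__)

WINDOW_DAYS = 365
SMD_THRESHOLD = 0.1

Convention = Literal["pooled_half", "root_sum"]
COUNT_DOMAINS = ("condition", "drug", "procedure", "measurement")


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: what it measures and how.

    kind drives the SMD variance model (``binary_presence`` → p(1−p);
    ``count_distinct``/``continuous`` → sample variance). ``source`` selects
    the construction rule; ``domain``/``code``/``visit_type``/``value``
    parameterize it.
    """

    covariate_id: str
    kind: Literal["binary_presence", "count_distinct", "continuous"]
    source: str
    domain: str | None = None
    code: str | None = None
    visit_type: str | None = None
    value: int | None = None


def default_covariate_specs(
    dataset: ClaimsDataset, cohort_kind: Literal["mother", "infant"]
) -> list[CovariateSpec]:
    """The standard covariate battery: per-code presence, distinct-code
    counts per domain, visit counts per type, age, prior/post observation
    time, Charlson index, index year/month one-hots, and (for mothers)
    pregnancy episode length."""
    specs: list[CovariateSpec] = [
        CovariateSpec("age_years", "continuous", "age"),
        CovariateSpec("prior_obs_days", "continuous", "prior_obs"),
        CovariateSpec("post_obs_days", "continuous", "post_obs"),
        CovariateSpec("charlson_index", "continuous", "charlson"),
    ]
    if cohort_kind == "mother":
        specs.append(
            CovariateSpec("episode_length_days", "continuous", "episode_length")
        )
    for domain in COUNT_DOMAINS:
        specs.append(
            CovariateSpec(f"distinct_{domain}s", "count_distinct",
                          "distinct_codes", domain=domain)
        )
    for vt in VISIT_TYPES:
        specs.append(
            CovariateSpec(f"visits_{vt}", "count_distinct", "visit_count",
                          visit_type=vt)
        )
    ev = dataset.clinical_events
    codes = (
        ev[ev["domain"] != "visit"][["domain", "concept_code"]]
        .drop_duplicates()
        .sort_values(["domain", "concept_code"])
    )
    for domain, code in codes.itertuples(index=False):
        specs.append(
            CovariateSpec(f"{domain}:{code}", "binary_presence",
                          "code_presence", domain=domain, code=code)
        )
    years = sorted(
        set(dataset.enrollment_spans["start_date"].dt.year)
        | set(dataset.enrollment_spans["end_date"].dt.year)
    )
    if years:
        for y in range(min(years), max(years) + 1):
            specs.append(
                CovariateSpec(f"index_year_{y}", "binary_presence",
                              "index_year", value=y)
            )
    for mth in range(1, 13):
        specs.append(
            CovariateSpec(f"index_month_{mth}", "binary_presence",
                          "index_month", value=mth)
        )
    return specs


def _window_bounds(index: pd.Series, direction: str) -> tuple[pd.Series, pd.Series]:
    delta = pd.Timedelta(days=WINDOW_DAYS)
    if direction == "pre":
        return index - delta, index
    return index, index + delta


def cohort_window_direction(cohort: Cohort) -> str:
    if cohort.cohort_id in MOTHER_COHORTS:
        return "pre"
    if cohort.cohort_id in INFANT_COHORTS:
        return "post"
    raise ValueError(f"unknown cohort id {cohort.cohort_id}")


def build_covariates(
    cohort: Cohort,
    dataset: ClaimsDataset,
    specs: Sequence[CovariateSpec],
    charlson: CharlsonMap | None = None,
    max_gap_days: int = 30,
    window: str | None = None,
) -> pd.DataFrame:
    """Covariate matrix: one row per cohort row, one column per spec.

    Raises if any cohort row's index date lies outside all of the person's
    observation periods (that would violate cohort construction).
    """
    if charlson is None:
        charlson = default_charlson_map()
    direction = window or cohort_window_direction(cohort)
    m = cohort.members.reset_index(drop=True).copy()
    n = len(m)
    m["row"] = np.arange(n)
    m["index_date"] = pd.to_datetime(m["index_date"])
    lo, hi = _window_bounds(m["index_date"], direction)
    m["win_lo"], m["win_hi"] = lo, hi

    if n:
        ev = dataset.clinical_events.merge(
            m[["row", "person_id", "win_lo", "win_hi"]], on="person_id"
        )
        evw = ev[(ev["event_date"] >= ev["win_lo"]) & (ev["event_date"] <= ev["win_hi"])]
    else:
        evw = dataset.clinical_events.iloc[0:0].assign(row=pd.Series(dtype=int))

    cols: dict[str, np.ndarray] = {}
    rows_idx = pd.RangeIndex(n)

    # --- event-derived pieces, computed once -------------------------------
    nonvisit = evw[evw["domain"] != "visit"]
    presence = nonvisit[["row", "domain", "concept_code"]].drop_duplicates()
    presence_keys = set(
        zip(presence["row"], presence["domain"], presence["concept_code"])
    )
    distinct = (
        nonvisit.groupby(["row", "domain"])["concept_code"].nunique()
        if len(nonvisit) else pd.Series(dtype="int64")
    )
    visits = evw[evw["domain"] == "visit"]
    visit_counts = (
        visits.groupby(["row", "visit_type"]).size()
        if len(visits) else pd.Series(dtype="int64")
    )
    cond = nonvisit[nonvisit["domain"] == "condition"][
        ["row", "concept_code"]
    ].drop_duplicates()
    if len(cond):
        cats = cond.assign(
            category=cond["concept_code"].map(charlson.code_to_category)
        ).dropna(subset=["category"]).drop_duplicates(["row", "category"])
        charlson_scores = (
            cats.assign(w=cats["category"].map(charlson.category_weight))
            .groupby("row")["w"].sum()
        )
    else:
        charlson_scores = pd.Series(dtype="int64")

    # --- person / period-derived pieces ------------------------------------
    persons = dataset.persons.set_index("person_id")
    yob = m["person_id"].map(persons["year_of_birth"]).astype("int64")
    episodes = dataset.pregnancy_episodes.set_index("episode_id")
    ep_end = m["episode_id"].map(episodes["end_date"])
    ep_len = (
        m["episode_id"].map(episodes["end_date"])
        - m["episode_id"].map(episodes["start_date"])
    ).dt.days

    # Observation placement. The cohort's qualifying anchor (episode end for
    # mothers, first enrollment for infants) is guaranteed to lie inside a
    # period, but an episode-START index may legitimately precede the
    # mother's coverage; such rows fall back to the period holding the
    # qualifying anchor, with prior observation floored at zero. Rows with no
    # usable period at all violate cohort construction and raise.
    obs = dataset.observation_periods(max_gap_days)
    m_anchor = m[["row", "person_id", "index_date"]].copy()
    m_anchor["qual_anchor"] = (
        ep_end.fillna(m["index_date"]) if direction == "pre" else m["index_date"]
    )
    with_obs = m_anchor.merge(obs, on="person_id")
    holds_index = (with_obs["index_date"] >= with_obs["start_date"]) & (
        with_obs["index_date"] <= with_obs["end_date"]
    )
    holds_anchor = (with_obs["qual_anchor"] >= with_obs["start_date"]) & (
        with_obs["qual_anchor"] <= with_obs["end_date"]
    )
    first_period = with_obs["ordinal"] == 1
    with_obs["_pref"] = np.select(
        [holds_index, holds_anchor, first_period], [0, 1, 2], default=3
    )
    with_obs = with_obs[with_obs["_pref"] < 3].sort_values(
        ["row", "_pref", "ordinal"], kind="mergesort"
    )
    containing = with_obs.drop_duplicates("row")
    if len(containing) < n:
        missing = sorted(set(range(n)) - set(containing["row"]))
        bad = m.loc[m["row"].isin(missing[:10]), ["person_id", "index_date"]]
        raise ValueError(
            f"no usable observation period for cohort rows:\n{bad}"
        )
    containing = containing.set_index("row").reindex(rows_idx)
    prior_days = (
        (containing["index_date"] - containing["start_date"]).dt.days.clip(lower=0)
    )

    if direction == "post":
        # linked infants: follow-up measured from the true birth date
        anchor = ep_end.fillna(containing["index_date"])
    else:
        anchor = containing["index_date"]
    post_days = (containing["end_date"] - anchor).dt.days.clip(lower=0)

    # --- assemble columns in spec order -------------------------------------
    for spec in specs:
        if spec.source == "age":
            vals = (m["index_date"].dt.year - yob).to_numpy(dtype=float)
        elif spec.source == "prior_obs":
            vals = prior_days.to_numpy(dtype=float)
        elif spec.source == "post_obs":
            vals = post_days.to_numpy(dtype=float)
        elif spec.source == "episode_length":
            vals = ep_len.fillna(0).to_numpy(dtype=float)
        elif spec.source == "charlson":
            vals = charlson_scores.reindex(rows_idx, fill_value=0).to_numpy(dtype=float)
        elif spec.source == "distinct_codes":
            if len(distinct):
                s = distinct.xs(spec.domain, level="domain") if (
                    spec.domain in distinct.index.get_level_values("domain")
                ) else pd.Series(dtype="int64")
            else:
                s = pd.Series(dtype="int64")
            vals = s.reindex(rows_idx, fill_value=0).to_numpy(dtype=float)
        elif spec.source == "visit_count":
            if len(visit_counts) and spec.visit_type in visit_counts.index.get_level_values("visit_type"):
                s = visit_counts.xs(spec.visit_type, level="visit_type")
            else:
                s = pd.Series(dtype="int64")
            vals = s.reindex(rows_idx, fill_value=0).to_numpy(dtype=float)
        elif spec.source == "code_presence":
            vals = np.fromiter(
                ((r, spec.domain, spec.code) in presence_keys for r in range(n)),
                dtype=float, count=n,
            )
        elif spec.source == "index_year":
            vals = (m["index_date"].dt.year == spec.value).to_numpy(dtype=float)
        elif spec.source == "index_month":
            vals = (m["index_date"].dt.month == spec.value).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown covariate source: {spec.source!r}")
        cols[spec.covariate_id] = vals

    return pd.DataFrame(cols, index=rows_idx)


# ---------------------------------------------------------------------------
# standardized mean differences
# ---------------------------------------------------------------------------

@dataclass
class CovariateComparison:
    covariate_id: str
    kind: str
    mean_a: float   # linked
    sd_a: float
    n_a: int
    mean_b: float   # non-linked
    sd_b: float
    n_b: int
    smd: float
    flag_meaningful: bool = False
    flag_infinite: bool = False

    def __post_init__(self):
        if np.isfinite(self.smd):
            self.flag_meaningful = abs(self.smd) > SMD_THRESHOLD


def _denominator(va: float, vb: float, convention: Convention) -> float:
    if convention == "pooled_half":
        return float(np.sqrt((va + vb) / 2.0))
    if convention == "root_sum":
        return float(np.sqrt(va + vb))
    raise ValueError(f"unknown SMD convention: {convention!r}")


def compute_smd(
    covariate_id: str,
    kind: str,
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    continuous_convention: Convention = "root_sum",
    binary_convention: Convention = "pooled_half",
) -> CovariateComparison:
    """SMD of one covariate between cohort a (linked) and b (non-linked).

    Sign convention: (mean_b − mean_a) / denominator, so a covariate larger
    among the linked carries a negative SMD. Binary covariates use the
    Bernoulli variance p(1−p) regardless of the supplied sd.
    """
    binary = kind == "binary_presence"
    if binary:
        va, vb = mean_a * (1 - mean_a), mean_b * (1 - mean_b)
        sd_a, sd_b = float(np.sqrt(va)), float(np.sqrt(vb))
        denom = _denominator(va, vb, binary_convention)
    else:
        denom = _denominator(sd_a**2, sd_b**2, continuous_convention)

    infinite = False
    if n_a == 0 or n_b == 0 or np.isnan(mean_a) or np.isnan(mean_b):
        smd = float("nan")
    elif denom == 0.0:
        if mean_a == mean_b:
            smd = 0.0
        else:
            smd = float(np.inf) if mean_b > mean_a else float(-np.inf)
            infinite = True
            warnings.warn(
                f"{covariate_id}: zero pooled SD with unequal means; "
                "SMD reported as infinite", stacklevel=2,
            )
    else:
        smd = (mean_b - mean_a) / denom
    return CovariateComparison(
        covariate_id, kind, mean_a, sd_a, n_a, mean_b, sd_b, n_b, smd,
        flag_infinite=infinite,
    )


def _column_stats(matrix: pd.DataFrame, covariate_id: str) -> tuple[float, float, int]:
    n = len(matrix)
    if n == 0:
        return float("nan"), float("nan"), 0
    col = matrix[covariate_id]
    mean = float(col.mean())
    if n == 1:
        logger.warning("cohort of size 1: sd reported as 0 for %s", covariate_id)
        return mean, 0.0, 1
    return mean, float(col.std(ddof=1)), n


@dataclass
class CohortComparison:
    """All per-covariate comparisons between two cohorts plus the binary
    prevalence scatter table."""

    comparisons: pd.DataFrame  # one row per covariate, sorted by |smd| desc
    scatter: pd.DataFrame      # covariate_id, prev_linked, prev_nonlinked
    records: list[CovariateComparison] = field(default_factory=list)


def compare_matrices(
    matrix_a: pd.DataFrame,
    matrix_b: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    continuous_convention: Convention = "root_sum",
    binary_convention: Convention = "pooled_half",
) -> CohortComparison:
    """Compare two covariate matrices over the union covariate set (a column
    absent from one matrix is treated as all-zero there)."""
    records = []
    for spec in specs:
        cid = spec.covariate_id
        ma = matrix_a if cid in matrix_a.columns else matrix_a.assign(**{cid: 0.0})
        mb = matrix_b if cid in matrix_b.columns else matrix_b.assign(**{cid: 0.0})
        mean_a, sd_a, n_a = _column_stats(ma, cid)
        mean_b, sd_b, n_b = _column_stats(mb, cid)
        records.append(
            compute_smd(
                cid, spec.kind, mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                continuous_convention=continuous_convention,
                binary_convention=binary_convention,
            )
        )
    comp = pd.DataFrame([vars(r) for r in records])
    comp["_abs"] = comp["smd"].abs()
    comp = (
        comp.sort_values(["_abs", "covariate_id"], ascending=[False, True],
                         kind="mergesort", na_position="last")
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    binary_ids = [s.covariate_id for s in specs if s.kind == "binary_presence"]
    scat = comp[comp["covariate_id"].isin(binary_ids)][
        ["covariate_id", "mean_a", "mean_b"]
    ].rename(columns={"mean_a": "prev_linked", "mean_b": "prev_nonlinked"})
    return CohortComparison(
        comparisons=comp, scatter=scat.reset_index(drop=True), records=records
    )


def compare_cohorts(
    cohort_a: Cohort,
    cohort_b: Cohort,
    dataset: ClaimsDataset,
    specs: Sequence[CovariateSpec] | None = None,
    charlson: CharlsonMap | None = None,
    continuous_convention: Convention = "root_sum",
    binary_convention: Convention = "pooled_half",
    max_gap_days: int = 30,
) -> CohortComparison:
    """Build covariates for two same-kind cohorts and compare them.

    Cohort a is conventionally the linked cohort and b the non-linked one;
    SMDs are reported as (b − a)/pooled SD.
    """
    kind_a = cohort_window_direction(cohort_a)
    if kind_a != cohort_window_direction(cohort_b):
        raise ValueError("cohorts must share an anchor kind (mother vs infant)")
    if specs is None:
        specs = default_covariate_specs(
            dataset, "mother" if kind_a == "pre" else "infant"
        )
    ma = build_covariates(cohort_a, dataset, specs, charlson, max_gap_days)
    mb = build_covariates(cohort_b, dataset, specs, charlson, max_gap_days)
    return compare_matrices(
        ma, mb, specs,
        continuous_convention=continuous_convention,
        binary_convention=binary_convention,
    )


def write_comparisons(result: CohortComparison, comparisons_path, scatter_path=None):
    """comparisons.csv (all CovariateComparison fields) and scatter.csv."""
    from pathlib import Path

    comparisons_path = Path(comparisons_path)
    comparisons_path.parent.mkdir(parents=True, exist_ok=True)
    out = result.comparisons.copy()
    out.to_csv(comparisons_path, index=False, lineterminator="\n",
               float_format="%.10g")
    if scatter_path is not None:
        result.scatter.to_csv(Path(scatter_path), index=False,
                              lineterminator="\n", float_format="%.10g")
    return comparisons_path
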