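"""Four-step linkage: candidate identification, matching, refinement."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from momlink import (
    LinkageConfig,
    SimulationConfig,
    build_candidate_links,
    identify_candidate_infants,
    identify_candidate_mothers,
    link_mother_infants,
    refine_links,
    simulate,
)

from .conftest import random_dataset, tiny_dataset
from .oracles import oracle_candidate_infants, oracle_candidate_links, oracle_candidate_mothers

D = date


def mother_family(
    *, sex="female", yob=1985, outcome="live_birth",
    episode=(D(2015, 1, 10), D(2015, 10, 10)),
    mother_cov=(D(2013, 1, 1), D(2017, 12, 31)),
    infant_yob=2015, infant_cov=(D(2015, 10, 10), D(2017, 12, 31)),
    infant_plan="PLAN1", infant_month=None, infant_day=None,
):
    """One-family fixture: a potential mother, episode, and infant."""
    return tiny_dataset(
        persons=[
            ("M1", sex, yob, None, None, "PLAN1"),
            ("I1", "female", infant_yob, infant_month, infant_day, infant_plan),
        ],
        spans=[("M1", *mother_cov), ("I1", *infant_cov)],
        episodes=[("E1", "M1", *episode, outcome)],
    )


class TestCandidateMothers:
    def test_qualifying_mother_retained(self):
        ds = mother_family()
        out = identify_candidate_mothers(ds)
        assert list(zip(out["person_id"], out["episode_id"])) == [("M1", "E1")]

    def test_male_record_excluded(self):
        out = identify_candidate_mothers(mother_family(sex="male"))
        assert out.empty

    def test_non_live_birth_excluded(self):
        out = identify_candidate_mothers(mother_family(outcome="stillbirth"))
        assert out.empty

    @pytest.mark.parametrize("yob,expected", [
        (2003, True),   # age 12 at episode start: inclusive bound
        (2004, False),  # age 11
        (1960, True),   # age 55
        (1959, False),  # age 56
    ])
    def test_age_bounds_inclusive(self, yob, expected):
        out = identify_candidate_mothers(mother_family(yob=yob))
        assert (len(out) == 1) == expected

    def test_delivery_outside_coverage_excluded(self):
        out = identify_candidate_mothers(
            mother_family(mother_cov=(D(2013, 1, 1), D(2015, 9, 1)))
        )
        assert out.empty

    def test_full_episode_anchor_variant(self):
        # coverage starts mid-pregnancy: end-anchor accepts, full-episode rejects
        ds = mother_family(mother_cov=(D(2015, 5, 1), D(2017, 12, 31)))
        assert len(identify_candidate_mothers(ds)) == 1
        full = LinkageConfig(episode_anchor="full")
        assert identify_candidate_mothers(ds, full).empty

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_filter(self, seed):
        ds = random_dataset(np.random.default_rng(seed), n_persons=40)
        cfg = LinkageConfig()
        got = set(
            zip(*[identify_candidate_mothers(ds, cfg)[c]
                  for c in ("person_id", "episode_id")])
        )
        assert got == oracle_candidate_mothers(ds, cfg)


class TestCandidateInfants:
    def test_dob_inferred_from_enrollment_start(self):
        ds = mother_family(infant_cov=(D(2015, 7, 1), D(2017, 1, 1)))
        mothers = identify_candidate_mothers(ds)
        infants = identify_candidate_infants(ds, mothers)
        assert list(infants["person_id"]) == ["I1"]
        assert infants.loc[0, "inferred_dob"] == pd.Timestamp("2015-07-01")
        assert bool(infants.loc[0, "month_inferred"])

    def test_recorded_birth_components_take_precedence(self):
        ds = mother_family(
            infant_month=3, infant_day=14, infant_cov=(D(2015, 7, 1), D(2017, 1, 1))
        )
        infants = identify_candidate_infants(ds, identify_candidate_mothers(ds))
        assert infants.loc[0, "inferred_dob"] == pd.Timestamp("2015-03-14")
        assert not bool(infants.loc[0, "month_inferred"])

    def test_year_mismatch_not_a_candidate(self):
        ds = mother_family(infant_yob=2014, infant_cov=(D(2015, 1, 1), D(2017, 1, 1)))
        infants = identify_candidate_infants(ds, identify_candidate_mothers(ds))
        assert infants.empty

    def test_plan_must_be_shared_with_candidate_mother(self):
        ds = mother_family(infant_plan="OTHER")
        infants = identify_candidate_infants(ds, identify_candidate_mothers(ds))
        assert infants.empty

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        ds = random_dataset(np.random.default_rng(500 + seed), n_persons=40)
        cfg = LinkageConfig()
        mothers = identify_candidate_mothers(ds, cfg)
        got = identify_candidate_infants(ds, mothers, cfg)
        expected = oracle_candidate_infants(
            ds, oracle_candidate_mothers(ds, cfg), cfg
        )
        assert {
            pid: (plan, dob.date())
            for pid, plan, dob in zip(
                got["person_id"], got["enrollment_id"], got["inferred_dob"]
            )
        } == expected


class TestCandidateLinks:
    def test_same_plan_dob_in_coverage_links(self):
        ds = mother_family()
        links = _candidates(ds)
        assert len(links) == 1
        assert links.loc[0, "delta_days"] == 0
        assert links.loc[0, "status"] == "candidate"

    def test_dob_in_coverage_gap_no_link(self):
        # mother's coverage split by a 44-day gap containing the infant DOB
        ds = tiny_dataset(
            persons=[("M1", "female", 1985, None, None, "PLAN1"),
                     ("I1", "male", 2015, None, None, "PLAN1")],
            spans=[("M1", D(2013, 1, 1), D(2015, 10, 1)),
                   ("M1", D(2015, 11, 15), D(2017, 12, 31)),
                   ("I1", D(2015, 10, 20), D(2017, 12, 31))],
            episodes=[("E1", "M1", D(2015, 1, 1), D(2015, 9, 30), "live_birth")],
        )
        assert _candidates(ds).empty

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nested_loop_oracle(self, seed):
        ds = random_dataset(np.random.default_rng(900 + seed), n_persons=35)
        cfg = LinkageConfig()
        links = _candidates(ds, cfg)
        got = set(
            zip(links["mother_person_id"], links["episode_id"],
                links["infant_person_id"], links["delta_days"])
        )
        assert got == oracle_candidate_links(ds, cfg)


def _candidates(ds, cfg=LinkageConfig()):
    mothers = identify_candidate_mothers(ds, cfg)
    infants = identify_candidate_infants(ds, mothers, cfg)
    return build_candidate_links(mothers, infants, ds, cfg)


def _links_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["mother_person_id", "episode_id", "infant_person_id",
                 "delta_days", "status"],
    )


class TestRefineLinks:
    @pytest.mark.parametrize("delta,kept", [
        (60, True), (-60, True), (61, False), (-61, False), (0, True),
    ])
    def test_window_boundary_inclusive(self, delta, kept):
        cand = _links_frame([("M1", "E1", "I1", delta, "candidate")])
        final, report = refine_links(cand, LinkageConfig(window_days=60))
        assert (len(final) == 1) == kept
        assert report.final_links == report.probable_links - report.ambiguous_links_removed

    def test_two_mothers_one_infant_both_removed(self):
        """Multi-mother ambiguity is excluded outright, not nearest-wins."""
        cand = _links_frame([
            ("M1", "E1", "I1", 5, "candidate"),
            ("M2", "E2", "I1", 20, "candidate"),
        ])
        final, report = refine_links(cand, LinkageConfig())
        assert final.empty
        assert report.ambiguous_links_removed == 2
        assert report.final_links == report.probable_links - report.ambiguous_links_removed

    def test_within_mother_episode_resolution_nearest_delta(self):
        cand = _links_frame([
            ("M1", "E1", "I1", 40, "candidate"),
            ("M1", "E2", "I1", -3, "candidate"),
        ])
        final, report = refine_links(cand, LinkageConfig())
        assert list(final["episode_id"]) == ["E2"]
        assert report.within_mother_removed == 1
        assert report.ambiguous_links_removed == 0

    def test_within_mother_tie_prefers_earlier_episode_end(self):
        cm = pd.DataFrame(
            {
                "person_id": ["M1", "M1"],
                "episode_id": ["E1", "E2"],
                "episode_start": pd.to_datetime(["2014-01-01", "2015-01-01"]),
                "episode_end": pd.to_datetime(["2014-10-01", "2015-10-01"]),
            }
        )
        cand = _links_frame([
            ("M1", "E2", "I1", 10, "candidate"),
            ("M1", "E1", "I1", -10, "candidate"),
        ])
        final, _ = refine_links(cand, LinkageConfig(), candidate_mothers=cm)
        assert list(final["episode_id"]) == ["E1"]

    def test_first_births_only_keeps_earliest_episode(self):
        cm = pd.DataFrame(
            {
                "person_id": ["M1", "M1"],
                "episode_id": ["E1", "E2"],
                "episode_start": pd.to_datetime(["2014-01-01", "2016-01-01"]),
                "episode_end": pd.to_datetime(["2014-10-01", "2016-10-01"]),
            }
        )
        cand = _links_frame([
            ("M1", "E1", "I1", 2, "candidate"),
            ("M1", "E2", "I2", 2, "candidate"),
        ])
        final, _ = refine_links(
            cand, LinkageConfig(first_births_only=True), candidate_mothers=cm
        )
        assert list(final["episode_id"]) == ["E1"]
        assert list(final["infant_person_id"]) == ["I1"]


class TestEndToEnd:
    def test_noise_free_recovery_is_exact(self):
        ds, gt = simulate(SimulationConfig.noise_free(150, 21))
        result = link_mother_infants(ds)
        got = set(
            zip(result.links["mother_person_id"], result.links["infant_person_id"])
        )
        assert got == gt.pair_set()
        # and every link carries the right episode
        truth_eps = set(map(tuple, gt.pairs[
            ["mother_person_id", "infant_person_id", "episode_id"]
        ].itertuples(index=False)))
        got_eps = set(
            zip(result.links["mother_person_id"], result.links["infant_person_id"],
                result.links["episode_id"])
        )
        assert got_eps == truth_eps

    def test_window_monotone_on_ambiguity_free_data(self):
        ds, _ = simulate(
            SimulationConfig(n_families=300, seed=9, p_multi_mother_household=0.0)
        )
        counts = [
            link_mother_infants(ds, LinkageConfig(window_days=w)).attrition.final_links
            for w in (30, 60, 90)
        ]
        assert counts[0] <= counts[1] <= counts[2]

    def test_row_order_invariance(self, default_sim):
        ds, _ = default_sim
        base = link_mother_infants(ds)
        shuffled = type(ds)(
            persons=ds.persons.sample(frac=1, random_state=4).reset_index(drop=True),
            enrollment_spans=ds.enrollment_spans.sample(frac=1, random_state=5)
            .reset_index(drop=True),
            pregnancy_episodes=ds.pregnancy_episodes.sample(frac=1, random_state=6)
            .reset_index(drop=True),
            clinical_events=ds.clinical_events.sample(frac=1, random_state=7)
            .reset_index(drop=True),
        )
        other = link_mother_infants(shuffled)
        pd.testing.assert_frame_equal(base.links, other.links)
        assert base.attrition.to_dict() == other.attrition.to_dict()

    def test_driver_equals_step_composition(self, default_sim):
        ds, _ = default_sim
        cfg = LinkageConfig()
        driver = link_mother_infants(ds, cfg)
        mothers = identify_candidate_mothers(ds, cfg)
        infants = identify_candidate_infants(ds, mothers, cfg)
        cand = build_candidate_links(mothers, infants, ds, cfg)
        final, report = refine_links(cand, cfg, candidate_mothers=mothers)
        report.candidate_infants = len(infants)
        report.finalize()
        pd.testing.assert_frame_equal(driver.links, final)
        assert driver.attrition.to_dict() == report.to_dict()

    def test_each_infant_in_at_most_one_final_link(self, default_sim):
        ds, _ = default_sim
        links = link_mother_infants(ds).links
        assert links["infant_person_id"].is_unique
        a = link_mother_infants(ds).attrition
        assert a.linked_infants == a.final_links
        assert a.linked_mothers <= a.candidate_mothers
        assert a.linked_infants <= a.candidate_infants
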