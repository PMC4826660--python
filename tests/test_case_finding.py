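"""The ascertainment algorithm: selection, linkage, exclusions, overlap."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

import msprev
from msprev.case_finding import VENN_KEYS, share_pct

from conftest import small_config


def blank_dx(**kw):
    row = {f"dx{i}": "" for i in range(1, 7)}
    row.update(kw)
    return row


def tiny_bundle(
    hdr_rows=(), pharmed_rows=(), ter_rows=(), deaths=(), assistance=()
) -> msprev.RegistryBundle:
    hdr = pd.DataFrame(
        list(hdr_rows),
        columns=["person_id", "discharge_date"] + [f"dx{i}" for i in range(1, 7)],
    )
    pharmed = pd.DataFrame(
        list(pharmed_rows), columns=["person_id", "dispense_date", "drug"]
    )
    ter = pd.DataFrame(
        list(ter_rows), columns=["person_id", "exemption_code", "start_date"]
    )
    rencam = pd.DataFrame(list(deaths), columns=["person_id", "death_date"])
    assist = pd.DataFrame(
        list(assistance),
        columns=["person_id", "birth_date", "gender", "district_id", "lhu_id", "registered"],
    )
    pop = pd.DataFrame(
        [
            {"area_id": "D1", "area_level": "district", "age_band": b,
             "gender": g, "population": 1000}
            for b in msprev.DEFAULT_BANDING.labels
            for g in ("female", "male")
        ]
    )
    areas = pd.DataFrame([{"district_id": "D1", "lhu_id": "L1"}])
    return msprev.RegistryBundle(hdr, pharmed, ter, rencam, assist, pop, areas)


def assist_row(pid, registered=True):
    return {
        "person_id": pid, "birth_date": dt.date(1970, 6, 15), "gender": "female",
        "district_id": "D1", "lhu_id": "L1", "registered": registered,
    }


WINDOW = (dt.date(2006, 1, 1), dt.date(2011, 12, 31))
PREV_DAY = dt.date(2011, 12, 31)


class TestSelectCandidates:
    def test_window_boundaries(self):
        bundle = tiny_bundle(
            hdr_rows=[
                {"person_id": "in", "discharge_date": dt.date(2008, 5, 1),
                 **blank_dx(dx1="340.0")},
                {"person_id": "early", "discharge_date": dt.date(2005, 12, 31),
                 **blank_dx(dx1="340.0")},
                {"person_id": "edge", "discharge_date": dt.date(2006, 1, 1),
                 **blank_dx(dx1="340.0")},
                {"person_id": "nonms", "discharge_date": dt.date(2008, 5, 1),
                 **blank_dx(dx1="345.9")},
            ]
        )
        sel = msprev.select_candidates(bundle, WINDOW)
        assert set(sel["HDR"]["person_id"]) == {"in", "edge"}
        assert sel["PHARMED"].empty and sel["TER"].empty

    def test_person_in_two_sources(self):
        bundle = tiny_bundle(
            pharmed_rows=[{"person_id": "p", "dispense_date": dt.date(2007, 1, 1),
                           "drug": "NATALIZUMAB"}],
            ter_rows=[{"person_id": "p", "exemption_code": "046.340",
                       "start_date": dt.date(2009, 1, 1)}],
        )
        sel = msprev.select_candidates(bundle, WINDOW)
        assert set(sel["PHARMED"]["person_id"]) == {"p"}
        assert set(sel["TER"]["person_id"]) == {"p"}

    def test_empty_window_is_error(self):
        with pytest.raises(ValueError, match="window"):
            msprev.select_candidates(
                tiny_bundle(), (dt.date(2011, 1, 1), dt.date(2006, 1, 1))
            )


class TestLinkAndDeduplicate:
    def test_same_id_all_sources_one_case(self):
        cands = {
            "HDR": pd.DataFrame({"person_id": ["x"], "claim_date": [dt.date(2007, 5, 1)]}),
            "PHARMED": pd.DataFrame({"person_id": ["x"], "claim_date": [dt.date(2008, 1, 1)]}),
            "TER": pd.DataFrame({"person_id": ["x"], "claim_date": [dt.date(2006, 3, 2)]}),
        }
        linked = msprev.link_and_deduplicate(cands)
        assert len(linked) == 1
        assert linked["sources"].iloc[0] == "HDR|PHARMED|TER"
        assert linked["first_claim_date"].iloc[0] == dt.date(2006, 3, 2)

    def test_disjoint_ids_union_is_sum(self):
        cands = {
            "HDR": pd.DataFrame({"person_id": ["a", "b"], "claim_date": [dt.date(2007, 1, 1)] * 2}),
            "TER": pd.DataFrame({"person_id": ["c"], "claim_date": [dt.date(2007, 1, 1)]}),
        }
        assert len(msprev.link_and_deduplicate(cands)) == 3


class TestApplyExclusions:
    def _bundle(self):
        return tiny_bundle(
            hdr_rows=[
                {"person_id": p, "discharge_date": dt.date(2008, 1, 1),
                 **blank_dx(dx1="340.0")}
                for p in ("alive", "dead", "late_death", "gone", "missing")
            ],
            deaths=[
                {"person_id": "dead", "death_date": dt.date(2010, 1, 1)},
                {"person_id": "late_death", "death_date": dt.date(2012, 6, 1)},
            ],
            assistance=[
                assist_row("alive"),
                assist_row("dead"),
                assist_row("late_death"),
                assist_row("gone", registered=False),
            ],
        )

    def test_exclusion_accounting(self):
        cases, report = msprev.find_cases(self._bundle(), WINDOW, PREV_DAY)
        ids = set(cases["person_id"])
        # death after the prevalence day leaves the person prevalent
        assert ids == {"alive", "late_death"}
        assert report.excluded_deceased == 1
        # unregistered and absent-from-assistance both count as non-resident
        assert report.excluded_nonresident == 2
        assert report.union_count == 5

    def test_demographics_from_assistance(self):
        cases, _ = msprev.find_cases(self._bundle(), WINDOW, PREV_DAY)
        row = cases.set_index("person_id").loc["alive"]
        assert row["gender"] == "female"
        assert row["age_band"] == "35-44"  # born 1970-06-15, aged 41
        assert row["district_id"] == "D1" and row["lhu_id"] == "L1"

    def test_no_exclusions_identity(self):
        bundle = tiny_bundle(
            hdr_rows=[{"person_id": "a", "discharge_date": dt.date(2008, 1, 1),
                       **blank_dx(dx1="340.0")}],
            assistance=[assist_row("a")],
        )
        cases, report = msprev.find_cases(bundle, WINDOW, PREV_DAY)
        assert report.prevalent_count == report.union_count == 1


class TestOverlapAndRepeats:
    def test_published_share_arithmetic(self):
        assert share_pct(1150, 7377) == 15.6
        assert share_pct(1034, 7377) == 14.0
        assert share_pct(766, 7377) == 10.4
        assert share_pct(329, 1150) == 28.6
        assert share_pct(599, 766) == 78.2

    def test_single_triple_case(self):
        cases = pd.DataFrame({"person_id": ["x"], "sources": ["HDR|PHARMED|TER"]})
        counts, shares = msprev.source_overlap(cases)
        assert counts["HDR|PHARMED|TER"] == 1
        assert shares["HDR|PHARMED|TER"] == 100.0

    def test_empty_case_set_all_zero(self):
        counts, shares = msprev.source_overlap(
            pd.DataFrame(columns=["person_id", "sources"])
        )
        assert all(v == 0 for v in counts.values())

    def test_repeat_claims_counted_for_exclusive_cases(self):
        bundle = tiny_bundle(
            hdr_rows=[
                {"person_id": "multi", "discharge_date": dt.date(2008, 1, 1),
                 **blank_dx(dx1="340.0")},
                {"person_id": "multi", "discharge_date": dt.date(2009, 1, 1),
                 **blank_dx(dx1="340.0")},
                {"person_id": "single", "discharge_date": dt.date(2008, 1, 1),
                 **blank_dx(dx1="340.0")},
            ],
            assistance=[assist_row("multi"), assist_row("single")],
        )
        _, report = msprev.find_cases(bundle, WINDOW, PREV_DAY)
        hdr = report.repeat_claim_counts["HDR"]
        assert hdr["exclusive_cases"] == 2
        assert hdr["multi_claim_cases"] == 1
        assert hdr["multi_claim_pct"] == 50.0


class TestAgainstTruth:
    def test_ascertainment_equals_truth_capture_union(self, small_bundle):
        """Without deaths/emigration/noise, cases = truth persons captured anywhere."""
        cfg, bundle, truth = small_bundle
        cases, _ = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        expected = truth.loc[
            truth["true_ms"]
            & truth[["captured_hdr", "captured_pharmed", "captured_ter"]].any(axis=1),
            "person_id",
        ]
        assert set(cases["person_id"]) == set(expected)

    def test_venn_counts_sum_to_prevalent(self, small_bundle):
        cfg, bundle, _ = small_bundle
        _, report = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        assert sum(report.venn.values()) == report.prevalent_count
        for source in ("HDR", "PHARMED", "TER"):
            marginal = sum(v for k, v in report.venn.items() if source in k.split("|"))
            assert report.candidates_per_source[source] >= marginal

    def test_row_order_invariance(self, small_bundle):
        cfg, bundle, _ = small_bundle
        rng = np.random.default_rng(0)
        shuffled = msprev.RegistryBundle(
            **{
                name: df.sample(frac=1, random_state=rng.integers(2**31)).reset_index(drop=True)
                for name, df in bundle.tables().items()
            }
        )
        c1, _ = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        c2, _ = msprev.find_cases(shuffled, cfg.study_window, cfg.prevalence_day)
        key = ["person_id"]
        pd.testing.assert_frame_equal(
            c1.sort_values(key).reset_index(drop=True),
            c2.sort_values(key).reset_index(drop=True),
        )

    def test_idempotence_on_own_output(self, small_bundle):
        """Restricting the registries to the ascertained persons changes nothing."""
        cfg, bundle, _ = small_bundle
        cases, _ = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        ids = set(cases["person_id"])
        subset = msprev.RegistryBundle(
            hdr=bundle.hdr[bundle.hdr["person_id"].isin(ids)].reset_index(drop=True),
            pharmed=bundle.pharmed[bundle.pharmed["person_id"].isin(ids)].reset_index(drop=True),
            ter=bundle.ter[bundle.ter["person_id"].isin(ids)].reset_index(drop=True),
            rencam=bundle.rencam,
            assistance=bundle.assistance,
            population=bundle.population,
            areas=bundle.areas,
        )
        again, _ = msprev.find_cases(subset, cfg.study_window, cfg.prevalence_day)
        assert set(again["person_id"]) == ids

    def test_distractor_records_do_not_become_cases(self):
        cfg = small_config(seed=17, distractor_rate=0.01)
        bundle, truth = msprev.simulate_bundle(cfg)
        cases, _ = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        non_cases = set(truth.loc[~truth["true_ms"], "person_id"])
        assert not (set(cases["person_id"]) & non_cases)

    def test_all_venn_keys_present(self, small_bundle):
        cfg, bundle, _ = small_bundle
        _, report = msprev.find_cases(bundle, cfg.study_window, cfg.prevalence_day)
        assert tuple(report.venn) == VENN_KEYS
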