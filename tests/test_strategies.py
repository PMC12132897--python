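"""Strategy rules: toy oracles, boundaries, resource matching, tie-breaks."""

import numpy as np
import pandas as pd
import pytest

from cacscreen import (
    StrategyParameterError,
    age_sex_adjusted_guideline_strategy,
    fixed_threshold_strategy,
    guideline_strategy,
    selfreport_benchmarked_strategy,
)
from cacscreen.strategies import FIXED_THRESHOLD_PRESETS

from conftest import make_toy_cohort


# ---------------------------------------------------------------------------
# Brute-force oracles: literal rule application, no ranking machinery.
# ---------------------------------------------------------------------------

def oracle_guideline(rows):
    treated = set()
    scanned = set()
    for r in rows:
        if r["pce_category"] == "high":
            treated.add(r["id"])
        elif r["pce_category"] == "intermediate":
            scanned.add(r["id"])
            if r["cacs"] >= 100:
                treated.add(r["id"])
    return scanned, treated


def oracle_benchmarked(rows, n_scans, n_treat):
    by_prob = sorted(rows, key=lambda r: (-r["selfreport_probability"], r["id"]))
    scanned = by_prob[:n_scans]
    by_cac = sorted(
        scanned, key=lambda r: (-r["cacs"], -r["selfreport_probability"], r["id"])
    )
    return {r["id"] for r in scanned}, {r["id"] for r in by_cac[:n_treat]}


def oracle_fixed(rows, p_cut, c_cut):
    scanned = {r["id"] for r in rows if r["selfreport_probability"] > p_cut}
    treated = {r["id"] for r in rows if r["id"] in scanned and r["cacs"] > c_cut}
    return scanned, treated


def flags_to_sets(outcome):
    f = outcome.flags
    return (
        set(f.loc[f["scanned"], "id"]),
        set(f.loc[f["treatment_eligible"], "id"]),
    )


def random_small_cohort(rng):
    n = int(rng.integers(1, 13))
    df = make_toy_cohort(
        rng.choice(np.round(rng.random(8), 2), size=n),  # deliberate prob ties
        rng.choice([0.0, 0.0, 5.0, 20.0, 100.0, 450.0], size=n),
        pce_category=rng.choice(["low", "borderline", "intermediate", "high"], size=n),
    )
    return df


class TestGuidelineStrategy:
    def make(self, cat, cacs):
        return make_toy_cohort([0.5], [cacs], pce_category=[cat])

    def test_high_risk_treated_without_scan(self):
        oc = guideline_strategy(self.make("high", 0.0))
        f = oc.flags.iloc[0]
        assert f["treatment_eligible"] and f["visited"] and not f["scanned"]

    def test_intermediate_with_high_cac_scanned_and_treated(self):
        f = guideline_strategy(self.make("intermediate", 150.0)).flags.iloc[0]
        assert f["scanned"] and f["treatment_eligible"]

    def test_intermediate_with_low_cac_scanned_not_treated(self):
        f = guideline_strategy(self.make("intermediate", 50.0)).flags.iloc[0]
        assert f["scanned"] and not f["treatment_eligible"]

    def test_cac_threshold_is_closed_at_100(self):
        f = guideline_strategy(self.make("intermediate", 100.0)).flags.iloc[0]
        assert f["treatment_eligible"]

    def test_low_risk_never_scanned_or_treated_despite_high_cac(self):
        f = guideline_strategy(self.make("low", 400.0)).flags.iloc[0]
        assert f["visited"] and not f["scanned"] and not f["treatment_eligible"]

    def test_borderline_never_treated(self):
        f = guideline_strategy(self.make("borderline", 500.0)).flags.iloc[0]
        assert not f["scanned"] and not f["treatment_eligible"]

    def test_everyone_visited(self, scored_cohort):
        oc = guideline_strategy(scored_cohort)
        assert oc.n_visits == len(scored_cohort)

    def test_missing_category_rejected(self):
        df = make_toy_cohort([0.5], [0.0], pce_category=[None])
        with pytest.raises(ValueError):
            guideline_strategy(df)


class TestBenchmarkedStrategy:
    def test_six_person_worked_example(self):
        df = make_toy_cohort(
            [0.9, 0.8, 0.7, 0.3, 0.2, 0.1], [0.0, 500.0, 20.0, 900.0, 0.0, 0.0]
        )
        oc = selfreport_benchmarked_strategy(df, n_scans=3, n_treat=2)
        scanned, treated = flags_to_sets(oc)
        assert scanned == {"T000", "T001", "T002"}
        assert treated == {"T001", "T002"}  # CACS 500 and 20; unscanned 900 never eligible

    def test_saturation(self):
        df = make_toy_cohort([0.5, 0.4], [0.0, 10.0])
        oc = selfreport_benchmarked_strategy(df, n_scans=2, n_treat=2)
        assert oc.n_scans == 2 and oc.n_treated == 2

    def test_zero_treatment_cap(self):
        df = make_toy_cohort([0.5, 0.4], [100.0, 10.0])
        oc = selfreport_benchmarked_strategy(df, n_scans=2, n_treat=0)
        assert oc.n_treated == 0

    def test_visits_equal_scans(self):
        df = make_toy_cohort([0.9, 0.5, 0.1], [10.0, 5.0, 0.0])
        oc = selfreport_benchmarked_strategy(df, n_scans=2, n_treat=1)
        assert oc.n_visits == oc.n_scans == 2

    def test_invalid_caps_rejected(self):
        df = make_toy_cohort([0.5], [0.0])
        with pytest.raises(StrategyParameterError):
            selfreport_benchmarked_strategy(df, n_scans=2, n_treat=1)
        with pytest.raises(StrategyParameterError):
            selfreport_benchmarked_strategy(df, n_scans=1, n_treat=2)

    def test_treated_cacs_dominates_untreated_scanned(self, scored_cohort):
        oc = selfreport_benchmarked_strategy(scored_cohort, n_scans=1500, n_treat=800)
        f = oc.flags
        cacs = scored_cohort.set_index("id")["cacs"]
        treated_cacs = cacs[f.loc[f["treatment_eligible"], "id"]]
        leftover = cacs[f.loc[f["scanned"] & ~f["treatment_eligible"], "id"]]
        assert treated_cacs.min() >= leftover.max()

    def test_no_zero_cac_treated_when_positive_scans_suffice(self, scored_cohort):
        oc = selfreport_benchmarked_strategy(scored_cohort, n_scans=1500, n_treat=600)
        f = oc.flags
        cacs = scored_cohort.set_index("id")["cacs"]
        n_positive_scanned = (cacs[f.loc[f["scanned"], "id"]] > 0).sum()
        assert n_positive_scanned >= 600
        assert (cacs[f.loc[f["treatment_eligible"], "id"]] > 0).all()

    def test_event_capture_monotone_in_treatment_cap(self, scored_cohort):
        events = scored_cohort["event_chd_all"].to_numpy()
        captured = []
        for n_treat in (200, 400, 600, 800, 1000):
            oc = selfreport_benchmarked_strategy(scored_cohort, n_scans=1200, n_treat=n_treat)
            captured.append(int((oc.treated.to_numpy() & events).sum()))
        assert captured == sorted(captured)


class TestFixedThresholdStrategy:
    def test_five_person_worked_example(self):
        df = make_toy_cohort(
            [0.30, 0.25, 0.10, 0.05, 0.01], [10.0, 200.0, 999.0, 0.0, 0.0]
        )
        oc = fixed_threshold_strategy(df, 0.15, 15.0)
        scanned, treated = flags_to_sets(oc)
        assert scanned == {"T000", "T001"}
        assert treated == {"T001"}

    def test_vacuous_threshold(self):
        df = make_toy_cohort([0.9, 0.8], [500.0, 500.0])
        oc = fixed_threshold_strategy(df, 1.0, 0.0)
        assert oc.n_scans == 0 and oc.n_treated == 0

    def test_strict_inequality_at_zero_cac_cutoff(self):
        df = make_toy_cohort([0.9, 0.8], [0.0, 0.0])
        oc = fixed_threshold_strategy(df, 0.5, 0.0)
        assert oc.n_scans == 2 and oc.n_treated == 0

    def test_presets_within_studied_ranges(self):
        assert FIXED_THRESHOLD_PRESETS["intermediate"] == (0.18, 15.0)
        for p_cut, c_cut in FIXED_THRESHOLD_PRESETS.values():
            assert 0.15 <= p_cut <= 0.20
            assert 0.0 <= c_cut <= 20.0

    def test_out_of_range_cutoffs_rejected(self):
        df = make_toy_cohort([0.5], [0.0])
        with pytest.raises(StrategyParameterError):
            fixed_threshold_strategy(df, 1.5, 0.0)
        with pytest.raises(StrategyParameterError):
            fixed_threshold_strategy(df, 0.5, -1.0)


class TestAgeSexAdjustedGuideline:
    def test_top_of_stratum_treated(self):
        rng = np.random.default_rng(0)
        df = make_toy_cohort(
            np.zeros(20),
            np.concatenate([[900.0], rng.integers(1, 100, 19).astype(float)]),
            pce_category=["intermediate"] * 20,
            sex=["male"] * 20,
            age=[62.0] * 20,
        )
        oc = age_sex_adjusted_guideline_strategy(df, percentile=75.0)
        assert oc.flags.iloc[0]["treatment_eligible"]

    def test_zero_cac_never_treated_via_percentile_branch(self):
        df = make_toy_cohort(
            np.zeros(12),
            np.zeros(12),
            pce_category=["intermediate"] * 12,
            sex=["female"] * 12,
            age=[55.0] * 12,
        )
        oc = age_sex_adjusted_guideline_strategy(df, percentile=1.0)
        assert oc.n_treated == 0

    def test_matches_sort_and_count_oracle(self):
        rng = np.random.default_rng(4)
        cacs = np.round(rng.lognormal(3, 1.5, 20), 1)
        df = make_toy_cohort(
            np.zeros(20),
            cacs,
            pce_category=["intermediate"] * 20,
            sex=["male"] * 20,
            age=[61.0] * 20,
        )
        oc = age_sex_adjusted_guideline_strategy(df, percentile=75.0)
        cutoff = np.percentile(cacs, 75.0)
        expected = {df["id"][i] for i in range(20) if cacs[i] > 0 and cacs[i] >= cutoff}
        _, treated = flags_to_sets(oc)
        assert treated == expected

    def test_small_stratum_falls_back_to_sex(self):
        df = make_toy_cohort(
            np.zeros(4),
            [500.0, 400.0, 10.0, 0.0],
            pce_category=["intermediate"] * 4,
            sex=["male", "male", "female", "female"],
            age=[48.0, 71.0, 52.0, 69.0],  # every sex x decade stratum < 10
        )
        oc = age_sex_adjusted_guideline_strategy(df, percentile=50.0, min_stratum=10)
        _, treated = flags_to_sets(oc)
        # male fallback pool {500, 400}: median 450, only T000 clears it;
        # female pool {10, 0}: median 5, T002 (CACS 10) clears it
        assert treated == {"T000", "T002"}

    def test_invalid_percentile_rejected(self):
        df = make_toy_cohort([0.0], [0.0], pce_category=["low"], sex=["male"], age=[50.0])
        with pytest.raises(StrategyParameterError):
            age_sex_adjusted_guideline_strategy(df, percentile=0.0)


class TestOracleEquivalence:
    def test_random_small_cohorts_match_literal_rules(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            df = random_small_cohort(rng)
            n = len(df)
            s, t = flags_to_sets(guideline_strategy(df))
            assert (s, t) == oracle_guideline(df.to_dict("records"))

            n_scans = int(rng.integers(0, n + 1))
            n_treat = int(rng.integers(0, n_scans + 1))
            s, t = flags_to_sets(selfreport_benchmarked_strategy(df, n_scans, n_treat))
            os_, ot = oracle_benchmarked(df.to_dict("records"), n_scans, n_treat)
            assert s == os_ and t == ot

            p_cut, c_cut = float(rng.random()), float(rng.choice([0.0, 15.0, 100.0]))
            s, t = flags_to_sets(fixed_threshold_strategy(df, p_cut, c_cut))
            assert (s, t) == oracle_fixed(df.to_dict("records"), p_cut, c_cut)


class TestResourceMatching:
    def test_benchmarked_matches_guideline_counts_exactly(self, scored_cohort):
        g = guideline_strategy(scored_cohort)
        s = selfreport_benchmarked_strategy(
            scored_cohort, n_scans=g.n_scans, n_treat=g.n_treated
        )
        assert s.n_scans == g.n_scans
        assert s.n_treated == g.n_treated
        assert s.n_visits == s.n_scans
        assert g.n_visits == len(scored_cohort)

    def test_aggregate_counts_equal_flag_sums(self, scored_cohort):
        oc = guideline_strategy(scored_cohort)
        f = oc.flags
        assert oc.n_visits == f["visited"].sum()
        assert oc.n_scans == f["scanned"].sum()
        assert oc.n_treated == f["treatment_eligible"].sum()
        assert not (f["scanned"] & ~f["visited"]).any()
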