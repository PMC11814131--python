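import numpy as np
import pandas as pd
import pytest

from mhwbloom import (
    DEFAULT_BLOOMING_PERIODS,
    BloomingPeriod,
    ExtremeEvent,
    classify_blooming_period,
    match_compounds,
    resolve_period,
    summarize_cases,
)

from _helpers import make_event
from _oracles import brute_match


class TestResolvePeriod:
    def test_january_march_window(self):
        assert resolve_period(DEFAULT_BLOOMING_PERIODS["NRS"], 2010) == (
            pd.Timestamp("2010-01-01"),
            pd.Timestamp("2010-03-31"),
        )

    def test_cross_year_window_ends_next_year(self):
        assert resolve_period(DEFAULT_BLOOMING_PERIODS["SRS"], 2012) == (
            pd.Timestamp("2012-10-01"),
            pd.Timestamp("2013-01-31"),
        )

    def test_february_end_respects_leap_years(self):
        _, end = resolve_period(DEFAULT_BLOOMING_PERIODS["NCRS"], 2007)
        assert end == pd.Timestamp("2008-02-29")
        _, end = resolve_period(DEFAULT_BLOOMING_PERIODS["NCRS"], 2008)
        assert end == pd.Timestamp("2009-02-28")

    def test_single_month_window(self):
        period = BloomingPeriod("test", 2, 1, 2, None)
        assert resolve_period(period, 2015) == (
            pd.Timestamp("2015-02-01"),
            pd.Timestamp("2015-02-28"),
        )

    def test_basin_window_is_six_months(self):
        start, end = resolve_period(DEFAULT_BLOOMING_PERIODS["basin"], 2000)
        assert start == pd.Timestamp("2000-10-01")
        assert end == pd.Timestamp("2001-03-31")

    def test_invalid_date_errors(self):
        with pytest.raises(ValueError, match="invalid period"):
            resolve_period(BloomingPeriod("bad", 2, 30, 3, 1), 2001)


class TestMatching:
    def test_overlap_is_concurrent(self):
        sst = make_event("sst", "high", "2010-01-10", "2010-01-20")
        chla = make_event("chla", "low", "2010-01-15", "2010-01-18")
        (m,) = match_compounds([sst], [chla])
        assert m.relation == "concurrent"
        assert m.expected_direction

    def test_lag_boundary_is_inclusive_at_seven_days(self):
        sst = make_event("sst", "high", "2010-01-01", "2010-01-12")
        at7 = make_event("chla", "low", "2010-01-19", "2010-01-22")
        at8 = make_event("chla", "low", "2010-01-20", "2010-01-23")
        assert [m.relation for m in match_compounds([sst], [at7])] == ["lagged"]
        assert match_compounds([sst], [at8]) == []

    def test_matches_equal_exhaustive_pairwise_check(self, rng):
        # fast spot check; the acceptance suite runs the full 500-set version
        t0 = pd.Timestamp("2005-01-01")
        for rep in range(50):
            sst = [
                make_event("sst", "high", t0 + pd.Timedelta(days=int(a)),
                           t0 + pd.Timedelta(days=int(a + d)))
                for a, d in zip(rng.integers(0, 300, 4), rng.integers(0, 30, 4))
            ]
            chla = [
                make_event("chla", "low", t0 + pd.Timedelta(days=int(a)),
                           t0 + pd.Timedelta(days=int(a + d)))
                for a, d in zip(rng.integers(0, 300, 5), rng.integers(0, 15, 5))
            ]
            lag = int(rng.integers(0, 10))
            got = {
                (sst.index(m.sst_event), chla.index(m.chla_event), m.relation)
                for m in match_compounds(sst, chla, max_lag=lag)
            }
            want = brute_match(
                [(e.start, e.end) for e in sst],
                [(e.start, e.end) for e in chla],
                lag,
            )
            assert got == want, f"rep {rep}"


class TestClassification:
    period = DEFAULT_BLOOMING_PERIODS["NRS"]

    def test_mhw_with_concurrent_low_chla_is_expected(self):
        case = classify_blooming_period(
            self.period, 2010,
            [make_event("sst", "high", "2010-01-04", "2010-03-19")],
            [make_event("chla", "low", "2010-02-09", "2010-02-26")],
        )
        assert case.classification == "expected"

    def test_mhw_followed_by_high_chla_only_is_opposite(self):
        case = classify_blooming_period(
            self.period, 2006,
            [make_event("sst", "high", "2006-01-05", "2006-01-20")],
            [make_event("chla", "high", "2006-01-24", "2006-01-30")],
        )
        assert case.classification == "opposite"

    def test_mhw_without_chla_extreme_is_sst_only(self):
        case = classify_blooming_period(
            self.period, 2011,
            [make_event("sst", "high", "2011-01-10", "2011-01-25")], [],
        )
        assert case.classification == "sst_only"

    def test_no_sst_event_is_none_and_chl_only_flagged(self):
        case = classify_blooming_period(
            self.period, 2003, [],
            [make_event("chla", "high", "2003-02-01", "2003-02-10")],
        )
        assert case.classification == "none"
        assert case.chl_only

    def test_expected_wins_over_opposite_with_ambiguity_flag(self):
        case = classify_blooming_period(
            self.period, 2010,
            [make_event("sst", "high", "2010-01-10", "2010-01-30")],
            [
                make_event("chla", "low", "2010-01-12", "2010-01-16"),
                make_event("chla", "high", "2010-01-20", "2010-01-24"),
            ],
        )
        assert case.classification == "expected"
        assert case.ambiguous

    def test_event_order_never_changes_the_result(self, rng):
        sst = [
            make_event("sst", "high", "2010-01-10", "2010-01-30"),
            make_event("sst", "low", "2010-03-01", "2010-03-15"),
        ]
        chla = [
            make_event("chla", "high", "2010-03-05", "2010-03-10"),
            make_event("chla", "low", "2010-01-15", "2010-01-20"),
        ]
        base = classify_blooming_period(self.period, 2010, sst, chla)
        for _ in range(5):
            a = [sst[i] for i in rng.permutation(2)]
            b = [chla[i] for i in rng.permutation(2)]
            assert classify_blooming_period(
                self.period, 2010, a, b).classification == base.classification

    def test_boundary_overlap_clipping(self):
        # one day inside the window counts; entirely before it does not
        inside = make_event("sst", "low", "2009-12-15", "2010-01-01")
        outside = make_event("sst", "low", "2009-11-01", "2009-12-31")
        case = classify_blooming_period(self.period, 2010, [inside, outside], [])
        assert case.sst_events == (inside,)

    def test_events_spanning_cross_year_window(self):
        case = classify_blooming_period(
            DEFAULT_BLOOMING_PERIODS["SRS"], 2012,
            [make_event("sst", "low", "2012-10-09", "2012-10-27")],
            [make_event("chla", "high", "2012-10-20", "2012-10-28")],
        )
        assert case.classification == "expected"


class TestSummary:
    def test_fifteen_expected_of_sixteen(self):
        cases = []
        for i in range(15):
            cases.append(classify_blooming_period(
                DEFAULT_BLOOMING_PERIODS["NRS"], 1998 + i,
                [make_event("sst", "high", f"{1998 + i}-01-10", f"{1998 + i}-01-25")],
                [make_event("chla", "low", f"{1998 + i}-01-12", f"{1998 + i}-01-20")],
            ))
        cases.append(classify_blooming_period(
            DEFAULT_BLOOMING_PERIODS["NRS"], 2014,
            [make_event("sst", "high", "2014-01-10", "2014-01-25")], [],
        ))
        summary = summarize_cases(cases)
        assert summary.percent_expected == pytest.approx(93.75)
        assert summary.percent_expected_rounded == 94
        assert summary.counts["expected"] == 15 and summary.counts["sst_only"] == 1

    def test_zero_expected(self):
        cases = [
            classify_blooming_period(
                DEFAULT_BLOOMING_PERIODS["NRS"], 2000 + i,
                [make_event("sst", "high", f"{2000 + i}-02-01", f"{2000 + i}-02-12")],
                [],
            )
            for i in range(4)
        ]
        assert summarize_cases(cases).percent_expected == 0.0

    def test_summary_equals_hand_tally(self, rng):
        for _ in range(20):
            cases = []
            tally = {"expected": 0, "opposite": 0, "sst_only": 0, "none": 0}
            for i in range(int(rng.integers(3, 12))):
                kind = rng.choice(["expected", "opposite", "sst_only", "none"])
                year = 2000 + i
                sst, chla = [], []
                if kind != "none":
                    sst = [make_event("sst", "high", f"{year}-01-10", f"{year}-01-25")]
                if kind == "expected":
                    chla = [make_event("chla", "low", f"{year}-01-12", f"{year}-01-18")]
                elif kind == "opposite":
                    chla = [make_event("chla", "high", f"{year}-01-12", f"{year}-01-18")]
                tally[kind] += 1
                cases.append(classify_blooming_period(
                    DEFAULT_BLOOMING_PERIODS["NRS"], year, sst, chla))
            summary = summarize_cases(cases)
            assert summary.counts == tally
            assert sum(summary.counts.values()) == summary.n_cases
            n_sst = summary.n_cases - tally["none"]
            if n_sst:
                assert summary.percent_expected == pytest.approx(
                    100 * tally["expected"] / n_sst)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no cases"):
            summarize_cases([])
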