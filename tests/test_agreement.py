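"""Agreement statistics: matching, F1/IoU, Bland-Altman, ICC, correlations."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mobimatch as mm

DATE = pd.Timestamp("2023-05-01")


def events(spans, pid="P1", date=DATE, **extra):
    """Event frame from (start_min, end_min) pairs on one day."""
    rows = []
    for s, e in spans:
        rows.append({"participant_id": pid, "date": date,
                     "start": date + pd.Timedelta(minutes=s),
                     "end": date + pd.Timedelta(minutes=e),
                     "duration_min": float(e - s), **extra})
    cols = ["participant_id", "date", "start", "end", "duration_min"] + list(extra)
    return pd.DataFrame(rows, columns=cols)


class TestMatchEvents:
    def test_identical_intervals_one_to_one(self):
        rec = mm.match_events(events([(0, 60)]), events([(0, 60)]))
        assert set(rec["cardinality"]) == {"1:1"}

    def test_spanning_event_is_one_to_n(self):
        rec = mm.match_events(events([(0, 120)]), events([(0, 30), (60, 90)]))
        rep = rec[rec["side"] == "REP"]
        gps = rec[rec["side"] == "GPS"]
        assert list(rep["cardinality"]) == ["1:n"] and rep["n_matches"].iloc[0] == 2
        assert list(gps["cardinality"]) == ["1:1", "1:1"]

    def test_disjoint_and_abutting_do_not_match(self):
        rec = mm.match_events(events([(0, 30)]), events([(30, 60)]))
        assert set(rec["cardinality"]) == {"1:0"}

    def test_cardinality_conservation(self):
        rng = np.random.default_rng(5)
        spans_a = sorted(rng.integers(0, 700, size=(8, 2)).tolist())
        spans_b = sorted(rng.integers(0, 700, size=(6, 2)).tolist())
        fix = lambda sp: [(min(a, b), max(a, b) + 1) for a, b in sp]
        rec = mm.match_events(events(fix(spans_a)), events(fix(spans_b)))
        table = mm.cardinality_table(rec)
        for side, n in (("REP", 8), ("GPS", 6)):
            t = table[table["side"] == side].set_index("cardinality")["n"]
            assert t["1:1"] + t["1:n"] + t["1:0"] == t["total"] == n


class TestPrecisionRecallF1:
    def test_half_recall_full_precision(self):
        rec = mm.match_events(events([(0, 60), (120, 180)]), events([(0, 60)]))
        out = mm.precision_recall_f1(rec)
        assert out["recall"] == 0.5 and out["precision"] == 1.0
        assert out["f1"] == pytest.approx(2 / 3)

    def test_no_gps_events_precision_undefined(self):
        rec = mm.match_events(events([(0, 60)]), events([]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = mm.precision_recall_f1(rec)
        assert out["recall"] == 0.0 and np.isnan(out["precision"])

    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20),
           st.integers(0, 20))
    @settings(max_examples=50, deadline=None)
    def test_f1_between_precision_and_recall(self, rm, ru, gm, gu):
        rec = pd.DataFrame(
            {"side": ["REP"] * (rm + ru) + ["GPS"] * (gm + gu),
             "n_matches": [1] * rm + [0] * ru + [1] * gm + [0] * gu})
        if rm + ru == 0 or gm + gu == 0:
            return
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = mm.precision_recall_f1(rec)
        p, r, f1 = out["precision"], out["recall"], out["f1"]
        if np.isnan(f1):
            assert p + r == 0
        else:
            assert min(p, r) - 1e-12 <= f1 <= max(p, r) + 1e-12
            if p == r:
                assert f1 == pytest.approx(p)


def minute_grid_iou(rep_spans, gps_spans, horizon=1440):
    """Independent rasterization oracle on a 1-min grid."""
    a = np.zeros(horizon, dtype=bool)
    b = np.zeros(horizon, dtype=bool)
    for s, e in rep_spans:
        a[s:e] = True
    for s, e in gps_spans:
        b[s:e] = True
    union = (a | b).sum()
    return (a & b).sum() / union if union else float("nan")


class TestIntervalIoU:
    def test_identical_and_disjoint(self):
        _, mean = mm.interval_iou(events([(0, 60)]), events([(0, 60)]))
        assert mean == 1.0
        _, mean = mm.interval_iou(events([(0, 60)]), events([(120, 180)]))
        assert mean == 0.0

    def test_one_third_overlap(self):
        _, mean = mm.interval_iou(events([(0, 60)]), events([(30, 90)]))
        assert mean == pytest.approx(1 / 3)
        assert mean == pytest.approx(minute_grid_iou([(0, 60)], [(30, 90)]))

    def test_zero_event_time_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="IoU undefined"):
            per, mean = mm.interval_iou(events([]), events([]),
                                        participants=["P1"])
        assert len(per) == 0 and np.isnan(mean)


class TestDurationDecomposition:
    @pytest.mark.parametrize("rep,gps,expected", [
        ([(0, 60)], [(0, 60)], (100.0, 0.0, 0.0)),
        ([(0, 60)], [(120, 180)], (0.0, 50.0, 50.0)),
        ([(0, 60)], [(30, 90)], (100 / 3, 100 / 3, 100 / 3)),
    ])
    def test_examples(self, rep, gps, expected):
        _, mean = mm.duration_decomposition(events(rep), events(gps))
        got = (mean["pct_intersection"], mean["pct_rep_only"], mean["pct_gps_only"])
        assert got == pytest.approx(expected)
        assert sum(got) == pytest.approx(100.0)

    def test_consistency_with_iou(self):
        """IoU equals intersection over union from the decomposition."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            rep = [(int(a), int(a) + int(d)) for a, d in
                   zip(rng.integers(0, 1200, 5), rng.integers(1, 200, 5))]
            gps = [(int(a), int(a) + int(d)) for a, d in
                   zip(rng.integers(0, 1200, 4), rng.integers(1, 200, 4))]
            _, iou = mm.interval_iou(events(rep), events(gps))
            _, dec = mm.duration_decomposition(events(rep), events(gps))
            assert iou == pytest.approx(dec["pct_intersection"] / 100.0)


class TestDailyDifferenceStats:
    def test_all_zero(self):
        df = pd.DataFrame({"participant_id": ["P1"] * 3 + ["P2"] * 3,
                           "rep": [5.0] * 6, "gps": [5.0] * 6})
        out = mm.daily_difference_stats(df, "rep", "gps", tolerances=(10,))
        assert out["mean"] == out["sd"] == out["median"] == 0
        assert out["tolerance_bands"][10]["pct_agree"] == 100.0

    def test_between_sd_sample_convention(self):
        # participants with constant differences +10 and -10:
        # SD of {+10, -10} with n-1 denominator is 14.142...
        df = pd.DataFrame({"participant_id": ["P1"] * 2 + ["P2"] * 2,
                           "rep": [10.0, 10.0, 0.0, 0.0],
                           "gps": [0.0, 0.0, 10.0, 10.0]})
        out = mm.daily_difference_stats(df, "rep", "gps")
        assert out["mean"] == 0.0
        assert out["sd_between"] == pytest.approx(10 * np.sqrt(2))

    def test_within_sd(self):
        df = pd.DataFrame({"participant_id": ["P1"] * 2,
                           "rep": [5.0, -5.0], "gps": [0.0, 0.0]})
        out = mm.daily_difference_stats(df, "rep", "gps")
        assert out["mean_sd_within"] == pytest.approx(5 * np.sqrt(2))


class TestBlandAltman:
    def test_constant_differences_zero_width(self):
        df = pd.DataFrame({"participant_id": ["P1", "P1", "P2", "P2"],
                           "diff": [3.0] * 4})
        out = mm.bland_altman_repeated(df)
        assert out["mean_diff"] == 3.0
        assert out["loa_low"] == out["loa_high"] == 3.0

    def test_single_observation_reduces_to_simple(self):
        rng = np.random.default_rng(2)
        d = rng.normal(5, 3, 12)
        df = pd.DataFrame({"participant_id": [f"P{i}" for i in range(12)],
                           "diff": d})
        out = mm.bland_altman_repeated(df)
        assert out["mean_diff"] == pytest.approx(d.mean())
        assert out["loa_high"] == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))
        assert out["loa_low"] == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))


class TestICC:
    def test_identical_columns_exactly_one(self):
        x = np.array([1.0, 5.0, 9.0, 2.0])
        out = mm.icc_oneway(x, x)
        assert out["icc"] == 1.0 and out["ci_low"] == 1.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = x + rng.normal(0, 0.3, size=20)
        a = mm.icc_oneway(x, y)["icc"]
        b = mm.icc_oneway(x + 7.0, y + 7.0)["icc"]
        assert a == pytest.approx(b)

    def test_crossed_values_near_zero(self):
        # equal unit means with maximally crossed values: no between-unit
        # variance in the construct -> ICC at its negative floor
        x = np.array([0.0, 1.0, 0.0, 1.0])
        y = np.array([1.0, 0.0, 1.0, 0.0])
        out = mm.icc_oneway(x, y)
        assert out["icc"] == pytest.approx(-1.0)

    def test_against_pingouin_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(10, 4, size=30)
        y = x + rng.normal(0, 2, size=30)
        ours = mm.icc_oneway(x, y)
        data = pd.DataFrame({
            "targets": np.repeat(np.arange(30), 2),
            "raters": ["a", "b"] * 30,
            "ratings": np.column_stack([x, y]).ravel()})
        ref = pingouin.intraclass_corr(data, targets="targets", raters="raters",
                                       ratings="ratings")
        icc1 = ref.loc[ref["Type"] == "ICC(1,1)"].iloc[0]
        assert ours["icc"] == pytest.approx(icc1["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to two decimals
        assert ours["ci_low"] == pytest.approx(icc1["CI95"][0], abs=6e-3)
        assert ours["ci_high"] == pytest.approx(icc1["CI95"][1], abs=6e-3)


class TestCorrelations:
    def test_perfect_agreement(self):
        df = pd.DataFrame({"participant_id": ["P1"] * 4 + ["P2"] * 4,
                           "rep": list(range(8)), "gps": list(range(8))})
        out = mm.correlations(df, "rep", "gps")
        assert out["spearman_pooled"] == 1.0
        assert out["icorr_mean"] == 1.0 and out["icorr_sd"] == 0.0

    def test_reversed_ranks(self):
        df = pd.DataFrame({"participant_id": ["P1"] * 5,
                           "rep": [1, 2, 3, 4, 5], "gps": [5, 4, 3, 2, 1]})
        out = mm.correlations(df, "rep", "gps")
        assert out["spearman_pooled"] == pytest.approx(-1.0)

    def test_one_discordant_pair_hand_value(self):
        # ranks (1..5) vs (1,2,3,5,4): rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 0.9
        df = pd.DataFrame({"participant_id": ["P1"] * 5,
                           "rep": [1, 2, 3, 4, 5], "gps": [1, 2, 3, 5, 4]})
        out = mm.correlations(df, "rep", "gps")
        assert out["spearman_pooled"] == pytest.approx(0.9)

    def test_constant_column_skipped(self):
        df = pd.DataFrame({"participant_id": ["P1"] * 4,
                           "rep": [1, 2, 3, 4], "gps": [2.0] * 4})
        with pytest.warns(UserWarning, match="constant"):
            out = mm.correlations(df, "rep", "gps")
        assert out["n_icorr"] == 0


class TestEventCharacteristics:
    def _records(self):
        rep = events([(0, 60), (120, 180), (240, 300), (360, 420)],
                     activity_type="commercial", indoor_outdoor="indoor")
        rep.loc[2:, "activity_type"] = "recreation"
        rep.loc[3, "activity_type"] = "unassignable"
        gps = events([(30, 90), (250, 310)])
        return mm.match_events(rep, gps)

    def test_match_rates_and_overlap(self):
        out = mm.event_characteristics(self._records())
        t = out["tables"]["activity_type"].set_index("activity_type")
        assert t.loc["commercial", "pct_matched"] == 50.0
        assert t.loc["recreation", "pct_matched"] == 100.0
        assert np.isnan(t.loc["unassignable", "pct_matched"])
        # REP [0,60) matched by GPS [30,90): half the event covered
        rec = self._records()
        first = rec[(rec["side"] == "REP")].sort_values("start").iloc[0]
        assert first["overlap_fraction"] == pytest.approx(0.5)

    def test_all_matched_is_100(self):
        rep = events([(0, 60)], activity_type="social", indoor_outdoor="indoor")
        rec = mm.match_events(rep, events([(0, 60)]))
        out = mm.event_characteristics(rec)
        t = out["tables"]["activity_type"].set_index("activity_type")
        assert t.loc["social", "pct_matched"] == 100.0


class TestBuildMatchedDays:
    def _daily(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "date",
                                           "rep_toh_min", "rep_nals"])

    def _gps(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "date",
                                           "gps_toh_min", "gps_nals"])

    def _events(self, pid_dates, worn=True):
        return pd.DataFrame({
            "participant_id": [p for p, _ in pid_dates],
            "date": [pd.Timestamp(d) for _, d in pid_dates],
            "worn_flag": worn})

    def test_contradiction_rules(self):
        dates = [pd.Timestamp(f"2023-05-0{i}") for i in range(1, 5)]
        daily_rep = self._daily([
            ("P1", dates[0], 0.0, 2),     # TOH day invalid: ALs but no TOH
            ("P1", dates[1], 45.0, 0),    # AL day invalid: >30 min TOH, no AL
            ("P1", dates[2], 60.0, 1),
            ("P1", dates[3], 90.0, 2)])
        daily_gps = self._gps([(("P1"), d, 50.0, 1) for d in dates])
        ev = self._events([("P1", d) for d in dates])
        out = mm.build_matched_days(daily_rep, daily_gps, ev, ev)
        assert dates[0] not in set(out["toh"]["date"])
        assert dates[1] in set(out["toh"]["date"])
        assert dates[1] not in set(out["al"]["date"])
        assert dates[0] in set(out["al"]["date"])

    def test_unworn_day_invalidates_gps(self):
        dates = [pd.Timestamp(f"2023-05-0{i}") for i in range(1, 4)]
        daily_rep = self._daily([("P1", d, 60.0, 1) for d in dates])
        daily_gps = self._gps([("P1", d, 50.0, 1) for d in dates])
        ev = self._events([("P1", d) for d in dates])
        ev.loc[0, "worn_flag"] = False
        out = mm.build_matched_days(daily_rep, daily_gps, ev, ev)
        assert dates[0] not in set(out["toh"]["date"])
        assert len(out["toh"]) == 2

    def test_single_matched_day_participant_excluded(self):
        dates = [pd.Timestamp(f"2023-05-0{i}") for i in range(1, 3)]
        daily_rep = self._daily([("P1", dates[0], 60.0, 1),
                                 ("P1", dates[1], 60.0, 1),
                                 ("P2", dates[0], 60.0, 1),
                                 ("P2", dates[1], 60.0, 1)])
        # P2 has GPS on only one day -> below the 2-matched-day floor
        daily_gps = self._gps([("P1", dates[0], 50.0, 1),
                               ("P1", dates[1], 50.0, 1),
                               ("P2", dates[0], 50.0, 1)])
        ev = self._events([("P1", d) for d in dates] + [("P2", d) for d in dates])
        out = mm.build_matched_days(daily_rep, daily_gps, ev, ev)
        assert set(out["toh"]["participant_id"]) == {"P1"}
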