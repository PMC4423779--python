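"""Independence filtering and relative-abundance arithmetic."""

import numpy as np
import pandas as pd
import pytest

from trailcam import events as ev
from conftest import make_deployments, make_photos


def brute_force_events(photos, gap_minutes=60.0):
    """Reference scan: sort each station-species series and cut at gaps
    strictly greater than the threshold."""
    out = []
    gap = pd.Timedelta(minutes=gap_minutes)
    for (st, sp), g in photos.groupby(["station_id", "species_id"]):
        times = sorted(g["timestamp"])
        start, n = times[0], 1
        for prev, cur in zip(times, times[1:]):
            if cur - prev > gap:
                out.append((st, sp, start, n))
                start, n = cur, 1
            else:
                n += 1
        out.append((st, sp, start, n))
    return sorted(out)


class TestFilterIndependentEvents:
    def test_chained_rule_worked_example(self):
        # 10:30 is 30 min after 10:00 (same event); 11:31 is 61 min later
        photos = make_photos([("s1", "impala", f"2023-01-01 {t}")
                              for t in ("10:00", "10:30", "11:31")])
        out = ev.filter_independent_events(photos)
        assert len(out) == 2
        assert list(out["n_photos"]) == [2, 1]
        assert out["event_start"].iloc[0] == pd.Timestamp("2023-01-01 10:00")

    def test_single_photo_is_one_event(self):
        out = ev.filter_independent_events(
            make_photos([("s1", "kudu", "2023-01-01 08:00")]))
        assert len(out) == 1 and out["n_photos"].iloc[0] == 1

    def test_exact_threshold_gap_stays_in_event(self):
        # the rule is "separated by MORE than one hour"
        photos = make_photos([("s1", "a", "2023-01-01 10:00"),
                              ("s1", "a", "2023-01-01 11:00")])
        assert len(ev.filter_independent_events(photos)) == 1
        photos2 = make_photos([("s1", "a", "2023-01-01 10:00"),
                               ("s1", "a", "2023-01-01 11:00:01")])
        assert len(ev.filter_independent_events(photos2)) == 2

    def test_species_do_not_reset_each_others_clock(self):
        photos = make_photos([("s1", "a", "2023-01-01 10:00"),
                              ("s1", "b", "2023-01-01 10:30"),
                              ("s1", "a", "2023-01-01 10:59")])
        out = ev.filter_independent_events(photos)
        assert len(out) == 2  # one per species

    def test_chained_vs_anchored(self):
        # photos at 0, 50, 100 min: every consecutive gap <= 60 but the
        # third is 100 min from the event anchor
        photos = make_photos([("s1", "a", "2023-01-01 10:00"),
                              ("s1", "a", "2023-01-01 10:50"),
                              ("s1", "a", "2023-01-01 11:40")])
        assert len(ev.filter_independent_events(photos, rule="chained")) == 1
        assert len(ev.filter_independent_events(photos, rule="anchored")) == 2

    def test_matches_brute_force_oracle_on_random_series(self):
        rng = np.random.default_rng(3)
        base = pd.Timestamp("2023-01-01")
        photos = pd.DataFrame({
            "station_id": rng.choice(["s1", "s2", "s3"], 1000),
            "species_id": rng.choice(["a", "b"], 1000),
            "timestamp": [base + pd.Timedelta(minutes=float(m))
                          for m in rng.uniform(0, 7 * 24 * 60, 1000)],
        })
        got = ev.filter_independent_events(photos)
        got_tuples = sorted(map(tuple, got[["station_id", "species_id",
                                            "event_start", "n_photos"]].to_numpy()))
        assert got_tuples == brute_force_events(photos)

    def test_order_invariance_and_idempotence(self):
        rng = np.random.default_rng(5)
        base = pd.Timestamp("2023-01-01")
        photos = pd.DataFrame({
            "station_id": "s1", "species_id": "a",
            "timestamp": [base + pd.Timedelta(minutes=float(m))
                          for m in rng.uniform(0, 5000, 200)],
        })
        a = ev.filter_independent_events(photos)
        b = ev.filter_independent_events(photos.sample(frac=1, random_state=0))
        pd.testing.assert_frame_equal(a, b)
        # filtering the event starts again changes nothing
        again = ev.filter_independent_events(
            a.rename(columns={"event_start": "timestamp"})
             .drop(columns="n_photos"))
        assert list(again["event_start"]) == list(a["event_start"])

    def test_event_count_bounded_by_photo_count(self):
        photos = make_photos([("s1", "a", "2023-01-01 10:00"),
                              ("s1", "a", "2023-01-01 13:00")])
        out = ev.filter_independent_events(photos)
        assert len(out) == 2  # equality iff all gaps exceed the threshold

    def test_invalid_gap_raises(self):
        with pytest.raises(ValueError):
            ev.filter_independent_events(make_photos([]), gap_minutes=-5)


class TestComputeRai:
    def test_rai_formula_and_zero_events(self):
        dep = make_deployments(["s1"], days=20.0)
        events = pd.DataFrame({"station_id": ["s1"] * 4, "species_id": "a",
                               "event_start": pd.Timestamp("2023-01-02")})
        out = ev.compute_rai(events, dep, "station", species=["a", "b"])
        a = out[out["species_id"] == "a"].iloc[0]
        b = out[out["species_id"] == "b"].iloc[0]
        assert a["rai"] == pytest.approx(100 * 4 / 20.0)
        assert b["n_events"] == 0 and b["rai"] == 0.0

    def test_doubling_effort_halves_rai(self):
        events = pd.DataFrame({"station_id": ["s1"] * 3, "species_id": "a",
                               "event_start": pd.Timestamp("2023-01-02")})
        r1 = ev.compute_rai(events, make_deployments(["s1"], days=10.0),
                            "station")["rai"].iloc[0]
        r2 = ev.compute_rai(events, make_deployments(["s1"], days=20.0),
                            "station")["rai"].iloc[0]
        assert r1 == pytest.approx(2 * r2)

    def test_survey_rai_pools_events_and_effort(self):
        # two stations, unequal effort: the survey RAI is total/total,
        # not the mean of the station RAIs
        dep = make_deployments(["s1", "s2"], days=[10.0, 40.0])
        events = pd.DataFrame({
            "station_id": ["s1"] * 2 + ["s2"] * 4,
            "species_id": "a", "event_start": pd.Timestamp("2023-01-02")})
        out = ev.compute_rai(events, dep, "survey")
        assert out["rai"].iloc[0] == pytest.approx(100 * 6 / 50.0)
        mean_of_stations = np.mean([100 * 2 / 10.0, 100 * 4 / 40.0])
        assert out["rai"].iloc[0] != pytest.approx(mean_of_stations)

    def test_rai_inverts_to_event_count(self):
        dep = make_deployments(["s1"], days=17.3)
        events = pd.DataFrame({"station_id": ["s1"] * 7, "species_id": "a",
                               "event_start": pd.Timestamp("2023-01-02")})
        out = ev.compute_rai(events, dep, "station")
        assert out["rai"].iloc[0] * 17.3 / 100 == pytest.approx(7, abs=1e-9)

    def test_nonpositive_effort_names_station(self):
        dep = make_deployments(["sbad"], days=5.0, downtime=5.0)
        with pytest.raises(ValueError, match="sbad"):
            ev.compute_rai(pd.DataFrame(columns=["station_id", "species_id",
                                                 "event_start"]), dep, "station")

    def test_unknown_station_raises(self):
        dep = make_deployments(["s1"])
        events = pd.DataFrame({"station_id": ["ghost"], "species_id": "a",
                               "event_start": pd.Timestamp("2023-01-02")})
        with pytest.raises(ValueError, match="ghost"):
            ev.compute_rai(events, dep, "station")


class TestInferEffort:
    @pytest.mark.parametrize("n,rai,expected", [
        (1929, 68.40, 2820),   # dry trail survey
        (1173, 41.26, 2843),   # dry random survey
        (354, 12.45, 2843),    # cross-check from a second species
    ])
    def test_inversion_reproduces_published_efforts(self, n, rai, expected):
        assert round(ev.infer_effort(n, rai)) == expected

    def test_zero_events_non_informative(self):
        assert ev.infer_effort(0, 3.0) == 0.0

    def test_invalid_rai(self):
        with pytest.raises(ValueError):
            ev.infer_effort(10, 0.0)


class TestReadTables:
    def test_header_only_photos(self, tmp_path):
        p = tmp_path / "photos.csv"
        p.write_text("station_id,species_id,timestamp\n")
        out = ev.read_photos(p)
        assert len(out) == 0

    def test_placement_case_normalised(self, tmp_path):
        p = tmp_path / "dep.csv"
        p.write_text("station_id,cell_id,placement,season,start,end,downtime_days\n"
                     "s1,c1,Trail,dry,2023-01-01T00:00:00,2023-01-11T00:00:00,0\n")
        out = ev.read_deployments(p)
        assert out["placement"].iloc[0] == "trail"

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "photos.csv"
        p.write_text("station_id,timestamp\ns1,2023-01-01T00:00:00\n")
        with pytest.raises(ev.FormatError, match="species_id"):
            ev.read_photos(p)

    def test_bad_timestamp_rows_dropped_with_warning(self, tmp_path):
        p = tmp_path / "photos.csv"
        p.write_text("station_id,species_id,timestamp\n"
                     "s1,a,2023-01-01T10:00:00\n"
                     "s1,a,not-a-time\n")
        with pytest.warns(UserWarning, match="unparseable"):
            out = ev.read_photos(p)
        assert len(out) == 1
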