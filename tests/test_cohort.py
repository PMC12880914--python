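"""Harmonization, validity screens, cohort selection, device overlap."""

from datetime import date, datetime

import numpy as np
import pandas as pd
import pytest

from sleepcohort.cohort import (
    DEFAULT_THRESHOLDS,
    ValidityThresholds,
    assign_night_date,
    average_per_child,
    device_night_overlap,
    is_valid_night,
    keep_main_sleep_period,
    metrics_to_frame,
    night_validity_reasons,
    screen_gross_duration,
    select_analysis_cohort,
)
from sleepcohort.dtypes import NightMetrics


def night(child="C1", nd=date(2023, 5, 3), device="watch", so_h=22, so_m=0,
          fa_h=6, fa_m=40, waso=60.0, quality=None, sol=15.0, tst=None):
    so = datetime(2023, 5, 2, so_h, so_m) if so_h >= 12 else \
        datetime(2023, 5, 3, so_h, so_m)
    fa = datetime(2023, 5, 3, fa_h, fa_m) if fa_h < 12 else \
        datetime(2023, 5, 2, fa_h, fa_m)
    span = (fa - so).total_seconds() / 60
    if tst is None:
        tst = span - waso
    else:
        waso = span - tst
    return NightMetrics(child_id=child, night_date=nd, device=device,
                        dialect="embrace", so=so, fa=fa, waso_min=waso,
                        tst_min=tst, sol_min=sol, quality_score=quality)


class TestNightDate:
    def test_morning_fa(self):
        m = night()
        assert assign_night_date(m) == date(2023, 5, 3)

    def test_early_evening_sleeper(self):
        m = night(so_h=14, fa_h=23, fa_m=50, waso=0, sol=5)
        m.fa = datetime(2023, 5, 2, 23, 50)
        m.so = datetime(2023, 5, 2, 14, 0)
        assert assign_night_date(m) == date(2023, 5, 2)

    def test_same_date_merges_to_one_record(self):
        a = night(device="watch")
        b = night(device="mat", so_h=22, so_m=5)
        df = metrics_to_frame([a, b])
        assert df["night_date"].nunique() == 1
        assert set(df["source"]) == {"watch", "mat"}


class TestScreens:
    @pytest.mark.parametrize("tst,expected", [
        (179, False), (180, True), (960, True), (961, False), (480, True)])
    def test_gross_duration_boundaries(self, tst, expected):
        m = night(so_h=20, fa_h=40 % 24, waso=0)
        m.tst_min = float(tst)
        assert screen_gross_duration(m) is expected

    def test_valid_night_happy_path(self):
        m = night(waso=60, quality=80, sol=15)
        assert is_valid_night(m)

    def test_waso_over_3h_invalid(self):
        m = night(waso=181)
        assert night_validity_reasons(m) == ["WASO > 3 h"]

    def test_quality_30_removed(self):
        m = night(quality=30)
        assert "quality score <= 30" in night_validity_reasons(m)
        assert is_valid_night(night(quality=31))

    def test_sol_outlier_excluded(self):
        m = night(sol=121)
        assert "SOL > 120 min (outlier)" in night_validity_reasons(m)

    def test_so_window_inclusive_bounds(self):
        ok = night(so_h=19, so_m=0, waso=0, tst=420)
        assert "SO outside 19:00-07:00" not in night_validity_reasons(ok)
        late = night(so_h=7, so_m=0, fa_h=11, fa_m=0, waso=0)
        assert "SO outside 19:00-07:00" not in night_validity_reasons(late)
        toolate = night(so_h=7, so_m=1, fa_h=11, fa_m=30, waso=0)
        assert "SO outside 19:00-07:00" in night_validity_reasons(toolate)

    def test_flag_decomposability(self):
        """Toggling one criterion's threshold changes only that flag."""
        m = night(waso=100)
        base = night_validity_reasons(m)
        tight = ValidityThresholds(waso_max=90)
        tightened = night_validity_reasons(m, tight)
        assert set(tightened) - set(base) == {"WASO > 3 h"}


class TestSelection:
    def _toy_table(self):
        """Five children with 0, 2, 3, 4, 10 simultaneously-valid nights."""
        rows = []
        counts = {"A": 0, "B": 2, "C": 3, "D": 4, "E": 10}
        for child, n_valid in counts.items():
            for i in range(max(n_valid, 1)):
                for src in ("watch", "diary"):
                    rows.append({
                        "child_id": child, "night_date": f"2023-05-{i+1:02d}",
                        "source": src, "valid": i < n_valid,
                        "tst_min": 480.0, "waso_min": 30.0,
                        "so_noon_min": 600.0, "fa_noon_min": 1110.0,
                        "sol_min": 10.0,
                    })
        return pd.DataFrame(rows)

    def test_three_of_five_children_retained(self):
        table = self._toy_table()
        selected, _ = select_analysis_cohort(table, min_valid_nights=3)
        assert sorted(selected["child_id"].unique()) == ["C", "D", "E"]

    def test_boundary_exactly_three_nights(self):
        table = self._toy_table()
        selected, _ = select_analysis_cohort(table, min_valid_nights=3)
        c = selected[selected.child_id == "C"]
        assert c.groupby("night_date").ngroups == 3

    def test_two_nights_dropped(self):
        table = self._toy_table()
        selected, _ = select_analysis_cohort(table, min_valid_nights=3)
        assert "B" not in set(selected["child_id"])

    def test_idempotence(self):
        table = self._toy_table()
        once, _ = select_analysis_cohort(table, min_valid_nights=3)
        twice, _ = select_analysis_cohort(once, min_valid_nights=3)
        pd.testing.assert_frame_equal(
            once.sort_values(list(once.columns)).reset_index(drop=True),
            twice.sort_values(list(once.columns)).reset_index(drop=True))

    def test_night_needs_all_required_sources(self):
        table = self._toy_table()
        # remove diary rows for child E: its nights no longer qualify
        table = table[~((table.child_id == "E") & (table.source == "diary"))]
        selected, _ = select_analysis_cohort(
            table, min_valid_nights=3, required_sources=["watch", "diary"])
        assert "E" not in set(selected["child_id"])


class TestOverlap:
    def _row(self, child, nd, src, tst=480.0):
        return {"child_id": child, "night_date": nd, "source": src,
                "tst_min": tst, "valid": True}

    def test_full_triple_overlap(self):
        rows = [self._row("A", f"2023-05-0{n}", s)
                for n in (1, 2) for s in ("watch", "mat", "eeg")]
        out = device_night_overlap(pd.DataFrame(rows))
        assert out["cells"]["eeg+mat+watch"] == 2
        assert sum(v for k, v in out["cells"].items()
                   if k != "eeg+mat+watch") == 0

    def test_pairwise_cells(self):
        rows = [self._row("A", "2023-05-01", "A_dev"),
                self._row("A", "2023-05-02", "A_dev"),
                self._row("A", "2023-05-02", "B_dev"),
                self._row("A", "2023-05-03", "B_dev")]
        out = device_night_overlap(pd.DataFrame(rows),
                                   devices=["A_dev", "B_dev", "C_dev"])
        assert out["cells"]["A_dev"] == 1
        assert out["cells"]["B_dev"] == 1
        assert out["cells"]["A_dev+B_dev"] == 1
        assert out["cells"]["C_dev"] == 0

    def test_empty_table(self):
        df = pd.DataFrame(columns=["child_id", "night_date", "source",
                                   "tst_min", "valid"])
        out = device_night_overlap(df, devices=["watch"])
        assert out["cells"] == {"watch": 0} and out["n_nights_any"] == 0

    def test_venn_conservation(self):
        rng = np.random.default_rng(0)
        rows = []
        for child in "ABCD":
            for n in range(1, 9):
                for s in ("watch", "mat", "eeg"):
                    if rng.random() < 0.6:
                        rows.append(self._row(child, f"2023-05-{n:02d}", s))
        df = pd.DataFrame(rows)
        out = device_night_overlap(df, devices=["watch", "mat", "eeg"])
        n_distinct = df.groupby(["child_id", "night_date"]).ngroups
        assert sum(out["cells"].values()) == n_distinct

    def test_gross_screen_applied(self):
        rows = [self._row("A", "2023-05-01", "watch", tst=100.0)]
        out = device_night_overlap(pd.DataFrame(rows), devices=["watch"])
        assert out["cells"]["watch"] == 0


class TestAveraging:
    def test_mean_and_identity(self):
        df = pd.DataFrame({
            "child_id": ["A"] * 3 + ["B"],
            "source": ["watch"] * 4,
            "tst_min": [400.0, 420.0, 440.0, 500.0],
        })
        out = average_per_child(df, "tst_min")
        assert out.loc[out.child_id == "A", "tst_min"].item() == 420.0
        assert out.loc[out.child_id == "B", "tst_min"].item() == 500.0

    def test_noon_anchored_so_mean(self):
        # 23:30 and 00:30 -> 690 and 750 noon-minutes -> mean 720 = midnight
        df = pd.DataFrame({"child_id": ["A", "A"], "source": ["watch"] * 2,
                           "so_noon_min": [690.0, 750.0]})
        out = average_per_child(df, "so_noon_min")
        assert out["so_noon_min"].item() == 720.0

    def test_unknown_measure(self):
        with pytest.raises(KeyError):
            average_per_child(pd.DataFrame({"child_id": [], "source": []}),
                              "nope")


def test_main_sleep_period_keeps_longest_tst():
    a = night(device="watch", waso=0, tst=300)
    b = night(device="watch", waso=0, tst=200)
    b.so = b.so.replace(hour=13)
    df = metrics_to_frame([a])
    df2 = metrics_to_frame([b])
    both = pd.concat([df, df2], ignore_index=True)
    kept = keep_main_sleep_period(both)
    assert len(kept) == 1 and kept["tst_min"].item() == 300.0
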