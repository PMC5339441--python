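"""Per-24 h metric tests: day splitting, outcome arithmetic, the 30 min
REM-deficiency flags, and the exclusion report."""

import numpy as np
import pandas as pd
import pytest

from equirest.metrics import (
    annotate_bouts,
    apply_exclusions,
    compute_day_metrics,
    day_metrics_table,
    flag_under_72h,
    split_days,
)


def bout_row(horse="h1", start=0, dur=600, surface="litter", lateral=0,
             n_present=1, termination="self"):
    return {
        "horse_id": horse, "start_s": start, "end_s": start + dur,
        "duration_s": dur, "surface": surface, "sternal_s": dur - lateral,
        "lateral_s": lateral, "n_present": n_present, "termination": termination,
    }


def table(*rows):
    return pd.DataFrame(list(rows))


class TestSplitDays:
    def test_bout_in_hour_30_lands_in_day_2(self):
        out = split_days(table(bout_row(start=30 * 3600)))
        assert out["day_index"].tolist() == [2]
        assert not out["is_continuation"].iloc[0]

    def test_boundary_spanning_bout_split_and_counted_in_both_days(self):
        # 40 min bout straddling hour 24 by 10 min
        out = split_days(table(bout_row(start=24 * 3600 - 30 * 60, dur=40 * 60)))
        assert out["day_index"].tolist() == [1, 2]
        assert out["duration_s"].tolist() == [30 * 60, 10 * 60]
        assert out["is_continuation"].tolist() == [False, True]

    def test_lateral_seconds_prorated_across_the_boundary(self):
        row = bout_row(start=24 * 3600 - 600, dur=1200, lateral=400)
        out = split_days(table(row))
        assert out["lateral_s"].sum() == pytest.approx(400, abs=1)
        assert (out["lateral_s"] + out["sternal_s"] == out["duration_s"]).all()

    def test_bout_outside_window_is_an_error(self):
        with pytest.raises(ValueError, match="outside"):
            split_days(table(bout_row(start=73 * 3600)))

    def test_empty_bout_table_gives_three_empty_days(self):
        m = day_metrics_table(table(bout_row()).iloc[0:0], horses=["h1"], group_size=4)
        assert len(m) == 3
        assert (m["n_bouts_total"] == 0).all()
        assert (m["duration_min_total"] == 0).all()
        assert m["under_30min"].all()
        assert m["pct_lateral"].isna().all() and m["pct_forced"].isna().all()


class TestDayMetrics:
    def test_29_minutes_flags_under_30(self):
        m = day_metrics_table(
            table(bout_row(start=0, dur=10 * 60), bout_row(start=3600, dur=19 * 60)),
            horses=["h1"], group_size=4,
        )
        d1 = m[m.day_index == 1].iloc[0]
        assert d1["duration_min_total"] == pytest.approx(29.0)
        assert d1["under_30min"]

    def test_hand_computed_percentages(self):
        # 60 min sternal-only self bout + 30 min bout with 15 min lateral, forced
        m = day_metrics_table(
            table(
                bout_row(start=0, dur=3600, lateral=0, termination="self"),
                bout_row(start=7200, dur=1800, lateral=900, termination="forced"),
            ),
            horses=["h1"], group_size=4,
        )
        d1 = m[m.day_index == 1].iloc[0]
        assert d1["pct_lateral"] == pytest.approx(100 * 15 / 90)
        assert d1["pct_forced"] == pytest.approx(50.0)

    def test_members_present_denominator_excludes_focal_by_default(self):
        bouts = table(bout_row(n_present=3))
        m = day_metrics_table(bouts, horses=["h1"], group_size=4)
        assert m[m.day_index == 1]["pct_present"].iloc[0] == pytest.approx(100.0)
        m2 = day_metrics_table(bouts, horses=["h1"], group_size=4, include_focal=True)
        assert m2[m2.day_index == 1]["pct_present"].iloc[0] == pytest.approx(75.0)

    def test_surface_additivity(self):
        m = day_metrics_table(
            table(
                bout_row(start=0, dur=600, surface="litter"),
                bout_row(start=1000, dur=300, surface="rubber_mats"),
                bout_row(start=2000, dur=120, surface="firm_ground"),
                bout_row(start=3000, dur=60, surface="litter"),
            ),
            horses=["h1"], group_size=3,
        )
        d1 = m[m.day_index == 1].iloc[0]
        surf_n = d1[[f"n_bouts_{s}" for s in ("litter", "rubber_mats", "firm_ground")]]
        surf_d = d1[[f"duration_min_{s}" for s in ("litter", "rubber_mats", "firm_ground")]]
        assert surf_n.sum() == d1["n_bouts_total"] == 4
        assert surf_d.sum() == pytest.approx(d1["duration_min_total"])

    def test_percentages_invariant_to_bout_order(self, rng):
        rows = [bout_row(start=i * 4000, dur=int(d), lateral=int(l))
                for i, (d, l) in enumerate(zip(rng.integers(60, 3000, 8),
                                               rng.integers(0, 50, 8)))]
        a = compute_day_metrics(split_days(table(*rows)), group_size=5)
        b = compute_day_metrics(split_days(table(*rows[::-1])), group_size=5)
        assert a["pct_lateral"] == pytest.approx(b["pct_lateral"])
        assert a["pct_forced"] == pytest.approx(b["pct_forced"])


class TestAnnotationJoin:
    def test_nearest_start_join_and_proration(self):
        from equirest.boutdetect import LyingBout

        ann = table(bout_row(start=1000, dur=600, lateral=300))
        out = annotate_bouts([LyingBout("h1", 1005, 1595)], ann)
        assert len(out) == 1
        assert out["duration_s"].iloc[0] == 590
        assert out["lateral_s"].iloc[0] == pytest.approx(295, abs=1)

    def test_unannotated_bout_is_an_error_listing_keys(self):
        from equirest.boutdetect import LyingBout

        ann = table(bout_row(start=1000))
        with pytest.raises(ValueError, match=r"\('h1', 50000\)"):
            annotate_bouts([LyingBout("h1", 50000, 50600)], ann)

    def test_spare_annotation_warns_and_is_ignored(self):
        from equirest.boutdetect import LyingBout

        ann = table(bout_row(start=1000), bout_row(start=9000))
        with pytest.warns(UserWarning, match="no matching bout"):
            out = annotate_bouts([LyingBout("h1", 1000, 1600)], ann)
        assert len(out) == 1


class TestStudyLevelFlags:
    @pytest.mark.parametrize(
        "day_minutes, expected",
        [((5, 10, 10), True), ((30, 0, 0), False), ((0, 0, 0), True)],
    )
    def test_under_30min_over_72h(self, day_minutes, expected):
        m = pd.DataFrame(
            {"horse_id": "h1", "treatment": "T1", "day_index": [1, 2, 3],
             "duration_min_total": day_minutes}
        )
        out = flag_under_72h(m)
        assert out["under_30min_72h"].iloc[0] == expected

    def test_exclusion_report_study_scale(self):
        rows = [{"horse_id": f"h{i}", "treatment": t, "day_index": d,
                 "duration_min_total": 0.0}
                for i in range(38) for t in ("T0", "T0.5", "T1", "T1.5")
                for d in (1, 2, 3)]
        m = pd.DataFrame(rows)
        excl = [(f"h{i}", "T0", "health") for i in range(6)] + \
               [(f"h{i}", "T0.5", "research") for i in range(2)] + \
               [(f"h{i}", "T1", "fodder") for i in range(8)] + \
               [(f"h{i}", "T1.5", "research") for i in range(3)]
        filtered, report = apply_exclusions(m, excl)
        assert report["n_excluded"] == 19
        assert report["pct_excluded"] == pytest.approx(12.5)
        assert len(filtered) == (152 - 19) * 3

    def test_empty_exclusion_list_is_identity(self):
        m = pd.DataFrame([{"horse_id": "h1", "treatment": "T0", "day_index": 1,
                           "duration_min_total": 5.0}])
        filtered, report = apply_exclusions(m, [])
        assert report["pct_excluded"] == 0.0
        pd.testing.assert_frame_equal(filtered, m)

    def test_toy_exclusion_percentage(self):
        rows = [{"horse_id": h, "treatment": t, "day_index": 1,
                 "duration_min_total": 0.0}
                for h in ("a", "b") for t in ("T0", "T0.5", "T1", "T1.5")]
        _, report = apply_exclusions(pd.DataFrame(rows), [("a", "T0", "x")])
        assert report["pct_excluded"] == pytest.approx(12.5)
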