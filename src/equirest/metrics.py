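"""Per-horse per-24 h lying-behaviour metrics.

Joins detector output with video-style bout annotations and computes the
outcome variables the mixed models consume, one row per horse-day: bout
counts and recumbency durations (total and per surface), the REM-deficiency
flag (total recumbency < 30 min per 24 h), the proportion of lateral
recumbency, the proportion of group members present at lie-down, and the
proportion of forcedly terminated bouts.

A 72 h recording yields three 24 h blocks per horse and treatment.  A bout
spanning a block boundary is split at the boundary; each fragment counts as
a bout in its own day and carries a duration-prorated share of the sternal/
lateral split.  Attributes tied to the lie-down moment (members present) are
credited only to the fragment that contains the lie-down; the termination
label is inherited by all fragments of the bout.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .boutdetect import LyingBout

__all__ = [
    "SURFACES",
    "annotate_bouts",
    "split_days",
    "compute_day_metrics",
    "day_metrics_table",
    "flag_under_72h",
    "apply_exclusions",
    "bouts_to_frame",
]

SURFACES = ("litter", "rubber_mats", "firm_ground")

DAY_S = 86_400
UNDER_30MIN_THRESHOLD_MIN = 30.0

_BOUT_COLS = ["horse_id", "start_s", "end_s", "duration_s", "surface",
              "sternal_s", "lateral_s", "n_present", "termination"]


def bouts_to_frame(bouts: Iterable[LyingBout]) -> pd.DataFrame:
    """Detector output as a table keyed by ``(horse_id, start_s)``."""
    return pd.DataFrame(
        [{"horse_id": b.horse_id, "start_s": b.start, "end_s": b.end,
          "duration_s": b.duration} for b in bouts],
        columns=["horse_id", "start_s", "end_s", "duration_s"],
    )


def annotate_bouts(
    bouts: pd.DataFrame | Iterable[LyingBout],
    annotations: pd.DataFrame,
    tolerance_s: int = 60,
) -> pd.DataFrame:
    """Join each bout with exactly one annotation by nearest start time.

    Detected bout boundaries can differ from the annotated (video) start by
    up to the smoothing window, so the join matches each bout to the nearest
    annotation of the same horse within ``tolerance_s``.  The annotated
    sternal/lateral split is prorated to the detected duration.  A bout with
    no matching annotation is an error listing the offending keys; an
    annotation with no bout is dropped with a warning.
    """
    if not isinstance(bouts, pd.DataFrame):
        bouts = bouts_to_frame(bouts)
    out_rows, unmatched, used = [], [], set()
    ann_by_horse = dict(tuple(annotations.groupby("horse_id", sort=False)))
    for row in bouts.itertuples(index=False):
        cand = ann_by_horse.get(row.horse_id)
        if cand is not None:
            dist = (cand["start_s"] - row.start_s).abs()
            j = dist.idxmin()
            if dist.loc[j] <= tolerance_s and (row.horse_id, j) not in used:
                used.add((row.horse_id, j))
                ann = cand.loc[j]
                dur = int(row.duration_s)
                lateral = int(round(ann["lateral_s"] * dur / max(ann["duration_s"], 1)))
                out_rows.append({
                    "horse_id": row.horse_id, "start_s": int(row.start_s),
                    "end_s": int(row.end_s), "duration_s": dur,
                    "surface": ann["surface"], "sternal_s": dur - lateral,
                    "lateral_s": lateral, "n_present": int(ann["n_present"]),
                    "termination": ann["termination"],
                })
                continue
        unmatched.append((row.horse_id, int(row.start_s)))
    if unmatched:
        raise ValueError(f"bouts without an annotation: {unmatched}")
    n_spare = len(annotations) - len(used)
    if n_spare > 0:
        warnings.warn(f"{n_spare} annotation(s) had no matching bout and were ignored",
                      stacklevel=2)
    return pd.DataFrame(out_rows, columns=_BOUT_COLS)


def split_days(
    bout_table: pd.DataFrame,
    recording_start: int = 0,
    n_days: int = 3,
) -> pd.DataFrame:
    """Tag bouts with their 24 h block, splitting boundary-spanning bouts.

    Days are consecutive 24 h blocks from ``recording_start`` (day_index
    1..n_days).  Each fragment keeps ≥1 s, counts as a bout in its own day
    and carries prorated sternal/lateral seconds; ``is_continuation`` marks
    fragments that do not contain the lie-down.  Bouts outside the recording
    window raise an error.
    """
    horizon = recording_start + n_days * DAY_S
    frags = []
    for row in bout_table.itertuples(index=False):
        if row.start_s < recording_start or row.end_s > horizon:
            raise ValueError(
                f"bout ({row.horse_id}, {row.start_s}) outside the {n_days * 24} h window"
            )
        d = dict(zip(bout_table.columns, row))
        start, end = int(row.start_s), int(row.end_s)
        first_day = (start - recording_start) // DAY_S
        last_day = (end - 1 - recording_start) // DAY_S
        for day in range(first_day, last_day + 1):
            lo = max(start, recording_start + day * DAY_S)
            hi = min(end, recording_start + (day + 1) * DAY_S)
            frag = dict(d)
            frag.update(start_s=lo, end_s=hi, duration_s=hi - lo,
                        day_index=day + 1, is_continuation=lo != start)
            if "lateral_s" in d and end > start:
                lat = int(round(d["lateral_s"] * (hi - lo) / (end - start)))
                frag["lateral_s"] = lat
                frag["sternal_s"] = (hi - lo) - lat
            frags.append(frag)
    cols = list(bout_table.columns) + ["day_index", "is_continuation"]
    return pd.DataFrame(frags, columns=cols)


def compute_day_metrics(
    day_bouts: pd.DataFrame,
    group_size: int,
    include_focal: bool = False,
) -> dict:
    """Outcome vector for one horse-day from its (possibly empty) bout table.

    Percentages: lateral recumbency relative to total recumbency; members
    present averaged over the day's lie-downs with denominator
    ``group_size - 1`` (the focal horse excluded; set ``include_focal`` to
    divide by the full group size); forced terminations relative to the
    day's bout count.  Proportions with an empty denominator are missing
    (NaN), not zero.
    """
    n_total = len(day_bouts)
    dur_s_total = float(day_bouts["duration_s"].sum()) if n_total else 0.0
    out = {"n_bouts_total": n_total, "duration_min_total": dur_s_total / 60.0}
    for surf in SURFACES:
        sub = day_bouts[day_bouts["surface"] == surf] if n_total else day_bouts
        out[f"n_bouts_{surf}"] = len(sub)
        out[f"duration_min_{surf}"] = float(sub["duration_s"].sum()) / 60.0 if len(sub) else 0.0
    out["under_30min"] = out["duration_min_total"] < UNDER_30MIN_THRESHOLD_MIN
    if dur_s_total > 0:
        out["pct_lateral"] = 100.0 * float(day_bouts["lateral_s"].sum()) / dur_s_total
    else:
        out["pct_lateral"] = np.nan
    starts = day_bouts[~day_bouts["is_continuation"]] if n_total else day_bouts
    denom = group_size if include_focal else group_size - 1
    if len(starts) and denom > 0:
        out["pct_present"] = 100.0 * float((starts["n_present"] / denom).mean())
    else:
        out["pct_present"] = np.nan
    if n_total:
        out["pct_forced"] = 100.0 * float((day_bouts["termination"] == "forced").mean())
    else:
        out["pct_forced"] = np.nan
    return out


def day_metrics_table(
    bout_table: pd.DataFrame,
    horses: Sequence[str],
    group_size: int,
    treatment: str | None = None,
    rank_class: dict[str, str] | None = None,
    group_id=None,
    recording_start: int = 0,
    n_days: int = 3,
    include_focal: bool = False,
) -> pd.DataFrame:
    """One row per horse per 24 h block (empty days included).

    ``bout_table`` is an annotated bout table (see :func:`annotate_bouts` or
    the generator's annotation output).  ``treatment``/``rank_class``/
    ``group_id`` are carried through as model covariates when given.
    """
    frags = split_days(bout_table, recording_start=recording_start, n_days=n_days)
    rows = []
    for horse in horses:
        for day in range(1, n_days + 1):
            sub = frags[(frags["horse_id"] == horse) & (frags["day_index"] == day)]
            row = {"horse_id": horse, "day_index": day}
            if group_id is not None:
                row["group"] = group_id
            if treatment is not None:
                row["treatment"] = treatment
            if rank_class is not None:
                row["rank_class"] = rank_class[horse]
            row.update(compute_day_metrics(sub, group_size, include_focal=include_focal))
            rows.append(row)
    return pd.DataFrame(rows)


def flag_under_72h(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per horse (and treatment, if present): total recumbency over the full
    recording < 30 min.  Requires the per-day rows to be present."""
    keys = ["horse_id"] + (["treatment"] if "treatment" in metrics.columns else [])
    agg = metrics.groupby(keys, sort=False)["duration_min_total"].sum().reset_index()
    agg["under_30min_72h"] = agg["duration_min_total"] < UNDER_30MIN_THRESHOLD_MIN
    return agg.drop(columns="duration_min_total")


def apply_exclusions(
    metrics: pd.DataFrame,
    exclusions: Sequence[tuple[str, str, str]],
) -> tuple[pd.DataFrame, dict]:
    """Remove all day-rows of each excluded (horse, treatment) combination.

    Returns the filtered table and a report with the excluded-combination
    count and its percentage of all horse × treatment combinations.
    """
    n_horses = metrics["horse_id"].nunique()
    n_treat = metrics["treatment"].nunique() if "treatment" in metrics.columns else 1
    drop = {(h, t) for h, t, _ in exclusions}
    if "treatment" in metrics.columns:
        mask = [
            (h, t) in drop
            for h, t in zip(metrics["horse_id"], metrics["treatment"])
        ]
    else:
        mask = metrics["horse_id"].isin({h for h, _, _ in drop}).tolist()
    mask = np.asarray(mask)
    total = n_horses * n_treat
    report = {
        "n_excluded": len(drop),
        "n_combinations": total,
        "pct_excluded": 100.0 * len(drop) / total if total else 0.0,
        "reasons": {f"{h}/{t}": r for h, t, r in exclusions},
    }
    return metrics.loc[~mask].reset_index(drop=True), report
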