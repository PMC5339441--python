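"""Littered-area dimensioning under the Swiss animal-welfare rules.

The legally required minimal littered area of a multi-roomed group housing
system is the sum, over group members, of a per-horse area determined by the
horse's withers-height category (FSVO schedule).  The experimental treatments
scale the littered portion to 0×, 0.5×, 1× or 1.5× this minimum, with the
remainder of a fixed 1.5× footprint covered by hard rubber mats.

Areas are computed in exact decimal arithmetic and rounded half-up to
0.1 m², the convention that reproduces the published treatment table.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = [
    "WITHERS_CATEGORIES",
    "CATEGORY_AREAS_M2",
    "TREATMENT_RATIOS",
    "STUDY_GROUPS",
    "STUDY_TABLE_PRINTED",
    "GroupComposition",
    "TreatmentAreas",
    "minimal_area",
    "treatment_areas",
    "treatment_table",
    "pony_count",
]

#: Withers-height categories (cm), in schedule order.
WITHERS_CATEGORIES = ("<120", "120-134", "134-148", "148-162", "162-175", ">175")

#: Minimal littered area per horse and category, m² (FSVO schedule, 2014 revision).
CATEGORY_AREAS_M2 = {
    "<120": Decimal("4.0"),
    "120-134": Decimal("4.5"),
    "134-148": Decimal("5.5"),
    "148-162": Decimal("6.0"),
    "162-175": Decimal("7.5"),
    ">175": Decimal("8.0"),
}

#: Treatment label → littered fraction of the legal minimum.
TREATMENT_RATIOS = {"T0": Decimal("0"), "T0.5": Decimal("0.5"),
                    "T1": Decimal("1"), "T1.5": Decimal("1.5")}

#: Total experimental footprint as a multiple of the legal minimum.
FOOTPRINT_RATIO = Decimal("1.5")

#: Ponies are horses with withers height ≤ 148 cm (the first three categories).
PONY_CATEGORIES = WITHERS_CATEGORIES[:3]


@dataclass(frozen=True)
class GroupComposition:
    """Horse counts per withers-height category for one group."""

    counts: dict[str, int]

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(WITHERS_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown withers categories: {sorted(unknown)}")
        for cat, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for category {cat}")

    @property
    def group_size(self) -> int:
        return sum(self.counts.values())

    @property
    def n_ponies(self) -> int:
        return sum(self.counts.get(c, 0) for c in PONY_CATEGORIES)


@dataclass(frozen=True)
class TreatmentAreas:
    treatment: str
    littered_m2: Decimal
    rubber_m2: Decimal


def _round_half_up(x: Decimal) -> Decimal:
    return x.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)


def minimal_area(comp: GroupComposition) -> Decimal:
    """Legal minimal littered area: counts · per-category areas, exact."""
    return sum(
        (CATEGORY_AREAS_M2[c] * comp.counts.get(c, 0) for c in WITHERS_CATEGORIES),
        Decimal("0.0"),
    )


def treatment_areas(minimal: Decimal | float | str, treatment: str) -> TreatmentAreas:
    """Littered and rubber-mat areas for one treatment, rounded half-up to 0.1 m².

    The littered portion is ``ratio × minimal``; rubber mats cover the rest
    of the 1.5× footprint, so T0 has no litter and T1.5 no rubber mats.
    """
    if treatment not in TREATMENT_RATIOS:
        raise ValueError(f"unknown treatment {treatment!r}; expected one of "
                         f"{sorted(TREATMENT_RATIOS)}")
    m = Decimal(str(minimal))
    if m < 0:
        raise ValueError("minimal area must be non-negative")
    ratio = TREATMENT_RATIOS[treatment]
    return TreatmentAreas(
        treatment,
        _round_half_up(ratio * m),
        _round_half_up((FOOTPRINT_RATIO - ratio) * m),
    )


def treatment_table(compositions: dict[int, GroupComposition]) -> pd.DataFrame:
    """Per-group littered areas for all four treatments (the study's design table)."""
    rows = []
    for gid, comp in compositions.items():
        m = minimal_area(comp)
        row = {"group": gid, "group_size": comp.group_size,
               "minimal_m2": float(m)}
        for t in TREATMENT_RATIOS:
            row[f"littered_{t}_m2"] = float(treatment_areas(m, t).littered_m2)
        rows.append(row)
    return pd.DataFrame(rows)


def pony_count(compositions: dict[int, GroupComposition]) -> int:
    """Number of ponies (withers height ≤ 148 cm) across all groups."""
    return sum(c.n_ponies for c in compositions.values())


def _comp(*counts: int) -> GroupComposition:
    return GroupComposition(dict(zip(WITHERS_CATEGORIES, counts)))


#: Withers-category counts of the eight study groups.
STUDY_GROUPS: dict[int, GroupComposition] = {
    1: _comp(4, 0, 0, 0, 0, 0),
    2: _comp(3, 1, 0, 0, 0, 0),
    3: _comp(7, 0, 0, 0, 0, 0),
    4: _comp(1, 0, 0, 3, 0, 0),
    5: _comp(0, 0, 0, 1, 5, 0),
    6: _comp(0, 0, 0, 1, 5, 0),
    7: _comp(1, 0, 1, 1, 0, 0),
    8: _comp(1, 0, 3, 0, 0, 0),
}

#: Littered areas (m²) as printed in the study's design table, per group and
#: treatment.  Group 8 / T0.5 prints 10.2 although 20.5 × 0.5 = 10.25 rounds
#: half-up to 10.3 — a typographical anomaly, kept verbatim for comparison.
STUDY_TABLE_PRINTED: dict[int, dict[str, float]] = {
    1: {"T0": 0.0, "T0.5": 8.0, "T1": 16.0, "T1.5": 24.0},
    2: {"T0": 0.0, "T0.5": 8.3, "T1": 16.5, "T1.5": 24.8},
    3: {"T0": 0.0, "T0.5": 14.0, "T1": 28.0, "T1.5": 42.0},
    4: {"T0": 0.0, "T0.5": 11.0, "T1": 22.0, "T1.5": 33.0},
    5: {"T0": 0.0, "T0.5": 21.8, "T1": 43.5, "T1.5": 65.3},
    6: {"T0": 0.0, "T0.5": 21.8, "T1": 43.5, "T1.5": 65.3},
    7: {"T0": 0.0, "T0.5": 7.8, "T1": 15.5, "T1.5": 23.3},
    8: {"T0": 0.0, "T0.5": 10.2, "T1": 20.5, "T1.5": 30.8},
}
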