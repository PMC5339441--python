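"""Dominance rank from paired feeding encounters.

Every unordered pair of group members meets once over a feed bucket; the
winner of each dyad is recorded.  A horse's dominance ratio is the fraction
of its own dyads it dominates (``wins / (group_size - 1)``), and the group is
dichotomised into low-ranking (ratio 0–0.5, inclusive) and high-ranking
(>0.5–1).  The encounter schedule is randomised under a welfare constraint:
no individual takes part in more than two consecutive encounters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from collections.abc import Sequence

import numpy as np
import pandas as pd

__all__ = ["RankResult", "schedule_encounters", "dominance_ratio", "rank_table"]

MAX_CONSECUTIVE_ENCOUNTERS = 2


@dataclass(frozen=True)
class RankResult:
    horse_id: str
    n_dominated: int
    ratio: float
    rank_class: str  # low | high

    def __post_init__(self) -> None:
        if not 0.0 <= self.ratio <= 1.0:
            raise ValueError("dominance ratio must lie in [0, 1]")


def _max_consecutive(order: list[tuple[str, str]]) -> int:
    worst = 0
    run: dict[str, int] = {}
    for pair in order:
        run = {h: run.get(h, 0) + 1 for h in pair}
        worst = max(worst, max(run.values()))
    return worst


def schedule_encounters(
    members: Sequence[str],
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, str]]:
    """Random round-robin order with no horse in >2 consecutive encounters.

    All ``n(n-1)/2`` dyads appear exactly once.  The order is drawn by
    seeded rejection sampling (feasible orders are plentiful for the group
    sizes of interest, 2-7); deterministic for a fixed seed.
    """
    if len(members) < 2:
        raise ValueError("need at least two group members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dyads = list(combinations(sorted(members), 2))
    if len(dyads) == 1:
        return dyads
    for _ in range(10_000):
        order = [dyads[i] for i in rng.permutation(len(dyads))]
        if _max_consecutive(order) <= MAX_CONSECUTIVE_ENCOUNTERS:
            return order
    raise RuntimeError("could not find a feasible encounter order")  # pragma: no cover


def dominance_ratio(outcomes: pd.DataFrame) -> list[RankResult]:
    """Dominance ratio and rank class for one group's round-robin outcomes.

    ``outcomes`` needs columns ``horse_a, horse_b, winner`` with winner in
    {'a', 'b'}.  Every unordered pair must appear exactly once; a missing or
    duplicated dyad is an error naming the pair.  The ratio denominator is
    the horse's own dyad count (``group_size - 1``), which maps each horse
    onto [0, 1]; a ratio of exactly 0.5 is classed low-ranking.
    """
    horses = sorted(set(outcomes["horse_a"]) | set(outcomes["horse_b"]))
    seen: set[tuple[str, str]] = set()
    wins: dict[str, int] = {h: 0 for h in horses}
    for row in outcomes.itertuples(index=False):
        pair = tuple(sorted((row.horse_a, row.horse_b)))
        if pair in seen:
            raise ValueError(f"duplicated dyad {pair}")
        seen.add(pair)
        if row.winner not in ("a", "b"):
            raise ValueError(f"winner must be 'a' or 'b', got {row.winner!r}")
        wins[row.horse_a if row.winner == "a" else row.horse_b] += 1
    missing = set(combinations(horses, 2)) - seen
    if missing:
        raise ValueError(f"missing dyad(s): {sorted(missing)}")
    n = len(horses)
    results = []
    for h in horses:
        ratio = wins[h] / (n - 1)
        results.append(RankResult(h, wins[h], ratio, "low" if ratio <= 0.5 else "high"))
    return results


def rank_table(outcomes: pd.DataFrame) -> pd.DataFrame:
    """:func:`dominance_ratio` as a tidy table."""
    return pd.DataFrame(
        [{"horse_id": r.horse_id, "n_dominated": r.n_dominated,
          "ratio": r.ratio, "rank_class": r.rank_class}
         for r in dominance_ratio(outcomes)]
    )
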