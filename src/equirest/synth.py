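"""Synthetic study generator: ground-truth lying schedules, accelerometer
traces, video-style bout annotations, pasture logs and dyadic feeding-test
outcomes.

The generator emulates a space-allowance experiment on group-housed horses:
each group is exposed to four treatments whose littered-area dimensions are
multiples (0, 0.5, 1, 1.5) of the legal minimum, and lying behaviour is
recorded for 72 h per treatment with a leg-worn 1 Hz accelerometer.  The
injected effect structure mirrors the phenomena the analysis is built to
detect: total recumbency rising with the treatment ratio, an extra rise for
low-ranking horses (rank × treatment interaction), bouts concentrated in the
dark period, and more forced bout terminations for low-ranking animals.

All randomness flows from ``SimConfig.seed`` through per-(group, treatment)
substreams of numpy's ``default_rng``, so every operation is reproducible.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from .boutdetect import AccelTrace, PastureInterval

__all__ = [
    "SimConfig",
    "TrueBout",
    "GroupSchedule",
    "simulate_schedule",
    "render_trace",
    "render_annotations",
    "simulate_dyads",
    "simulate_pasture_log",
    "simulate_study",
    "write_trace_csv",
    "write_annotations_csv",
    "write_dyads_csv",
    "write_pasture_csv",
]

#: Group sizes of the eight study groups (38 horses total).
STUDY_GROUP_SIZES = (4, 4, 7, 4, 6, 6, 3, 4)

DARK_START_H = 0.0   # dark period used for bout timing: 00:00–06:00
DARK_END_H = 6.0

_FORCED_CAUSES = ("displacement", "threat", "aggression")


@dataclass(frozen=True)
class SimConfig:
    """Scenario parameters for the synthetic study.

    Durations are minutes unless suffixed otherwise; acceleration levels are
    in g on the vertical leg axis.  ``treatment_effect`` is the extra total
    recumbency (min per 24 h) per unit treatment ratio; ``rank_interaction``
    is the additional treatment effect received by low-ranking horses.
    """

    n_groups: int = 8
    group_sizes: tuple[int, ...] = STUDY_GROUP_SIZES
    treatment_ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    recording_hours: float = 72.0
    sample_rate: float = 1.0
    standing_level: float = -1.0
    lying_level: float = 0.0
    noise_sd: float = 0.05
    locomotion_amplitude: float = 0.15
    bout_rate_per_24h: float = 4.0
    bout_duration_mean: float = 10.0
    treatment_effect: float = 25.0
    rank_interaction: float = 25.0
    forced_termination_prob_low: float = 0.25
    forced_termination_prob_high: float = 0.05
    lateral_fraction: float = 0.08
    dark_period_weight: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "forced_termination_prob_low",
            "forced_termination_prob_high",
            "lateral_fraction",
            "dark_period_weight",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("recording_hours", "sample_rate", "bout_rate_per_24h", "bout_duration_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not self.standing_level < -0.75 < self.lying_level:
            raise ValueError(
                "standing_level and lying_level must straddle the -0.75 g threshold"
            )
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes must have n_groups entries")
        for gs in self.group_sizes:
            if not 3 <= gs <= 7:
                warnings.warn(
                    f"group size {gs} outside the 3-7 range of the study design",
                    stacklevel=2,
                )

    # -- YAML scenario files ------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("group_sizes", "treatment_ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["group_sizes"] = list(d["group_sizes"])
        d["treatment_ratios"] = list(d["treatment_ratios"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass(frozen=True)
class TrueBout:
    """Ground-truth twin of an observed lying bout (seconds, half-open)."""

    horse_id: str
    start: int
    end: int
    position_profile: tuple[tuple[str, int], ...]  # (position, seconds)
    surface: str  # litter | rubber_mats | firm_ground
    n_members_present_at_start: int
    terminated: str  # self | forced

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout end must exceed start")
        if sum(d for _, d in self.position_profile) != self.end - self.start:
            raise ValueError("position profile durations must sum to bout duration")

    @property
    def duration(self) -> int:
        return self.end - self.start

    @property
    def lateral_s(self) -> int:
        return sum(d for p, d in self.position_profile if p == "lateral")

    @property
    def sternal_s(self) -> int:
        return sum(d for p, d in self.position_profile if p == "sternal")


@dataclass(frozen=True)
class GroupSchedule:
    """Ground truth for one group under one treatment ratio."""

    group_id: int
    treatment_ratio: float
    horses: tuple[str, ...]
    latent_rank: dict[str, float]  # higher score = more dominant
    rank_class: dict[str, str]  # low | high (median split of the latent score)
    bouts: dict[str, list[TrueBout]]  # per horse, non-overlapping, sorted


def _horse_ids(group_id: int, size: int) -> tuple[str, ...]:
    return tuple(f"g{group_id}h{i + 1}" for i in range(size))


def _latent_ranks(rng: np.random.Generator, horses: tuple[str, ...]) -> tuple[dict, dict]:
    scores = rng.uniform(size=len(horses))
    latent = dict(zip(horses, scores))
    med = float(np.median(scores))
    # median split; scores are continuous so ties have probability zero
    rank_class = {h: ("low" if s <= med else "high") for h, s in latent.items()}
    return latent, rank_class

def _surface_probs(ratio: float) -> tuple[tuple[str, ...], tuple[float, ...]]:
    if ratio == 0.0:  # no litter offered
        return ("rubber_mats", "firm_ground"), (0.8, 0.2)
    if ratio >= 1.5:  # fully littered, no uncovered mats
        return ("litter", "firm_ground"), (0.92, 0.08)
    return ("litter", "rubber_mats", "firm_ground"), (0.85, 0.10, 0.05)


def _draw_start(rng: np.random.Generator, day: int, dark_weight: float) -> int:
    """Bout onset from a day/night mixture: weight ``dark_weight`` on 00:00-06:00."""
    if rng.uniform() < dark_weight:
        hour = rng.uniform(DARK_START_H, DARK_END_H)
    else:
        hour = rng.uniform(DARK_END_H, 24.0)
    return int(day * 86400 + hour * 3600)


def simulate_schedule(
    config: SimConfig,
    group_id: int,
    treatment_ratio: float,
) -> GroupSchedule:
    """Simulate one group's ground-truth lying schedule for one treatment.

    Bout counts per 24 h are Poisson(``bout_rate_per_24h``); durations are
    exponential with a mean inflated so that the expected *total* recumbency
    per 24 h equals ``bout_rate × bout_duration_mean`` plus the treatment
    effect (and the rank interaction for low-ranking horses).  Bouts are
    placed without overlap by rejection within each horse's timeline.
    Identical ``(config, group_id, treatment_ratio)`` → identical output.
    """
    gs = config.group_sizes[(group_id - 1) % len(config.group_sizes)]
    horses = _horse_ids(group_id, gs)
    rank_rng = np.random.default_rng([config.seed, group_id, 10_000])
    latent, rank_class = _latent_ranks(rank_rng, horses)

    tcode = int(round(treatment_ratio * 10))
    n_days = int(np.ceil(config.recording_hours / 24.0))
    horizon = int(config.recording_hours * 3600)
    surfaces, sprobs = _surface_probs(treatment_ratio)
    p_present = min(1.0, 0.52 + 0.055 * treatment_ratio)

    bouts: dict[str, list[TrueBout]] = {}
    for hi, horse in enumerate(horses):
        rng = np.random.default_rng([config.seed, group_id, tcode, hi])
        effect = config.treatment_effect * treatment_ratio
        if rank_class[horse] == "low":
            effect += config.rank_interaction * treatment_ratio
        mean_s = 60.0 * (config.bout_duration_mean + effect / config.bout_rate_per_24h)
        occupied: list[tuple[int, int]] = []
        for day in range(n_days):
            for _ in range(rng.poisson(config.bout_rate_per_24h)):
                dur = max(5, int(round(rng.exponential(mean_s))))
                for _attempt in range(100):
                    start = _draw_start(rng, day, config.dark_period_weight)
                    end = min(start + dur, horizon)
                    if end - start < 5:
                        continue
                    if all(end <= s or start >= e for s, e in occupied):
                        occupied.append((start, end))
                        break
        occupied.sort()
        horse_bouts = []
        for start, end in occupied:
            dur = end - start
            lateral = int(rng.binomial(dur, config.lateral_fraction))
            profile = tuple(
                (p, d) for p, d in (("sternal", dur - lateral), ("lateral", lateral)) if d > 0
            )
            surface = surfaces[rng.choice(len(surfaces), p=sprobs)]
            n_present = int(rng.binomial(gs - 1, p_present))
            p_forced = (
                config.forced_termination_prob_low
                if rank_class[horse] == "low"
                else config.forced_termination_prob_high
            )
            terminated = "forced" if rng.uniform() < p_forced else "self"
            horse_bouts.append(
                TrueBout(horse, start, end, profile, surface, n_present, terminated)
            )
        bouts[horse] = horse_bouts
    return GroupSchedule(group_id, treatment_ratio, horses, latent, rank_class, bouts)


def render_trace(
    bouts: list[TrueBout],
    config: SimConfig,
    horse_id: str = "",
    seed: int | None = None,
) -> AccelTrace:
    """Invert the sensor physics: lying reads near ``lying_level`` (0 g,
    horizontal leg), standing near ``standing_level`` (−1 g) with locomotion.

    Locomotion is bounded oscillation around the standing level, clipped so
    it never crosses −0.8 g, plus isolated 1–3 s spikes toward lying — long
    enough to test the smoother, never long enough to mimic a bout.  Gaussian
    noise of ``noise_sd`` is added everywhere; samples inside bouts are drawn
    around the lying level.  Overlapping bouts are rejected.
    """
    horizon = int(config.recording_hours * 3600)
    ivs = sorted((b.start, b.end) for b in bouts)
    for (s0, e0), (s1, _) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise ValueError(f"overlapping bouts at t={s1}")
    for s, e in ivs:
        if s < 0 or e > horizon:
            raise ValueError("bout outside the recording window")

    rng = np.random.default_rng(
        [config.seed, zlib.crc32(horse_id.encode())] if seed is None else seed
    )
    t = np.arange(horizon, dtype=np.int64)
    accel = np.full(horizon, config.standing_level)

    # locomotion bursts: ~6 per hour, mean 45 s, sinusoid clipped below -0.8 g
    n_bursts = rng.poisson(6.0 * config.recording_hours)
    for _ in range(n_bursts):
        b0 = int(rng.uniform(0, horizon))
        b1 = min(horizon, b0 + max(5, int(rng.exponential(45.0))))
        phase = rng.uniform(0, 2 * np.pi)
        osc = config.locomotion_amplitude * np.sin(
            2 * np.pi * 0.5 * np.arange(b1 - b0) + phase
        )
        accel[b0:b1] = np.minimum(config.standing_level + osc, -0.8)

    # brief spikes toward lying (hoof lifts, scratching): 1-3 s, never longer
    for _ in range(rng.poisson(2.0 * config.recording_hours)):
        s0 = int(rng.uniform(0, horizon - 3))
        accel[s0 : s0 + int(rng.integers(1, 4))] = -0.5

    lying_mask = np.zeros(horizon, dtype=bool)
    for s, e in ivs:
        lying_mask[s:e] = True
    accel[lying_mask] = config.lying_level
    if config.noise_sd > 0:
        accel = accel + rng.normal(0.0, config.noise_sd, size=horizon)
    return AccelTrace(horse_id or (bouts[0].horse_id if bouts else "unknown"), t, accel)


def render_annotations(bouts: list[TrueBout]) -> pd.DataFrame:
    """Video-annotation table carrying every ground-truth bout attribute.

    One row per bout, keyed by ``(horse_id, start_s)``; forced terminations
    carry a cause category as a video observer would log one.
    """
    rows = []
    for b in sorted(bouts, key=lambda b: (b.horse_id, b.start)):
        rows.append(
            {
                "horse_id": b.horse_id,
                "start_s": b.start,
                "end_s": b.end,
                "duration_s": b.duration,
                "surface": b.surface,
                "sternal_s": b.sternal_s,
                "lateral_s": b.lateral_s,
                "n_present": b.n_members_present_at_start,
                "termination": b.terminated,
                "termination_cause": _FORCED_CAUSES[b.start % 3] if b.terminated == "forced" else "",
            }
        )
    cols = [
        "horse_id", "start_s", "end_s", "duration_s", "surface",
        "sternal_s", "lateral_s", "n_present", "termination", "termination_cause",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_dyads(
    latent_rank: dict[str, float],
    upset_prob: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Round-robin feeding-test outcomes from latent dominance scores.

    With ``upset_prob = 0`` the higher-scored horse wins every encounter;
    otherwise each outcome flips with the given probability.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    horses = sorted(latent_rank)
    rows = []
    for i, a in enumerate(horses):
        for b in horses[i + 1 :]:
            winner = "a" if latent_rank[a] > latent_rank[b] else "b"
            if rng.uniform() < upset_prob:
                winner = "b" if winner == "a" else "a"
            rows.append({"horse_a": a, "horse_b": b, "winner": winner})
    return pd.DataFrame(rows, columns=["horse_a", "horse_b", "winner"])


def simulate_pasture_log(
    config: SimConfig,
    start_hour: float = 10.0,
    hours_per_day: float = 2.0,
) -> list[PastureInterval]:
    """Daily pasture-access intervals (access is capped at 4 h per day)."""
    if hours_per_day > 4.0:
        warnings.warn("pasture access above the 4 h/day cap of the study design", stacklevel=2)
    n_days = int(np.ceil(config.recording_hours / 24.0))
    out = []
    for day in range(n_days):
        s = int(day * 86400 + start_hour * 3600)
        out.append(PastureInterval(s, s + int(hours_per_day * 3600)))
    return out


def simulate_study(config: SimConfig) -> list[GroupSchedule]:
    """All groups × all treatment ratios, deterministically from the config."""
    return [
        simulate_schedule(config, gid, ratio)
        for gid in range(1, config.n_groups + 1)
        for ratio in config.treatment_ratios
    ]


# ---------------------------------------------------------------------------
# CSV export (one-to-one with the reader dialect in boutdetect)

def write_trace_csv(trace: AccelTrace, path, origin=pd.Timestamp("2014-03-01")) -> None:
    ts = origin + pd.to_timedelta(trace.timestamps, unit="s")
    pd.DataFrame(
        {"horse_id": trace.horse_id, "timestamp_iso": ts.map(lambda t: t.isoformat()),
         "accel_g": trace.accel}
    ).to_csv(path, index=False)


def write_annotations_csv(annotations: pd.DataFrame, path) -> None:
    annotations.to_csv(path, index=False)


def write_dyads_csv(dyads: pd.DataFrame, path) -> None:
    dyads.to_csv(path, index=False)


def write_pasture_csv(pasture: list[PastureInterval], path) -> None:
    pd.DataFrame([{"start_s": p.start, "end_s": p.end} for p in pasture]).to_csv(
        path, index=False
    )
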