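"""Synthetic cohorts of hourly behavioral streams and daily productivity scores.

The generator inverts the cosinor model: each stream is a mesor plus a sum of
cosine components at fixed periods (8/12/24 h by default), with day-to-day
jitter of each component's acrophase and amplitude, additive Gaussian noise,
and block-structured missingness.  Daily 0-4 productivity scores are coupled
to a participant's latent rhythm stability so that downstream correlation
analyses have a planted, sign-known effect to recover.

Seeding uses ``numpy.random.SeedSequence`` with explicit spawn keys per
participant and feature, so enlarging a cohort never perturbs the streams of
participants already present.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .series import HourlySeries, write_streams

__all__ = [
    "RhythmProfile",
    "SimulationConfig",
    "Cohort",
    "simulate_feature_stream",
    "inject_missing",
    "simulate_productivity",
    "simulate_cohort",
    "default_group_profiles",
]

HOURS_PER_DAY = 24
HOURS_PER_WEEK = 168
DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class RhythmProfile:
    """Generative rhythm parameters for one participant x feature stream.

    ``amp_by_period`` and ``acro_by_period`` are keyed by period length in
    hours; acrophases are hours from midnight to the component peak, in
    [0, period).  ``phase_jitter_sd`` (hours/day) and ``amp_jitter_sd``
    (fraction/day) inject day-level instability; ``noise_sd`` is the additive
    hourly noise, all in signal units.
    """

    mesor: float
    amp_by_period: Mapping[float, float]
    acro_by_period: Mapping[float, float]
    noise_sd: float = 0.0
    phase_jitter_sd: float = 0.0
    amp_jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if set(self.amp_by_period) != set(self.acro_by_period):
            raise ValueError("amp_by_period and acro_by_period must share periods")
        for period, amp in self.amp_by_period.items():
            if amp < 0:
                raise ValueError(f"amplitude for period {period} must be >= 0")
            acro = self.acro_by_period[period]
            if not 0 <= acro < period:
                raise ValueError(f"acrophase for period {period} must lie in [0, {period})")
        for name in ("noise_sd", "phase_jitter_sd", "amp_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def periods(self) -> tuple[float, ...]:
        return tuple(sorted(self.amp_by_period))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_feature_stream(
    profile: RhythmProfile,
    n_hours: int,
    seed,
    participant_id: str = "sim",
    feature_name: str = "feature",
) -> HourlySeries:
    """Generate one complete (no missing hours) hourly stream.

    Hour ``t`` of day ``d = t // 24`` takes the value

        mesor + sum_c a_c(d) * cos(2*pi*(t - phi_c(d)) / T_c) + eps_t

    where per day the acrophase is jittered by N(0, phase_jitter_sd^2) hours
    and the amplitude is scaled by max(0, 1 + N(0, amp_jitter_sd^2)), and
    eps_t ~ N(0, noise_sd^2).
    """
    if n_hours < 24:
        raise ValueError(f"n_hours must be >= 24, got {n_hours}")
    rng = _as_rng(seed)
    t = np.arange(n_hours, dtype=float)
    day = (t // HOURS_PER_DAY).astype(int)
    n_days = int(day[-1]) + 1

    values = np.full(n_hours, profile.mesor, dtype=float)
    for period in profile.periods:
        base_amp = profile.amp_by_period[period]
        base_acro = profile.acro_by_period[period]
        phase_shift = rng.normal(0.0, profile.phase_jitter_sd, size=n_days)
        amp_factor = np.clip(1.0 + rng.normal(0.0, profile.amp_jitter_sd, size=n_days), 0.0, None)
        phi_d = base_acro + phase_shift[day]
        a_d = base_amp * amp_factor[day]
        values += a_d * np.cos(2.0 * np.pi * (t - phi_d) / period)
    if profile.noise_sd > 0:
        values += rng.normal(0.0, profile.noise_sd, size=n_hours)

    return HourlySeries(
        participant_id=participant_id,
        feature_name=feature_name,
        hours=np.arange(n_hours),
        values=values,
        missing_mask=np.zeros(n_hours, dtype=bool),
    )


def inject_missing(
    series: HourlySeries, fraction: float, block_mean: float, seed
) -> HourlySeries:
    """Blank out ~``fraction`` of hours in geometric-length blocks.

    An alternating renewal process draws observed gaps with mean
    ``block_mean * (1 - fraction) / fraction`` and missing blocks with mean
    ``block_mean`` (both geometric on {1, 2, ...}), which makes the long-run
    missing fraction converge to ``fraction``.  Observed values are never
    altered; missing hours get NaN values and a True mask.  With any positive
    fraction the output always has at least one missing and one observed hour.
    """
    if not 0 <= fraction < 1:
        raise ValueError(f"fraction must be in [0, 1), got {fraction}")
    if block_mean < 1:
        raise ValueError(f"block_mean must be >= 1, got {block_mean}")
    out = series.copy()
    if fraction == 0:
        return out
    rng = _as_rng(seed)
    n = series.n_hours
    p_block = 1.0 / block_mean
    gap_mean = block_mean * (1.0 - fraction) / fraction
    p_gap = min(1.0, 1.0 / gap_mean)

    mask = np.zeros(n, dtype=bool)
    pos = 0
    while pos < n:
        pos += int(rng.geometric(p_gap))  # observed gap
        if pos >= n:
            break
        length = int(rng.geometric(p_block))
        mask[pos : min(n, pos + length)] = True
        pos += length
    if not mask.any():  # guarantee the configured process left a trace
        start = int(rng.integers(0, n))
        mask[start : min(n, start + max(1, round(block_mean)))] = True
    if mask.all():
        mask[int(rng.integers(0, n))] = False

    out.missing_mask = mask
    out.values = np.where(mask, np.nan, out.values)
    return out


def simulate_productivity(
    stability: float,
    survey_weeks: Sequence[int],
    days_per_week: int,
    coupling: float,
    seed,
    sigma_day: float = 0.7,
    participant_id: str = "sim",
    baseline: float = 2.0,
) -> pd.DataFrame:
    """Daily 0-4 productivity records for the survey weeks of one participant.

    Each day's score is ``clamp(round(baseline + coupling*stability +
    N(0, sigma_day^2)), 0, 4)``; ``stability`` is the participant's latent
    rhythm-stability z score (standardized across the cohort).
    """
    weeks = sorted(set(int(w) for w in survey_weeks))
    if not weeks:
        raise ValueError("survey_weeks must be non-empty")
    if not np.isfinite(coupling):
        raise ValueError("coupling must be finite")
    rng = _as_rng(seed)
    records = []
    for week in weeks:
        latent = baseline + coupling * stability + rng.normal(0.0, sigma_day, size=days_per_week)
        scores = np.clip(np.rint(latent), 0, 4).astype(int)
        for j, score in enumerate(scores):
            records.append(
                {
                    "participant_id": participant_id,
                    "day": (week - 1) * DAYS_PER_WEEK + j + 1,
                    "week": week,
                    "score": int(score),
                }
            )
    return pd.DataFrame.from_records(records, columns=["participant_id", "day", "week", "score"])


def default_group_profiles() -> dict[str, tuple[RhythmProfile, RhythmProfile]]:
    """Low/high sampling ranges per stability group.

    Two groups that differ only in day-to-day phase jitter: "stable"
    participants wander ~0.5 h/day in acrophase, "unstable" ones ~3 h/day —
    the instability contrast the correlation analysis is meant to detect.
    Other fields span ranges typical of standardized hourly activity-count
    features.
    """

    def ranges(jitter: float) -> tuple[RhythmProfile, RhythmProfile]:
        lo = RhythmProfile(
            mesor=10.0,
            amp_by_period={8: 0.25, 12: 0.5, 24: 2.0},
            acro_by_period={8: 0.0, 12: 0.0, 24: 12.0},
            noise_sd=1.0,
            phase_jitter_sd=jitter,
            amp_jitter_sd=0.1,
        )
        hi = RhythmProfile(
            mesor=20.0,
            amp_by_period={8: 1.0, 12: 2.0, 24: 5.0},
            acro_by_period={8: 7.9, 12: 11.9, 24: 18.0},
            noise_sd=2.0,
            phase_jitter_sd=jitter,
            amp_jitter_sd=0.1,
        )
        return lo, hi

    return {"stable": ranges(0.5), "unstable": ranges(3.0)}


@dataclass
class SimulationConfig:
    """Cohort-level simulation settings; defaults mirror the study design:

    16 study weeks, productivity surveyed in weeks 1, 6 and 15, ~10% missing
    hours in blocks of mean 1.7 h, and a 0.8 coupling between latent rhythm
    stability and the expected daily score.
    """

    n_participants: int = 100
    n_weeks: int = 16
    survey_weeks: tuple[int, ...] = (1, 6, 15)
    feature_names: tuple[str, ...] = ("steps", "sleep_minutes", "calories")
    group_profiles: Mapping[str, tuple[RhythmProfile, RhythmProfile]] = field(
        default_factory=default_group_profiles
    )
    productivity_coupling: float = 0.8
    sigma_day: float = 0.7
    days_per_week: int = 7
    missing_fraction: float = 0.10
    missing_block_mean: float = 1.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not set(self.survey_weeks) <= set(range(1, self.n_weeks + 1)):
            raise ValueError("survey_weeks must lie within 1..n_weeks")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if not self.feature_names:
            raise ValueError("at least one feature name required")


@dataclass
class Cohort:
    """Simulation output: streams, productivity records, and ground truth."""

    streams: list[HourlySeries]
    productivity: pd.DataFrame
    profiles: dict[str, dict]
    config: SimulationConfig

    def write(self, out_dir) -> None:
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_streams(self.streams, out / "streams.csv")
        self.productivity.to_csv(out / "productivity.csv", index=False)
        truth = {
            pid: {
                "group": info["group"],
                "stability": info["stability"],
                "profiles": {
                    feat: dataclasses.asdict(prof) for feat, prof in info["profiles"].items()
                },
            }
            for pid, info in self.profiles.items()
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, default=float)


def _sample_profile(
    lo: RhythmProfile, hi: RhythmProfile, rng: np.random.Generator
) -> RhythmProfile:
    """Draw a profile uniformly (fieldwise) between a low and high bound."""

    def u(a: float, b: float) -> float:
        return float(rng.uniform(a, b)) if b > a else float(a)

    periods = lo.periods
    return RhythmProfile(
        mesor=u(lo.mesor, hi.mesor),
        amp_by_period={p: u(lo.amp_by_period[p], hi.amp_by_period[p]) for p in periods},
        acro_by_period={p: u(lo.acro_by_period[p], hi.acro_by_period[p]) for p in periods},
        noise_sd=u(lo.noise_sd, hi.noise_sd),
        phase_jitter_sd=u(lo.phase_jitter_sd, hi.phase_jitter_sd),
        amp_jitter_sd=u(lo.amp_jitter_sd, hi.amp_jitter_sd),
    )


def _substream(seed: int, *key: int) -> np.random.Generator:
    # counter-based: (participant, feature, purpose) spawn key off one root seed
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Simulate a full cohort: one stream per participant x feature plus
    productivity records for the survey weeks, with ground-truth profiles
    retained for parameter-recovery tests.

    Participants alternate between the configured groups; latent stability is
    the cohort-standardized negative of the participant's phase jitter SD.
    """
    groups = sorted(config.group_profiles)
    n_hours = config.n_weeks * HOURS_PER_WEEK
    width = len(str(max(config.n_participants - 1, 1)))

    assignments: list[tuple[str, str, dict[str, RhythmProfile]]] = []
    for i in range(config.n_participants):
        pid = f"p{i:0{width}d}"
        group = groups[i % len(groups)]
        lo, hi = config.group_profiles[group]
        prof_rng = _substream(config.seed, i, 0)
        profiles = {feat: _sample_profile(lo, hi, prof_rng) for feat in config.feature_names}
        assignments.append((pid, group, profiles))

    jitters = np.array(
        [next(iter(profs.values())).phase_jitter_sd for _, _, profs in assignments]
    )
    raw = -jitters
    sd = raw.std()
    stability = (raw - raw.mean()) / sd if sd > 0 else np.zeros_like(raw)

    streams: list[HourlySeries] = []
    profiles_out: dict[str, dict] = {}
    prod_frames = []
    for i, (pid, group, profs) in enumerate(assignments):
        for j, feat in enumerate(config.feature_names):
            stream = simulate_feature_stream(
                profs[feat], n_hours, _substream(config.seed, i, 1 + j),
                participant_id=pid, feature_name=feat,
            )
            if config.missing_fraction > 0:
                stream = inject_missing(
                    stream,
                    config.missing_fraction,
                    config.missing_block_mean,
                    _substream(config.seed, i, 1000 + j),
                )
            streams.append(stream)
        prod_frames.append(
            simulate_productivity(
                float(stability[i]),
                config.survey_weeks,
                config.days_per_week,
                config.productivity_coupling,
                _substream(config.seed, i, 2000),
                sigma_day=config.sigma_day,
                participant_id=pid,
            )
        )
        profiles_out[pid] = {
            "group": group,
            "stability": float(stability[i]),
            "profiles": profs,
        }

    productivity = pd.concat(prod_frames, ignore_index=True)
    return Cohort(streams=streams, productivity=productivity, profiles=profiles_out, config=config)
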