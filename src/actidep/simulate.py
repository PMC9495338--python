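"""Synthetic actigraphy cohorts in the Depresjon layout.

The simulator emulates the statistical structure the classifier assumes:
per-minute activity counts with near-zero nocturnal values, a smooth 24-h
circadian profile during wakefulness, and overdispersed count noise.
Depressed ("condition") subjects show globally reduced daytime activity
(multiplicative factor) and more fragmented activity (extra zero-activity
bouts) — the two qualitative contrasts visible between healthy and depressed
actigraphy traces.

It is a testing fixture with the right marginal shape, not a fitted model of
any real cohort: no ultradian cycles, no weekday/weekend structure, no
inter-daily variability beyond count noise, and no MADRS severity gradient.

Counts are drawn from a negative binomial with mean ``mu`` and shape
``noise_dispersion`` (variance ``mu + mu^2/dispersion``) — actigraphy counts
are zero-inflated and strongly overdispersed, which Poisson noise would
understate.  All randomness derives from ``SimulationConfig.seed`` via
``numpy.random.SeedSequence`` spawning, so an identical config reproduces the
cohort byte for byte.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CONDITION,
    CONTROL,
    MINUTES_PER_DAY,
    CompleteDay,
    SubjectSeries,
    write_subject_csv,
)

# Simulated recordings all start on the same (arbitrary, fixed) Monday so that
# identical configs give identical timestamps.
_START_DATE = _dt.date(2020, 1, 6)

# Zero-activity bouts are injected in blocks of this many minutes.
_BOUT_MINUTES = 20


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions the classifier targets: 55 subjects
    (32 control, 23 condition) with 7 complete days each.  ``baseline_mean``
    is the expected awake activity count per minute for a control subject;
    ``circadian_amplitude`` modulates it sinusoidally over 24 h with its peak
    at ``wake_phase_hours``.  Condition subjects have their awake mean
    multiplied by ``depression_activity_factor`` and each awake 20-minute
    bout zeroed with probability ``depression_fragmentation``.
    """

    n_control: int = 32
    n_condition: int = 23
    days_per_subject: int = 7
    seed: int = 0
    baseline_mean: float = 240.0
    circadian_amplitude: float = 0.4
    wake_phase_hours: float = 14.0
    depression_activity_factor: float = 0.6
    depression_fragmentation: float = 0.15
    noise_dispersion: float = 1.5
    sleep_start_hour: float = 23.0
    sleep_end_hour: float = 7.0
    sleep_mean: float = 2.0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_condition < 0:
            raise ValueError("subject counts must be >= 0")
        if self.n_control + self.n_condition < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.days_per_subject < 1:
            raise ValueError("days_per_subject must be >= 1")
        if not 0.0 <= self.circadian_amplitude <= 1.0:
            raise ValueError("circadian_amplitude must be in [0, 1]")
        if not 0.0 < self.depression_activity_factor <= 1.0:
            raise ValueError("depression_activity_factor must be in (0, 1]")
        if not 0.0 <= self.depression_fragmentation <= 1.0:
            raise ValueError("depression_fragmentation must be in [0, 1]")
        if self.noise_dispersion <= 0:
            raise ValueError("noise_dispersion must be > 0")


def awake_mask(config: SimulationConfig) -> np.ndarray:
    """Boolean mask over the 1440 minute slots: True where the subject is awake."""
    hours = np.arange(MINUTES_PER_DAY) / 60.0
    lo, hi = config.sleep_start_hour, config.sleep_end_hour
    if lo <= hi:
        asleep = (hours >= lo) & (hours < hi)
    else:  # window wraps midnight, e.g. 23:00 -> 07:00
        asleep = (hours >= lo) | (hours < hi)
    return ~asleep


def expected_profile(config: SimulationConfig, group: int) -> np.ndarray:
    """Expected activity count per minute slot, before fragmentation."""
    hours = np.arange(MINUTES_PER_DAY) / 60.0
    circadian = 1.0 + config.circadian_amplitude * np.cos(
        2.0 * np.pi * (hours - config.wake_phase_hours) / 24.0
    )
    mu = np.where(
        awake_mask(config), config.baseline_mean * circadian, config.sleep_mean
    )
    if group == CONDITION:
        mu = np.where(awake_mask(config), mu * config.depression_activity_factor, mu)
    return mu


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    # NB parameterised by shape r and success prob p = r / (r + mu);
    # mean mu, variance mu + mu^2 / r.  mu == 0 slots stay exactly zero.
    counts = np.zeros_like(mu, dtype=np.int64)
    pos = mu > 0
    p = dispersion / (dispersion + mu[pos])
    counts[pos] = rng.negative_binomial(dispersion, p)
    return counts


def simulate_day(
    config: SimulationConfig,
    group: int,
    rng: np.random.Generator,
    date: _dt.date = _START_DATE,
) -> CompleteDay:
    """Draw one complete day of per-minute counts for one subject.

    For the condition group, after scaling the awake mean, contiguous
    20-minute awake bouts are independently zeroed with probability
    ``depression_fragmentation`` (fragmented, interrupted activity).
    """
    mu = expected_profile(config, group).copy()
    if group == CONDITION and config.depression_fragmentation > 0:
        awake = awake_mask(config)
        n_bouts = int(np.ceil(MINUTES_PER_DAY / _BOUT_MINUTES))
        zero_bout = rng.random(n_bouts) < config.depression_fragmentation
        bout_of_minute = np.arange(MINUTES_PER_DAY) // _BOUT_MINUTES
        mu[awake & zero_bout[bout_of_minute]] = 0.0
    values = _draw_counts(mu, config.noise_dispersion, rng)
    return CompleteDay(date=date, values=values)


def _subject_series(
    config: SimulationConfig, subject_id: str, group: int, rng: np.random.Generator
) -> SubjectSeries:
    days = [
        simulate_day(config, group, rng, date=_START_DATE + _dt.timedelta(days=d))
        for d in range(config.days_per_subject)
    ]
    timestamps = pd.concat(
        [
            pd.Series(
                pd.date_range(
                    start=pd.Timestamp(day.date), periods=MINUTES_PER_DAY, freq="min"
                )
            )
            for day in days
        ],
        ignore_index=True,
    )
    frame = pd.DataFrame(
        {
            "timestamp": timestamps,
            "date": timestamps.dt.date,
            "activity": np.concatenate([day.values for day in days]),
        }
    )
    return SubjectSeries(subject_id=subject_id, group=group, frame=frame)


def simulate_cohort(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> list[SubjectSeries]:
    """Simulate the full cohort; optionally write the Depresjon-style CSV tree.

    When ``out_dir`` is given, writes ``<out>/control/*.csv``,
    ``<out>/condition/*.csv`` and a ``manifest.json`` with subject ids, groups
    and the seed.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_control + config.n_condition
    )
    cohort: list[SubjectSeries] = []
    idx = 0
    for group, label, count in (
        (CONTROL, "control", config.n_control),
        (CONDITION, "condition", config.n_condition),
    ):
        for k in range(count):
            rng = np.random.Generator(np.random.PCG64(seeds[idx]))
            cohort.append(_subject_series(config, f"{label}_{k + 1:02d}", group, rng))
            idx += 1
    if out_dir is not None:
        out_dir = Path(out_dir)
        for series in cohort:
            sub = "control" if series.group == CONTROL else "condition"
            write_subject_csv(series, out_dir / sub / f"{series.subject_id}.csv")
        manifest = {
            "config": asdict(config),
            "subjects": [
                {"subject_id": s.subject_id, "group": s.group} for s in cohort
            ],
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohort
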