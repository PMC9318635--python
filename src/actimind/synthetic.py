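"""Synthetic circadian actigraphy cohorts.

Generates minute-epoch wrist-actigraphy count series for three groups —
healthy controls (0), depressive patients (1) and schizophrenic patients
(2) — with the qualitative structure reported for the public Depresjon and
Psykose recordings: daytime activity ordered control > depression >
schizophrenia, near-zero zero-inflated night activity, a lower-variance
("more structured") schizophrenia signal, and multiplicative between-subject
heterogeneity.

The expected count follows a truncated raised-cosine day bump on top of a
group-specific night floor; observed counts are zero-inflated negative
binomial draws around the subject-scaled profile.  A single ``separation``
scalar in [0, 1] interpolates every group-specific parameter between the
control values (0: all groups statistically identical) and the full
class-conditional values (1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL",
    "DEPRESSION",
    "SCHIZOPHRENIA",
    "GROUPS",
    "GROUP_NAMES",
    "SyntheticCohortSpec",
    "SubjectRecording",
    "circadian_profile",
    "generate_cohort",
]

CONTROL, DEPRESSION, SCHIZOPHRENIA = 0, 1, 2
GROUPS = (CONTROL, DEPRESSION, SCHIZOPHRENIA)
GROUP_NAMES = {CONTROL: "control", DEPRESSION: "depression", SCHIZOPHRENIA: "schizophrenia"}

MINUTES_PER_DAY = 1440
#: wake window [06:00, 24:00); minutes before 06:00 are "night"
NIGHT_MINUTES = 360

#: all cohorts start at this fixed timestamp so segment counts are exact
SYNTHETIC_START = pd.Timestamp("2020-01-06 00:00:00")

#: within-day count noise of the schizophrenia group is tightened by this
#: factor (larger negative-binomial size = less overdispersion), mimicking
#: the more structured activity reported for schizophrenic patients
SCHIZOPHRENIA_DISPERSION_SCALE = 2.0


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a class-conditional synthetic actigraphy cohort.

    Defaults emulate roughly two weeks of minute-epoch Actiwatch counts per
    subject.  Daytime mean amplitudes are ordered control > depression >
    schizophrenia; night floors and night zero-inflation are ordered the
    opposite way (patients sleep worse), which concentrates class signal in
    the night hours.
    """

    n_per_class: int = 10
    n_days: int = 13
    epoch_minutes: int = 1
    class_amplitude: Mapping[int, float] = field(
        default_factory=lambda: {CONTROL: 320.0, DEPRESSION: 220.0, SCHIZOPHRENIA: 130.0}
    )
    night_floor: Mapping[int, float] = field(
        default_factory=lambda: {CONTROL: 4.0, DEPRESSION: 12.0, SCHIZOPHRENIA: 25.0}
    )
    zero_inflation_night: Mapping[int, float] = field(
        default_factory=lambda: {CONTROL: 0.60, DEPRESSION: 0.35, SCHIZOPHRENIA: 0.20}
    )
    subject_sd: float = 0.15
    dispersion: float = 1.5
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.epoch_minutes != 1:
            raise ValueError("only 1-minute epochs are supported")
        for g in GROUPS:
            if self.class_amplitude[g] < 0 or self.night_floor[g] < 0:
                raise ValueError("amplitudes and night floors must be >= 0")
            if not 0.0 <= self.zero_inflation_night[g] <= 1.0:
                raise ValueError("zero_inflation_night must lie in [0, 1]")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")

    # group parameters after interpolating toward the control values by
    # (1 - separation); at separation=0 every group collapses onto control
    def effective_amplitude(self, group: int) -> float:
        base = self.class_amplitude[CONTROL]
        return base + self.separation * (self.class_amplitude[group] - base)

    def effective_night_floor(self, group: int) -> float:
        base = self.night_floor[CONTROL]
        return base + self.separation * (self.night_floor[group] - base)

    def effective_zero_inflation(self, group: int) -> float:
        base = self.zero_inflation_night[CONTROL]
        return base + self.separation * (self.zero_inflation_night[group] - base)

    def effective_dispersion(self, group: int) -> float:
        scale = SCHIZOPHRENIA_DISPERSION_SCALE if group == SCHIZOPHRENIA else 1.0
        return self.dispersion * (1.0 + self.separation * (scale - 1.0))


@dataclass(frozen=True)
class SubjectRecording:
    """One participant's labeled minute-epoch activity series.

    ``data`` holds two columns: ``timestamp`` (minute resolution, strictly
    increasing) and ``activity`` (non-negative integer counts, or real
    z-scores once ``standardized`` is set).
    """

    subject_id: str
    group: int
    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group}")
        missing = {"timestamp", "activity"} - set(self.data.columns)
        if missing:
            raise ValueError(f"recording missing columns {sorted(missing)}")
        if not self.standardized and (self.data["activity"].to_numpy() < 0).any():
            raise ValueError("activity counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.data)


def _day_bump(minute_of_day: np.ndarray) -> np.ndarray:
    """Raised-cosine wake-period bump: 0 over the night window, smoothly
    rising/falling over [NIGHT_MINUTES, 1440) with peak mid-afternoon."""
    m = np.asarray(minute_of_day, dtype=float)
    wake = m >= NIGHT_MINUTES
    phase = 2.0 * np.pi * (m - NIGHT_MINUTES) / (MINUTES_PER_DAY - NIGHT_MINUTES)
    return np.where(wake, 0.5 * (1.0 - np.cos(phase)), 0.0)


def circadian_profile(group: int, minute_of_day, spec: SyntheticCohortSpec):
    """Expected activity count for `group` at a given minute of the day.

    Periodic with period 1440; accepts a scalar or array of minutes in
    [0, 1439].  The night window (minutes 0-359) sits at the group's night
    floor; the wake window adds the group's raised-cosine amplitude bump.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group}")
    m = np.asarray(minute_of_day)
    if ((m < 0) | (m >= MINUTES_PER_DAY)).any():
        raise ValueError("minute_of_day must lie in [0, 1439]")
    profile = spec.effective_night_floor(group) + spec.effective_amplitude(group) * _day_bump(m)
    return float(profile) if np.isscalar(minute_of_day) else profile


def _negative_binomial(rng: np.random.Generator, mu: np.ndarray, size_param: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + mu^2/size_param."""
    mu = np.asarray(mu, dtype=float)
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def generate_cohort(spec: SyntheticCohortSpec) -> list[SubjectRecording]:
    """Draw ``3 * n_per_class`` labeled subject recordings.

    All randomness flows from a single generator seeded with ``spec.seed``;
    identical specs produce identical cohorts.
    """
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_days * MINUTES_PER_DAY
    timestamps = pd.date_range(SYNTHETIC_START, periods=n_samples, freq="min")
    minute_of_day = (np.arange(n_samples) % MINUTES_PER_DAY).astype(float)
    night_mask = minute_of_day < NIGHT_MINUTES

    recordings: list[SubjectRecording] = []
    for group in GROUPS:
        base_profile = circadian_profile(group, minute_of_day, spec)
        zi = spec.effective_zero_inflation(group)
        k = spec.effective_dispersion(group)
        for i in range(spec.n_per_class):
            subject_scale = float(np.exp(rng.normal(0.0, spec.subject_sd)))
            mu = subject_scale * base_profile
            counts = _negative_binomial(rng, mu, k)
            zero_draw = rng.random(n_samples)
            counts = np.where(night_mask & (zero_draw < zi), 0, counts)
            frame = pd.DataFrame(
                {"timestamp": timestamps, "activity": counts.astype(np.int64)}
            )
            recordings.append(
                SubjectRecording(
                    subject_id=f"{GROUP_NAMES[group]}_{i:02d}",
                    group=group,
                    data=frame,
                )
            )
    return recordings
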