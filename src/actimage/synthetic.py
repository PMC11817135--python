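"""Synthetic actigraphy cohorts with condition-dependent activity structure.

Each subject's per-minute expected activity follows a single-harmonic
circadian (cosinor) curve, ``max(0, mesor_s + amplitude * cos(2*pi*(t -
acrophase)/1440))``, where the subject-level mesor is drawn once per subject
(between-subject variability).  Counts are overdispersed via a gamma-Poisson
(negative-binomial-type) mixture and passed through a zero-inflation gate —
wrist actigraphy is zero-heavy (sleep, device off) and overdispersed.

Condition profiles encode the contrasts the classification task assumes:
depressed subjects have the lowest overall activity and the most inactive
minutes, schizophrenia the highest activity — higher than controls — with a
blunted, phase-shifted rhythm.  Because each day-image is min-max rescaled
independently, the class signal that survives encoding is carried by the
zero fraction, the relative diurnal swing and the noise texture, not by the
absolute level; the presets separate the classes on those axes too.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import Condition, SubjectSeries, write_activity_csv
from .preprocess import DAY_MINUTES


@dataclasses.dataclass
class ConditionProfile:
    """Generative parameters for one diagnostic group.

    mesor
        Mean activity level, counts/min.
    amplitude
        Diurnal swing around the mesor, counts/min.
    acrophase
        Peak time, minutes after midnight.
    dispersion
        Overdispersion coefficient alpha: count variance is
        lam + alpha * lam**2 (alpha -> 0 approaches Poisson noise).
    zero_inflation
        Extra probability that a minute records zero regardless of the rhythm.
    subject_sd
        Between-subject standard deviation of the mesor.
    """

    mesor: float
    amplitude: float
    acrophase: float
    dispersion: float
    zero_inflation: float
    subject_sd: float

    def __post_init__(self) -> None:
        if min(self.mesor, self.amplitude, self.dispersion, self.subject_sd) < 0:
            raise ValueError("mesor, amplitude, dispersion, subject_sd must be >= 0")
        if not 0 <= self.zero_inflation < 1:
            raise ValueError("zero_inflation must lie in [0, 1)")


# Presets: "easy" separates the groups by several pooled SDs on zero fraction
# and relative swing (guarantees learnability in end-to-end checks); "hard"
# overlaps the distributions for robustness testing.
EASY_PROFILES: dict[Condition, ConditionProfile] = {
    Condition.CONTROL: ConditionProfile(
        mesor=300, amplitude=250, acrophase=870, dispersion=0.6,
        zero_inflation=0.30, subject_sd=30,
    ),
    Condition.DEPRESSION: ConditionProfile(
        mesor=110, amplitude=80, acrophase=870, dispersion=0.8,
        zero_inflation=0.55, subject_sd=20,
    ),
    Condition.SCHIZOPHRENIA: ConditionProfile(
        mesor=480, amplitude=160, acrophase=990, dispersion=0.5,
        zero_inflation=0.10, subject_sd=40,
    ),
}

HARD_PROFILES: dict[Condition, ConditionProfile] = {
    Condition.CONTROL: ConditionProfile(
        mesor=240, amplitude=180, acrophase=870, dispersion=0.8,
        zero_inflation=0.35, subject_sd=60,
    ),
    Condition.DEPRESSION: ConditionProfile(
        mesor=190, amplitude=140, acrophase=840, dispersion=0.9,
        zero_inflation=0.45, subject_sd=60,
    ),
    Condition.SCHIZOPHRENIA: ConditionProfile(
        mesor=290, amplitude=150, acrophase=930, dispersion=0.8,
        zero_inflation=0.30, subject_sd=60,
    ),
}

PRESETS = {"easy": EASY_PROFILES, "hard": HARD_PROFILES}


@dataclasses.dataclass
class GeneratorConfig:
    preset: str = "easy"
    subjects_per_condition: int = 20
    days_per_subject: int = 10
    seed: int = 0
    profiles: dict[Condition, ConditionProfile] | None = None
    start_date: str = "2020-03-02"

    def __post_init__(self) -> None:
        if self.subjects_per_condition < 1 or self.days_per_subject < 1:
            raise ValueError("subjects and days must be at least 1")
        if self.profiles is None:
            self.profiles = PRESETS[self.preset]


def generate_subject(
    profile: ConditionProfile,
    days: int,
    seed,
    *,
    subject_id: str = "subject",
    condition: Condition | None = None,
    start_date: str = "2020-03-02",
) -> SubjectSeries:
    """Simulate one subject: ``days`` complete days at one-minute cadence.

    Identical seeds give identical series.  Counts are nonnegative integers
    with expected value (1 - zero_inflation) * lam(t), where lam follows the
    subject's cosinor curve.
    """
    rng = np.random.default_rng(seed)
    n = days * DAY_MINUTES
    mesor_s = max(0.0, rng.normal(profile.mesor, profile.subject_sd))
    t = np.arange(n) % DAY_MINUTES
    lam = np.maximum(
        0.0,
        mesor_s
        + profile.amplitude * np.cos(2 * np.pi * (t - profile.acrophase) / DAY_MINUTES),
    )
    if profile.dispersion > 0:
        # gamma-Poisson mixture: Var = lam + dispersion * lam^2
        shape = 1.0 / profile.dispersion
        mix = rng.gamma(shape, profile.dispersion * lam)
        counts = rng.poisson(mix)
    else:
        counts = rng.poisson(lam)
    if profile.zero_inflation > 0:
        counts = counts * (rng.random(n) >= profile.zero_inflation)
    timestamps = pd.date_range(start_date, periods=n, freq="min")
    return SubjectSeries(
        subject_id=subject_id,
        condition=condition,
        timestamps=timestamps,
        activity=counts.astype(np.int64),
    )


def generate_cohort(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> dict[Condition, list[SubjectSeries]]:
    """Simulate a full cohort, optionally writing one CSV per subject.

    Files land in one subdirectory per condition, in the deposited dialect,
    next to a ``manifest.json`` recording every generative parameter.
    """
    master = np.random.default_rng(config.seed)
    cohorts: dict[Condition, list[SubjectSeries]] = {}
    for cond in Condition:
        profile = config.profiles[cond]
        subjects = []
        for i in range(config.subjects_per_condition):
            sub_seed = int(master.integers(2**31))
            subjects.append(
                generate_subject(
                    profile,
                    config.days_per_subject,
                    sub_seed,
                    subject_id=f"{cond.value}_{i + 1:02d}",
                    condition=cond,
                    start_date=config.start_date,
                )
            )
        cohorts[cond] = subjects
    if out_dir is not None:
        out_dir = Path(out_dir)
        for cond, subjects in cohorts.items():
            for series in subjects:
                write_activity_csv(series, out_dir / cond.value / f"{series.subject_id}.csv")
        manifest = {
            "preset": config.preset,
            "subjects_per_condition": config.subjects_per_condition,
            "days_per_subject": config.days_per_subject,
            "seed": config.seed,
            "start_date": config.start_date,
            "profiles": {
                cond.value: dataclasses.asdict(p) for cond, p in config.profiles.items()
            },
        }
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return cohorts


def cosinor_fit(series: SubjectSeries) -> tuple[float, float, float]:
    """Least-squares single-harmonic cosinor fit.

    Returns (mesor, amplitude, acrophase in minutes after midnight); used to
    verify that the generated diurnal signal is recoverable.
    """
    t = (
        series.timestamps.hour * 60 + series.timestamps.minute
    ).to_numpy(dtype=float)
    theta = 2 * np.pi * t / DAY_MINUTES
    X = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    beta, *_ = np.linalg.lstsq(X, series.activity.astype(float), rcond=None)
    mesor, a, b = beta
    amplitude = float(np.hypot(a, b))
    acrophase = float(np.arctan2(b, a) * DAY_MINUTES / (2 * np.pi)) % DAY_MINUTES
    return float(mesor), amplitude, acrophase
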