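"""Synthetic wearable-cohort generator.

Produces minute-cadence (heart rate, steps) streams with diurnal
structure, activity bouts, and infection episodes that elevate resting
heart rate with a pre-onset ramp, plus the toy rotated-Gaussian outlier
dataset used to demonstrate cokurtosis-vector alignment.  Every
generator is a pure function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .moments import DataMatrix
from .stream import VitalsSeries

__all__ = [
    "UserProfile",
    "InfectionEpisode",
    "ToySpec",
    "simulate_user",
    "simulate_cohort",
    "toy_outlier_dataset",
]

MINUTES_PER_DAY = 1440
DEFAULT_START = np.datetime64("2024-01-01T00:00:00", "s")


@dataclass
class UserProfile:
    """Physiological parameters of one synthetic user."""

    baseline_rhr: float = 65.0  # bpm
    diurnal_amplitude: float = 5.0  # bpm, midday peak vs. nightly trough
    activity_rate: float = 4.0  # bouts per day
    hr_per_step: float = 0.3  # bpm per (step per minute)
    noise_sd: float = 3.0  # bpm
    seed: int = 0

    def __post_init__(self):
        if not (50 <= self.baseline_rhr <= 90):
            raise ConfigurationError(f"baseline_rhr {self.baseline_rhr} outside [50, 90]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class InfectionEpisode:
    """A sickness interval with elevated resting heart rate.

    The elevation ramps up linearly over ``ramp_minutes`` *before*
    ``onset`` (pre-symptomatic drift), holds at ``rhr_elevation`` during
    [onset, end), then drops.
    """

    onset: np.datetime64
    end: np.datetime64
    rhr_elevation: float = 15.0
    ramp_minutes: int = 720  # 12 h on-ramp

    def __post_init__(self):
        self.onset = np.datetime64(self.onset, "s")
        self.end = np.datetime64(self.end, "s")
        if not self.onset < self.end:
            raise ConfigurationError("episode onset must precede end")
        if self.rhr_elevation <= 0:
            raise ConfigurationError("rhr_elevation must be positive")


@dataclass
class ToySpec:
    """Rotated anisotropic bivariate Gaussian with planted outliers.

    ``outliers`` lists (distance_in_sd, count) groups placed along a
    single direction (random unless ``direction_deg`` is given); the
    distance is measured in units of the cloud's sd along that
    direction.
    """

    n: int = 1000
    variances: tuple[float, float] = (1.0, 0.2)
    rotation_deg: float = 30.0
    outliers: list[tuple[float, int]] = field(default_factory=lambda: [(8.0, 5)])
    direction_deg: float | None = None

    def __post_init__(self):
        if self.n < 100:
            raise ConfigurationError("need at least 100 points per cluster")
        if any(v <= 0 for v in self.variances):
            raise ConfigurationError("variances must be positive")


def _episode_elevation(minutes: np.ndarray, start: np.datetime64, ep: InfectionEpisode) -> np.ndarray:
    """Per-minute elevation profile for one episode (vector over minutes)."""
    t = minutes  # minute index from series start
    onset_m = float((ep.onset - start) / np.timedelta64(60, "s"))
    end_m = float((ep.end - start) / np.timedelta64(60, "s"))
    ramp_start = onset_m - ep.ramp_minutes
    elev = np.zeros_like(t, dtype=float)
    in_ramp = (t >= ramp_start) & (t < onset_m)
    elev[in_ramp] = (t[in_ramp] - ramp_start) / ep.ramp_minutes
    elev[(t >= onset_m) & (t < end_m)] = 1.0
    return elev * ep.rhr_elevation


def simulate_user(
    profile: UserProfile,
    days: int,
    episodes: list[InfectionEpisode] | None = None,
    start: np.datetime64 = DEFAULT_START,
    user_id: str = "U000",
) -> tuple[VitalsSeries, np.ndarray]:
    """Simulate one user's minute-cadence stream.

    heart rate = baseline + diurnal sinusoid + hr_per_step * steps
                 + episode elevation (ramped) + Gaussian noise

    Steps come from a Poisson bout process (bout starts in daytime,
    lognormal durations, 60-140 steps/min inside a bout; zero outside).

    Returns the series and a boolean per-minute ground-truth label array
    marking [onset, end) episode minutes.
    """
    if days < 1:
        raise ConfigurationError("days must be >= 1")
    episodes = list(episodes or [])
    for a in range(len(episodes)):
        for b in range(a + 1, len(episodes)):
            if episodes[a].onset < episodes[b].end and episodes[b].onset < episodes[a].end:
                raise ConfigurationError("overlapping infection episodes")
    rng = np.random.default_rng(profile.seed)
    n = days * MINUTES_PER_DAY
    minutes = np.arange(n, dtype=float)
    timestamps = start + (minutes.astype(int) * np.timedelta64(60, "s"))

    # diurnal: trough at midnight-ish, peak midday
    diurnal = -profile.diurnal_amplitude * np.cos(2 * math.pi * minutes / MINUTES_PER_DAY)

    # activity bouts: Poisson count per day, daytime starts, lognormal length
    steps = np.zeros(n, dtype=int)
    for day in range(days):
        for _ in range(rng.poisson(profile.activity_rate)):
            start_min = day * MINUTES_PER_DAY + int(rng.uniform(8 * 60, 22 * 60))
            # lognormal durations, capped below the window length so every
            # window keeps at least a few resting minutes
            duration = max(2, min(40, int(rng.lognormal(mean=2.8, sigma=0.5))))
            stop = min(n, start_min + duration)
            steps[start_min:stop] = rng.integers(60, 141, size=stop - start_min)

    elevation = np.zeros(n)
    for ep in episodes:
        elevation += _episode_elevation(minutes, start, ep)

    hr = (
        profile.baseline_rhr
        + diurnal
        + profile.hr_per_step * steps
        + elevation
        + rng.normal(0.0, profile.noise_sd, size=n)
    )
    hr = np.clip(hr, 25.0, 245.0)

    labels = np.zeros(n, dtype=bool)
    for ep in episodes:
        onset_m = int((ep.onset - start) / np.timedelta64(60, "s"))
        end_m = int((ep.end - start) / np.timedelta64(60, "s"))
        labels[max(0, onset_m) : max(0, min(n, end_m))] = True

    series = VitalsSeries(
        user_id=user_id, timestamps=timestamps, heart_rate=hr, steps=steps, cadence=60
    )
    return series, labels


@dataclass
class CohortMemberInfo:
    """One simulated user plus ground truth."""

    series: VitalsSeries
    labels: np.ndarray
    episodes: list[InfectionEpisode]
    profile: UserProfile

    @property
    def is_sick(self) -> bool:
        return len(self.episodes) > 0


def simulate_cohort(
    n_users: int,
    sick_fraction: float,
    days: int = 28,
    seed: int = 0,
    rhr_elevation: float = 15.0,
    start: np.datetime64 = DEFAULT_START,
) -> list[CohortMemberInfo]:
    """Simulate a cohort; the first ceil(sick_fraction*n) users get one episode.

    Profiles are drawn so baseline RHR spans >= 20 bpm across users and
    episodes begin after a 7-day healthy calibration span (onsets in
    days 10-22), leaving room for the 12-h pre-onset ramp.
    """
    if not 0 <= sick_fraction <= 1:
        raise ConfigurationError("sick_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sick = math.ceil(sick_fraction * n_users)
    members: list[CohortMemberInfo] = []
    for u in range(n_users):
        # hourly-mean RHR varies only a few bpm in healthy adults; keep the
        # per-user healthy range narrow while baselines span >= 20 bpm
        profile = UserProfile(
            baseline_rhr=rng.uniform(55.0, 75.0),
            diurnal_amplitude=rng.uniform(2.5, 4.5),
            activity_rate=rng.uniform(2.0, 6.0),
            hr_per_step=rng.uniform(0.2, 0.4),
            noise_sd=rng.uniform(2.0, 3.5),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        episodes: list[InfectionEpisode] = []
        if u < n_sick:
            # onset after the calibration span, at a daytime hour so the
            # 12-h pre-onset ramp overlaps a diurnal peak
            lo_day = min(10, max(1, days - 3))
            hi_day = max(lo_day, min(21, days - 3))
            onset_day = int(rng.integers(lo_day, hi_day + 1))
            onset_hour = rng.uniform(10.0, 17.0)
            duration_days = rng.uniform(3.0, 6.0)
            onset = start + np.timedelta64(
                onset_day * 86400 + int(onset_hour * 3600), "s"
            )
            end = onset + np.timedelta64(int(duration_days * 86400), "s")
            episodes.append(
                InfectionEpisode(onset=onset, end=end, rhr_elevation=rhr_elevation)
            )
        series, labels = simulate_user(
            profile, days, episodes, start=start, user_id=f"U{u:03d}"
        )
        members.append(
            CohortMemberInfo(series=series, labels=labels, episodes=episodes, profile=profile)
        )
    return members


def toy_outlier_dataset(
    spec: ToySpec, seed: int = 0
) -> tuple[DataMatrix, np.ndarray]:
    """Rotated anisotropic Gaussian cloud with planted outliers.

    Returns the data matrix and the true (unit) outlier direction in
    original coordinates, for alignment tests against the leading
    cokurtosis singular vector.
    """
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(spec.n, 2)) * np.sqrt(np.asarray(spec.variances))
    theta = math.radians(spec.rotation_deg)
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    cloud = base @ R.T

    if spec.direction_deg is None:
        phi = rng.uniform(0.0, 2 * math.pi)
    else:
        phi = math.radians(spec.direction_deg)
    u = np.array([math.cos(phi), math.sin(phi)])

    cov = R @ np.diag(spec.variances) @ R.T
    sd_along_u = math.sqrt(float(u @ cov @ u))
    rows = [cloud]
    for distance, count in spec.outliers:
        jitter = rng.normal(scale=0.05 * sd_along_u, size=(count, 2))
        rows.append(distance * sd_along_u * u + jitter)
    data = np.vstack(rows)
    return DataMatrix(values=data, feature_names=["x", "y"]), u
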