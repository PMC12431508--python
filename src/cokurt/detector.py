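"""Reference-grid anomaly scoring and alerting.

A healthy reference distribution H is an integer lattice over the
(heart-rate, step-total) ranges observed during a healthy period.  Each
streamed window contributes an observation D = (rhr, step_total); the
score is the Hellinger distance between the FMM of H u {D} and the FMM
of H alone, and an alert fires when the score exceeds the threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, InsufficientHistoryError
from .moments import (
    FMMVector,
    cokurtosis_tensor,
    feature_moment_metric,
    fmm_of,
    hellinger_distance,
    hosvd_factors,
    standardize,
)
from .stream import WindowFeatures

__all__ = [
    "HealthyRanges",
    "ReferenceGrid",
    "Alert",
    "AlertSeries",
    "AdaptiveBound",
    "healthy_ranges_from_features",
    "build_reference_grid",
    "anomaly_score",
    "detect",
    "adaptive_rhr_bound",
]

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.008
DEFAULT_NABLA = 100.0
DEFAULT_GRID_CAP = 2500


@dataclass(frozen=True)
class HealthyRanges:
    """Healthy (min, max) bounds for heart rate (alpha) and steps (beta)."""

    alpha_low: float
    alpha_high: float
    beta_low: float
    beta_high: float

    def __post_init__(self):
        if not self.alpha_low < self.alpha_high:
            raise ConfigurationError(
                f"degenerate heart-rate range [{self.alpha_low}, {self.alpha_high}]"
            )
        if self.beta_low > self.beta_high:
            raise ConfigurationError("beta_low must be <= beta_high")


@dataclass
class ReferenceGrid:
    """Strided integer lattice over the healthy ranges, with its FMM."""

    points: np.ndarray  # (N, 2): columns alpha (heart rate), beta (steps)
    stride: int
    ranges: HealthyRanges
    fmm_ref: FMMVector = field(init=False)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        self.fmm_ref = fmm_of(self.points)

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class Alert:
    """One scored window."""

    window_start: np.datetime64
    window_end: np.datetime64
    score: float
    is_anomaly: bool
    threshold: float
    observation: tuple[float, float]
    rhr: float
    step_total: int


@dataclass
class AlertSeries:
    """All alerts for one user, plus skipped-window bookkeeping."""

    user_id: str
    alerts: list[Alert]
    threshold: float
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.alerts)

    @property
    def max_score(self) -> float:
        return max((a.score for a in self.alerts), default=0.0)

    @property
    def anomalies(self) -> list[Alert]:
        return [a for a in self.alerts if a.is_anomaly]


@dataclass
class AdaptiveBound:
    """Personalized RHR upper bound from recent history."""

    nabla: float
    lookback_hours: float
    percentile: float = 90.0


def healthy_ranges_from_features(
    features: list[WindowFeatures],
    margin: float = 0.0,
    beta_margin: float | None = None,
) -> HealthyRanges:
    """Observed (min, max) ranges of window RHR and step totals.

    ``margin`` expands the heart-rate range by that fraction of its
    width on both sides; ``beta_margin`` (defaults to ``margin``) does
    the same for the step axis.  Margins guard against a calibration
    span undersampling the healthy extremes — the step axis usually
    needs more slack because window totals depend on how activity bouts
    happen to align with window boundaries.  Windows without a genuine
    resting observation (imputed RHR) contribute only to the step range.
    """
    if beta_margin is None:
        beta_margin = margin
    rhr = np.array([
        f.rhr
        for f in features
        if f.rhr is not None and not f.degenerate and not f.rhr_imputed
    ])
    steps = np.array([f.step_total for f in features if not f.degenerate])
    if rhr.size == 0 or steps.size == 0:
        raise DataError("no usable windows to estimate healthy ranges")
    a_lo, a_hi = float(rhr.min()), float(rhr.max())
    b_lo, b_hi = float(steps.min()), float(steps.max())
    a_pad, b_pad = margin * (a_hi - a_lo), beta_margin * (b_hi - b_lo)
    return HealthyRanges(
        alpha_low=math.floor(a_lo - a_pad),
        alpha_high=math.ceil(a_hi + a_pad),
        beta_low=math.floor(max(0.0, b_lo - b_pad)),
        beta_high=math.ceil(b_hi + b_pad),
    )


def build_reference_grid(
    ranges: HealthyRanges, cap: int = DEFAULT_GRID_CAP
) -> ReferenceGrid:
    """Integer lattice over the ranges, stride-subsampled to <= cap points.

    The stride is the smallest integer applied equally to both axes that
    brings the lattice under the cap; retained points remain lattice
    members, so subsampling never fabricates observations.
    """
    if cap < 100:
        raise ConfigurationError("grid cap must be >= 100")
    a_lo, a_hi = int(ranges.alpha_low), int(ranges.alpha_high)
    b_lo, b_hi = int(ranges.beta_low), int(ranges.beta_high)
    stride = 1
    while True:
        alphas = np.arange(a_lo, a_hi + 1, stride)
        betas = np.arange(b_lo, b_hi + 1, stride)
        if alphas.size >= 2 and betas.size >= 2 and alphas.size * betas.size > cap:
            stride += 1
            continue
        break
    A, B = np.meshgrid(alphas, betas, indexing="ij")
    points = np.column_stack([A.ravel(), B.ravel()]).astype(float)
    return ReferenceGrid(points=points, stride=stride, ranges=ranges)


def anomaly_score(grid: ReferenceGrid, observation: tuple[float, float]) -> float:
    """Hellinger distance between the FMMs of H u {D} and H.

    The observation is appended as an additional row (multiset union),
    so an interior observation perturbs the reference distribution only
    marginally and scores near zero, while a far-outside observation
    drags fourth moments along its direction and scores high.
    """
    obs = np.asarray(observation, dtype=float)
    if obs.shape != (2,) or not np.all(np.isfinite(obs)):
        raise DataError(f"observation must be a finite (alpha, beta) pair, got {observation}")
    augmented = np.vstack([grid.points, obs])
    d1 = feature_moment_metric(
        hosvd_factors(cokurtosis_tensor(standardize(augmented)))
    )
    return hellinger_distance(d1, grid.fmm_ref)


def detect(
    features: list[WindowFeatures],
    grid: ReferenceGrid,
    delta: float = DEFAULT_DELTA,
    user_id: str = "",
    include_imputed: bool = False,
) -> AlertSeries:
    """Score every usable window and flag anomalies at threshold delta.

    Degenerate and low-coverage windows are skipped (counted, logged),
    not errored: a stream must survive flat or gappy segments.  Windows
    whose RHR had to be imputed (no zero-step minute, i.e. no resting
    observation exists) are likewise skipped unless ``include_imputed``.
    """
    if delta < 0:
        raise ConfigurationError("delta must be nonnegative")
    alerts: list[Alert] = []
    skipped = 0
    for f in features:
        if (
            f.degenerate
            or f.low_coverage
            or f.rhr is None
            or (f.rhr_imputed and not include_imputed)
        ):
            skipped += 1
            logger.debug(
                "skipping window %s: flags=%s", f.window_start, sorted(f.flags)
            )
            continue
        obs = (f.rhr, float(f.step_total))
        score = anomaly_score(grid, obs)
        alerts.append(
            Alert(
                window_start=f.window_start,
                window_end=f.window_end,
                score=score,
                is_anomaly=score > delta,
                threshold=delta,
                observation=obs,
                rhr=f.rhr,
                step_total=f.step_total,
            )
        )
    return AlertSeries(user_id=user_id, alerts=alerts, threshold=delta, n_skipped=skipped)


def adaptive_rhr_bound(
    features: list[WindowFeatures],
    lookback_hours: float = 48.0,
    percentile: float = 90.0,
    band: tuple[float, float] = (90.0, 110.0),
) -> AdaptiveBound:
    """Personalized RHR bound: the 90th percentile of recent window RHR,
    clipped to the [90, 110] bpm band.

    The lookback is anchored at the first window (a healthy observation
    period) and must lie within 24-48 h.
    """
    if not 24.0 <= lookback_hours <= 48.0:
        raise ConfigurationError("lookback must lie within [24, 48] hours")
    if not features:
        raise InsufficientHistoryError("no windows in lookback", count=0)
    t0 = features[0].window_start
    horizon = t0 + np.timedelta64(int(lookback_hours * 3600), "s")
    rhr = [
        f.rhr
        for f in features
        if f.rhr is not None and not f.degenerate and f.window_start < horizon
    ]
    if len(rhr) < 10:
        raise InsufficientHistoryError(
            f"only {len(rhr)} RHR values in lookback (need >= 10)", count=len(rhr)
        )
    p = float(np.percentile(rhr, percentile))
    return AdaptiveBound(
        nabla=float(np.clip(p, band[0], band[1])),
        lookback_hours=lookback_hours,
        percentile=percentile,
    )
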