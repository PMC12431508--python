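"""End-to-end orchestration: stream -> calibrate -> grid -> detect -> evaluate.

The per-user flow mirrors the deployed detector: windows are extracted
through the sliding queue, a healthy calibration span (default the
first 7 days, minus any labeled sick intervals) fixes the reference
ranges and grid, the personalized RHR bound is read off the first
24-48 h, and every subsequent window is scored against the grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .detector import (
    DEFAULT_DELTA,
    DEFAULT_GRID_CAP,
    DEFAULT_NABLA,
    AlertSeries,
    adaptive_rhr_bound,
    build_reference_grid,
    detect,
    healthy_ranges_from_features,
)
from .errors import CokurtError
from .stream import VitalsSeries, WindowFeatures, WindowSpec, stream_process

__all__ = ["DetectConfig", "UserDetection", "detect_user", "detect_cohort"]

logger = logging.getLogger(__name__)

_DAY_SECONDS = 86_400


@dataclass(frozen=True)
class DetectConfig:
    """Operating point of the detector; defaults are the selected ones
    (1-h window / 30-min slide, delta 0.008, fixed nabla 100)."""

    window: int = 3600
    slide: int = 1800
    delta: float = DEFAULT_DELTA
    nabla: float = DEFAULT_NABLA
    adaptive_rhr: bool = False
    adaptive_lookback_hours: float = 48.0
    grid_cap: int = DEFAULT_GRID_CAP
    calibration_days: float = 7.0
    range_margin: float = 0.05
    beta_margin: float = 0.25
    min_coverage: float = 0.5
    include_imputed: bool = False


@dataclass
class UserDetection:
    """All per-user artifacts of one detection run."""

    user_id: str
    features: list[WindowFeatures]
    alerts: AlertSeries
    nabla: float
    calibration_windows: int = 0
    skipped_reason: str | None = None
    grid_size: int = 0
    stride: int = 0


def _in_any_interval(
    t: np.datetime64, intervals: list[tuple[np.datetime64, np.datetime64]]
) -> bool:
    return any(a <= t < b for a, b in intervals)


def detect_user(
    series: VitalsSeries,
    config: DetectConfig = DetectConfig(),
    sick_intervals: list[tuple[np.datetime64, np.datetime64]] | None = None,
) -> UserDetection:
    """Run the full detector on one user's stream.

    ``sick_intervals`` (labeled illness spans, if known) are excluded
    from the calibration windows so the healthy ranges stay healthy.
    All windows — calibration included — are scored and eligible to
    alert.
    """
    sick_intervals = sick_intervals or []
    spec = WindowSpec(window=config.window, slide=config.slide)
    features = stream_process(series, spec, min_coverage=config.min_coverage)
    if not features:
        return UserDetection(
            user_id=series.user_id, features=[], nabla=config.nabla,
            alerts=AlertSeries(user_id=series.user_id, alerts=[], threshold=config.delta),
            skipped_reason="no windows",
        )
    t0 = features[0].window_start
    calib_end = t0 + np.timedelta64(int(config.calibration_days * _DAY_SECONDS), "s")
    calibration = [
        f
        for f in features
        if f.window_start < calib_end
        and not f.low_coverage
        and not _in_any_interval(f.window_start, sick_intervals)
    ]
    try:
        ranges = healthy_ranges_from_features(
            calibration, margin=config.range_margin, beta_margin=config.beta_margin
        )
    except CokurtError as exc:
        logger.warning("user %s: cannot calibrate (%s)", series.user_id, exc)
        return UserDetection(
            user_id=series.user_id, features=features, nabla=config.nabla,
            alerts=AlertSeries(user_id=series.user_id, alerts=[], threshold=config.delta),
            skipped_reason=str(exc),
        )
    grid = build_reference_grid(ranges, cap=config.grid_cap)
    nabla = config.nabla
    if config.adaptive_rhr:
        try:
            nabla = adaptive_rhr_bound(
                features, lookback_hours=config.adaptive_lookback_hours
            ).nabla
        except CokurtError as exc:
            logger.warning(
                "user %s: adaptive bound unavailable (%s); keeping %g",
                series.user_id, exc, nabla,
            )
    alerts = detect(features, grid, delta=config.delta, user_id=series.user_id,
                    include_imputed=config.include_imputed)
    return UserDetection(
        user_id=series.user_id,
        features=features,
        alerts=alerts,
        nabla=nabla,
        calibration_windows=len(calibration),
        grid_size=len(grid),
        stride=grid.stride,
    )


def detect_cohort(
    series_by_user: dict[str, VitalsSeries],
    config: DetectConfig = DetectConfig(),
    sick_intervals: dict[str, list[tuple[np.datetime64, np.datetime64]]] | None = None,
) -> dict[str, UserDetection]:
    sick_intervals = sick_intervals or {}
    return {
        uid: detect_user(s, config, sick_intervals.get(uid))
        for uid, s in series_by_user.items()
    }
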