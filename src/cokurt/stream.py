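"""Sliding-window stream processing of wearable vitals.

A variable-length time-sensitive queue accumulates a window ``w`` of
per-minute (heart rate, steps) records, extracts latent features
(resting / active / overall heart rate and step totals), then shrinks
by the slide ``s`` to make room for new data.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, OrderingError

__all__ = [
    "VitalsSeries",
    "WindowSpec",
    "WindowFeatures",
    "window_slices",
    "window_latent_features",
    "stream_process",
]

_SECOND = np.timedelta64(1, "s")


@dataclass
class VitalsSeries:
    """One user's time-ordered (heart rate, steps) stream.

    Timestamps are ``datetime64[s]``; gaps are allowed.  ``cadence`` is
    the nominal sampling interval in seconds (60 for per-minute data).
    """

    user_id: str
    timestamps: np.ndarray
    heart_rate: np.ndarray
    steps: np.ndarray
    cadence: int = 60

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.heart_rate = np.asarray(self.heart_rate, dtype=float)
        self.steps = np.asarray(self.steps, dtype=int)
        if not (self.timestamps.shape == self.heart_rate.shape == self.steps.shape):
            raise DataError("timestamps/heart_rate/steps length mismatch")
        if self.timestamps.size == 0:
            raise DataError("empty vitals series")
        dt = np.diff(self.timestamps.astype("int64"))
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0))
            raise OrderingError(
                f"timestamps not strictly increasing at {self.timestamps[i + 1]}"
            )
        if np.any(self.heart_rate <= 20) or np.any(self.heart_rate >= 250):
            raise DataError("heart rate outside physiological range (20, 250)")
        if np.any(self.steps < 0):
            raise DataError("negative step counts")

    def __len__(self) -> int:
        return self.timestamps.size

    @property
    def span_seconds(self) -> int:
        """Series span including the final record's sampling interval."""
        return int(
            (self.timestamps[-1] - self.timestamps[0]) / _SECOND
        ) + self.cadence


@dataclass(frozen=True)
class WindowSpec:
    """Window length and slide, in seconds; 0 < slide <= window."""

    window: int
    slide: int

    def __post_init__(self):
        if not (0 < self.slide <= self.window):
            raise ConfigurationError(
                f"slide must satisfy 0 < s <= w, got s={self.slide}, w={self.window}"
            )


@dataclass
class WindowFeatures:
    """Latent features aggregated over one half-open window [start, end).

    rhr: mean heart rate over zero-step minutes (imputed from the lowest
    decile when no such minute exists); ahr: mean heart rate over
    minutes with steps > 0 (None if none); ohr: mean over all minutes.
    """

    window_start: np.datetime64
    window_end: np.datetime64
    rhr: float | None
    ahr: float | None
    ohr: float | None
    step_total: int
    n_minutes: int
    degenerate: bool = False
    rhr_imputed: bool = False
    low_coverage: bool = False
    flags: set = field(default_factory=set)


def window_slices(
    series: VitalsSeries, spec: WindowSpec
) -> list[tuple[np.datetime64, np.datetime64]]:
    """Half-open window slices [t0 + k*s, t0 + k*s + w).

    Returns ``floor((T - w)/s) + 1`` windows where T is the series span;
    an empty list (with a warning) when the span is shorter than the
    window.
    """
    T = series.span_seconds
    w, s = spec.window, spec.slide
    if T < w:
        warnings.warn(
            f"series span {T}s shorter than window {w}s; no windows emitted",
            stacklevel=2,
        )
        return []
    t0 = series.timestamps[0]
    n_windows = (T - w) // s + 1
    return [
        (t0 + np.timedelta64(k * s, "s"), t0 + np.timedelta64(k * s + w, "s"))
        for k in range(n_windows)
    ]


def _features_from_arrays(
    hr: np.ndarray,
    steps: np.ndarray,
    start: np.datetime64,
    end: np.datetime64,
    expected: int | None = None,
    min_coverage: float = 0.5,
) -> WindowFeatures | None:
    if hr.size == 0:
        return None
    resting = steps == 0
    active = ~resting
    rhr_imputed = False
    if resting.any():
        rhr = float(hr[resting].mean())
    else:
        # no zero-step minute: fall back to the mean of the lowest decile
        k = max(1, int(np.ceil(hr.size * 0.1)))
        rhr = float(np.sort(hr)[:k].mean())
        rhr_imputed = True
    ahr = float(hr[active].mean()) if active.any() else None
    ohr = float(hr.mean())
    degenerate = bool(np.ptp(hr) == 0 and np.ptp(steps) == 0)
    low_coverage = expected is not None and hr.size < min_coverage * expected
    flags = set()
    if degenerate:
        flags.add("degenerate")
    if rhr_imputed:
        flags.add("rhr_imputed")
    if low_coverage:
        flags.add("low_coverage")
    return WindowFeatures(
        window_start=start,
        window_end=end,
        rhr=rhr,
        ahr=ahr,
        ohr=ohr,
        step_total=int(steps.sum()),
        n_minutes=int(hr.size),
        degenerate=degenerate,
        rhr_imputed=rhr_imputed,
        low_coverage=low_coverage,
        flags=flags,
    )


def window_latent_features(
    series: VitalsSeries,
    start: np.datetime64,
    end: np.datetime64,
    min_coverage: float = 0.5,
) -> WindowFeatures | None:
    """Latent features for records in [start, end); None for an empty window."""
    mask = (series.timestamps >= start) & (series.timestamps < end)
    expected = int((end - start) / _SECOND) // series.cadence
    return _features_from_arrays(
        series.heart_rate[mask],
        series.steps[mask],
        start,
        end,
        expected=expected,
        min_coverage=min_coverage,
    )


def stream_process(
    series: VitalsSeries,
    spec: WindowSpec,
    consumer=None,
    min_coverage: float = 0.5,
    queue_trace: list | None = None,
) -> list[WindowFeatures]:
    """Process the stream through a bounded time-sensitive queue.

    Records are consumed in arrival order; the queue accumulates at most
    one window of data, emits that window's features, then shrinks by
    the slide.  ``consumer``, if given, is called with each emitted
    ``WindowFeatures``.  ``queue_trace``, if given, records the queue
    length at every append (the memory contract: peak <= ceil(w/cadence)).

    Empty windows are skipped (gap); the emitted sequence matches a
    batch pass with :func:`window_slices` + :func:`window_latent_features`.
    """
    slices = window_slices(series, spec)
    out: list[WindowFeatures] = []
    if not slices:
        return out
    queue: deque[int] = deque()  # indices into the series arrays
    widx = 0
    n = len(series)
    expected = spec.window // series.cadence
    i = 0
    prev_ts = None
    while widx < len(slices):
        start, end = slices[widx]
        # ingest records up to the current window's end
        while i < n and series.timestamps[i] < end:
            if prev_ts is not None and series.timestamps[i] <= prev_ts:
                raise OrderingError(f"out-of-order record at {series.timestamps[i]}")
            prev_ts = series.timestamps[i]
            queue.append(i)
            if queue_trace is not None:
                queue_trace.append(len(queue))
            i += 1
        idx = np.fromiter(
            (j for j in queue if series.timestamps[j] >= start), dtype=int, count=-1
        )
        feats = _features_from_arrays(
            series.heart_rate[idx] if idx.size else np.empty(0),
            series.steps[idx] if idx.size else np.empty(0, dtype=int),
            start,
            end,
            expected=expected,
            min_coverage=min_coverage,
        )
        if feats is not None:
            out.append(feats)
            if consumer is not None:
                consumer(feats)
        # shrink: drop records older than the next window's start
        next_start = start + np.timedelta64(spec.slide, "s")
        while queue and series.timestamps[queue[0]] < next_start:
            queue.popleft()
        widx += 1
    return out
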