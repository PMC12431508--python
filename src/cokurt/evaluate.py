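"""Patient-level evaluation: confusion matrix, F1/FNR, threshold sweep.

A patient is *observed* sick when their maximum window RHR exceeds the
margin nabla, and *predicted* sick when their maximum Hellinger score
exceeds the threshold delta.  Metrics are computed per patient, and the
(delta, nabla) grid sweep summarizes uncertainty with empirical
percentile bands across the swept nuisance axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detector import AlertSeries

__all__ = [
    "PatientLabel",
    "ConfusionMatrix",
    "SweepResult",
    "patient_summary",
    "label_patients",
    "confusion_matrix",
    "f1_fnr",
    "uncertainty_sweep",
]

logger = logging.getLogger(__name__)


@dataclass
class PatientLabel:
    user_id: str
    observed_sick: bool  # RHR criterion: max_rhr > nabla
    predicted_sick: bool  # Hellinger criterion: max_score > delta
    max_rhr: float
    max_score: float


@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int
    delta: float
    nabla: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class SweepResult:
    """Grid of per-(delta, nabla) metrics with 90% empirical CI bands."""

    deltas: np.ndarray
    nablas: np.ndarray
    f1: np.ndarray  # shape (len(deltas), len(nablas)); NaN where undefined
    fnr: np.ndarray
    ci_level: float
    # (low, high) empirical bands of each metric across the other axis
    f1_band_per_delta: np.ndarray  # (len(deltas), 2)
    fnr_band_per_delta: np.ndarray
    f1_band_per_nabla: np.ndarray  # (len(nablas), 2)
    fnr_band_per_nabla: np.ndarray


def patient_summary(alerts: AlertSeries) -> tuple[float, float] | None:
    """(max window RHR, max Hellinger score) for one user; None if unscored."""
    if not alerts.alerts:
        return None
    max_rhr = max(a.rhr for a in alerts.alerts)
    max_score = max(a.score for a in alerts.alerts)
    return max_rhr, max_score


def label_patients(
    alerts_per_user: dict[str, AlertSeries],
    delta: float,
    nabla: float | dict[str, float],
) -> list[PatientLabel]:
    """Apply the per-patient sick rules at (delta, nabla).

    ``nabla`` may be a single margin or a per-user mapping (the adaptive
    personalized bound).  Users with zero scored windows are excluded
    with a logged reason.  Both inequalities are strict.
    """
    labels: list[PatientLabel] = []
    for uid, series in alerts_per_user.items():
        summary = patient_summary(series)
        if summary is None:
            logger.warning("user %s has no scored windows; excluded", uid)
            continue
        max_rhr, max_score = summary
        bound = nabla[uid] if isinstance(nabla, dict) else nabla
        labels.append(
            PatientLabel(
                user_id=uid,
                observed_sick=max_rhr > bound,
                predicted_sick=max_score > delta,
                max_rhr=max_rhr,
                max_score=max_score,
            )
        )
    return labels


def confusion_matrix(
    labels: list[PatientLabel],
    delta: float,
    nabla: float,
    truth: dict[str, bool] | None = None,
) -> ConfusionMatrix:
    """Patient-level confusion counts.

    By default the observed class is the RHR-proxy rule carried in the
    labels; passing ``truth`` (user -> actually-sick) scores the
    predictions against simulator ground truth instead.
    """
    tp = tn = fp = fn = 0
    for lab in labels:
        observed = truth[lab.user_id] if truth is not None else lab.observed_sick
        if observed and lab.predicted_sick:
            tp += 1
        elif observed and not lab.predicted_sick:
            fn += 1
        elif not observed and lab.predicted_sick:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn, delta=delta, nabla=nabla)


def f1_fnr(cm: ConfusionMatrix) -> tuple[float | None, float | None]:
    """F1 = 2tp/(2tp+fp+fn); FNR = fn/(tp+fn); None where undefined."""
    f1 = None
    if 2 * cm.tp + cm.fp + cm.fn > 0:
        f1 = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn)
    fnr = None
    if cm.tp + cm.fn > 0:
        fnr = cm.fn / (cm.tp + cm.fn)
    return f1, fnr


def _band(values: np.ndarray, ci_level: float) -> tuple[float, float]:
    finite = values[np.isfinite(values)]
    if finite.size == 0:
        return (float("nan"), float("nan"))
    lo = (1.0 - ci_level) / 2.0 * 100.0
    return (
        float(np.percentile(finite, lo)),
        float(np.percentile(finite, 100.0 - lo)),
    )


def uncertainty_sweep(
    summaries: dict[str, tuple[float, float]],
    delta_grid: np.ndarray,
    nabla_grid: np.ndarray,
    ci_level: float = 0.90,
    truth: dict[str, bool] | None = None,
) -> SweepResult:
    """Relabel every patient at each (delta, nabla) grid point and compute
    F1/FNR, with empirical CI bands per delta (across the nabla grid)
    and per nabla (across the delta grid).

    ``summaries`` maps user -> (max_rhr, max_score); a pure function of
    its inputs.
    """
    deltas = np.asarray(delta_grid, dtype=float)
    nablas = np.asarray(nabla_grid, dtype=float)
    users = sorted(summaries)
    max_rhr = np.array([summaries[u][0] for u in users])
    max_score = np.array([summaries[u][1] for u in users])
    if truth is not None:
        observed_fixed = np.array([bool(truth[u]) for u in users])
    f1 = np.full((deltas.size, nablas.size), np.nan)
    fnr = np.full((deltas.size, nablas.size), np.nan)
    for i, d in enumerate(deltas):
        predicted = max_score > d
        for j, nb in enumerate(nablas):
            observed = observed_fixed if truth is not None else (max_rhr > nb)
            tp = int(np.sum(observed & predicted))
            fp_ = int(np.sum(~observed & predicted))
            fn_ = int(np.sum(observed & ~predicted))
            if 2 * tp + fp_ + fn_ > 0:
                f1[i, j] = 2 * tp / (2 * tp + fp_ + fn_)
            if tp + fn_ > 0:
                fnr[i, j] = fn_ / (tp + fn_)
    return SweepResult(
        deltas=deltas,
        nablas=nablas,
        f1=f1,
        fnr=fnr,
        ci_level=ci_level,
        f1_band_per_delta=np.array([_band(f1[i, :], ci_level) for i in range(deltas.size)]),
        fnr_band_per_delta=np.array([_band(fnr[i, :], ci_level) for i in range(deltas.size)]),
        f1_band_per_nabla=np.array([_band(f1[:, j], ci_level) for j in range(nablas.size)]),
        fnr_band_per_nabla=np.array([_band(fnr[:, j], ci_level) for j in range(nablas.size)]),
    )
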