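"""CSV readers/writers for wearables streams, alerts, labels, and sweeps.

Formats
-------
wearables CSV : ``user,datetime,heart_rate,steps`` (ISO-8601 datetimes)
labels CSV    : ``user,onset,end``
features CSV  : ``user,window_start,window_end,rhr,ahr,ohr,step_total,n_minutes,flags``
alerts CSV    : ``user,window_start,window_end,rhr,steps,score,threshold,is_anomaly``
sweep CSV     : ``delta,nabla,tp,fp,fn,tn,f1,fnr``
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import AlertSeries
from .errors import DataError
from .stream import VitalsSeries, WindowFeatures

__all__ = [
    "ReadReport",
    "read_vitals_csv",
    "write_vitals_csv",
    "read_labels_csv",
    "write_labels_csv",
    "write_features_csv",
    "write_alerts_csv",
    "write_sweep_csv",
    "write_manifest",
]

logger = logging.getLogger(__name__)

VITALS_COLUMNS = ["user", "datetime", "heart_rate", "steps"]


@dataclass
class ReadReport:
    """Parsed per-user series plus malformed-row accounting."""

    series: dict[str, VitalsSeries] = field(default_factory=dict)
    n_rows: int = 0
    n_rejected: int = 0
    reject_reasons: list[str] = field(default_factory=list)


def read_vitals_csv(path: str | Path, cadence: int = 60) -> ReadReport:
    """Read a wearables CSV into one time-sorted VitalsSeries per user.

    Malformed rows (unparseable datetime, non-numeric vitals, heart rate
    outside (20, 250), negative steps, duplicate timestamps) are dropped,
    counted, and reported; a missing column is a schema error.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"user": str})
    missing = [c for c in VITALS_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    report = ReadReport(n_rows=len(df))
    if df.empty:
        logger.warning("%s: no data rows", path)
        return report

    dt = pd.to_datetime(df["datetime"], errors="coerce", utc=True, format="ISO8601")
    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    steps = pd.to_numeric(df["steps"], errors="coerce")
    ok = (
        dt.notna()
        & hr.notna()
        & steps.notna()
        & (hr > 20)
        & (hr < 250)
        & (steps >= 0)
    )
    for i in np.flatnonzero(~ok.to_numpy()):
        report.reject_reasons.append(f"line {i + 2}: malformed row")
    report.n_rejected = int((~ok).sum())
    if report.n_rejected:
        logger.warning("%s: rejected %d malformed row(s)", path, report.n_rejected)
    clean = pd.DataFrame(
        {
            "user": df.loc[ok, "user"],
            "datetime": dt[ok].dt.tz_localize(None),
            "heart_rate": hr[ok],
            "steps": steps[ok].astype(int),
        }
    )
    for uid, grp in clean.groupby("user", sort=True):
        grp = grp.sort_values("datetime")
        dup = grp["datetime"].duplicated()
        if dup.any():
            report.n_rejected += int(dup.sum())
            report.reject_reasons.append(f"user {uid}: {int(dup.sum())} duplicate timestamps")
            grp = grp[~dup]
        report.series[str(uid)] = VitalsSeries(
            user_id=str(uid),
            timestamps=grp["datetime"].to_numpy().astype("datetime64[s]"),
            heart_rate=grp["heart_rate"].to_numpy(),
            steps=grp["steps"].to_numpy(),
            cadence=cadence,
        )
    return report


def write_vitals_csv(series_list: list[VitalsSeries], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "user": s.user_id,
                "datetime": np.datetime_as_string(s.timestamps, unit="s"),
                "heart_rate": np.round(s.heart_rate, 3),
                "steps": s.steps,
            }
        )
        for s in series_list
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> dict[str, list[tuple[np.datetime64, np.datetime64]]]:
    df = pd.read_csv(path, dtype={"user": str})
    missing = [c for c in ("user", "onset", "end") if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    out: dict[str, list[tuple[np.datetime64, np.datetime64]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["user"]), []).append(
            (np.datetime64(row["onset"], "s"), np.datetime64(row["end"], "s"))
        )
    return out


def write_labels_csv(
    labels: dict[str, list[tuple[np.datetime64, np.datetime64]]], path: str | Path
) -> None:
    rows = [
        {"user": uid, "onset": str(np.datetime64(a, "s")), "end": str(np.datetime64(b, "s"))}
        for uid, spans in labels.items()
        for a, b in spans
    ]
    pd.DataFrame(rows, columns=["user", "onset", "end"]).to_csv(path, index=False)


def write_features_csv(
    features_per_user: dict[str, list[WindowFeatures]], path: str | Path
) -> None:
    rows = []
    for uid, feats in features_per_user.items():
        for f in feats:
            rows.append(
                {
                    "user": uid,
                    "window_start": str(f.window_start),
                    "window_end": str(f.window_end),
                    "rhr": f.rhr,
                    "ahr": f.ahr,
                    "ohr": f.ohr,
                    "step_total": f.step_total,
                    "n_minutes": f.n_minutes,
                    "flags": "|".join(sorted(f.flags)),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "user", "window_start", "window_end", "rhr", "ahr", "ohr",
            "step_total", "n_minutes", "flags",
        ],
    ).to_csv(path, index=False)


def write_alerts_csv(alerts_per_user: dict[str, AlertSeries], path: str | Path) -> None:
    rows = []
    for uid, series in alerts_per_user.items():
        for a in series.alerts:
            rows.append(
                {
                    "user": uid,
                    "window_start": str(a.window_start),
                    "window_end": str(a.window_end),
                    "rhr": a.rhr,
                    "steps": a.step_total,
                    "score": a.score,
                    "threshold": a.threshold,
                    "is_anomaly": a.is_anomaly,
                }
            )
    pd.DataFrame(
        rows,
        columns=["user", "window_start", "window_end", "rhr", "steps",
                 "score", "threshold", "is_anomaly"],
    ).to_csv(path, index=False)


def write_sweep_csv(sweep, cms: list | None, path: str | Path) -> None:
    """Serialize a SweepResult grid to ``delta,nabla,...,f1,fnr`` rows."""
    rows = []
    for i, d in enumerate(sweep.deltas):
        for j, nb in enumerate(sweep.nablas):
            rows.append(
                {
                    "delta": d,
                    "nabla": nb,
                    "f1": sweep.f1[i, j],
                    "fnr": sweep.fnr[i, j],
                }
            )
    pd.DataFrame(rows, columns=["delta", "nabla", "f1", "fnr"]).to_csv(path, index=False)


def write_manifest(path: str | Path, **entries) -> None:
    """Write a reproducibility manifest (seeds, config, versions)."""
    import cokurt

    manifest = {"cokurt_version": cokurt.__version__, **entries}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
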