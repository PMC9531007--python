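"""Sliding-window thresholding of anomaly score series.

Each scored context is tested against the multiset of scores dated within its
own trailing window (current score included).  Three rules are supported:

* robust z: flag when 0.6745 * (x - median) / MAD exceeds the threshold (the
  modified z-score, insensitive to window outliers);
* Tukey / IQR: flag when x > Q3 + thr * (Q3 - Q1);
* quantile: flag when x exceeds the empirical q-quantile of the window.

Windows with fewer than ``min_window_count`` scores never flag: MAD and IQR
are not meaningful on one or two points and the start of a series would
otherwise alert spuriously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import ScoreSeries

__all__ = ["TABLE_GRID", "ThresholdConfig", "AlertSet", "window_scores",
           "robust_z_flag", "iqr_flag", "quantile_flag", "detect",
           "write_alerts_csv", "read_alerts_csv"]

logger = logging.getLogger(__name__)

# canonical experimental grid
TABLE_GRID = {
    "window_days": (7, 14, 21, 30, 60, 90),
    "z_thr": (1.65, 1.8, 3.0, 4.0),
    "iqr_thr": (1.0, 1.2),
    "q_thr": (0.95, 0.96, 0.97, 0.98),
}

_MAD_SCALE = 0.6745  # makes MAD consistent with the SD under normality


@dataclass(frozen=True)
class ThresholdConfig:
    method: str = "robust_z"  # robust_z | iqr | quantile
    window_days: int = 7
    z_thr: float = 1.65
    iqr_thr: float = 1.2
    q_thr: float = 0.95
    min_window_count: int = 3

    def __post_init__(self) -> None:
        if self.method not in ("robust_z", "iqr", "quantile"):
            raise ValueError(f"unknown thresholding method {self.method!r}")
        if self.min_window_count < 1:
            raise ValueError("min_window_count must be >= 1")
        for name, grid in (("window_days", TABLE_GRID["window_days"]),
                           ("z_thr", TABLE_GRID["z_thr"]),
                           ("iqr_thr", TABLE_GRID["iqr_thr"]),
                           ("q_thr", TABLE_GRID["q_thr"])):
            val = getattr(self, name)
            if val not in grid:
                logger.warning("%s=%s is off the canonical grid %s", name, val, grid)

    @property
    def threshold(self) -> float:
        return {"robust_z": self.z_thr, "iqr": self.iqr_thr,
                "quantile": self.q_thr}[self.method]


@dataclass
class AlertSet:
    """Flagged contexts: frame columns context_id, end_date, score."""

    patient_id: str
    frame: pd.DataFrame
    method: str = ""
    params: dict | None = None

    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.frame["end_date"])


def window_scores(scores: ScoreSeries, t, window_days: int) -> np.ndarray:
    """All scores dated in the half-open window (t - window_days, t]."""
    f = scores.frame
    t = pd.Timestamp(t)
    lo = t - pd.Timedelta(days=window_days)
    sel = (f["end_date"] > lo) & (f["end_date"] <= t)
    return f.loc[sel, "score"].to_numpy()


def robust_z_flag(window: np.ndarray, current: float, z_thr: float,
                  min_window_count: int = 3) -> bool:
    if window.size < min_window_count:
        return False
    med = float(np.median(window))
    mad = float(np.median(np.abs(window - med)))
    if mad == 0:
        logger.debug("MAD = 0; falling back to median-exceedance test")
        return current > med
    return _MAD_SCALE * (current - med) / mad > z_thr


def iqr_flag(window: np.ndarray, current: float, iqr_thr: float,
             min_window_count: int = 3) -> bool:
    if window.size < min_window_count:
        return False
    q1, q3 = np.quantile(window, [0.25, 0.75])  # linear interpolation
    return current > q3 + iqr_thr * (q3 - q1)


def quantile_flag(window: np.ndarray, current: float, q_thr: float,
                  min_window_count: int = 3) -> bool:
    if window.size < min_window_count:
        return False
    return current > float(np.quantile(window, q_thr))


_FLAGGERS = {"robust_z": ("z_thr", robust_z_flag),
             "iqr": ("iqr_thr", iqr_flag),
             "quantile": ("q_thr", quantile_flag)}


def detect(scores: ScoreSeries, cfg: ThresholdConfig) -> AlertSet:
    """One causal pass over contexts in date order; flagged ones become alerts."""
    attr, flag = _FLAGGERS[cfg.method]
    thr = getattr(cfg, attr)
    f = scores.frame.sort_values("end_date", kind="stable")
    rows = []
    for row in f.itertuples(index=False):
        w = window_scores(scores, row.end_date, cfg.window_days)
        if flag(w, row.score, thr, cfg.min_window_count):
            rows.append((row.context_id, row.end_date, row.score))
    frame = pd.DataFrame(rows, columns=["context_id", "end_date", "score"])
    params = {"window_days": cfg.window_days, "threshold": thr}
    return AlertSet(patient_id=scores.patient_id, frame=frame,
                    method=cfg.method, params=params)


def write_alerts_csv(alerts: list[AlertSet], path) -> None:
    frames = []
    for a in alerts:
        f = a.frame.copy()
        f.insert(0, "patient_id", a.patient_id)
        f["end_date"] = pd.to_datetime(f["end_date"]).dt.strftime("%Y-%m-%d")
        f["method"] = a.method
        f["window_days"] = (a.params or {}).get("window_days")
        f["threshold"] = (a.params or {}).get("threshold")
        frames.append(f)
    cols = ["patient_id", "context_id", "end_date", "score", "method",
            "window_days", "threshold"]
    out = (pd.concat(frames, ignore_index=True) if frames
           else pd.DataFrame(columns=cols))
    out.to_csv(path, index=False, columns=cols)


def read_alerts_csv(path) -> list[AlertSet]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["end_date"] = pd.to_datetime(df["end_date"])
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        frame = grp[["context_id", "end_date", "score"]].reset_index(drop=True)
        method = grp["method"].iloc[0] if len(grp) else ""
        params = ({"window_days": grp["window_days"].iloc[0],
                   "threshold": grp["threshold"].iloc[0]} if len(grp) else None)
        out.append(AlertSet(patient_id=pid, frame=frame, method=method, params=params))
    return out
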