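"""Event-stream and label containers plus their CSV dialects.

A sensor event stream is the raw input of the whole pipeline: one row per
passive-infrared (PIR) firing, (patient_id, timestamp, location), with the
closed five-room vocabulary of a monitored household.  Labels are weak,
day-dated annotations of adverse events (UTI or hospitalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "LOCATIONS",
    "LABEL_TYPES",
    "SensorEventStream",
    "LabelSet",
    "read_events_csv",
    "write_events_csv",
    "read_labels_csv",
    "write_labels_csv",
]

LOCATIONS = ("bathroom", "bedroom", "hallway", "kitchen", "lounge")
LABEL_TYPES = ("UTI", "hospitalization")


@dataclass
class SensorEventStream:
    """Ordered PIR firings for one patient.

    ``events`` has columns ``timestamp`` (datetime64, minute resolution) and
    ``location``; rows are sorted by timestamp.
    """

    patient_id: str
    events: pd.DataFrame

    def __post_init__(self) -> None:
        ev = self.events
        if list(ev.columns) != ["timestamp", "location"]:
            raise ValueError("events must have columns [timestamp, location]")
        if len(ev) and not ev["timestamp"].is_monotonic_increasing:
            raise ValueError("event timestamps must be non-decreasing")

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class LabelSet:
    """Weak anomaly labels for one patient: (date, type) pairs."""

    patient_id: str
    labels: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["date", "type"]))

    def __post_init__(self) -> None:
        lb = self.labels
        if list(lb.columns) != ["date", "type"]:
            raise ValueError("labels must have columns [date, type]")
        bad = set(lb["type"]) - set(LABEL_TYPES)
        if bad:
            raise ValueError(f"unknown label types: {sorted(bad)}")
        if lb.duplicated(["date", "type"]).any():
            raise ValueError("duplicate (date, type) label")

    def __len__(self) -> int:
        return len(self.labels)


def write_events_csv(streams: list[SensorEventStream], path: str | Path) -> None:
    frames = []
    for s in streams:
        f = s.events.copy()
        f.insert(0, "patient_id", s.patient_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "timestamp", "location"])
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[SensorEventStream]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        ev = grp[["timestamp", "location"]].sort_values("timestamp", kind="stable")
        out.append(SensorEventStream(patient_id=pid, events=ev.reset_index(drop=True)))
    return out


def write_labels_csv(labels: list[LabelSet], path: str | Path) -> None:
    frames = []
    for ls in labels:
        f = ls.labels.copy()
        f.insert(0, "patient_id", ls.patient_id)
        frames.append(f)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["patient_id", "date", "type"])
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> list[LabelSet]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["date"] = pd.to_datetime(df["date"])
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        out.append(LabelSet(patient_id=pid, labels=grp[["date", "type"]].reset_index(drop=True)))
    return out
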