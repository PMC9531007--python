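"""Daily feature engineering from raw PIR event streams.

Raw firings are collapsed into *runs* (maximal bursts of consecutive firings
from the same sensor), which are the unit of activity counting.  From the runs
we derive, per calendar day, the fixed 11-feature vocabulary used for anomaly
scoring: day-to-day Wasserstein change of the hourly activity histogram
(bathroom, hallway, lounge), early-morning [00:00, 06:00) and late-evening
[18:00, 24:00)-of-previous-day counts (bathroom, kitchen, bedroom), and dwell
durations (bedroom, bathroom).  Communal-space durations are excluded: patient
and carer activity cannot be distinguished there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance

from .streams import LOCATIONS, SensorEventStream

__all__ = ["FEATURES", "EventRun", "FeatureSeries", "collapse_runs", "location_durations",
           "daily_counts", "hourly_histogram", "wasserstein_1d", "build_feature_series",
           "write_features_csv", "read_features_csv"]

logger = logging.getLogger(__name__)

FEATURES = (
    "bathroom_wass", "hallway_wass", "lounge_wass",
    "bathroom_em", "bathroom_le",
    "kitchen_em", "kitchen_le",
    "bedroom_em", "bedroom_le",
    "bedroom_duration", "bathroom_duration",
)

_EM_HOURS = (0, 6)    # [00:00, 06:00) current day
_LE_HOURS = (18, 24)  # [18:00, 24:00) previous day
_WASS_LOCATIONS = ("bathroom", "hallway", "lounge")
_MIN_PER_DAY = 1440


@dataclass(frozen=True)
class EventRun:
    """Maximal run of consecutive same-sensor firings."""

    location: str
    first_firing: pd.Timestamp
    last_firing: pd.Timestamp
    n_firings: int

    def __post_init__(self) -> None:
        if self.first_firing > self.last_firing:
            raise ValueError("run must have first_firing <= last_firing")


@dataclass
class FeatureSeries:
    """Per-patient daily feature matrix over a contiguous calendar span.

    ``frame`` is indexed by day (DatetimeIndex, no gaps) with the 11 feature
    columns; ``missing`` flags days with no events at all (their feature rows
    are zero-filled).
    """

    patient_id: str
    frame: pd.DataFrame
    missing: pd.Series

    @property
    def observed_days(self) -> int:
        return int((~self.missing).sum())


def collapse_runs(stream: SensorEventStream) -> list[EventRun]:
    """Collapse consecutive same-location firings into runs.

    Firings at unknown locations are dropped with a warning.  Idempotent on an
    already-collapsed sequence (alternating locations yield one run each).
    """
    ev = stream.events
    known = ev["location"].isin(LOCATIONS)
    if not known.all():
        bad = ev.loc[~known, "location"].unique().tolist()
        logger.warning("%s: dropping %d firings at unknown locations %s",
                       stream.patient_id, int((~known).sum()), bad)
        ev = ev[known]
    if not len(ev):
        return []
    ts = ev["timestamp"].to_numpy()
    loc = ev["location"].to_numpy()
    new_run = np.ones(len(ev), dtype=bool)
    new_run[1:] = loc[1:] != loc[:-1]
    starts = np.flatnonzero(new_run)
    ends = np.r_[starts[1:], len(ev)] - 1
    return [EventRun(location=str(loc[s]),
                     first_firing=pd.Timestamp(ts[s]),
                     last_firing=pd.Timestamp(ts[e]),
                     n_firings=int(e - s + 1))
            for s, e in zip(starts, ends)]


def _runs_frame(runs: list[EventRun]) -> pd.DataFrame:
    return pd.DataFrame({
        "location": [r.location for r in runs],
        "first": pd.to_datetime([r.first_firing for r in runs]),
        "last": pd.to_datetime([r.last_firing for r in runs]),
        "n": [r.n_firings for r in runs],
    })


def location_durations(runs: list[EventRun]) -> pd.DataFrame:
    """Dwell minutes per (day, location).

    Dwell of run k at location X is first_firing(k+1) - last_firing(k), split
    across midnights into the days it covers; the record's final run gets zero
    tail dwell.  Capped at 1440 min per location-day.
    """
    if len(runs) < 2:
        return pd.DataFrame(columns=list(LOCATIONS), dtype=float)
    rf = _runs_frame(runs)
    start = rf["last"].to_numpy("datetime64[m]").astype(np.int64)[:-1]
    end = rf["first"].to_numpy("datetime64[m]").astype(np.int64)[1:]
    if (end < start).any():
        raise ValueError("out-of-order runs: negative dwell")
    loc = rf["location"].to_numpy()[:-1]
    acc: dict[tuple[np.int64, str], float] = {}

    def add(day: np.int64, location: str, minutes: float) -> None:
        key = (day, location)
        acc[key] = acc.get(key, 0.0) + minutes

    for s, e, lc in zip(start, end, loc):
        d = s // _MIN_PER_DAY
        while True:
            day_end = (d + 1) * _MIN_PER_DAY
            add(d, lc, float(min(e, day_end) - max(s, d * _MIN_PER_DAY)))
            if e <= day_end:
                break
            d += 1
    if not acc:
        return pd.DataFrame(columns=list(LOCATIONS), dtype=float)
    idx = pd.MultiIndex.from_tuples(acc.keys(), names=["day", "location"])
    ser = pd.Series(list(acc.values()), index=idx)
    table = ser.unstack("location").fillna(0.0).clip(upper=_MIN_PER_DAY)
    table.index = pd.to_datetime(np.asarray(table.index, dtype="int64"), unit="D")
    return table.reindex(columns=list(LOCATIONS), fill_value=0.0)


def daily_counts(runs: list[EventRun], counts: str = "runs") -> pd.DataFrame:
    """Per-day per-location activity counts plus circadian window counts.

    A run is counted on (and within) the day/window of its *first* firing.
    ``counts="runs"`` counts visits (collapsed runs); ``counts="raw"`` counts
    every firing in the run.  Window columns: ``<loc>_em`` counts runs first
    firing in [00:00, 06:00) of the day; ``<loc>_le`` attributed to day d is
    the count in [18:00, 24:00) of day d-1.
    """
    if counts not in ("runs", "raw"):
        raise ValueError("counts must be 'runs' or 'raw'")
    cols = ([f"{loc}" for loc in LOCATIONS]
            + [f"{loc}_em" for loc in LOCATIONS] + [f"{loc}_le" for loc in LOCATIONS])
    if not runs:
        return pd.DataFrame(columns=cols, dtype=float)
    rf = _runs_frame(runs)
    w = rf["n"] if counts == "raw" else pd.Series(1, index=rf.index)
    day = rf["first"].dt.normalize()
    hour = rf["first"].dt.hour
    base = pd.DataFrame({"day": day, "location": rf["location"], "w": w})
    total = base.pivot_table(index="day", columns="location", values="w",
                             aggfunc="sum", fill_value=0)
    em = base[(hour >= _EM_HOURS[0]) & (hour < _EM_HOURS[1])].pivot_table(
        index="day", columns="location", values="w", aggfunc="sum", fill_value=0)
    le_prev = base[(hour >= _LE_HOURS[0]) & (hour < _LE_HOURS[1])].pivot_table(
        index="day", columns="location", values="w", aggfunc="sum", fill_value=0)
    le_prev.index = le_prev.index + pd.Timedelta(days=1)  # attributed to next day
    days = total.index.union(em.index).union(le_prev.index)
    out = pd.DataFrame(0.0, index=days, columns=cols)
    for loc in LOCATIONS:
        if loc in total:
            out[loc] = total[loc].reindex(days, fill_value=0)
        if loc in em:
            out[f"{loc}_em"] = em[loc].reindex(days, fill_value=0)
        if loc in le_prev:
            out[f"{loc}_le"] = le_prev[loc].reindex(days, fill_value=0)
    return out


def hourly_histogram(runs: list[EventRun], day, location: str) -> np.ndarray:
    """24-bin probability vector of run first-firings for one location-day.

    A day with no activity at the location returns the uniform vector, so the
    Wasserstein change is defined everywhere and a dead day reads as maximally
    spread activity.
    """
    day = pd.Timestamp(day).normalize()
    h = np.zeros(24)
    for r in runs:
        if r.location == location and r.first_firing.normalize() == day:
            h[r.first_firing.hour] += 1
    total = h.sum()
    if total == 0:
        return np.full(24, 1.0 / 24.0)
    return h / total


def wasserstein_1d(p, q) -> float:
    """First-order Wasserstein distance between two 24-bin histograms.

    Unit ground distance between adjacent hour bins; equals the summed
    absolute CDF difference.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (24,) or q.shape != (24,):
        raise ValueError("histograms must have 24 bins")
    if abs(p.sum() - 1.0) > 1e-9 or abs(q.sum() - 1.0) > 1e-9:
        raise ValueError("histograms must sum to 1")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("histograms must be non-negative")
    bins = np.arange(24, dtype=float)
    return float(wasserstein_distance(bins, bins, p, q))


def _hourly_histograms_matrix(rf: pd.DataFrame, days: pd.DatetimeIndex,
                              location: str) -> np.ndarray:
    """n_days x 24 histogram matrix (uniform rows for inactive days)."""
    sel = rf[rf["location"] == location]
    day_pos = days.get_indexer(sel["first"].dt.normalize())
    hours = sel["first"].dt.hour.to_numpy()
    ok = day_pos >= 0
    hist = np.zeros((len(days), 24))
    np.add.at(hist, (day_pos[ok], hours[ok]), 1.0)
    totals = hist.sum(axis=1, keepdims=True)
    uniform = np.full(24, 1.0 / 24.0)
    out = np.where(totals > 0, hist / np.where(totals > 0, totals, 1.0), uniform)
    return out


def build_feature_series(stream: SensorEventStream, start=None, end=None,
                         counts: str = "runs", duration: str = "literal"
                         ) -> FeatureSeries:
    """Assemble the 11 daily features over a contiguous calendar span.

    The span defaults to [first event day, last event day]; pass ``start`` /
    ``end`` to pin it (e.g. to the simulated observation window).  Wasserstein
    features for day d compare day d-1's hourly histogram with day d's; the
    first day's are 0.  Days with no events are flagged in ``missing`` and
    zero-filled.  ``duration="span"`` uses next-first minus this-first instead
    of the literal next-first minus this-last dwell rule.
    """
    if duration not in ("literal", "span"):
        raise ValueError("duration must be 'literal' or 'span'")
    runs = collapse_runs(stream)
    if not runs:
        raise ValueError(f"{stream.patient_id}: empty event stream")
    first_day = pd.Timestamp(start).normalize() if start is not None \
        else runs[0].first_firing.normalize()
    last_day = pd.Timestamp(end).normalize() if end is not None \
        else runs[-1].last_firing.normalize()
    days = pd.date_range(first_day, last_day, freq="D")
    if len(days) < 2:
        raise ValueError("stream must span at least 2 days")

    if duration == "span":
        shifted = [EventRun(r.location, r.first_firing, r.first_firing, r.n_firings)
                   for r in runs]
        dur = location_durations(shifted)
    else:
        dur = location_durations(runs)
    cnt = daily_counts(runs, counts=counts)
    rf = _runs_frame(runs)

    frame = pd.DataFrame(0.0, index=days, columns=list(FEATURES))
    for loc in _WASS_LOCATIONS:
        hists = _hourly_histograms_matrix(rf, days, loc)
        cdf = np.cumsum(hists, axis=1)
        wass = np.abs(cdf[1:] - cdf[:-1]).sum(axis=1)
        frame.loc[days[1:], f"{loc}_wass"] = wass
    for col in ("bathroom_em", "bathroom_le", "kitchen_em", "kitchen_le",
                "bedroom_em", "bedroom_le"):
        if col in cnt:
            frame[col] = cnt[col].reindex(days, fill_value=0.0).to_numpy()
    for loc in ("bedroom", "bathroom"):
        if loc in dur.columns:
            frame[f"{loc}_duration"] = dur[loc].reindex(days, fill_value=0.0).to_numpy()

    active_days = rf["first"].dt.normalize().unique()
    missing = pd.Series(~days.isin(active_days), index=days, name="missing")
    frame.loc[missing.to_numpy(), :] = 0.0
    return FeatureSeries(patient_id=stream.patient_id, frame=frame, missing=missing)


def write_features_csv(series_list: list[FeatureSeries], path) -> None:
    frames = []
    for fs in series_list:
        f = fs.frame.copy()
        f.insert(0, "patient_id", fs.patient_id)
        f.insert(1, "date", fs.frame.index.strftime("%Y-%m-%d"))
        f["missing"] = fs.missing.astype(int).to_numpy()
        frames.append(f.reset_index(drop=True))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_features_csv(path) -> list[FeatureSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    out = []
    for pid, grp in df.groupby("patient_id", sort=True):
        idx = pd.to_datetime(grp["date"])
        frame = grp[list(FEATURES)].set_index(pd.DatetimeIndex(idx))
        missing = pd.Series(grp["missing"].astype(bool).to_numpy(),
                            index=frame.index, name="missing")
        out.append(FeatureSeries(patient_id=pid, frame=frame, missing=missing))
    return out
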