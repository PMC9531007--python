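"""Seeded synthetic household-movement simulator.

Generates per-patient PIR event streams with circadian structure and injects
two kinds of multi-day adverse episodes with ground-truth labels:

* UTI-like: night-time (00:00-06:00) bathroom visit rate multiplied (default
  x3), night bedroom rate mildly raised (x1.5) — the nocturia / disturbed-sleep
  signature of urinary tract infection in people living with dementia;
* hospitalization-like: all activity suppressed to a fraction (default x0.1)
  of baseline — an (almost) empty house.

The generative model: per day a lognormal activity-level factor shared across
locations; per (day, location, hour) a Poisson number of *visits* at rate
base_rate x day_factor x episode_multiplier; each visit gets a uniform random
minute within its hour and is expanded into 1 + Poisson(burst_size_mean)
consecutive sensor firings, so that downstream run-collapsing is exercised.
Everything is determined by (seed, patient_index).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date

import numpy as np
import pandas as pd

from .streams import LOCATIONS, LabelSet, SensorEventStream

__all__ = ["SynthConfig", "Episode", "default_hourly_profiles", "simulate_visits",
           "simulate_patient", "simulate_cohort"]

NIGHT_HOURS = range(0, 6)  # [00:00, 06:00)


def default_hourly_profiles() -> dict[str, np.ndarray]:
    """Plausible base visit rates (visits/hour) per location over 24 h.

    Bathroom is bimodal (morning/evening) with a nocturia-scale night base;
    bedroom is night-loaded; kitchen peaks at meal times; lounge is a daytime
    plateau; hallway is flat transit traffic.
    """
    h = np.zeros(24)

    bathroom = h.copy()
    bathroom[0:6] = 0.15            # ~0.9 night visits: typical nocturia
    bathroom[6:10] = [0.4, 0.7, 0.8, 0.5]
    bathroom[10:18] = 0.18
    bathroom[18:23] = [0.3, 0.45, 0.55, 0.4, 0.3]
    bathroom[23] = 0.18

    bedroom = h.copy()
    bedroom[0:7] = 0.5              # turning over / restlessness firings
    bedroom[7] = 0.4
    bedroom[8:21] = 0.08
    bedroom[21:24] = [0.3, 0.6, 0.6]

    kitchen = h.copy()
    kitchen[0:6] = 0.01
    kitchen[6] = 0.15
    kitchen[7:10] = [0.5, 0.7, 0.4]
    kitchen[10:12] = 0.15
    kitchen[12:14] = [0.6, 0.5]
    kitchen[14:17] = 0.15
    kitchen[17:20] = [0.5, 0.7, 0.4]
    kitchen[20:23] = 0.1
    kitchen[23] = 0.02

    lounge = h.copy()
    lounge[0:8] = 0.02
    lounge[8] = 0.3
    lounge[9:21] = 0.8
    lounge[21:23] = 0.3
    lounge[23] = 0.05

    hallway = h.copy()
    hallway[0:7] = 0.05
    hallway[7:23] = 0.25
    hallway[23] = 0.05

    return {"bathroom": bathroom, "bedroom": bedroom, "hallway": hallway,
            "kitchen": kitchen, "lounge": lounge}


@dataclass(frozen=True)
class Episode:
    start_day: int
    duration: int
    kind: str  # "UTI" | "hospitalization"

    @property
    def days(self) -> range:
        return range(self.start_day, self.start_day + self.duration)


@dataclass
class SynthConfig:
    """Study conditions for the simulated cohort (see docs/methods.md)."""

    n_patients: int = 15
    n_days: int = 624
    hourly_rate_profile: dict[str, np.ndarray] = field(default_factory=default_hourly_profiles)
    day_noise_sigma: float = 0.15
    burst_size_mean: float = 2.0
    uti_episodes_per_patient: int = 2
    uti_duration_days: tuple[int, int] = (3, 8)
    uti_night_bathroom_multiplier: float = 3.0
    uti_night_bedroom_multiplier: float = 1.5
    hosp_episodes_per_patient: int = 1
    hosp_activity_multiplier: float = 0.1
    hosp_duration_days: tuple[int, int] = (2, 10)
    min_episode_gap_days: int = 14
    seed: int = 0
    start_date: date = date(2021, 1, 1)

    def __post_init__(self) -> None:
        if self.n_patients < 0 or self.n_days < 1:
            raise ValueError("n_patients must be >= 0 and n_days >= 1")
        if set(self.hourly_rate_profile) != set(LOCATIONS):
            raise ValueError(f"hourly_rate_profile must cover exactly {LOCATIONS}")
        for loc, rates in self.hourly_rate_profile.items():
            rates = np.asarray(rates, dtype=float)
            if rates.shape != (24,) or (rates < 0).any():
                raise ValueError(f"{loc}: need 24 non-negative hourly rates")
            self.hourly_rate_profile[loc] = rates
        for name in ("uti_night_bathroom_multiplier", "uti_night_bedroom_multiplier",
                     "hosp_activity_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.day_noise_sigma < 0 or self.burst_size_mean < 0:
            raise ValueError("noise sigma and burst mean must be >= 0")
        for rng_name in ("uti_duration_days", "hosp_duration_days"):
            lo, hi = getattr(self, rng_name)
            if not (1 <= lo <= hi):
                raise ValueError(f"{rng_name} must be a 1 <= lo <= hi range")
        self._check_capacity()

    def _check_capacity(self) -> None:
        n_ep = self.uti_episodes_per_patient + self.hosp_episodes_per_patient
        if n_ep == 0:
            return
        worst = (self.uti_episodes_per_patient * self.uti_duration_days[1]
                 + self.hosp_episodes_per_patient * self.hosp_duration_days[1]
                 + (n_ep - 1) * self.min_episode_gap_days)
        if worst > self.n_days:
            raise ValueError(
                f"n_days={self.n_days} cannot hold {n_ep} episodes with "
                f"{self.min_episode_gap_days}-day gaps (needs up to {worst} days)")


def _patient_rng(cfg: SynthConfig, patient_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(patient_index)]))


def _place_episodes(cfg: SynthConfig, rng: np.random.Generator) -> list[Episode]:
    """Uniform random starts with >= min_episode_gap_days clean days between
    episodes; rejection-sampled, erroring out if the days cannot hold them."""
    wanted: list[tuple[str, int]] = []
    for _ in range(cfg.uti_episodes_per_patient):
        wanted.append(("UTI", int(rng.integers(cfg.uti_duration_days[0],
                                               cfg.uti_duration_days[1] + 1))))
    for _ in range(cfg.hosp_episodes_per_patient):
        wanted.append(("hospitalization", int(rng.integers(cfg.hosp_duration_days[0],
                                                           cfg.hosp_duration_days[1] + 1))))
    placed: list[Episode] = []
    gap = cfg.min_episode_gap_days
    for kind, dur in wanted:
        for _attempt in range(1000):
            start = int(rng.integers(0, cfg.n_days - dur + 1))
            ok = all(start + dur + gap <= e.start_day or e.start_day + e.duration + gap <= start
                     for e in placed)
            if ok:
                placed.append(Episode(start, dur, kind))
                break
        else:
            raise ValueError("could not place episodes: n_days too small for the "
                             "requested episode count, durations and gaps")
    return sorted(placed, key=lambda e: e.start_day)


def _rate_tensor(cfg: SynthConfig, rng: np.random.Generator,
                 episodes: list[Episode]) -> np.ndarray:
    """Expected visit counts, shape (n_days, n_locations, 24)."""
    base = np.stack([cfg.hourly_rate_profile[loc] for loc in LOCATIONS])  # L x 24
    rates = np.broadcast_to(base, (cfg.n_days,) + base.shape).copy()
    if cfg.day_noise_sigma > 0:
        s = cfg.day_noise_sigma
        # mean-1 lognormal so noise reshuffles but does not inflate activity
        noise = rng.lognormal(mean=-0.5 * s * s, sigma=s, size=cfg.n_days)
        rates *= noise[:, None, None]
    i_bath = LOCATIONS.index("bathroom")
    i_bed = LOCATIONS.index("bedroom")
    night = list(NIGHT_HOURS)
    for ep in episodes:
        days = slice(ep.start_day, ep.start_day + ep.duration)
        if ep.kind == "UTI":
            rates[days, i_bath, night[0]:night[-1] + 1] *= cfg.uti_night_bathroom_multiplier
            rates[days, i_bed, night[0]:night[-1] + 1] *= cfg.uti_night_bedroom_multiplier
        else:
            rates[days, :, :] *= cfg.hosp_activity_multiplier
    return rates


def simulate_visits(cfg: SynthConfig, patient_index: int
                    ) -> tuple[pd.DataFrame, list[Episode]]:
    """Visit table (day, hour, minute, location) before burst expansion.

    Exposed separately so the generative rates can be checked directly against
    the visit counts, independent of burst expansion and run collapsing.
    """
    if not 0 <= patient_index < max(cfg.n_patients, 1):
        raise ValueError(f"patient_index {patient_index} out of range")
    rng = _patient_rng(cfg, patient_index)
    episodes = _place_episodes(cfg, rng)
    rates = _rate_tensor(cfg, rng, episodes)
    counts = rng.poisson(rates)  # n_days x L x 24
    d_idx, l_idx, h_idx = np.nonzero(counts)
    n = counts[d_idx, l_idx, h_idx]
    day = np.repeat(d_idx, n)
    loc = np.repeat(l_idx, n)
    hour = np.repeat(h_idx, n)
    minute = rng.integers(0, 60, size=day.size)
    visits = pd.DataFrame({
        "day": day, "hour": hour, "minute": minute,
        "location": pd.Categorical.from_codes(loc, categories=list(LOCATIONS)),
    })
    visits = visits.sort_values(["day", "hour", "minute", "location"],
                                kind="stable").reset_index(drop=True)
    return visits, episodes


def simulate_patient(cfg: SynthConfig, patient_index: int
                     ) -> tuple[SensorEventStream, LabelSet]:
    """One patient's firing stream and labels, deterministic in (seed, index)."""
    visits, episodes = simulate_visits(cfg, patient_index)
    # burst expansion must reuse the same generator stream deterministically
    rng = np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed), int(patient_index), 1]))
    n_fire = 1 + rng.poisson(cfg.burst_size_mean, size=len(visits))
    rep = visits.loc[visits.index.repeat(n_fire)]
    start = pd.Timestamp(cfg.start_date)
    ts = (start
          + pd.to_timedelta(rep["day"].to_numpy(), unit="D")
          + pd.to_timedelta(rep["hour"].to_numpy(), unit="h")
          + pd.to_timedelta(rep["minute"].to_numpy(), unit="m"))
    events = pd.DataFrame({"timestamp": ts.to_numpy(),
                           "location": rep["location"].astype(str).to_numpy()})
    pid = f"synth-{patient_index:03d}"
    stream = SensorEventStream(patient_id=pid, events=events.reset_index(drop=True))
    labels = pd.DataFrame({
        "date": [start + pd.Timedelta(days=e.start_day) for e in episodes],
        "type": [e.kind for e in episodes],
    })
    if not len(labels):
        labels = pd.DataFrame(columns=["date", "type"])
    return stream, LabelSet(patient_id=pid, labels=labels)


def simulate_cohort(cfg: SynthConfig) -> list[tuple[SensorEventStream, LabelSet]]:
    """Independent streams for all patients (per-patient derived seeds)."""
    return [simulate_patient(cfg, i) for i in range(cfg.n_patients)]
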