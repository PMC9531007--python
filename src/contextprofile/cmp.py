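"""Contextual Matrix Profile (CMP) for a single daily feature series.

The CMP generalises the Matrix Profile from per-subsequence nearest-neighbour
distances to *contexts*: disjoint blocks of ``c`` consecutive subsequence start
positions.  Cell ``(i, j)`` of the CMP holds the minimum z-normalised Euclidean
distance between any subsequence starting in context ``i`` and any starting in
context ``j``.  Taking the minimum over a rectangular block of the all-pairs
distance matrix denoises the profile and decouples anomaly granularity from
subsequence length, and makes the score resistant to masking: a duplicated
anomaly elsewhere in the series cannot zero out a whole context's distances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "ContextConfig",
    "ContextIndex",
    "CMPMatrix",
    "znorm_distance",
    "distance_matrix",
    "build_contexts",
    "cmp_self_join",
    "cmp_to_frame",
]


@dataclass(frozen=True)
class ContextConfig:
    """Subsequence length ``m`` (days) and context window ``c`` (subsequences).

    Defaults (m=3, c=3) give one scored time segment per 3 days, each segment
    spanning 5 calendar days, balancing granularity against denoising for
    multi-day health events.
    """

    m: int = 3
    c: int = 3
    exclusion: str = "mp_half_m"  # or "none"

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("subsequence length m must be >= 2 (z-normalisation undefined for m < 2)")
        if self.c < 1:
            raise ValueError("context window c must be >= 1")
        if self.exclusion not in ("mp_half_m", "none"):
            raise ValueError(f"unknown exclusion policy {self.exclusion!r}")


@dataclass(frozen=True)
class ContextIndex:
    """Tiling of subsequence start positions into disjoint contexts.

    Context ``i`` owns start positions ``[i*c, i*c + c - 1]`` and spans days
    ``[i*c, i*c + c + m - 2]``; trailing starts that do not fill a whole
    context are dropped.  Neighbouring context day-spans overlap by ``m - 1``
    days.
    """

    n: int
    m: int
    c: int

    @property
    def n_contexts(self) -> int:
        return (self.n - self.m + 1) // self.c

    def starts(self, i: int) -> range:
        self._check(i)
        return range(i * self.c, i * self.c + self.c)

    def day_span(self, i: int) -> tuple[int, int]:
        """Inclusive (first, last) day index covered by context ``i``."""
        self._check(i)
        return i * self.c, i * self.c + self.c + self.m - 2

    def end_day(self, i: int) -> int:
        return self.day_span(i)[1]

    def end_days(self) -> np.ndarray:
        """Last-day index of every context, in context order."""
        c, m = self.c, self.m
        return np.arange(self.n_contexts) * c + c + m - 2

    def _check(self, i: int) -> None:
        if not 0 <= i < self.n_contexts:
            raise IndexError(f"context {i} out of range [0, {self.n_contexts})")


@dataclass
class CMPMatrix:
    """Symmetric C x C block-minimum distance matrix for one feature."""

    values: np.ndarray
    context_index: ContextIndex
    feature: str = ""


def _znorm_subsequences(x: np.ndarray, m: int) -> np.ndarray:
    """All length-``m`` subsequences of ``x``, z-normalised (population sd).

    Zero-variance (flat) subsequences map to the zero vector, so the Euclidean
    distance between a flat and a non-flat subsequence is ||z|| = sqrt(m) and
    between two flat ones is 0 — the conventional flat-window treatment.
    """
    x = np.asarray(x, dtype=float)
    windows = np.lib.stride_tricks.sliding_window_view(x, m).astype(float)
    mu = windows.mean(axis=1, keepdims=True)
    sd = windows.std(axis=1, keepdims=True)  # population sd
    out = np.zeros_like(windows)
    np.divide(windows - mu, sd, out=out, where=sd > 0)
    return out


def znorm_distance(a, b) -> float:
    """z-normalised Euclidean distance between two equal-length vectors.

    Both flat -> 0; exactly one flat -> sqrt(m).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D vectors of equal length")
    m = a.size
    if m < 2:
        raise ValueError("vectors must have length >= 2")
    za = _znorm_subsequences(a, m)[0]
    zb = _znorm_subsequences(b, m)[0]
    return float(np.linalg.norm(za - zb))


def _exclusion_radius(m: int) -> int:
    # strict bound |i-j| < ceil(m/2); equals the |i-j| < m/2 band for all m
    return math.ceil(m / 2)


def distance_matrix(x, cfg: ContextConfig) -> np.ndarray:
    """All-pairs z-normalised distance matrix of a self-join.

    Entries with ``|i - j| < m/2`` (trivial self-matches) are +inf under the
    ``mp_half_m`` exclusion policy.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < cfg.m + cfg.c - 1:
        raise ValueError(f"series of length {n} too short for m={cfg.m}, c={cfg.c}")
    z = _znorm_subsequences(x, cfg.m)
    d = cdist(z, z)
    # clean tiny negative/asymmetric float residue, enforce exact symmetry
    d = (d + d.T) / 2.0
    if cfg.exclusion == "mp_half_m":
        k = _exclusion_radius(cfg.m)
        idx = np.arange(d.shape[0])
        mask = np.abs(idx[:, None] - idx[None, :]) < k
        d[mask] = np.inf
    return d


def build_contexts(n: int, cfg: ContextConfig) -> ContextIndex:
    """Tile ``n - m + 1`` subsequence starts into disjoint blocks of ``c``."""
    if n < cfg.m + cfg.c - 1:
        raise ValueError(f"series of length {n} admits no context for m={cfg.m}, c={cfg.c}")
    return ContextIndex(n=n, m=cfg.m, c=cfg.c)


def cmp_self_join(x, cfg: ContextConfig, feature: str = "") -> CMPMatrix:
    """Block-minimum CMP of a series with itself.

    Cell (i, j) is the minimum finite distance-matrix entry over the
    rectangular block of context-i rows x context-j columns; a fully excluded
    block yields +inf (downstream scoring skips such cells).
    """
    x = np.asarray(x, dtype=float)
    ci = build_contexts(x.size, cfg)
    C, c = ci.n_contexts, cfg.c
    d = distance_matrix(x, cfg)
    # trim to the starts that fill whole contexts, then block-reduce
    d = d[: C * c, : C * c]
    blocks = d.reshape(C, c, C, c)
    with np.errstate(invalid="ignore"):
        vals = blocks.min(axis=(1, 3))
    return CMPMatrix(values=vals, context_index=ci, feature=feature)


def cmp_to_frame(cmp: CMPMatrix, dates=None) -> pd.DataFrame:
    """CMP as a DataFrame with context end-date (or end-day index) labels.

    ``dates`` is the calendar index of the underlying daily series; labels are
    each context's last covered day, ISO formatted, matching the heat-map
    export convention.
    """
    ends = cmp.context_index.end_days()
    if dates is not None:
        labels = [pd.Timestamp(dates[e]).date().isoformat() for e in ends]
    else:
        labels = [str(e) for e in ends]
    return pd.DataFrame(cmp.values, index=labels, columns=labels)
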