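"""Regularity statistics: approximate entropy and fuzzy entropy.

Both quantify how unpredictable a series is by counting repeated templates.
ApEn uses hard (Heaviside) template matching under the Chebyshev distance and
ranges from about 0 (perfectly regular) to about 2 (noise); FuzzyEn replaces
the hard match with an exponential membership mu(d) = exp(-(d/r)^n) on
mean-subtracted templates, giving graded similarity.  Used here to weight
per-feature anomaly scores inversely to the feature's entropy.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

__all__ = ["approximate_entropy", "fuzzy_entropy"]

_EPS_TOL = 1e-6  # absolute tolerance floor when the series is flat (sd = 0)


def _templates(x: np.ndarray, m: int) -> np.ndarray:
    return np.lib.stride_tricks.sliding_window_view(x, m)


def _resolve_tolerance(x: np.ndarray, r: float, absolute: bool) -> float:
    if absolute:
        return float(r)
    sd = float(np.std(x))  # population sd
    return r * sd if sd > 0 else _EPS_TOL


def approximate_entropy(x, m: int = 7, r: float = 0.2, absolute: bool = False) -> float:
    """ApEn(m, r) with self-matches included.

    ``r`` is a multiple of the series SD unless ``absolute`` is set, in which
    case it is the raw Chebyshev tolerance.  A flat series returns exactly 0
    for any positive tolerance: every template matches every other.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 1:
        raise ValueError(f"series of length {n} too short for m={m}")
    tol = _resolve_tolerance(x, r, absolute)
    if tol <= 0:
        raise ValueError("tolerance must be positive")

    def phi(mm: int) -> float:
        t = _templates(x, mm)
        d = cdist(t, t, metric="chebyshev")
        # self-matches included: the diagonal is 0 <= tol
        counts = (d <= tol).sum(axis=1) / t.shape[0]
        return float(np.mean(np.log(counts)))

    return phi(m) - phi(m + 1)


def fuzzy_entropy(x, m: int = 7, r: float = 0.2, n_fuzzy: float = 2.0,
                  absolute: bool = False) -> float:
    """FuzzyEn(m, r, n) on mean-subtracted templates, self-matches excluded.

    Both template lengths use the same N - m vectors so the two similarity
    averages are comparable; returns -ln(phi_{m+1} / phi_m) >= 0 up to float
    rounding.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        raise ValueError(f"series of length {n} too short for m={m}")
    if n_fuzzy <= 0:
        raise ValueError("fuzzy gradient must be positive")
    tol = _resolve_tolerance(x, r, absolute)
    if tol <= 0:
        raise ValueError("tolerance must be positive")

    def phi(mm: int) -> float:
        t = _templates(x, mm)[: n - m]  # N - m templates for both lengths
        t = t - t.mean(axis=1, keepdims=True)
        d = cdist(t, t, metric="chebyshev")
        mu = np.exp(-np.power(d / tol, n_fuzzy))
        np.fill_diagonal(mu, 0.0)
        return float(mu.sum() / (t.shape[0] * (t.shape[0] - 1)))

    pm, pm1 = phi(m), phi(m + 1)
    return float(-np.log(pm1 / pm))
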