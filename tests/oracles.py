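"""Independent brute-force reference implementations used only by tests.

Every function here follows the plain mathematical definition with explicit
loops and no shortcuts shared with the package code paths it checks.
"""

from __future__ import annotations

import math

import numpy as np


def znorm_oracle(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def znorm_distance_oracle(a, b) -> float:
    return float(np.sqrt(((znorm_oracle(a) - znorm_oracle(b)) ** 2).sum()))


def distance_matrix_oracle(x: np.ndarray, m: int, exclusion: bool = True) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n_sub = len(x) - m + 1
    d = np.empty((n_sub, n_sub))
    for i in range(n_sub):
        for j in range(n_sub):
            if exclusion and abs(i - j) < math.ceil(m / 2):
                d[i, j] = np.inf
            else:
                d[i, j] = znorm_distance_oracle(x[i:i + m], x[j:j + m])
    return d


def cmp_oracle(x: np.ndarray, m: int, c: int, exclusion: bool = True) -> np.ndarray:
    """Block-minimum CMP straight from the definition, O(C^2 c^2 m)."""
    d = distance_matrix_oracle(x, m, exclusion)
    C = d.shape[0] // c
    out = np.full((C, C), np.inf)
    for i in range(C):
        for j in range(C):
            block = d[i * c:(i + 1) * c, j * c:(j + 1) * c]
            finite = block[np.isfinite(block)]
            if finite.size:
                out[i, j] = finite.min()
    return out


def apen_oracle(x, m: int, r_abs: float) -> float:
    """Textbook double-loop ApEn with self-matches included."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm: int) -> float:
        temps = [x[i:i + mm] for i in range(N - mm + 1)]
        total = 0.0
        for t1 in temps:
            c = 0
            for t2 in temps:
                if max(abs(a - b) for a, b in zip(t1, t2)) <= r_abs:
                    c += 1
            total += math.log(c / len(temps))
        return total / len(temps)

    return phi(m) - phi(m + 1)


def fuzzyen_oracle(x, m: int, r_abs: float, n_fuzzy: float) -> float:
    """Double-loop FuzzyEn: mean-subtracted templates, Chebyshev distance,
    exponential membership, self-matches excluded, N - m templates for both
    lengths."""
    x = list(map(float, x))
    N = len(x)

    def phi(mm: int) -> float:
        temps = []
        for i in range(N - m):
            t = x[i:i + mm]
            mu = sum(t) / len(t)
            temps.append([v - mu for v in t])
        total = 0.0
        for i, t1 in enumerate(temps):
            for j, t2 in enumerate(temps):
                if i == j:
                    continue
                d = max(abs(a - b) for a, b in zip(t1, t2))
                total += math.exp(-((d / r_abs) ** n_fuzzy))
        return total / (len(temps) * (len(temps) - 1))

    return -math.log(phi(m + 1) / phi(m))


def knee_oracle(y) -> int | None:
    """Max perpendicular distance from the chord, after min-max normalisation."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3 or y.max() == y.min():
        return None
    xs = np.arange(n) / (n - 1)
    ys = (y - y.min()) / (y.max() - y.min())
    # distance from point to the line through (0,0) and (1,1): |y - x| / sqrt(2)
    dist = (ys - xs) / math.sqrt(2)
    k = int(np.argmax(dist))
    if dist[k] <= 1e-12 or k in (0, n - 1):
        return None
    return k


def robust_z_flag_oracle(window, current, thr) -> bool:
    w = sorted(window)
    n = len(w)
    med = (w[n // 2] if n % 2 else 0.5 * (w[n // 2 - 1] + w[n // 2]))
    dev = sorted(abs(v - med) for v in w)
    mad = (dev[n // 2] if n % 2 else 0.5 * (dev[n // 2 - 1] + dev[n // 2]))
    if mad == 0:
        return current > med
    return 0.6745 * (current - med) / mad > thr


def quantile_oracle(window, q) -> float:
    w = sorted(window)
    pos = q * (len(w) - 1)
    lo = int(math.floor(pos))
    hi = int(math.ceil(pos))
    return w[lo] + (pos - lo) * (w[hi] - w[lo])


def iqr_flag_oracle(window, current, thr) -> bool:
    q1 = quantile_oracle(window, 0.25)
    q3 = quantile_oracle(window, 0.75)
    return current > q3 + thr * (q3 - q1)


def quantile_flag_oracle(window, current, q) -> bool:
    return current > quantile_oracle(window, q)
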