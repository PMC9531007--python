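"""Multidimensional Contextual Matrix Profile.

Per-feature CMPs are stacked into an F x C x C tensor and each (i, j) cell is
sorted ascending along the feature axis, recording which feature produced each
rank.  Layer ``k`` of the k-dimensional CMP then holds, per cell, the mean of
the ``k + 1`` smallest per-feature distances — layer 0 is the elementwise
minimum across features, layer F-1 the plain cross-feature mean.  The optimal
``k`` for a patient is the knee of the (non-decreasing) curve of per-layer
median distances, found with the kneedle procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cmp import CMPMatrix, ContextIndex

__all__ = ["StackedCMP", "KDimCMP", "stack_cmps", "kdim_cmp", "select_layer", "optimal_k", "kneedle"]


@dataclass
class StackedCMP:
    """Feature-sorted stack of per-feature CMP cells.

    ``values[r, i, j]`` is the r-th smallest per-feature distance at cell
    (i, j); ``feature_order[r, i, j]`` indexes into ``features`` and names the
    feature that produced it.  Ties (and +inf cells, which sort last) are
    broken by lexicographic feature name for reproducible attribution.
    """

    values: np.ndarray          # F x C x C, ascending along axis 0
    feature_order: np.ndarray   # F x C x C int indices into `features`
    features: tuple[str, ...]   # lexicographically sorted vocabulary
    context_index: ContextIndex


@dataclass
class KDimCMP:
    """Prefix-mean tensor: layer k averages the k+1 smallest distances."""

    values: np.ndarray          # F x C x C, non-decreasing along axis 0
    features: tuple[str, ...]
    context_index: ContextIndex


def stack_cmps(cmps: list[CMPMatrix]) -> StackedCMP:
    """Stack per-feature CMPs and sort every cell along the feature axis."""
    if len(cmps) < 2:
        raise ValueError("need at least 2 feature CMPs to stack")
    ci = cmps[0].context_index
    shape = cmps[0].values.shape
    for m in cmps[1:]:
        if m.values.shape != shape or m.context_index != ci:
            raise ValueError("all CMPs must share one context index and shape")
    names = [m.feature for m in cmps]
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in stack")
    # lexicographic base order makes the stable sort's tie-break lexicographic
    lex = np.argsort(names)
    features = tuple(names[i] for i in lex)
    raw = np.stack([cmps[i].values for i in lex], axis=0)
    order = np.argsort(raw, axis=0, kind="stable")
    values = np.take_along_axis(raw, order, axis=0)
    return StackedCMP(values=values, feature_order=order, features=features, context_index=ci)


def unstack(stacked: StackedCMP) -> np.ndarray:
    """Recover the unsorted F x C x C tensor (feature axis in vocab order)."""
    raw = np.empty_like(stacked.values)
    np.put_along_axis(raw, stacked.feature_order, stacked.values, axis=0)
    return raw


def kdim_cmp(stacked: StackedCMP) -> KDimCMP:
    """Running prefix means along the sorted feature axis.

    +inf entries propagate into every layer whose prefix includes them.
    """
    F = stacked.values.shape[0]
    csum = np.cumsum(stacked.values, axis=0)
    layers = csum / np.arange(1, F + 1, dtype=float)[:, None, None]
    return KDimCMP(values=layers, features=stacked.features, context_index=stacked.context_index)


def select_layer(kdim: KDimCMP, k: int) -> CMPMatrix:
    """Layer ``k`` (0-based) as a CMP-shaped matrix with the shared index."""
    F = kdim.values.shape[0]
    if not 0 <= k < F:
        raise IndexError(f"k={k} out of range [0, {F})")
    return CMPMatrix(values=kdim.values[k].copy(), context_index=kdim.context_index,
                     feature=f"kdim[{k}]")


def kneedle(y: np.ndarray) -> int | None:
    """Knee of an increasing concave curve via max distance from the chord.

    Both axes are min-max normalised; the knee is the first index maximising
    ``y_norm - x_norm`` (the normalised difference curve).  Returns ``None``
    when the curve is flat or has no interior bend (difference never positive).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        return None
    rng = y.max() - y.min()
    if rng <= 0 or not np.isfinite(rng):
        return None
    x_n = np.arange(n) / (n - 1)
    y_n = (y - y.min()) / rng
    diff = y_n - x_n
    k = int(np.argmax(diff))
    if diff[k] <= 1e-12 or k in (0, n - 1):
        return None
    return k


def optimal_k(kdim: KDimCMP) -> int:
    """Per-patient optimal dimension: knee of the per-layer median curve.

    The curve uses the median over finite upper-triangle-population cells of
    each layer (exclusion-zone +inf cells are ignored so they cannot move the
    knee).  Falls back to k* = 1 when no knee exists (flat or linear curve) —
    the best-performing fixed setting in practice.
    """
    F = kdim.values.shape[0]
    if F < 3:
        raise ValueError("knee detection needs at least 3 layers")
    meds = np.empty(F)
    for k in range(F):
        layer = kdim.values[k]
        finite = layer[np.isfinite(layer)]
        meds[k] = np.median(finite) if finite.size else np.nan
    if np.isnan(meds).any():
        return 1
    k = kneedle(meds)
    return 1 if k is None else k
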