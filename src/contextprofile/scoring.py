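"""Anomaly scoring: from CMP layers to one dated score per context.

A context's anomaly score is the average of its block-minimum distances to
strictly *past* contexts (streaming contract: only historical data at each
time point), either equally weighted or inverse-hop weighted (a context three
hops back contributes one third of the weight of the previous context).
Univariate per-feature score series can be fused by sum / mean / median / max
or by inverse-entropy weighting, where a feature whose raw daily series is
noisier (higher ApEn or FuzzyEn) gets less say.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cmp import CMPMatrix, ContextConfig, cmp_self_join
from .entropy import approximate_entropy, fuzzy_entropy
from .features import FEATURES, FeatureSeries
from .multidim import KDimCMP, StackedCMP, kdim_cmp, optimal_k, select_layer, stack_cmps

__all__ = ["EntropyConfig", "ScoreSeries", "MODEL_TAGS", "context_score_equal",
           "context_score_distance_weighted", "entropy_weights", "fuse_univariate",
           "score_contexts", "score_pipeline", "mdcmp_artifacts",
           "write_scores_csv", "read_scores_csv"]

MODEL_TAGS = ("sum", "mean", "median", "max", "apen", "fuzzyen",
              "mdcmp_equal", "mdcmp_distance")
_UNIVARIATE_TAGS = ("sum", "mean", "median", "max", "apen", "fuzzyen")

_EPS_WEIGHT = 1e-6


@dataclass(frozen=True)
class EntropyConfig:
    """Entropy estimation settings: trailing window N, tolerance r (in SDs),
    template length m_e, and the fuzzy membership gradient n_fuzzy."""

    N: int = 500
    r: float = 0.2
    m_e: int = 7
    n_fuzzy: float = 2.0

    def __post_init__(self) -> None:
        if self.N < self.m_e + 1:
            raise ValueError("N must be >= m_e + 1")
        if self.r <= 0 or self.n_fuzzy <= 0:
            raise ValueError("r and n_fuzzy must be positive")


@dataclass
class ScoreSeries:
    """Dated per-context anomaly scores for one patient.

    ``frame`` columns: context_id, end_date, score; strictly increasing dates.
    """

    patient_id: str
    frame: pd.DataFrame
    model_tag: str


def context_score_equal(cmp_layer: np.ndarray, i: int) -> float | None:
    """Mean of finite distances from context ``i`` to all past contexts."""
    if i < 1:
        return None
    past = cmp_layer[i, :i]
    finite = past[np.isfinite(past)]
    return float(finite.mean()) if finite.size else None


def context_score_distance_weighted(cmp_layer: np.ndarray, i: int) -> float | None:
    """Inverse-hop weighted mean: the cell j hops back gets weight 1/j."""
    if i < 1:
        return None
    past = cmp_layer[i, :i]
    mask = np.isfinite(past)
    if not mask.any():
        return None
    hops = i - np.arange(i)  # hop distance of each past context
    w = 1.0 / hops[mask]
    return float(np.sum(w * past[mask]) / np.sum(w))


def score_contexts(layer: CMPMatrix, dates: pd.DatetimeIndex, patient_id: str,
                   model_tag: str, weighting: str = "equal") -> ScoreSeries:
    """Score every context of a CMP layer against its past (context 0 skipped)."""
    scorer = {"equal": context_score_equal,
              "distance": context_score_distance_weighted}[weighting]
    ends = layer.context_index.end_days()
    rows = []
    for i in range(layer.context_index.n_contexts):
        s = scorer(layer.values, i)
        if s is not None:
            rows.append((i, dates[ends[i]], s))
    frame = pd.DataFrame(rows, columns=["context_id", "end_date", "score"])
    return ScoreSeries(patient_id=patient_id, frame=frame, model_tag=model_tag)


def entropy_weights(features: FeatureSeries, kind: str,
                    cfg: EntropyConfig = EntropyConfig()) -> pd.Series:
    """Per-feature weights proportional to 1 / entropy, summing to 1.

    Entropy is computed once per patient on each feature's raw daily series
    (trailing N points); near-zero entropy (a very regular feature) is floored
    at a small epsilon so flat features dominate without producing NaN.
    """
    ent_fn = {"apen": lambda x: approximate_entropy(x, cfg.m_e, cfg.r),
              "fuzzyen": lambda x: fuzzy_entropy(x, cfg.m_e, cfg.r, cfg.n_fuzzy)}[kind]
    inv = {}
    for f in features.frame.columns:
        x = features.frame[f].to_numpy()[-cfg.N:]
        h = ent_fn(x)
        inv[f] = 1.0 / max(h, _EPS_WEIGHT)
    w = pd.Series(inv)
    return w / w.sum()


def fuse_univariate(per_feature_scores: dict[str, ScoreSeries], method: str,
                    weights: pd.Series | None = None) -> ScoreSeries:
    """Aggregate aligned per-feature score series into one series per context."""
    if method not in _UNIVARIATE_TAGS:
        raise ValueError(f"unknown fusion method {method!r}")
    names = sorted(per_feature_scores)
    frames = [per_feature_scores[f].frame for f in names]
    ref = frames[0][["context_id", "end_date"]]
    for f in frames[1:]:
        if not f["context_id"].equals(ref["context_id"]) \
                or not f["end_date"].equals(ref["end_date"]):
            raise ValueError("per-feature score series are not aligned on one context grid")
    mat = np.column_stack([f["score"].to_numpy() for f in frames])
    if method in ("apen", "fuzzyen"):
        if weights is None:
            raise ValueError(f"method {method!r} requires entropy weights")
        w = weights.reindex(names).to_numpy()
        fused = mat @ w
    else:
        fused = {"sum": mat.sum(axis=1), "mean": mat.mean(axis=1),
                 "median": np.median(mat, axis=1), "max": mat.max(axis=1)}[method]
    out = ref.copy()
    out["score"] = fused
    first = per_feature_scores[names[0]]
    return ScoreSeries(patient_id=first.patient_id, frame=out, model_tag=method)


def _feature_cmps(features: FeatureSeries, cfg: ContextConfig) -> list[CMPMatrix]:
    return [cmp_self_join(features.frame[f].to_numpy(), cfg, feature=f)
            for f in FEATURES]


def mdcmp_artifacts(features: FeatureSeries, cfg: ContextConfig, k: int | str = "auto"
                    ) -> tuple[StackedCMP, KDimCMP, int, CMPMatrix]:
    """Stack -> k-dimensional CMP -> chosen layer, with the k actually used.

    ``k="auto"`` picks the knee of the per-layer median-distance curve.
    """
    stacked = stack_cmps(_feature_cmps(features, cfg))
    kdim = kdim_cmp(stacked)
    k_used = optimal_k(kdim) if k == "auto" else int(k)
    return stacked, kdim, k_used, select_layer(kdim, k_used)


def score_pipeline(features: FeatureSeries, cfg: ContextConfig = ContextConfig(),
                   model_tag: str = "mdcmp_equal", k: int | str = 1,
                   entropy_cfg: EntropyConfig = EntropyConfig()) -> ScoreSeries:
    """End-to-end scoring of one patient's feature series.

    Univariate tags (sum/mean/median/max/apen/fuzzyen) score each feature's
    own CMP with equal past-weighting and fuse; mdcmp tags build the
    multidimensional CMP, select layer ``k`` (or the per-patient optimum when
    ``k="auto"``) and score it with equal or inverse-hop weighting.
    """
    if model_tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {model_tag!r}")
    dates = features.frame.index
    if model_tag in _UNIVARIATE_TAGS:
        per_feature = {
            m.feature: score_contexts(m, dates, features.patient_id, model_tag)
            for m in _feature_cmps(features, cfg)
        }
        weights = (entropy_weights(features, model_tag, entropy_cfg)
                   if model_tag in ("apen", "fuzzyen") else None)
        fused = fuse_univariate(per_feature, model_tag, weights)
        fused.patient_id = features.patient_id
        return fused
    _, _, _, layer = mdcmp_artifacts(features, cfg, k)
    weighting = "equal" if model_tag == "mdcmp_equal" else "distance"
    return score_contexts(layer, dates, features.patient_id, model_tag, weighting)


def write_scores_csv(series_list: list[ScoreSeries], path) -> None:
    frames = []
    for ss in series_list:
        f = ss.frame.copy()
        f.insert(0, "patient_id", ss.patient_id)
        f["end_date"] = pd.to_datetime(f["end_date"]).dt.strftime("%Y-%m-%d")
        f["model"] = ss.model_tag
        frames.append(f)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_scores_csv(path) -> list[ScoreSeries]:
    df = pd.read_csv(path, dtype={"patient_id": str})
    df["end_date"] = pd.to_datetime(df["end_date"])
    out = []
    for (pid, model), grp in df.groupby(["patient_id", "model"], sort=True):
        frame = grp[["context_id", "end_date", "score"]].reset_index(drop=True)
        out.append(ScoreSeries(patient_id=pid, frame=frame, model_tag=model))
    return out
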