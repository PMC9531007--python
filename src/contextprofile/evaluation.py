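"""Evaluation against weak labels, parameter-grid search, and biomarkers.

Labels of adverse events (UTI, hospitalization) are weak: onset dates are
imprecise, so an alert counts as a true detection if it falls inside a soft
buffer around the label date (default 10 days before to 7 days after).
Reported metrics follow the remote-monitoring framing: per-patient recall,
alerts raised and alert rate (per observed day), the number of patients with
more than a third of their events recalled, and precision — read relatively,
since unlabeled genuine anomalies (visitors, sensor faults) depress it.

Biomarker attribution reads the sorted feature order of the stacked CMP: the
modal feature in dimension 0 is the behaviour that most often produced the
smallest cross-context distance, i.e. the patient's leading digital biomarker.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .multidim import StackedCMP
from .scoring import ScoreSeries
from .streams import LabelSet
from .thresholds import TABLE_GRID, AlertSet, ThresholdConfig, detect

__all__ = ["EvalConfig", "match_alerts", "evaluate_patient", "evaluate_cohort",
           "label_fraction", "grid_search", "biomarker_contributions",
           "cohort_biomarkers"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvalConfig:
    """Soft-buffer half-widths (days) and the patient-recall cut-off."""

    buffer_before: int = 10
    buffer_after: int = 7
    recall_patient_threshold: float = 1.0 / 3.0

    def __post_init__(self) -> None:
        if self.buffer_before < 0 or self.buffer_after < 0:
            raise ValueError("buffers must be >= 0")


def match_alerts(alerts: AlertSet, labels: LabelSet,
                 cfg: EvalConfig = EvalConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (label recalled, alert is true positive).

    Alert date a matches label date L iff L - buffer_before <= a <= L +
    buffer_after (closed interval).  One alert may validate several labels and
    several alerts may validate one label.
    """
    a_dates = pd.to_datetime(alerts.frame["end_date"]).to_numpy()
    l_dates = pd.to_datetime(labels.labels["date"]).to_numpy()
    if not len(a_dates) or not len(l_dates):
        return np.zeros(len(l_dates), bool), np.zeros(len(a_dates), bool)
    lo = l_dates - np.timedelta64(cfg.buffer_before, "D")
    hi = l_dates + np.timedelta64(cfg.buffer_after, "D")
    hit = (a_dates[:, None] >= lo[None, :]) & (a_dates[:, None] <= hi[None, :])
    return hit.any(axis=0), hit.any(axis=1)


def evaluate_patient(alerts: AlertSet, labels: LabelSet, observed_days: int,
                     cfg: EvalConfig = EvalConfig()) -> dict:
    """Per-patient recall %, alert counts and rate %, and precision %."""
    if observed_days <= 0:
        raise ValueError("observed_days must be positive")
    recalled, tp = match_alerts(alerts, labels, cfg)
    n_labels, n_alerts = len(recalled), len(tp)
    if n_labels == 0:
        logger.info("%s: no labels; recall undefined", alerts.patient_id)
    return {
        "patient_id": alerts.patient_id,
        "n_labels": n_labels,
        "recalled_labels": int(recalled.sum()),
        "recall_pct": 100.0 * recalled.sum() / n_labels if n_labels else np.nan,
        "alerts_raised": n_alerts,
        "matched_alerts": int(tp.sum()),
        "observed_days": int(observed_days),
        "alert_rate_pct": 100.0 * n_alerts / observed_days,
        "precision_pct": 100.0 * tp.sum() / n_alerts if n_alerts else np.nan,
    }


def evaluate_cohort(per_patient: list[dict], cfg: EvalConfig = EvalConfig()) -> dict:
    """Unweighted cohort means; the >1/3-recall count uses a strict inequality.

    Patients without labels are excluded from recall-based aggregates (logged
    by evaluate_patient); patients without alerts are excluded from the mean
    precision.
    """
    if not per_patient:
        raise ValueError("need at least one evaluable patient")
    df = pd.DataFrame(per_patient)
    with_labels = df[df["n_labels"] > 0]
    cut = 100.0 * cfg.recall_patient_threshold
    return {
        "n_patients": len(df),
        "n_patients_with_labels": len(with_labels),
        "mean_recall_pct": float(with_labels["recall_pct"].mean()),
        "mean_alerts": float(df["alerts_raised"].mean()),
        "mean_alert_rate_pct": float(df["alert_rate_pct"].mean()),
        "patients_above_third_recall": int((with_labels["recall_pct"] > cut).sum()),
        "mean_precision_pct": float(df["precision_pct"].mean()),
        "total_labels": int(df["n_labels"].sum()),
        "total_observed_days": int(df["observed_days"].sum()),
    }


def label_fraction(n_labels: int, n_days: int) -> float:
    """Labelled fraction of the data set, in percent (e.g. 41/9363 -> 0.44)."""
    if n_days <= 0:
        raise ValueError("n_days must be positive")
    return 100.0 * n_labels / n_days


def grid_search(scores_by_patient: dict[str, ScoreSeries],
                labels_by_patient: dict[str, LabelSet],
                observed_days_by_patient: dict[str, int],
                eval_cfg: EvalConfig = EvalConfig(),
                grid: dict | None = None) -> tuple[dict, pd.DataFrame]:
    """Exhaustively evaluate the threshold grid; return (best-per-method, table).

    "Best" maximises mean recall, breaking ties by fewer mean alerts, then by
    smaller window.
    """
    grid = grid or TABLE_GRID
    method_thrs = {"robust_z": grid["z_thr"], "iqr": grid["iqr_thr"],
                   "quantile": grid["q_thr"]}
    rows = []
    for method, thrs in method_thrs.items():
        attr = {"robust_z": "z_thr", "iqr": "iqr_thr", "quantile": "q_thr"}[method]
        for w, thr in itertools.product(grid["window_days"], thrs):
            cfg = ThresholdConfig(method=method, window_days=w, **{attr: thr})
            per_patient = []
            for pid, ss in scores_by_patient.items():
                alerts = detect(ss, cfg)
                per_patient.append(evaluate_patient(
                    alerts, labels_by_patient[pid], observed_days_by_patient[pid],
                    eval_cfg))
            rep = evaluate_cohort(per_patient, eval_cfg)
            rows.append({"method": method, "window_days": w, "threshold": thr, **rep})
    table = pd.DataFrame(rows)
    best = {}
    for method in method_thrs:
        sub = table[table["method"] == method].sort_values(
            ["mean_recall_pct", "mean_alerts", "window_days"],
            ascending=[False, True, True], kind="stable")
        best[method] = sub.iloc[0].to_dict()
    return best, table


def biomarker_contributions(stacked: StackedCMP, k_used: int,
                            dims: str = "top1") -> dict:
    """Per-patient feature contributions from the sorted CMP stack.

    Importance is read dimension-wise from the sorted stack: the default
    ``dims="top1"`` contribution of feature f is the fraction of finite
    upper-triangle cells whose *smallest* distance came from f (the modal
    feature of dimension 0 being the patient's leading biomarker);
    ``dims="leq_k"`` instead counts occupancy of every dimension <= k_used.
    The top1 reading keeps a degenerate near-constant feature — whose
    distances are exactly zero almost everywhere and therefore always sort
    into the low dimensions — from crowding the ranking via tied slots.
    Fractions sum to 1; dimension-0 ties break lexicographically.
    """
    F = len(stacked.features)
    if not 0 <= k_used < F:
        raise IndexError(f"k_used={k_used} out of range [0, {F})")
    if dims not in ("leq_k", "top1"):
        raise ValueError("dims must be 'leq_k' or 'top1'")
    C = stacked.values.shape[1]
    iu = np.triu_indices(C, k=1)
    max_dim = 0 if dims == "top1" else k_used
    counts = np.zeros(F, dtype=float)
    for r in range(max_dim + 1):
        vals = stacked.values[r][iu]
        feats = stacked.feature_order[r][iu]
        finite = np.isfinite(vals)
        counts += np.bincount(feats[finite], minlength=F)
    total = counts.sum()
    contributions = pd.Series(counts / total if total else counts,
                              index=list(stacked.features))
    top0 = stacked.feature_order[0][iu][np.isfinite(stacked.values[0][iu])]
    if top0.size:
        mode_counts = np.bincount(top0, minlength=F)
        top = stacked.features[int(np.argmax(mode_counts))]  # argmax: first = lexicographic
    else:
        top = None
    return {"contributions": contributions, "top_biomarker": top, "k_used": k_used}


def cohort_biomarkers(reports: list[dict]) -> pd.DataFrame:
    """Per-feature median contribution across patients, ranked descending."""
    if not reports:
        raise ValueError("need at least one patient report")
    mat = pd.DataFrame({i: r["contributions"] for i, r in enumerate(reports)})
    out = pd.DataFrame({
        "median_contribution": mat.median(axis=1),
        "mean_contribution": mat.mean(axis=1),
    })
    tops = pd.Series([r["top_biomarker"] for r in reports])
    out["n_patients_top"] = tops.value_counts().reindex(out.index, fill_value=0)
    return out.sort_values(["median_contribution"], ascending=False, kind="stable")
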