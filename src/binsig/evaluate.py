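"""Model evaluation: confusion counts, accuracy/precision, rank AUC,
Kaplan-Meier curves for risk-stratified groups.

Accuracy is the fraction of instances classified correctly and precision
is TP / (TP + FP); both are also reported per class.  The AUC is the
rank-based (Mann-Whitney) estimate, with tied scores contributing 1/2.
Disease-free survival per risk group uses the product-limit estimator;
patients without recurrence are censored at their follow-up time.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import rankdata

from .containers import BinsigError


@dataclass
class EvaluationReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None  # None when TP+FP == 0
    precision_per_class: dict = field(default_factory=dict)
    auc: float | None = None
    horizon_months: float | None = None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def to_json(self) -> str:
        d = {
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "precision_per_class": self.precision_per_class,
            "auc": self.auc,
            "horizon_months": self.horizon_months,
        }
        return json.dumps(d, sort_keys=True)


def confusion(pred, truth) -> EvaluationReport:
    """Confusion counts plus accuracy and precision (pooled and per class)."""
    pred = np.asarray(pred, dtype=int)
    truth = np.asarray(truth, dtype=int)
    if pred.shape != truth.shape:
        raise BinsigError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if len(pred) < 1:
        raise BinsigError("need at least one prediction")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    acc = (tp + tn) / len(pred)
    prec = tp / (tp + fp) if tp + fp > 0 else None
    prec_neg = tn / (tn + fn) if tn + fn > 0 else None
    return EvaluationReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=acc,
        precision=prec,
        precision_per_class={"positive": prec, "negative": prec_neg},
    )


def roc_auc(scores, truth) -> float:
    """Mann-Whitney AUC from raw scores; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    n1 = int(truth.sum())
    n0 = len(truth) - n1
    if n1 == 0 or n0 == 0:
        raise BinsigError("roc_auc needs both classes present")
    r = rankdata(scores)
    return float((r[truth == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class KMCurve:
    """Product-limit survival curve for one risk group."""

    group: str
    times: np.ndarray  # ascending, starts at 0
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray  # S(t), non-increasing from 1

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "group": self.group,
                "time": self.times,
                "at_risk": self.at_risk,
                "events": self.events,
                "survival": self.survival,
            }
        )


def km_curve(times, events, groups=None) -> dict[str, KMCurve]:
    """Kaplan-Meier estimate per group (single group "all" when omitted)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise BinsigError("times must be non-negative")
    if groups is None:
        groups = np.array(["all"] * len(times))
    groups = np.asarray(groups)
    out: dict[str, KMCurve] = {}
    for g in pd.unique(groups):
        mask = groups == g
        if not mask.any():
            warnings.warn(f"empty group {g!r} omitted", stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        table = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
        out[str(g)] = KMCurve(
            group=str(g),
            times=table.index.to_numpy(dtype=float),
            at_risk=table["at_risk"].to_numpy(dtype=int),
            events=table["observed"].to_numpy(dtype=int),
            survival=surv,
        )
    return out


def km_table(curves: dict[str, KMCurve]) -> pd.DataFrame:
    """Stacked long-format KM table (group, time, at_risk, events, survival)."""
    return pd.concat([c.as_frame() for c in curves.values()], ignore_index=True)


def risk_stratify(probabilities, cut: float = 0.5) -> np.ndarray:
    """Label samples 'high' when P(BCR) >= cut, else 'low'."""
    p = np.asarray(probabilities, dtype=float)
    return np.where(p >= cut, "high", "low")
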