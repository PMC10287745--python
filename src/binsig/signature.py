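"""Interval-weight logistic signatures on binned expression.

A signature is an intercept b0 plus terms (gene, interval union, weight).
A sample's final score is b0 plus the weights of every term whose interval
contains the sample's min-max-scaled expression of that gene (plus an
optional PSA indicator term), and the probability of biochemical
recurrence is the logistic sigmoid of that score:

    P(BCR) = exp(score) / (1 + exp(score))

Training one-hot-encodes a discretized matrix (one indicator per gene and
bin, no reference category dropped — the L2 penalty handles the
collinearity), fits an L2-regularised logistic regression with the
liblinear solver, and merges adjacent bins whose fitted weights are within
a tolerance into interval unions, which is how compact unions such as
"(0.4-1)" arise from a five-bin scheme.

The published ten-gene recurrence signature (intercept 1.5, five-bin
equal-width intervals) is packaged and available via
:func:`load_printed_signature`.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .containers import BinsigError
from .discretize import DiscreteMatrix


@dataclass
class Interval:
    """One piece of an interval union over [0, 1].

    ``closure`` is two characters from ``(``/``[`` and ``)``/``]`` telling
    whether each end is open or closed, e.g. ``(]`` for the usual
    left-open right-closed bin and ``[]`` for the lowest bin, which is
    closed at the minimum.
    """

    lo: float
    hi: float
    closure: str = "(]"

    def contains(self, x: float) -> bool:
        lo_ok = x >= self.lo if self.closure[0] == "[" else x > self.lo
        hi_ok = x <= self.hi if self.closure[1] == "]" else x < self.hi
        return lo_ok and hi_ok

    def as_list(self) -> list:
        return [self.lo, self.hi, self.closure]


@dataclass
class SignatureTerm:
    gene: str
    intervals: list[Interval]
    weight: float

    def matches(self, x: float) -> bool:
        return any(iv.contains(x) for iv in self.intervals)


@dataclass
class RiskPrediction:
    sample_id: str
    final_score: float
    probability: float
    predicted_class: int


def sigmoid(score: float) -> float:
    if score >= 0:
        return 1.0 / (1.0 + math.exp(-score))
    e = math.exp(score)
    return e / (1.0 + e)


@dataclass
class SignatureModel:
    """Intercept + (gene, interval union, weight) terms with a logistic link."""

    task: str  # status | early_bcr
    intercept: float
    terms: list[SignatureTerm]
    psa_term: tuple[float, float] | None = None  # (threshold ng/mL, weight if PSA below)

    @property
    def gene_ids(self) -> list[str]:
        return sorted({t.gene for t in self.terms})

    def score(self, values: dict, psa: float | None = None, sample_id: str = "") -> RiskPrediction:
        """Score one sample from its min-max-scaled gene values.

        ``values`` maps gene id -> value in [0, 1] (out-of-range values are
        clamped, matching the bin clamp for test cohorts).
        """
        missing = [t.gene for t in self.terms if t.gene not in values]
        if missing:
            raise BinsigError(f"profile missing model genes: {sorted(set(missing))}")
        s = self.intercept
        for term in self.terms:
            x = min(1.0, max(0.0, float(values[term.gene])))
            if term.matches(x):
                s += term.weight
        if self.psa_term is not None:
            if psa is None:
                raise BinsigError("model has a PSA term but no psa value was given")
            threshold, w = self.psa_term
            if psa < threshold:
                s += w
        p = sigmoid(s)
        return RiskPrediction(sample_id=sample_id, final_score=s, probability=p, predicted_class=int(p >= 0.5))

    def score_table(self, values: pd.DataFrame, psa: pd.Series | None = None) -> pd.DataFrame:
        """Score every column (sample) of a genes x samples table."""
        rows = []
        for sid in values.columns:
            pred = self.score(
                values[sid].to_dict(),
                psa=float(psa.loc[sid]) if psa is not None else None,
                sample_id=str(sid),
            )
            rows.append(
                {
                    "sample_id": pred.sample_id,
                    "final_score": pred.final_score,
                    "probability": pred.probability,
                    "predicted_class": pred.predicted_class,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")

    def to_json(self) -> str:
        payload = {
            "task": self.task,
            "intercept": self.intercept,
            "terms": [
                {"gene": t.gene, "intervals": [iv.as_list() for iv in t.intervals], "weight": t.weight}
                for t in self.terms
            ],
            "psa_term": list(self.psa_term) if self.psa_term is not None else None,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SignatureModel":
        payload = json.loads(text)
        terms = [
            SignatureTerm(
                gene=t["gene"],
                intervals=[Interval(lo, hi, closure) for lo, hi, closure in t["intervals"]],
                weight=t["weight"],
            )
            for t in payload["terms"]
        ]
        psa = payload.get("psa_term")
        return cls(
            task=payload["task"],
            intercept=payload["intercept"],
            terms=terms,
            psa_term=tuple(psa) if psa is not None else None,
        )


def _bin_label(gene: str, lo: float, hi: float, first: bool) -> str:
    left = "[" if first else "("
    return f"{gene}:{left}{lo:g}-{hi:g}]"


def one_hot_encode(matrix: DiscreteMatrix) -> pd.DataFrame:
    """Samples x indicators table, one 0/1 column per (gene, bin).

    No reference category is dropped; columns are named ``GENE:(lo-hi]``
    and ordered gene by gene, bins ascending, so the argmax over a gene's
    columns recovers the bin index.
    """
    scheme = matrix.scheme
    cols = {}
    for gene in matrix.gene_ids:
        bins = matrix.values.loc[gene].to_numpy(dtype=int)
        for b, (lo, hi) in enumerate(scheme.bin_bounds(gene)):
            cols[_bin_label(gene, lo, hi, first=b == 0)] = (bins == b).astype(int)
    return pd.DataFrame(cols, index=matrix.sample_ids)


def fit_l2_logistic(
    X: pd.DataFrame, y, l2_strength: float = 1.0, tol: float = 1e-9, max_iter: int = 10000
) -> tuple[float, pd.Series]:
    """L2-penalised logistic fit (liblinear); returns (intercept, weights).

    Deterministic: same inputs give identical weights.  ``l2_strength`` is
    the penalty multiplier (sklearn's C is its inverse).
    """
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise BinsigError("training labels contain a single class")
    if counts.min() < 2:
        raise BinsigError("need at least 2 samples per class")
    # default penalty is the L2 norm; C is the inverse regularization
    # strength; the large intercept_scaling leaves the intercept
    # effectively unpenalised by liblinear
    clf = LogisticRegression(
        C=1.0 / l2_strength,
        solver="liblinear",
        tol=tol,
        max_iter=max_iter,
        random_state=0,
        intercept_scaling=100.0,
    )
    clf.fit(X.to_numpy(dtype=float), y)
    return float(clf.intercept_[0]), pd.Series(clf.coef_[0], index=X.columns)


def signature_from_bin_weights(
    intercept: float,
    matrix: DiscreteMatrix,
    bin_weights: pd.Series,
    merge_tol: float = 0.05,
    drop_tol: float = 0.0,
    task: str = "status",
    psa_term: tuple[float, float] | None = None,
) -> SignatureModel:
    """Collapse per-bin weights into interval-union terms.

    Adjacent bins of a gene whose weights differ by less than ``merge_tol``
    are merged into one interval carrying their mean weight; merged runs
    with |weight| <= ``drop_tol`` are omitted from the emitted model.
    """
    scheme = matrix.scheme
    terms: list[SignatureTerm] = []
    pos = 0
    for gene in matrix.gene_ids:
        bounds = scheme.bin_bounds(gene)
        w = bin_weights.iloc[pos : pos + len(bounds)].to_numpy(dtype=float)
        pos += len(bounds)
        runs: list[list[int]] = [[0]]
        for b in range(1, len(bounds)):
            if abs(w[b] - w[runs[-1][-1]]) < merge_tol:
                runs[-1].append(b)
            else:
                runs.append([b])
        for run in runs:
            weight = float(w[run].mean())
            if abs(weight) <= drop_tol:
                continue
            lo = bounds[run[0]][0]
            hi = bounds[run[-1]][1]
            closure = "[]" if run[0] == 0 else "(]"
            terms.append(SignatureTerm(gene=gene, intervals=[Interval(lo, hi, closure)], weight=weight))
    return SignatureModel(task=task, intercept=float(intercept), terms=terms, psa_term=psa_term)


def train_logistic(
    matrix: DiscreteMatrix,
    labels,
    l2_strength: float = 1.0,
    merge_tol: float = 0.05,
    drop_tol: float = 0.0,
    task: str = "status",
    psa: pd.Series | None = None,
    psa_threshold: float | None = None,
) -> SignatureModel:
    """Train an interval-weight signature on a discretized matrix.

    With ``psa`` and ``psa_threshold`` given (the early/late-recurrence
    task), a binary "PSA below threshold" indicator joins the design
    matrix and its fitted weight is emitted as the model's PSA term.
    """
    X = one_hot_encode(matrix)
    psa_col = None
    if psa is not None:
        if psa_threshold is None:
            raise BinsigError("psa given without psa_threshold")
        psa_col = "PSA:below"
        X[psa_col] = (psa.loc[X.index].to_numpy(dtype=float) < psa_threshold).astype(int)
    intercept, w = fit_l2_logistic(X, labels, l2_strength=l2_strength)
    psa_term = None
    if psa_col is not None:
        psa_term = (float(psa_threshold), float(w.loc[psa_col]))
        w = w.drop(psa_col)
    return signature_from_bin_weights(
        intercept, matrix, w, merge_tol=merge_tol, drop_tol=drop_tol, task=task, psa_term=psa_term
    )


def score_sample(model: SignatureModel, values: dict, psa: float | None = None, sample_id: str = "") -> RiskPrediction:
    """Functional alias for :meth:`SignatureModel.score`."""
    return model.score(values, psa=psa, sample_id=sample_id)


#: the published ten-gene recurrence signature: five-bin equal-width
#: intervals on min-max-scaled expression, intercept 1.5
_PRINTED_TERMS = [
    ("ZFHX3", 0.8, 1.0, "(]", -0.73),
    ("EMP2", 0.6, 0.8, "(]", -0.49),
    ("ITPR1", 0.2, 0.4, "(]", 0.66),
    ("NFIB", 0.6, 0.8, "(]", -0.57),
    ("PCCA", 0.6, 0.8, "(]", -0.73),
    ("RGS2", 0.4, 1.0, "(]", -1.06),
    ("WDR5", 0.8, 1.0, "(]", -1.15),
    ("SRGAP2", 0.2, 0.4, "(]", -0.48),
    ("AIDA", 0.4, 1.0, "(]", 0.57),
    ("SLC25A30", 0.0, 0.2, "[]", 0.84),
]


def load_printed_signature() -> SignatureModel:
    """The packaged ten-gene BCR status signature (intercept 1.5)."""
    terms = [
        SignatureTerm(gene=g, intervals=[Interval(lo, hi, closure)], weight=w)
        for g, lo, hi, closure, w in _PRINTED_TERMS
    ]
    return SignatureModel(task="status", intercept=1.5, terms=terms, psa_term=None)
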