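"""Expression preprocessing: log2 transform, CV filter, min-max rescaling.

The chain mirrors standard bulk RNA-seq practice for binned-signature
modelling: raw values are log2(x + 1)-transformed, genes whose coefficient
of variation (sd/mean on the log2 scale) falls at or below a threshold are
dropped as uninformative, and the survivors are rescaled per gene so the
training minimum maps to 0 and the training maximum to 1.  Min-max
parameters are fitted on the training cohort only and applied unchanged to
test cohorts (with clipping), so bin boundaries mean the same thing in
every cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import BinsigError, ExpressionMatrix


def log2_transform(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) elementwise; raw -> log2 scale.

    The default pseudocount of 1 sends zero counts to exactly 0 and leaves
    the transform strictly monotone.
    """
    if matrix.scale != "raw":
        raise BinsigError(f"log2_transform expects raw scale, got {matrix.scale}")
    vals = matrix.values
    if (vals.to_numpy() < 0).any():
        neg = vals.stack()
        neg = neg[neg < 0]
        gene, sample = neg.index[0]
        raise BinsigError(
            f"negative expression value {neg.iloc[0]} at gene {gene!r}, sample {sample!r}"
        )
    return ExpressionMatrix(np.log2(vals + pseudocount), scale="log2")


def coefficient_of_variation(matrix: ExpressionMatrix) -> pd.Series:
    """Per-gene sd/mean on the current scale (population sd, ddof=0).

    Genes with zero mean get CV 0 so they are dropped by any positive
    threshold rather than producing infinities.
    """
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean == 0, 0.0, sd / np.where(mean == 0, 1.0, mean))
    return pd.Series(cv, index=matrix.values.index, name="cv")


def cv_filter(matrix: ExpressionMatrix, threshold: float = 1.5) -> ExpressionMatrix:
    """Retain genes whose coefficient of variation exceeds ``threshold``.

    Operates on the log2 scale; gene order is preserved.  An empty result
    raises a warning, not an error, so callers can surface it.
    """
    if matrix.scale != "log2":
        raise BinsigError(f"cv_filter expects log2 scale, got {matrix.scale}")
    cv = coefficient_of_variation(matrix)
    keep = cv > threshold
    if not keep.any():
        warnings.warn(
            f"cv_filter(threshold={threshold}) removed every gene", stacklevel=2
        )
    return ExpressionMatrix(matrix.values.loc[keep[keep].index], scale="log2")


@dataclass
class MinMaxParams:
    """Per-gene (E_min, E_max) fitted on a training cohort.

    Genes whose min equals their max are *degenerate*: they carry no
    information on this cohort and are excluded when the parameters are
    applied.
    """

    e_min: pd.Series
    e_max: pd.Series

    @property
    def degenerate(self) -> pd.Series:
        return self.e_min == self.e_max

    @property
    def gene_ids(self) -> list[str]:
        return list(self.e_min.index)


def minmax_fit(matrix: ExpressionMatrix) -> MinMaxParams:
    """Fit per-gene min/max on the given (training) samples."""
    if matrix.scale != "log2":
        raise BinsigError(f"minmax_fit expects log2 scale, got {matrix.scale}")
    vals = matrix.values
    params = MinMaxParams(e_min=vals.min(axis=1), e_max=vals.max(axis=1))
    n_deg = int(params.degenerate.sum())
    if n_deg:
        warnings.warn(f"{n_deg} degenerate gene(s) (min == max) will be excluded", stacklevel=2)
    return params


def minmax_apply(
    matrix: ExpressionMatrix, params: MinMaxParams, clip: bool = True
) -> ExpressionMatrix:
    """(x - E_min)/(E_max - E_min) per gene; log2 -> minmax scale.

    Degenerate genes are dropped.  With ``clip`` (the default for test
    cohorts scored with training parameters), out-of-range values are
    clamped into [0, 1].
    """
    missing = [g for g in matrix.gene_ids if g not in params.e_min.index]
    if missing:
        raise BinsigError(f"min-max parameters missing for genes: {missing[:5]}")
    keep = [g for g in matrix.gene_ids if not params.degenerate.loc[g]]
    vals = matrix.values.loc[keep]
    lo = params.e_min.loc[keep]
    span = params.e_max.loc[keep] - lo
    out = vals.sub(lo, axis=0).div(span, axis=0)
    if clip:
        out = out.clip(0.0, 1.0)
    return ExpressionMatrix(out, scale="minmax")
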