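"""Core in-memory containers: expression matrices and clinical tables.

An :class:`ExpressionMatrix` is a genes x samples grid carried by a pandas
DataFrame plus a *scale* tag recording where in the preprocessing chain the
values live (``raw`` counts, ``log2``-transformed, or ``minmax``-rescaled to
[0, 1]).  A :class:`ClinicalTable` holds per-patient outcome data: the
biochemical-recurrence (BCR) indicator, the disease-free follow-up time in
months (a censoring time for patients without BCR), and serum PSA in ng/mL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SCALES = ("raw", "log2", "minmax")


class BinsigError(Exception):
    """Base class for user-facing errors raised by this package."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale tag.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id with sample ids as columns.
    scale:
        One of ``raw`` (non-negative counts/intensities), ``log2``
        (log2(x + pseudocount) values) or ``minmax`` (per-gene rescaled,
        every value in [0, 1] once clipping is applied).
    """

    values: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise BinsigError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()].tolist()
            raise BinsigError(f"duplicate gene ids: {dup[:5]}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()].tolist()
            raise BinsigError(f"duplicate sample ids: {dup[:5]}")
        if self.values.isna().any().any():
            bad = self.values.columns[self.values.isna().any(axis=0)].tolist()
            raise BinsigError(f"missing values in samples {bad[:5]}; impute or drop first")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise BinsigError(f"genes not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.scale)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise BinsigError(f"samples not in matrix: {missing[:5]}")
        return ExpressionMatrix(self.values[list(sample_ids)], self.scale)


@dataclass
class ClinicalTable:
    """Per-sample clinical outcomes, indexed by sample id.

    Required columns: ``bcr`` (0/1 biochemical recurrence) and
    ``dfs_months`` (disease-free or follow-up time, months).  Optional:
    ``psa`` (ng/mL, may be NaN), ``gleason``, ``age``, ``stage``.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        for col in ("bcr", "dfs_months"):
            if col not in self.data.columns:
                raise BinsigError(f"clinical table missing required column {col!r}")
        if not self.data.index.is_unique:
            raise BinsigError("duplicate sample ids in clinical table")
        if self.data["bcr"].isna().any() or self.data["dfs_months"].isna().any():
            raise BinsigError("bcr and dfs_months must be complete")
        if (np.asarray(self.data["dfs_months"], dtype=float) < 0).any():
            raise BinsigError("dfs_months must be non-negative")
        bad = set(np.unique(np.asarray(self.data["bcr"]))) - {0, 1, True, False}
        if bad:
            raise BinsigError(f"bcr must be binary; found {sorted(bad)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, matrix: ExpressionMatrix) -> "ClinicalTable":
        """Rows of this table in the matrix's sample order.

        The clinical table must cover every sample in the matrix.
        """
        missing = [s for s in matrix.sample_ids if s not in self.data.index]
        if missing:
            raise BinsigError(f"clinical table missing samples: {missing[:5]}")
        return ClinicalTable(self.data.loc[matrix.sample_ids])

    def labels(self, task: str = "status", horizon_months: float = 24.0) -> np.ndarray:
        """Binary targets for a classification task.

        ``status``: BCR vs no BCR.  ``early_bcr``: recurrence within
        ``horizon_months`` of treatment vs everything else.
        """
        bcr = np.asarray(self.data["bcr"], dtype=bool)
        if task == "status":
            return bcr.astype(int)
        if task == "early_bcr":
            t = np.asarray(self.data["dfs_months"], dtype=float)
            return (bcr & (t <= horizon_months)).astype(int)
        raise BinsigError(f"unknown task {task!r}")
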