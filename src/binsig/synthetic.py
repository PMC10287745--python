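"""Seeded synthetic prostate-cancer cohorts for end-to-end testing.

The generator emulates the statistical structure the pipeline assumes in a
training cohort of 143 patients with near-balanced recurrence classes
(71 with BCR, 72 without): a few thousand genes of which a small planted
subset differs between classes in *bin occupancy* on the [0, 1] scale,
PSA values whose class-conditional distributions cross a low decision
threshold, and disease-free times spanning a 24-month horizon with
censoring for patients who never recur.

Informative genes are modelled directly where the method looks: a latent
value u in [0, 1] per sample drawn from a Beta distribution whose mean is
shifted between classes by the ``effect`` parameter (mean 0.5 +/- effect/2
at a common concentration), so their five-bin occupancy separates the
classes.  Noise genes draw u from Beta(2, 2) identically in both classes;
``effect=0`` makes planted genes indistinguishable from noise.  Latent
values are mapped to a raw scale via 2**(L*u) - 1 with a gene-specific
dynamic range L, so the pipeline's log2 + min-max chain recovers u up to
an affine map and the planted bin structure survives preprocessing intact.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .containers import BinsigError, ClinicalTable, ExpressionMatrix


@dataclass
class CohortConfig:
    """Generative settings for one synthetic cohort."""

    n_bcr: int = 71
    n_nonbcr: int = 72
    n_genes: int = 500
    n_informative: int = 10
    effect: float = 0.4  # class shift of the latent Beta mean, in [0, 1]
    concentration: float = 12.0  # Beta concentration of informative genes
    noise_beta: tuple[float, float] = (2.0, 2.0)
    log2_range: tuple[float, float] = (4.0, 10.0)  # per-gene dynamic range L
    psa_split: float = 0.38  # ng/mL decision threshold the classes straddle
    psa_median_bcr: float = 0.25  # ng/mL, lognormal median for BCR patients
    psa_median_nonbcr: float = 5.0
    psa_sigma: float = 1.0
    bcr_time_scale: float = 26.0  # months, exponential mean of time to BCR
    followup_scale: float = 64.5  # months, exponential mean of censoring time
    match_followup: bool = False  # draw non-BCR follow-up from the BCR time model
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_bcr, self.n_nonbcr, self.n_genes, self.n_informative) < 1:
            raise BinsigError("all counts must be >= 1")
        if not 0.0 <= self.effect <= 1.0:
            raise BinsigError(f"effect must be in [0, 1], got {self.effect}")
        if self.n_informative > self.n_genes:
            raise BinsigError("n_informative cannot exceed n_genes")


def _sample_expression(
    cfg: CohortConfig,
    rng: np.random.Generator,
    informative: np.ndarray,
    log2_span: np.ndarray,
    y: np.ndarray,
) -> np.ndarray:
    """Raw-scale expression (genes x samples) given gene roles."""
    n = len(y)
    u = rng.beta(cfg.noise_beta[0], cfg.noise_beta[1], size=(cfg.n_genes, n))
    kappa = cfg.concentration
    mu = {0: 0.5 - cfg.effect / 2.0, 1: 0.5 + cfg.effect / 2.0}
    for g in np.flatnonzero(informative):
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            m = mu[cls]
            u[g, idx] = rng.beta(kappa * m, kappa * (1.0 - m), size=len(idx))
    return np.power(2.0, log2_span[:, None] * u) - 1.0


def _sample_clinical(cfg: CohortConfig, rng: np.random.Generator, y: np.ndarray, sample_ids) -> ClinicalTable:
    n = len(y)
    psa_median = np.where(y == 1, cfg.psa_median_bcr, cfg.psa_median_nonbcr)
    psa = np.exp(np.log(psa_median) + cfg.psa_sigma * rng.standard_normal(n))
    t_bcr = rng.exponential(cfg.bcr_time_scale, size=n)
    if cfg.match_followup:
        t_cens = rng.exponential(cfg.bcr_time_scale, size=n)
    else:
        t_cens = rng.exponential(cfg.followup_scale, size=n)
    times = np.where(y == 1, t_bcr, t_cens)
    df = pd.DataFrame(
        {
            "bcr": y.astype(int),
            "dfs_months": np.round(times, 2),
            "psa": np.round(psa, 3),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ClinicalTable(df)


def generate_cohort(config: CohortConfig) -> tuple[ExpressionMatrix, ClinicalTable, dict]:
    """One seeded training cohort: expression, clinical table, truth record.

    The truth record lists the planted informative genes and the per-gene
    dynamic ranges, and is what a matched test set is generated from.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_bcr + cfg.n_nonbcr
    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n)]
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[: cfg.n_bcr]] = 1
    informative = np.zeros(cfg.n_genes, dtype=bool)
    informative[rng.choice(cfg.n_genes, size=cfg.n_informative, replace=False)] = True
    log2_span = rng.uniform(cfg.log2_range[0], cfg.log2_range[1], size=cfg.n_genes)
    raw = _sample_expression(cfg, rng, informative, log2_span, y)
    expr = ExpressionMatrix(
        pd.DataFrame(np.round(raw, 4), index=gene_ids, columns=sample_ids), scale="raw"
    )
    clinical = _sample_clinical(cfg, rng, y, sample_ids)
    truth = {
        "informative_genes": [g for g, f in zip(gene_ids, informative) if f],
        "effect": cfg.effect,
        "log2_span": {g: float(s) for g, s in zip(gene_ids, log2_span)},
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
    }
    return expr, clinical, truth


def generate_matched_testset(
    config: CohortConfig,
    truth: dict,
    n_bcr: int = 36,
    n_nonbcr: int = 104,
    seed: int | None = None,
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """New samples from the same generative process as a training cohort.

    The planted gene identities and per-gene dynamic ranges come from the
    training truth record; class balance is configurable (the default
    mimics an imbalanced 36/104 external testing cohort).  Normalization
    and discretization parameters must still be taken from training.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = n_bcr + n_nonbcr
    gene_ids = list(truth["log2_span"])
    sample_ids = [f"T{i:04d}" for i in range(n)]
    y = np.zeros(n, dtype=int)
    y[rng.permutation(n)[:n_bcr]] = 1
    informative = np.array([g in set(truth["informative_genes"]) for g in gene_ids])
    log2_span = np.array([truth["log2_span"][g] for g in gene_ids])
    raw = _sample_expression(cfg, rng, informative, log2_span, y)
    expr = ExpressionMatrix(
        pd.DataFrame(np.round(raw, 4), index=gene_ids, columns=sample_ids), scale="raw"
    )
    clinical = _sample_clinical(cfg, rng, y, sample_ids)
    return expr, clinical


def write_truth(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
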