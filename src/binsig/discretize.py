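"""Bin-count rules and equal-width / equal-frequency discretization.

Eight classical histogram rules estimate the number of bins k.  Six are
*static* — they depend only on the number of observations n per attribute:

    square root        k = sqrt(n)
    cencov             k = n^(1/3)
    rice               k = 2 n^(1/3)
    terrell_scott      k = (2n)^(1/3)
    sturges            k = log2(n) + 1
    brooks_carruthers  k = 5 log10(n)

Two are *dynamic*, needing each attribute's spread: Freedman-Diaconis
(bin width 2*IQR*n^(-1/3), so k = R / (2*IQR*n^(-1/3))) and Scott
(width 3.49*sigma*n^(-1/3)).  Each rule carries its own rounding mode;
the defaults are the conventional choices for these estimators
(round-half-up for the static rules except Terrell-Scott, which floors;
ceil for the width-based dynamic rules).

Intervals follow the left-open right-closed convention "(a, b]" with the
lowest bin closed at the minimum, so a value equal to an interior edge
falls in the lower bin.  Schemes are fitted on training data and applied
unchanged elsewhere; out-of-range values clamp to the first or last bin.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BinsigError, ExpressionMatrix

STATIC_RULES = (
    "sqrt",
    "cencov",
    "rice",
    "terrell_scott",
    "sturges",
    "brooks_carruthers",
)
DYNAMIC_RULES = ("freedman_diaconis", "scott")
RULES = STATIC_RULES + DYNAMIC_RULES

#: default rounding mode per rule
DEFAULT_ROUNDING: dict[str, str] = {
    "sqrt": "round",
    "cencov": "round",
    "rice": "round",
    "terrell_scott": "floor",
    "sturges": "round",
    "brooks_carruthers": "round",
    "freedman_diaconis": "ceil",
    "scott": "ceil",
}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


_ROUNDERS = {"floor": lambda x: int(math.floor(x)), "round": _round_half_up, "ceil": lambda x: int(math.ceil(x))}


def _raw_bin_estimate(rule: str, n: int, R: float = None, iqr: float = None, sigma: float = None) -> float:
    if rule == "sqrt":
        return math.sqrt(n)
    if rule == "cencov":
        return n ** (1.0 / 3.0)
    if rule == "rice":
        return 2.0 * n ** (1.0 / 3.0)
    if rule == "terrell_scott":
        return (2.0 * n) ** (1.0 / 3.0)
    if rule == "sturges":
        return math.log2(n) + 1.0
    if rule == "brooks_carruthers":
        return 5.0 * math.log10(n)
    if rule == "freedman_diaconis":
        return R / (2.0 * iqr * n ** (-1.0 / 3.0))
    if rule == "scott":
        return R / (3.49 * sigma * n ** (-1.0 / 3.0))
    raise BinsigError(f"unknown bin rule {rule!r}; expected one of {RULES}")


def estimate_bins(
    rule: str,
    n: int,
    stats: dict | None = None,
    rounding: str | None = None,
    fallback_k: int = 5,
):
    """Number of bins under a named rule for n observations.

    Static rules return a single int.  Dynamic rules require ``stats`` with
    per-attribute arrays/Series ``R`` (range), ``iqr`` and ``sigma`` and
    return a per-attribute integer Series; attributes with zero IQR/sigma
    fall back to ``fallback_k`` with a warning.
    """
    if n < 1:
        raise BinsigError(f"n must be >= 1, got {n}")
    if rule not in RULES:
        raise BinsigError(f"unknown bin rule {rule!r}; expected one of {RULES}")
    rounder = _ROUNDERS[rounding or DEFAULT_ROUNDING[rule]]
    if rule in STATIC_RULES:
        return max(1, rounder(_raw_bin_estimate(rule, n)))
    if rule not in DYNAMIC_RULES:
        raise BinsigError(f"unknown bin rule {rule!r}; expected one of {RULES}")
    if stats is None:
        raise BinsigError(f"rule {rule!r} needs per-attribute stats (R, iqr, sigma)")
    R = pd.Series(stats["R"], dtype=float)
    spread = pd.Series(stats["iqr" if rule == "freedman_diaconis" else "sigma"], dtype=float)
    ks = {}
    n_fallback = 0
    for attr in R.index:
        if spread.loc[attr] <= 0 or R.loc[attr] <= 0:
            ks[attr] = fallback_k
            n_fallback += 1
        else:
            ks[attr] = max(
                1,
                rounder(
                    _raw_bin_estimate(
                        rule, n, R=float(R.loc[attr]),
                        iqr=float(spread.loc[attr]), sigma=float(spread.loc[attr]),
                    )
                ),
            )
    if n_fallback:
        warnings.warn(
            f"{rule}: {n_fallback} attribute(s) with zero spread fell back to k={fallback_k}",
            stacklevel=2,
        )
    return pd.Series(ks, dtype=int)


def equal_width_edges(k: int, vmin: float, vmax: float) -> np.ndarray:
    """k-1 interior cut points splitting [vmin, vmax] into equal spans."""
    if k < 1:
        raise BinsigError(f"k must be >= 1, got {k}")
    if not vmax > vmin:
        raise BinsigError(f"degenerate range [{vmin}, {vmax}]")
    return vmin + (vmax - vmin) * np.arange(1, k) / k


def equal_frequency_edges(k: int, values) -> np.ndarray:
    """Interior edges putting (nearly) equal counts in each of k bins.

    Cut candidates are the midpoints between consecutive *distinct* sorted
    values.  Each target quantile rank i*n/k is matched to a distinct
    candidate by a monotone assignment minimising total rank deviation, so
    ties shrink the effective bin count instead of producing duplicate
    edges, and on all-distinct data bin occupancies differ by at most one.
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if k < 1:
        raise BinsigError(f"k must be >= 1, got {k}")
    if n < k:
        raise BinsigError(f"need at least k={k} values, got {n}")
    distinct, counts = np.unique(values, return_counts=True)
    if len(distinct) < 2:
        raise BinsigError("all values identical: degenerate gene")
    # candidate cut j sits after cum[j] observations, at the midpoint
    # between distinct[j] and distinct[j+1]
    cum = np.cumsum(counts)[:-1].astype(float)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    m = len(mids)
    targets = n * np.arange(1, k) / k
    if m <= len(targets):
        return mids.copy()
    # monotone min-cost assignment of targets to strictly increasing
    # candidate ranks (cost = |candidate rank - target rank|)
    t = len(targets)
    cost = np.abs(cum[None, :] - targets[:, None])  # t x m
    INF = np.inf
    dp = np.full((t, m), INF)
    choice = np.zeros((t, m), dtype=int)
    best = INF
    for j in range(m - t + 1):
        dp[0, j] = cost[0, j]
    for i in range(1, t):
        # dp[i, j] = cost[i, j] + min_{j' < j} dp[i-1, j']
        run_min = INF
        run_arg = -1
        for j in range(i, m - (t - 1 - i)):
            if dp[i - 1, j - 1] < run_min:
                run_min = dp[i - 1, j - 1]
                run_arg = j - 1
            dp[i, j] = cost[i, j] + run_min
            choice[i, j] = run_arg
    j = int(np.argmin(dp[t - 1]))
    picks = [j]
    for i in range(t - 1, 0, -1):
        j = choice[i, j]
        picks.append(j)
    picks.reverse()
    return mids[picks]


@dataclass
class DiscretizationScheme:
    """Per-gene cut points plus the strategy and rule that produced them."""

    strategy: str  # equal_width | equal_frequency
    edges: dict[str, np.ndarray]
    rule: str | None = None
    rounding: str | None = None
    k_nominal: int | None = None  # requested k for static rules

    def k(self, gene: str) -> int:
        """Effective bin count for a gene (ties may shrink it)."""
        return len(self.edges[gene]) + 1

    @property
    def gene_ids(self) -> list[str]:
        return list(self.edges)

    def bin_bounds(self, gene: str) -> list[tuple[float, float]]:
        """(lo, hi) of every bin of a gene, lowest bin closed at lo."""
        e = self.edges[gene]
        lo = np.concatenate([[0.0 if self.strategy == "equal_width" else -np.inf], e])
        hi = np.concatenate([e, [1.0 if self.strategy == "equal_width" else np.inf]])
        return list(zip(lo.tolist(), hi.tolist()))

    def to_json(self) -> str:
        payload = {
            "strategy": self.strategy,
            "rule": self.rule,
            "rounding": self.rounding,
            "k_nominal": self.k_nominal,
            "edges": {g: list(map(float, e)) for g, e in self.edges.items()},
        }
        return json.dumps(payload, indent=None, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiscretizationScheme":
        payload = json.loads(text)
        return cls(
            strategy=payload["strategy"],
            edges={g: np.asarray(e, dtype=float) for g, e in payload["edges"].items()},
            rule=payload["rule"],
            rounding=payload["rounding"],
            k_nominal=payload["k_nominal"],
        )


@dataclass
class DiscreteMatrix:
    """Integer bin indices (genes x samples) plus the scheme that made them."""

    values: pd.DataFrame = field(repr=False)
    scheme: DiscretizationScheme = None

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def fit_scheme(
    matrix: ExpressionMatrix,
    strategy: str = "equal_width",
    rule: str | None = None,
    k: int | None = None,
    rounding: str | None = None,
    fallback_k: int = 5,
) -> DiscretizationScheme:
    """Fit per-gene cut points on a (training) matrix.

    Either a fixed ``k`` or a named ``rule`` must be given.  Equal-width
    cuts on min-max data span [0, 1]; equal-frequency cuts come from the
    observed values.  n for the bin rules is the number of samples.
    """
    if strategy not in ("equal_width", "equal_frequency"):
        raise BinsigError(f"unknown strategy {strategy!r}")
    if (rule is None) == (k is None):
        raise BinsigError("give exactly one of rule= or k=")
    n = matrix.n_samples
    vals = matrix.values
    if k is not None:
        per_gene_k = pd.Series(k, index=vals.index, dtype=int)
        k_nominal = k
    elif rule in STATIC_RULES:
        k_static = estimate_bins(rule, n, rounding=rounding)
        per_gene_k = pd.Series(k_static, index=vals.index, dtype=int)
        k_nominal = k_static
    else:
        arr = vals.to_numpy(dtype=float)
        q75, q25 = np.percentile(arr, [75, 25], axis=1)
        stats = {
            "R": pd.Series(arr.max(axis=1) - arr.min(axis=1), index=vals.index),
            "iqr": pd.Series(q75 - q25, index=vals.index),
            "sigma": pd.Series(arr.std(axis=1, ddof=0), index=vals.index),
        }
        per_gene_k = estimate_bins(rule, n, stats=stats, rounding=rounding, fallback_k=fallback_k)
        k_nominal = None
    edges: dict[str, np.ndarray] = {}
    for gene in vals.index:
        kg = int(per_gene_k.loc[gene])
        row = vals.loc[gene].to_numpy(dtype=float)
        if strategy == "equal_width":
            if matrix.scale == "minmax":
                vmin, vmax = 0.0, 1.0
            else:
                vmin, vmax = float(row.min()), float(row.max())
            edges[gene] = equal_width_edges(kg, vmin, vmax)
        else:
            edges[gene] = equal_frequency_edges(kg, row)
    return DiscretizationScheme(
        strategy=strategy,
        edges=edges,
        rule=rule,
        rounding=rounding or (DEFAULT_ROUNDING[rule] if rule else None),
        k_nominal=k_nominal,
    )


def apply_scheme(matrix: ExpressionMatrix, scheme: DiscretizationScheme) -> DiscreteMatrix:
    """Map continuous values to bin indices under the (a, b] convention.

    Values at or below the lowest edge map to bin 0 and values above the
    highest edge to bin k-1, which clamps test data that falls outside the
    training range.
    """
    missing = [g for g in matrix.gene_ids if g not in scheme.edges]
    if missing:
        raise BinsigError(f"scheme has no edges for genes: {missing[:5]}")
    out = {}
    for gene in matrix.gene_ids:
        row = matrix.values.loc[gene].to_numpy(dtype=float)
        # side='left': value equal to an edge goes to the lower bin
        out[gene] = np.searchsorted(scheme.edges[gene], row, side="left")
    df = pd.DataFrame.from_dict(out, orient="index", columns=matrix.sample_ids).astype(int)
    df = df.loc[matrix.gene_ids]
    return DiscreteMatrix(values=df, scheme=scheme)
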