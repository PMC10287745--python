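"""Correlation-based feature selection (CFS) on discretized genes.

A candidate subset S of l features is scored by the merit

    merit(S) = l * t_c / sqrt(l + l*(l-1) * t_f)

where t_c is the mean feature-class correlation over S and t_f the mean
pairwise feature-feature correlation — relevance rewarded, redundancy
penalised.  On nominal (binned) data the correlation is the symmetrical
uncertainty SU(A, B) = 2*I(A;B) / (H(A) + H(B)), which lives in [0, 1];
absolute Pearson correlation on the continuous values is available for the
undiscretized baseline.  The search (best-first with a stall budget, or
plain forward selection) is deterministic, with ties broken by gene id.
Only a final subset whose merit exceeds the retention threshold (default
0.60) is returned; otherwise the subset is empty and a warning is issued.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import BinsigError
from .discretize import DiscreteMatrix


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetrical_uncertainty(a, b) -> float:
    """SU(A, B) = 2 I(A;B) / (H(A)+H(B)) on two discrete vectors.

    Returns 0 when either vector has zero entropy (a constant feature
    carries no information).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if len(a) != len(b) or len(a) < 2:
        raise BinsigError("su needs two equal-length vectors of length >= 2")
    a = a - a.min()
    b = b - b.min()
    ka, kb = int(a.max()) + 1, int(b.max()) + 1
    joint = np.bincount(a * kb + b, minlength=ka * kb).astype(float)
    ha = _entropy(np.bincount(a, minlength=ka).astype(float))
    hb = _entropy(np.bincount(b, minlength=kb).astype(float))
    if ha == 0.0 or hb == 0.0:
        return 0.0
    hj = _entropy(joint)
    return 2.0 * (ha + hb - hj) / (ha + hb)


def su_to_target(features: np.ndarray, target: np.ndarray) -> np.ndarray:
    """SU of each row of a (features x samples) int matrix with a target."""
    f = np.asarray(features, dtype=int)
    y = np.asarray(target, dtype=int)
    y = y - y.min()
    kt = int(y.max()) + 1
    f = f - f.min(axis=1, keepdims=True)
    kf = int(f.max()) + 1 if f.size else 1
    n_feat, n = f.shape
    codes = (np.arange(n_feat)[:, None] * (kf * kt) + f * kt + y[None, :]).ravel()
    pj = np.bincount(codes, minlength=n_feat * kf * kt).reshape(n_feat, kf, kt) / n

    def _h(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        return -t.sum(axis=-1)

    hf = _h(pj.sum(axis=2))
    hy = _h(pj.sum(axis=1))
    hj = _h(pj.reshape(n_feat, -1))
    denom = hf + hy
    out = np.zeros(n_feat)
    ok = (denom > 0) & (hf > 0) & (hy > 0)
    out[ok] = 2.0 * (denom[ok] - hj[ok]) / denom[ok]
    return np.clip(out, 0.0, 1.0)


def pearson_abs(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def correlation(a, b, method: str = "symmetrical_uncertainty") -> float:
    """Feature-feature or feature-class association in [0, 1]."""
    if method == "symmetrical_uncertainty":
        return symmetrical_uncertainty(a, b)
    if method == "pearson":
        return pearson_abs(a, b)
    raise BinsigError(f"unknown correlation method {method!r}")


def merit_score(t_c: float, t_f: float, l: int) -> float:
    """CFS merit l*t_c / sqrt(l + l(l-1)*t_f) for a subset of l features."""
    if l < 1:
        raise BinsigError(f"subset size must be >= 1, got {l}")
    if t_f < 0:
        raise BinsigError("t_f must be >= 0 (use absolute correlations)")
    return l * t_c / np.sqrt(l + l * (l - 1) * t_f)


@dataclass
class FeatureSubset:
    """A selected gene subset with the correlations behind its merit."""

    gene_ids: list[str]
    t_c: float
    t_f: float
    merit: float
    inclusion_order: list[str] = field(default_factory=list)
    merit_trajectory: list[float] = field(default_factory=list)
    singleton_tc: pd.Series | None = None

    @property
    def l(self) -> int:
        return len(self.gene_ids)

    def report(self) -> pd.DataFrame:
        """Per-gene selection report (TSV-friendly)."""
        rows = []
        for order, g in enumerate(self.inclusion_order, start=1):
            rows.append(
                {
                    "gene_id": g,
                    "singleton_tc": float(self.singleton_tc.loc[g])
                    if self.singleton_tc is not None
                    else np.nan,
                    "inclusion_order": order,
                    "merit_after_inclusion": self.merit_trajectory[order - 1],
                }
            )
        return pd.DataFrame(
            rows, columns=["gene_id", "singleton_tc", "inclusion_order", "merit_after_inclusion"]
        )


class _MeritCache:
    """Class and pairwise correlations over integer feature indices.

    Pairwise correlations of one feature against all others are computed
    vectorised on first use and cached, so subset search touches each
    member's correlation row once.
    """

    def __init__(self, feats: np.ndarray, y: np.ndarray, method: str, raw: np.ndarray | None = None):
        self.feats = feats
        self.raw = raw if raw is not None else feats
        self.method = method
        if method == "symmetrical_uncertainty":
            self.tc = su_to_target(feats, y)
        else:
            yf = np.asarray(y, dtype=float)
            self.tc = np.array([pearson_abs(self.raw[i], yf) for i in range(feats.shape[0])])
        self._rows: dict[int, np.ndarray] = {}

    def pair_row(self, m: int) -> np.ndarray:
        if m not in self._rows:
            if self.method == "symmetrical_uncertainty":
                row = su_to_target(self.feats, self.feats[m])
            else:
                x = self.raw.astype(float)
                sd = x.std(axis=1)
                with np.errstate(divide="ignore", invalid="ignore"):
                    c = ((x - x.mean(axis=1, keepdims=True)) @ (x[m] - x[m].mean())) / (
                        len(x[m]) * sd * x[m].std()
                    )
                row = np.abs(np.where((sd == 0) | (x[m].std() == 0), 0.0, c))
            row[m] = 1.0
            self._rows[m] = row
        return self._rows[m]

    def pair(self, i: int, j: int) -> float:
        return float(self.pair_row(j)[i])

    def pair_sums(self, members) -> np.ndarray:
        """For every feature, the summed pair correlation with ``members``."""
        out = np.zeros(self.feats.shape[0])
        for m in members:
            out += self.pair_row(m)
        return out

    def merit_from_sums(self, l: int, sum_tc: float, pair_total: float) -> float:
        if l == 0:
            return 0.0
        t_c = sum_tc / l
        t_f = pair_total / (l * (l - 1) / 2) if l > 1 else 0.0
        return float(merit_score(t_c, t_f, l))


def subset_merit(matrix, members, y, method: str = "symmetrical_uncertainty") -> float:
    """Merit of an explicit feature subset (diagnostics and test oracles)."""
    cache = _MeritCache(np.asarray(matrix, dtype=int), np.asarray(y, dtype=int), method)
    members = list(members)
    sum_tc = float(cache.tc[members].sum())
    pair_total = sum(cache.pair(i, j) for a, i in enumerate(members) for j in members[a + 1 :])
    return cache.merit_from_sums(len(members), sum_tc, pair_total)


def cfs_select(
    matrix: DiscreteMatrix | pd.DataFrame | np.ndarray,
    target,
    threshold: float = 0.60,
    strategy: str = "best_first",
    method: str = "symmetrical_uncertainty",
    stall_budget: int = 5,
    raw_values: np.ndarray | None = None,
) -> FeatureSubset:
    """Search for the merit-maximising gene subset.

    ``best_first`` keeps a priority queue of partial subsets and stops after
    ``stall_budget`` consecutive expansions that fail to improve the best
    merit seen; ``forward`` greedily adds the best single gene until no
    addition improves the merit.  Both are deterministic; merit ties are
    broken by lexicographic gene id (genes are processed in sorted order).

    The returned subset's merit must exceed ``threshold``; otherwise an
    empty subset is returned with a warning.
    """
    if isinstance(matrix, DiscreteMatrix):
        genes = list(matrix.gene_ids)
        feats = matrix.values.to_numpy(dtype=int)
    elif isinstance(matrix, pd.DataFrame):
        genes = list(matrix.index)
        feats = matrix.to_numpy()
    else:
        feats = np.asarray(matrix)
        genes = [f"f{i:04d}" for i in range(feats.shape[0])]
    y = np.asarray(target, dtype=int)
    if feats.shape[0] < 2:
        raise BinsigError("cfs_select needs at least 2 features")
    if feats.shape[1] != len(y):
        raise BinsigError("labels must cover all samples")
    if len(np.unique(y)) < 2:
        raise BinsigError("target must have two classes")
    if strategy not in ("best_first", "forward"):
        raise BinsigError(f"unknown search strategy {strategy!r}")

    order = np.argsort(np.asarray(genes, dtype=object), kind="stable")
    feats = np.ascontiguousarray(feats[order]).astype(int)
    raw = raw_values[np.asarray(order)] if raw_values is not None else None
    genes_sorted = [genes[i] for i in order]
    cache = _MeritCache(feats, y, method, raw=raw)
    singleton_tc = pd.Series(cache.tc, index=genes_sorted)
    n_feat = feats.shape[0]

    empty = FeatureSubset([], 0.0, 0.0, 0.0, singleton_tc=singleton_tc)
    if np.all(cache.tc == 0):
        warnings.warn("all features uncorrelated or constant: empty subset", stacklevel=2)
        return empty

    # state: sorted tuple of member indices
    # info: (merit, sum_tc, pair_total, added_order, merit_trajectory)
    start: tuple[int, ...] = ()
    info: dict[tuple[int, ...], tuple[float, float, float, list[int], list[float]]] = {
        start: (0.0, 0.0, 0.0, [], [])
    }
    heap: list[tuple[float, tuple[int, ...]]] = [(0.0, start)]
    visited: set[tuple[int, ...]] = set()
    best_state: tuple[int, ...] = start
    best = (0.0, 0.0, 0.0, [], [])
    stall = 0

    if strategy == "forward":
        state = start
        merit, sum_tc, pair_total, added, traj = info[start]
        while True:
            psums = cache.pair_sums(state)
            cand_merits = np.array(
                [
                    cache.merit_from_sums(len(state) + 1, sum_tc + cache.tc[i], pair_total + psums[i])
                    if i not in state
                    else -np.inf
                    for i in range(n_feat)
                ]
            )
            i_best = int(np.argmax(cand_merits))
            if cand_merits[i_best] <= merit + 1e-12:
                break
            merit = float(cand_merits[i_best])
            sum_tc += cache.tc[i_best]
            pair_total += psums[i_best]
            state = tuple(sorted(state + (i_best,)))
            added = added + [i_best]
            traj = traj + [merit]
        if not state or merit <= threshold:
            warnings.warn(
                f"no subset with merit > {threshold} (best {merit:.3f}): empty subset",
                stacklevel=2,
            )
            return empty
        best_state, best = state, (merit, sum_tc, pair_total, added, traj)
    else:
        while heap and stall <= stall_budget:
            neg_m, state = heapq.heappop(heap)
            if state in visited:
                continue
            visited.add(state)
            merit, sum_tc, pair_total, added, traj = info.pop(state)
            psums = cache.pair_sums(state)
            improved = False
            for i in range(n_feat):
                if i in state:
                    continue
                succ = tuple(sorted(state + (i,)))
                if succ in visited or succ in info:
                    continue
                m = cache.merit_from_sums(len(succ), sum_tc + cache.tc[i], pair_total + psums[i])
                info[succ] = (m, sum_tc + cache.tc[i], pair_total + psums[i], added + [i], traj + [m])
                heapq.heappush(heap, (-m, succ))
                if m > best[0] + 1e-12:
                    best_state, best = succ, info[succ]
                    improved = True
            stall = 0 if improved else stall + 1
        merit = best[0]
        if not best_state or merit <= threshold:
            warnings.warn(
                f"no subset with merit > {threshold} (best {merit:.3f}): empty subset",
                stacklevel=2,
            )
            return empty

    merit, sum_tc, pair_total, added, traj = best
    l = len(best_state)
    return FeatureSubset(
        gene_ids=[genes_sorted[i] for i in best_state],
        t_c=float(sum_tc / l),
        t_f=float(pair_total / (l * (l - 1) / 2)) if l > 1 else 0.0,
        merit=float(merit),
        inclusion_order=[genes_sorted[i] for i in added],
        merit_trajectory=list(traj),
        singleton_tc=singleton_tc,
    )
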