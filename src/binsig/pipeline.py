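"""End-to-end orchestration: preprocess -> discretize -> select -> train
-> evaluate, plus the rule-comparison grid.

Every run is driven by a :class:`PipelineConfig` whose defaults are the
method's standard constants (CV threshold 1.5, merit threshold 0.60, L2
strength 1.0, 24-month horizon).  Min-max parameters and discretization
schemes are fitted on the training cohort only and applied unchanged to
test data; all randomness flows from the single config seed.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import discretize as disc
from . import evaluate as ev
from . import feature_select as fs
from . import preprocess as pp
from .containers import BinsigError, ClinicalTable, ExpressionMatrix
from .signature import SignatureModel, train_logistic


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run; round-trips through a flat config file."""

    cv_threshold: float = 1.5
    strategy: str = "equal_width"
    rule: str | None = "cencov"  # named bin rule, or None with fixed k
    k: int | None = None
    merit_threshold: float = 0.60
    search: str = "best_first"
    correlation: str = "symmetrical_uncertainty"
    l2_strength: float = 1.0
    merge_tol: float = 0.05
    task: str = "status"
    horizon_months: float = 24.0
    psa_threshold: float | None = None  # set to use the PSA-below indicator
    risk_cut: float = 0.5
    seed: int = 0

    def to_flat(self) -> str:
        lines = []
        for key, val in asdict(self).items():
            lines.append(f"{key}={'' if val is None else val}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_flat(cls, text: str) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in cls.__dataclass_fields__.values()}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in cls.__dataclass_fields__:
                raise BinsigError(f"unknown config key {key!r}")
            if val == "":
                kwargs[key] = None
                continue
            t = types[key]
            if "int" in t and "float" not in t:
                kwargs[key] = int(val)
            elif "float" in t:
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class StageLog:
    """Gene/sample bookkeeping of a single run, stage by stage."""

    records: list[dict] = field(default_factory=list)

    def add(self, stage: str, **info) -> None:
        self.records.append({"stage": stage, **info})

    def echo(self, stream=sys.stderr) -> None:
        for rec in self.records:
            extras = " ".join(f"{k}={v}" for k, v in rec.items() if k != "stage")
            print(f"[{rec['stage']}] {extras}", file=stream)


@dataclass
class PipelineResult:
    model: SignatureModel
    report: ev.EvaluationReport
    scheme: disc.DiscretizationScheme
    subset: fs.FeatureSubset
    predictions: pd.DataFrame
    km: dict[str, ev.KMCurve] | None
    log: StageLog
    minmax: pp.MinMaxParams


def _stage(name):
    """Re-raise stage failures with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, BinsigError):
                raise BinsigError(f"stage {name!r} failed: {exc}") from exc
            if isinstance(exc, BinsigError) and not str(exc).startswith("stage "):
                raise BinsigError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def preprocess_cohort(
    matrix: ExpressionMatrix, config: PipelineConfig, params: pp.MinMaxParams | None = None
) -> tuple[ExpressionMatrix, pp.MinMaxParams]:
    """log2 -> CV filter -> min-max.  With ``params`` given (test cohorts),
    the CV filter restricts to the training genes and the training min-max
    parameters are applied with clipping."""
    m = matrix
    if m.scale == "raw":
        m = pp.log2_transform(m)
    if params is not None:
        m = m.subset_genes([g for g in params.gene_ids])
        return pp.minmax_apply(m, params, clip=True), params
    m = pp.cv_filter(m, threshold=config.cv_threshold)
    if m.n_genes == 0:
        raise BinsigError(f"cv_filter(threshold={config.cv_threshold}) left no genes")
    fitted = pp.minmax_fit(m)
    return pp.minmax_apply(m, fitted, clip=True), fitted


def run_pipeline(
    config: PipelineConfig,
    train: tuple[ExpressionMatrix, ClinicalTable],
    test: tuple[ExpressionMatrix, ClinicalTable] | None = None,
) -> PipelineResult:
    """Full train(/test) run; deterministic given the config seed."""
    log = StageLog()
    train_expr, train_clin = train
    train_clin = train_clin.aligned_to(train_expr)
    y_train = train_clin.labels(config.task, config.horizon_months)
    log.add("input", genes=train_expr.n_genes, samples=train_expr.n_samples)

    with _stage("preprocess"):
        norm_train, params = preprocess_cohort(train_expr, config)
    log.add("preprocess", genes_out=norm_train.n_genes)

    with _stage("discretize"):
        scheme = disc.fit_scheme(
            norm_train, strategy=config.strategy, rule=config.rule, k=config.k
        )
        dm_train = disc.apply_scheme(norm_train, scheme)
    ks = [scheme.k(g) for g in scheme.gene_ids]
    log.add("discretize", strategy=config.strategy, rule=config.rule or f"k={config.k}",
            k_min=min(ks), k_max=max(ks))

    with _stage("select"):
        subset = fs.cfs_select(
            dm_train,
            y_train,
            threshold=config.merit_threshold,
            strategy=config.search,
            method=config.correlation,
        )
        if subset.l == 0:
            raise BinsigError(
                f"feature selection returned no subset with merit > {config.merit_threshold}"
            )
        dm_sel = disc.DiscreteMatrix(dm_train.values.loc[subset.gene_ids], scheme)
    log.add("select", n_genes=subset.l, merit=round(subset.merit, 4))

    with _stage("train"):
        psa = train_clin.data["psa"] if config.psa_threshold is not None else None
        model = train_logistic(
            dm_sel,
            y_train,
            l2_strength=config.l2_strength,
            merge_tol=config.merge_tol,
            task=config.task,
            psa=psa,
            psa_threshold=config.psa_threshold,
        )
    log.add("train", terms=len(model.terms))

    with _stage("evaluate"):
        if test is not None:
            test_expr, test_clin = test
            test_clin = test_clin.aligned_to(test_expr)
            norm_test, _ = preprocess_cohort(test_expr, config, params=params)
            eval_values = norm_test.values.loc[subset.gene_ids]
            eval_clin = test_clin
        else:
            eval_values = norm_train.values.loc[subset.gene_ids]
            eval_clin = train_clin
        y_eval = eval_clin.labels(config.task, config.horizon_months)
        psa_eval = eval_clin.data["psa"] if config.psa_threshold is not None else None
        preds = model.score_table(eval_values, psa=psa_eval)
        report = ev.confusion(preds["predicted_class"].to_numpy(), y_eval)
        report.auc = ev.roc_auc(preds["final_score"].to_numpy(), y_eval)
        report.horizon_months = config.horizon_months
        groups = ev.risk_stratify(preds["probability"].to_numpy(), cut=config.risk_cut)
        km = None
        if len(np.unique(groups)) >= 1:
            km = ev.km_curve(
                eval_clin.data["dfs_months"].to_numpy(dtype=float),
                eval_clin.data["bcr"].to_numpy(dtype=int),
                groups,
            )
    log.add("evaluate", n=report.n, accuracy=round(report.accuracy, 4),
            auc=round(report.auc, 4))

    return PipelineResult(
        model=model,
        report=report,
        scheme=scheme,
        subset=subset,
        predictions=preds,
        km=km,
        log=log,
        minmax=params,
    )


def compare_rules(
    config: PipelineConfig,
    train: tuple[ExpressionMatrix, ClinicalTable],
    test: tuple[ExpressionMatrix, ClinicalTable] | None = None,
    rules: tuple[str, ...] = disc.RULES,
) -> pd.DataFrame:
    """Rule x strategy grid of (k, accuracy, precision, n_genes) plus an
    undiscretized baseline row (Pearson-based selection on continuous
    values)."""
    rows = []
    # baseline: no discretization
    rows.append(_baseline_row(config, train, test))
    for strategy in ("equal_width", "equal_frequency"):
        for rule in rules:
            cfg = PipelineConfig(**{**asdict(config), "strategy": strategy, "rule": rule, "k": None})
            label_k = "dynamic" if rule in disc.DYNAMIC_RULES else disc.estimate_bins(rule, train[0].n_samples)
            try:
                res = run_pipeline(cfg, train, test)
                rows.append(
                    {
                        "rule": rule,
                        "strategy": strategy,
                        "k": label_k,
                        "accuracy": res.report.accuracy,
                        "precision": res.report.precision,
                        "n_genes": res.subset.l,
                    }
                )
            except BinsigError as exc:
                rows.append(
                    {"rule": rule, "strategy": strategy, "k": label_k,
                     "accuracy": np.nan, "precision": np.nan, "n_genes": 0, "note": str(exc)}
                )
    return pd.DataFrame(rows)


def _baseline_row(config, train, test) -> dict:
    """Continuous (undiscretized) benchmark: Pearson CFS + logistic on values."""
    from sklearn.linear_model import LogisticRegression

    train_expr, train_clin = train
    train_clin = train_clin.aligned_to(train_expr)
    y = train_clin.labels(config.task, config.horizon_months)
    try:
        norm, params = preprocess_cohort(train_expr, config)
        vals = norm.values.to_numpy(dtype=float)
        # CFS needs discrete features for SU; the baseline uses |pearson|
        subset = fs.cfs_select(
            norm.values.rank(axis=1).astype(int),  # placeholder ints; pearson uses raw_values
            y,
            threshold=config.merit_threshold,
            strategy=config.search,
            method="pearson",
            raw_values=vals,
        )
        if subset.l == 0:
            raise BinsigError("empty baseline subset")
        clf = LogisticRegression(
            C=1.0 / config.l2_strength, solver="liblinear", random_state=0
        )
        Xtr = norm.values.loc[subset.gene_ids].to_numpy(dtype=float).T
        clf.fit(Xtr, y)
        if test is not None:
            test_expr, test_clin = test
            test_clin = test_clin.aligned_to(test_expr)
            norm_te, _ = preprocess_cohort(test_expr, config, params=params)
            Xte = norm_te.values.loc[subset.gene_ids].to_numpy(dtype=float).T
            y_te = test_clin.labels(config.task, config.horizon_months)
        else:
            Xte, y_te = Xtr, y
        pred = clf.predict(Xte)
        rep = ev.confusion(pred, y_te)
        return {
            "rule": "without_discretization",
            "strategy": "none",
            "k": 0,
            "accuracy": rep.accuracy,
            "precision": rep.precision,
            "n_genes": subset.l,
        }
    except BinsigError as exc:
        return {"rule": "without_discretization", "strategy": "none", "k": 0,
                "accuracy": np.nan, "precision": np.nan, "n_genes": 0, "note": str(exc)}


def run_manifest(config: PipelineConfig, inputs: dict[str, str]) -> str:
    """Provenance record: config echo plus sha256 of each input file."""
    hashes = {}
    for name, path in inputs.items():
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(1 << 20), b""):
                h.update(chunk)
        hashes[name] = h.hexdigest()
    return json.dumps({"config": asdict(config), "inputs": hashes}, indent=2, sort_keys=True)
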