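import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import binsig as bs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def raw_matrix() -> bs.ExpressionMatrix:
    """4 genes x 5 samples raw matrix with one constant gene."""
    df = pd.DataFrame(
        {
            "s1": [0.0, 3.0, 2.0, 7.0],
            "s2": [1.0, 3.0, 4.0, 0.0],
            "s3": [7.0, 3.0, 6.0, 1.0],
            "s4": [3.0, 3.0, 0.0, 15.0],
            "s5": [0.0, 3.0, 8.0, 31.0],
        },
        index=["gA", "gB", "gC", "gD"],
    )
    return bs.ExpressionMatrix(df, scale="raw")


@pytest.fixture
def small_cohort():
    """Seeded synthetic cohort small enough for fast tests."""
    cfg = bs.CohortConfig(n_genes=80, n_informative=5, effect=0.5, seed=7)
    expr, clin, truth = bs.generate_cohort(cfg)
    return cfg, expr, clin, truth


@pytest.fixture
def minmax_values(raw_matrix):
    m = bs.log2_transform(raw_matrix)
    m = bs.ExpressionMatrix(m.values.drop(index="gB"), scale="log2")  # drop constant gene
    params = bs.minmax_fit(m)
    return bs.minmax_apply(m, params, clip=True)


def su_oracle(a, b) -> float:
    """Independent symmetric-uncertainty computation with plain loops."""
    a = list(a)
    b = list(b)
    n = len(a)

    def ent(xs):
        h = 0.0
        for v in set(xs):
            p = xs.count(v) / n
            h -= p * np.log2(p)
        return h

    ha, hb = ent(a), ent(b)
    if ha == 0 or hb == 0:
        return 0.0
    pairs = list(zip(a, b))
    hj = 0.0
    for v in set(pairs):
        p = pairs.count(v) / n
        hj -= p * np.log2(p)
    return 2.0 * (ha + hb - hj) / (ha + hb)


def merit_oracle(features, members, y) -> float:
    """Merit of a subset computed directly from the formula and su_oracle."""
    members = list(members)
    l = len(members)
    tc = sum(su_oracle(features[i], y) for i in members) / l
    if l > 1:
        pairs = [
            su_oracle(features[i], features[j])
            for ai, i in enumerate(members)
            for j in members[ai + 1 :]
        ]
        tf = sum(pairs) / len(pairs)
    else:
        tf = 0.0
    return l * tc / np.sqrt(l + l * (l - 1) * tf)
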