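import math

import numpy as np
import pandas as pd
import pytest

import binsig as bs
from binsig.discretize import DiscretizationScheme, DiscreteMatrix
from binsig.signature import (
    Interval,
    SignatureModel,
    SignatureTerm,
    fit_l2_logistic,
    sigmoid,
)


def _discrete(k, rows, genes=None, samples=None):
    genes = genes or [f"g{i}" for i in range(len(rows))]
    samples = samples or [f"s{j}" for j in range(len(rows[0]))]
    scheme = DiscretizationScheme(
        strategy="equal_width",
        edges={g: bs.equal_width_edges(k, 0.0, 1.0) for g in genes},
    )
    df = pd.DataFrame(rows, index=genes, columns=samples)
    return DiscreteMatrix(values=df, scheme=scheme)


class TestOneHot:
    def test_single_sample_single_indicator(self):
        dm = _discrete(5, [[2]])
        X = bs.one_hot_encode(dm)
        assert X.shape == (1, 5)
        assert X.iloc[0].sum() == 1
        assert X.iloc[0].to_numpy().argmax() == 2

    def test_column_count_sums_bin_counts(self):
        dm = _discrete(5, [[0, 1], [4, 2], [3, 3]])
        assert bs.one_hot_encode(dm).shape[1] == 15

    def test_argmax_round_trip(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 4, size=(3, 10))
        dm = _discrete(4, rows.tolist())
        X = bs.one_hot_encode(dm)
        for gi, g in enumerate(dm.gene_ids):
            cols = [c for c in X.columns if c.startswith(f"{g}:")]
            rec = X[cols].to_numpy().argmax(axis=1)
            assert (rec == rows[gi]).all()

    def test_column_naming_convention(self):
        dm = _discrete(5, [[0]], genes=["TP53"])
        cols = list(bs.one_hot_encode(dm).columns)
        assert cols[0] == "TP53:[0-0.2]"
        assert cols[1] == "TP53:(0.2-0.4]"
        assert cols[-1] == "TP53:(0.8-1]"


class TestTrainLogistic:
    def test_2x2_closed_form_at_vanishing_regularization(self):
        # 60/40 vs 40/60 split: log odds-ratio = ln(2.25)
        x = np.array([1] * 100 + [0] * 100)
        y = np.array([1] * 60 + [0] * 40 + [1] * 40 + [0] * 60)
        X = pd.DataFrame({"x": x})
        b0, w = fit_l2_logistic(X, y, l2_strength=1e-6)
        assert w.loc["x"] == pytest.approx(math.log(2.25), abs=1e-3)
        assert b0 == pytest.approx(math.log(40 / 60), abs=1e-3)

    def test_strong_regularization_shrinks_to_prior(self):
        rng = np.random.default_rng(0)
        y = np.array([1] * 30 + [0] * 10)
        X = pd.DataFrame({"a": rng.integers(0, 2, 40), "b": rng.integers(0, 2, 40)})
        b0, w = fit_l2_logistic(X, y, l2_strength=1e3)
        assert np.abs(w.to_numpy()).max() < 1e-2
        assert b0 == pytest.approx(math.log(3.0), abs=0.05)

    def test_separable_data_stays_finite_with_default_l2(self):
        dm = _discrete(2, [[0, 0, 0, 1, 1, 1]])
        y = [0, 0, 0, 1, 1, 1]
        model = bs.train_logistic(dm, y, merge_tol=1e-9)
        assert all(np.isfinite(t.weight) for t in model.terms)
        assert np.isfinite(model.intercept)

    def test_single_class_labels_rejected(self):
        dm = _discrete(2, [[0, 1, 0, 1]])
        with pytest.raises(bs.BinsigError, match="single class"):
            bs.train_logistic(dm, [1, 1, 1, 1])

    def test_deterministic_refit_identical(self):
        rng = np.random.default_rng(2)
        dm = _discrete(4, rng.integers(0, 4, size=(3, 60)).tolist())
        y = rng.integers(0, 2, 60)
        m1 = bs.train_logistic(dm, y)
        m2 = bs.train_logistic(dm, y)
        assert m1.to_json() == m2.to_json()

    def test_adjacent_near_equal_weights_merge_into_unions(self):
        # one gene whose top three bins behave identically -> one interval
        rng = np.random.default_rng(3)
        bins = rng.integers(0, 5, 300)
        y = (bins >= 2).astype(int)
        flips = rng.random(300) < 0.1
        y[flips] = 1 - y[flips]
        dm = _discrete(5, [bins.tolist()])
        model = bs.train_logistic(dm, y, merge_tol=0.2)
        gene_terms = [t for t in model.terms if t.gene == "g0"]
        assert len(gene_terms) < 5  # some bins merged
        covered = sum(iv.hi - iv.lo for t in gene_terms for iv in t.intervals)
        assert covered == pytest.approx(1.0, abs=1e-9)

    def test_planted_bin_sign_recovery(self):
        """A class-enriched bin earns a positive weight in >=95% of replicates."""
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(rep)
            n = 150
            y = rng.integers(0, 2, n)
            bins = rng.integers(0, 5, n)
            # plant: class-1 samples moved into bin 4 with prob 0.5
            moved = (y == 1) & (rng.random(n) < 0.5)
            bins[moved] = 4
            dm = _discrete(5, [bins.tolist()])
            model = bs.train_logistic(dm, y, merge_tol=1e-9)
            w4 = [t.weight for t in model.terms if t.intervals[0].lo == pytest.approx(0.8)]
            if w4 and w4[0] > 0:
                hits += 1
        assert hits >= 95


class TestScoring:
    def test_probability_is_sigmoid_and_flips_at_zero(self):
        assert sigmoid(0.0) == 0.5
        m = SignatureModel(task="status", intercept=0.0, terms=[])
        assert m.score({}).predicted_class == 1  # p = 0.5 >= 0.5
        m_neg = SignatureModel(task="status", intercept=-1e-9, terms=[])
        assert m_neg.score({}).predicted_class == 0

    def test_matched_negative_weight_never_increases_probability(self):
        base = SignatureModel(task="status", intercept=0.8, terms=[])
        with_term = SignatureModel(
            task="status",
            intercept=0.8,
            terms=[SignatureTerm("g", [Interval(0.4, 1.0)], -0.9)],
        )
        assert with_term.score({"g": 0.7}).probability < base.score({}).probability

    def test_missing_gene_listed_in_error(self):
        model = bs.load_printed_signature()
        with pytest.raises(bs.BinsigError, match="ZFHX3"):
            model.score({"EMP2": 0.5})

    def test_psa_term_applies_below_threshold(self):
        model = SignatureModel(task="early_bcr", intercept=0.0, terms=[], psa_term=(0.38, 1.2))
        lo = model.score({}, psa=0.2)
        hi = model.score({}, psa=2.0)
        assert lo.final_score == pytest.approx(1.2)
        assert hi.final_score == pytest.approx(0.0)
        with pytest.raises(bs.BinsigError, match="psa"):
            model.score({})


class TestPrintedSignature:
    def test_ten_gene_terms_with_fifth_width_bounds(self):
        model = bs.load_printed_signature()
        assert len(model.terms) == 10
        assert model.intercept == 1.5
        for t in model.terms:
            for iv in t.intervals:
                assert round(iv.lo * 5, 9) == int(iv.lo * 5)
                assert round(iv.hi * 5, 9) == int(iv.hi * 5)

    def test_no_interval_profile_scores_intercept(self):
        model = bs.load_printed_signature()
        profile = {g: 0.5 for g in model.gene_ids}
        profile["RGS2"] = 0.1
        profile["AIDA"] = 0.1
        pred = model.score(profile)
        assert pred.final_score == pytest.approx(1.5, abs=1e-12)
        assert pred.probability == pytest.approx(1 / (1 + math.exp(-1.5)), abs=1e-9)

    def test_wdr5_rgs2_profile_hand_sum(self):
        model = bs.load_printed_signature()
        profile = {g: 0.5 for g in model.gene_ids}
        profile.update({"RGS2": 0.5, "WDR5": 0.9, "AIDA": 0.1})
        pred = model.score(profile)
        assert pred.final_score == pytest.approx(1.5 - 1.15 - 1.06, abs=1e-12)
        assert pred.probability == pytest.approx(1 / (1 + math.exp(0.71)), abs=1e-9)

    def test_serialization_round_trips_bit_exactly(self):
        model = bs.load_printed_signature()
        back = SignatureModel.from_json(model.to_json())
        assert back.to_json() == model.to_json()
        assert back.score({g: 0.85 for g in model.gene_ids}).final_score == pytest.approx(
            model.score({g: 0.85 for g in model.gene_ids}).final_score, abs=0
        )
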