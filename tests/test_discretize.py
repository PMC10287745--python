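import itertools
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

import binsig as bs
from binsig.discretize import STATIC_RULES, DiscretizationScheme


def equal_frequency_oracle(k, values):
    """Enumerate every placement of k-1 cuts at midpoints between distinct
    sorted values; return the edge set minimising the summed absolute
    deviation of bin occupancies from n/k (ties: first in enumeration)."""
    values = np.sort(np.asarray(values, dtype=float))
    n = len(values)
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2
    n_cuts = min(k - 1, len(mids))
    best, best_dev = None, np.inf
    for combo in itertools.combinations(range(len(mids)), n_cuts):
        edges = mids[list(combo)]
        bins = np.searchsorted(edges, values, side="left")
        occ = np.bincount(bins, minlength=n_cuts + 1)
        dev = np.abs(occ - n / k).sum()
        if dev < best_dev - 1e-12:
            best, best_dev = edges, dev
    return best, best_dev


class TestEstimateBins:
    @pytest.mark.parametrize(
        "rule,expected",
        [
            ("sqrt", 12),
            ("cencov", 5),
            ("rice", 10),
            ("terrell_scott", 6),
            ("sturges", 8),
            ("brooks_carruthers", 11),
        ],
    )
    def test_static_rules_at_n143(self, rule, expected):
        assert bs.estimate_bins(rule, 143) == expected

    def test_sturges_single_observation(self):
        assert bs.estimate_bins("sturges", 1) == 1

    def test_result_at_least_one(self):
        for rule in STATIC_RULES:
            assert bs.estimate_bins(rule, 1) >= 1

    def test_dynamic_rules_per_attribute(self):
        stats = {
            "R": pd.Series({"g1": 1.0, "g2": 2.0}),
            "iqr": pd.Series({"g1": 0.25, "g2": 0.5}),
            "sigma": pd.Series({"g1": 0.2, "g2": 0.3}),
        }
        ks = bs.estimate_bins("freedman_diaconis", 64, stats=stats)
        # k = R / (2*IQR*64^(-1/3)) = R / (2*IQR/4)
        assert ks.loc["g1"] == int(np.ceil(1.0 / (2 * 0.25 / 4)))
        assert ks.loc["g2"] == int(np.ceil(2.0 / (2 * 0.5 / 4)))
        ks2 = bs.estimate_bins("scott", 64, stats=stats)
        assert ks2.loc["g1"] == int(np.ceil(1.0 / (3.49 * 0.2 / 4)))

    def test_zero_spread_falls_back_with_warning(self):
        stats = {
            "R": pd.Series({"g1": 1.0}),
            "iqr": pd.Series({"g1": 0.0}),
            "sigma": pd.Series({"g1": 0.0}),
        }
        with pytest.warns(UserWarning, match="fell back"):
            ks = bs.estimate_bins("freedman_diaconis", 100, stats=stats, fallback_k=7)
        assert ks.loc["g1"] == 7

    def test_unknown_rule_rejected(self):
        with pytest.raises(bs.BinsigError, match="unknown bin rule"):
            bs.estimate_bins("doane", 100)


class TestEqualWidth:
    def test_five_bins_on_unit_interval(self):
        edges = bs.equal_width_edges(5, 0.0, 1.0)
        np.testing.assert_allclose(edges, [0.2, 0.4, 0.6, 0.8], atol=1e-15)

    def test_single_bin_no_edges(self):
        assert bs.equal_width_edges(1, 0.0, 1.0).size == 0

    def test_plain_arithmetic(self):
        np.testing.assert_allclose(bs.equal_width_edges(4, 0, 8), [2, 4, 6])

    def test_degenerate_range_rejected(self):
        with pytest.raises(bs.BinsigError, match="degenerate"):
            bs.equal_width_edges(3, 1.0, 1.0)

    @given(st.integers(1, 20))
    def test_all_widths_exactly_one_over_k(self, k):
        edges = np.concatenate([[0.0], bs.equal_width_edges(k, 0.0, 1.0), [1.0]])
        np.testing.assert_allclose(np.diff(edges), 1.0 / k, atol=1e-12)


class TestEqualFrequency:
    def test_ten_distinct_k5_two_per_bin(self):
        vals = np.arange(10, dtype=float)
        edges = bs.equal_frequency_edges(5, vals)
        occ = np.bincount(np.searchsorted(edges, vals, side="left"))
        assert occ.tolist() == [2, 2, 2, 2, 2]

    def test_median_split(self):
        edges = bs.equal_frequency_edges(2, np.arange(1, 9, dtype=float))
        assert len(edges) == 1 and 4 < edges[0] < 5
        occ = np.bincount(np.searchsorted(edges, np.arange(1, 9), side="left"))
        assert occ.tolist() == [4, 4]

    @pytest.mark.parametrize(
        "vals,k",
        [
            ([1, 1, 1, 1, 2, 3], 3),
            ([1, 1, 2, 2, 2, 3, 3, 4], 4),
            ([5, 5, 5, 1, 1, 9], 3),
            ([1, 2, 2, 2, 2, 2, 3, 4], 3),
        ],
    )
    def test_tied_vectors_match_enumeration_oracle(self, vals, k):
        edges = bs.equal_frequency_edges(k, vals)
        _, best_dev = equal_frequency_oracle(k, vals)
        vals_sorted = np.sort(np.asarray(vals, dtype=float))
        occ = np.bincount(np.searchsorted(edges, vals_sorted, side="left"), minlength=len(edges) + 1)
        dev = np.abs(occ - len(vals) / k).sum()
        assert dev == pytest.approx(best_dev)

    def test_all_identical_rejected(self):
        with pytest.raises(bs.BinsigError, match="identical"):
            bs.equal_frequency_edges(2, [3.0, 3.0, 3.0])

    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=30, unique=True), st.integers(2, 6))
    def test_occupancy_spread_at_most_one_on_distinct(self, vals, k):
        assume(len(vals) >= k)
        edges = bs.equal_frequency_edges(k, vals)
        occ = np.bincount(
            np.searchsorted(edges, np.asarray(vals), side="left"), minlength=len(edges) + 1
        )
        assert occ.max() - occ.min() <= 1


class TestApplySchemeAndRoundTrip:
    def _scheme(self, k=5):
        return DiscretizationScheme(
            strategy="equal_width", edges={"g": bs.equal_width_edges(k, 0.0, 1.0)}, rule=None
        )

    def _matrix(self, vals):
        df = pd.DataFrame([vals], index=["g"], columns=[f"s{i}" for i in range(len(vals))])
        return bs.ExpressionMatrix(df, scale="minmax")

    def test_right_closed_convention_and_clamp(self):
        scheme = self._scheme()
        m = bs.ExpressionMatrix(
            pd.DataFrame([[0.2, 0.2000001, 0.0, 1.0]], index=["g"], columns=list("abcd")).clip(0, 1),
            scale="minmax",
        )
        dm = bs.apply_scheme(m, scheme)
        assert dm.values.loc["g"].tolist() == [0, 1, 0, 4]

    def test_out_of_range_clamps_to_extreme_bins(self):
        scheme = self._scheme()
        # unclipped test data can fall outside the training range
        df = pd.DataFrame([[1.3, -0.2]], index=["g"], columns=["a", "b"])
        dm = bs.apply_scheme(bs.ExpressionMatrix(df, scale="minmax"), scheme)
        assert dm.values.loc["g"].tolist() == [4, 0]

    def test_unknown_gene_errors(self):
        scheme = self._scheme()
        with pytest.raises(bs.BinsigError, match="gX"):
            bs.apply_scheme(
                bs.ExpressionMatrix(
                    pd.DataFrame([[0.5]], index=["gX"], columns=["a"]), scale="minmax"
                ),
                scheme,
            )

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20), st.integers(1, 8))
    def test_monotonicity(self, vals, k):
        scheme = self._scheme(k)
        dm = bs.apply_scheme(self._matrix(vals), scheme)
        bins = dm.values.loc["g"].to_numpy()
        order = np.argsort(vals, kind="stable")
        assert (np.diff(bins[order]) >= 0).all()

    def test_scheme_json_round_trip_bit_exact(self, minmax_values):
        scheme = bs.fit_scheme(minmax_values, strategy="equal_frequency", rule="sturges")
        back = DiscretizationScheme.from_json(scheme.to_json())
        assert back.strategy == scheme.strategy
        assert back.rule == scheme.rule
        for g in scheme.gene_ids:
            assert back.edges[g].tolist() == scheme.edges[g].tolist()
        assert back.to_json() == scheme.to_json()

    def test_fit_scheme_fixed_k_equal_width_on_minmax(self, minmax_values):
        scheme = bs.fit_scheme(minmax_values, strategy="equal_width", k=5)
        for g in scheme.gene_ids:
            np.testing.assert_allclose(scheme.edges[g], [0.2, 0.4, 0.6, 0.8], atol=1e-15)
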