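"""Mutual-information estimation and JMIM ranking against exhaustive oracles."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datscreen.mi_selection import (
    discretize,
    jmim_rank,
    joint_mutual_information,
    mutual_information,
)


def mi_oracle(x, y):
    """Plug-in MI by direct summation over observed cells (bits)."""
    n = len(x)
    cxy = Counter(zip(x, y))
    cx = Counter(x)
    cy = Counter(y)
    return sum(
        (c / n) * math.log2((c / n) / ((cx[a] / n) * (cy[b] / n)))
        for (a, b), c in cxy.items()
    )


def entropy(x):
    n = len(x)
    return -sum((c / n) * math.log2(c / n) for c in Counter(x).values())


def jmim_oracle(table, y, k):
    """Exhaustive greedy JMIM re-evaluation using the oracle MI."""
    feats = list(table.columns)
    coded = {f: tuple(table[f]) for f in feats}
    pairs = {}

    def jmi(f, s):
        key = (f, s)
        if key not in pairs:
            pairs[key] = mi_oracle(list(zip(coded[f], coded[s])), y)
        return pairs[key]

    first = max(feats, key=lambda f: mi_oracle(coded[f], y))
    sel = [first]
    vals = [mi_oracle(coded[first], y)]
    while len(sel) < k:
        rest = [f for f in feats if f not in sel]
        best, bv = None, -np.inf
        for f in rest:
            v = min(jmi(f, s) for s in sel)
            if v > bv:
                best, bv = f, v
        sel.append(best)
        vals.append(bv)
    return sel, vals


class TestDiscretize:
    def test_two_bins(self):
        assert list(discretize([1, 2, 3, 4], 2)) == [0, 0, 1, 1]

    def test_constant(self):
        assert list(discretize([7, 7, 7], 3)) == [0, 0, 0]

    def test_three_bins_rank_binning(self):
        assert list(discretize([5, 1, 3, 2, 4, 6], 3)) == [2, 0, 1, 0, 1, 2]

    def test_too_few_bins(self):
        with pytest.raises(ValueError, match="n_bins"):
            discretize([1, 2], 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-100, 100), min_size=2, max_size=60),
        st.integers(2, 6),
    )
    def test_monotone_and_tied(self, values, n_bins):
        codes = discretize(values, n_bins)
        order = np.argsort(values, kind="stable")
        assert (np.diff(codes[order]) >= 0).all()
        for v, c in zip(values, codes):
            same = [ci for vi, ci in zip(values, codes) if vi == v]
            assert all(ci == c for ci in same)


class TestMutualInformation:
    def test_identical_balanced_binary(self):
        x = [0, 1] * 10
        assert mutual_information(x, x) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        assert mutual_information([3] * 8, [0, 1] * 4) == 0

    def test_hand_computed_2x2(self):
        # joint counts [[2,1],[1,2]]
        x = [0, 0, 0, 1, 1, 1]
        y = [0, 0, 1, 0, 1, 1]
        expected = (2 / 3) * math.log2(4 / 3) + (1 / 3) * math.log2(2 / 3)
        assert mutual_information(x, y) == pytest.approx(expected)
        assert expected == pytest.approx(0.0817, abs=5e-4)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_symmetry_and_bounds(self, data):
        n = data.draw(st.integers(2, 80))
        x = data.draw(st.lists(st.integers(0, 3), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        mi = mutual_information(x, y)
        assert mi == pytest.approx(mi_oracle(x, y))
        assert mi == pytest.approx(mutual_information(y, x))
        assert -1e-12 <= mi <= min(entropy(x), entropy(y)) + 1e-12
        assert mutual_information(x, x) == pytest.approx(entropy(x))


class TestJointMutualInformation:
    def test_xor_synergy(self):
        rng = np.random.default_rng(0)
        x1 = rng.integers(0, 2, 400)
        x2 = rng.integers(0, 2, 400)
        y = x1 ^ x2
        assert mutual_information(x1, y) < 0.02
        assert joint_mutual_information(x1, x2, y) == pytest.approx(1.0, abs=0.02)

    def test_constant_partner_reduces_to_marginal(self):
        x = [0, 1, 2, 0, 1, 2]
        y = [0, 1, 1, 0, 1, 1]
        assert joint_mutual_information(x, [5] * 6, y) == pytest.approx(
            mutual_information(x, y)
        )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_exhaustive_summation_oracle(self, data):
        n = data.draw(st.integers(3, 60))
        xi = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        xj = data.draw(st.lists(st.integers(0, 2), min_size=n, max_size=n))
        y = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        got = joint_mutual_information(xi, xj, y)
        assert got == pytest.approx(mi_oracle(list(zip(xi, xj)), y))
        assert got >= max(mi_oracle(xi, y), mi_oracle(xj, y)) - 1e-12


class TestJMIMRank:
    def test_exact_label_feature_first(self):
        rng = np.random.default_rng(1)
        y = np.array(["CP", "CN"] * 30)
        table = pd.DataFrame(
            {
                "a": (y == "CP").astype(float),
                "b": rng.normal(size=60),
                "c": rng.normal(size=60),
            }
        )
        r = jmim_rank(table, y, n_bins=2)
        assert r.ordered_features[0] == "a"
        assert r.criterion_values[0] == pytest.approx(1.0)

    def test_xor_pair_completed(self):
        rng = np.random.default_rng(2)
        x1 = rng.integers(0, 2, 400)
        x2 = rng.integers(0, 2, 400)
        y = np.where(x1 ^ x2 == 1, "CP", "CN")
        # bias x1 first via a tiny marginal signal, then x2 must follow
        table = pd.DataFrame({"x1": x1, "x2": x2, "noise": rng.normal(size=400)})
        r = jmim_rank(table, y, discrete_features=("x1", "x2"), n_bins=2)
        assert set(r.ordered_features[:2]) == {"x1", "x2"}
        assert r.criterion_values[1] == pytest.approx(1.0, abs=0.02)

    def test_degenerate_labels(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="degenerate labels"):
            jmim_rank(table, ["CP", "CP", "CP"])

    def test_row_permutation_invariance(self, default_cohort):
        from datscreen.epoch_features import MODEL_FEATURES

        table = default_cohort[list(MODEL_FEATURES)]
        y = default_cohort["label"].to_numpy()
        r1 = jmim_rank(table, y)
        perm = np.random.default_rng(3).permutation(len(table))
        r2 = jmim_rank(table.iloc[perm].reset_index(drop=True), y[perm])
        assert r1.ordered_features == r2.ordered_features
        assert np.allclose(r1.criterion_values, r2.criterion_values)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_exhaustive_oracle(self, data):
        n = data.draw(st.integers(10, 120))
        n_feat = data.draw(st.integers(2, 6))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        table = pd.DataFrame(
            {f"f{i}": rng.integers(0, 3, n) for i in range(n_feat)}
        )
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        got = jmim_rank(table, y, discrete_features=tuple(table.columns))
        exp_order, exp_vals = jmim_oracle(table, list(y), k=n_feat)
        assert got.ordered_features == exp_order
        assert np.allclose(got.criterion_values, exp_vals)
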