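"""Exact-test engine vs independent enumeration oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import hypergeom

from phenokit.exact_tests import (
    ContingencyTable,
    _freeman_halton_enumerate,
    _freeman_halton_monte_carlo,
    build_count_table,
    fisher_exact,
    proportion_effect,
)

from conftest import make_phenlist


def oracle_2x2(a, b, c, d):
    """Brute-force hypergeometric enumeration, probability-ordering rule."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = hypergeom.pmf(ks, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def oracle_rxc(counts):
    """Independent Freeman–Halton oracle: itertools over all tables."""
    counts = np.asarray(counts)
    row_margins = counts.sum(axis=1)
    col_margins = counts.sum(axis=0)
    from math import factorial

    def prob(t):
        num = 1.0
        for r in row_margins:
            num *= factorial(r)
        for c in col_margins:
            num *= factorial(c)
        den = float(factorial(counts.sum()))
        for v in np.asarray(t).ravel():
            den *= factorial(int(v))
        return num / den

    p_obs = prob(counts)
    total = 0.0
    nrow, ncol = counts.shape
    ranges = [range(min(row_margins[i], col_margins[j]) + 1)
              for i in range(nrow - 1) for j in range(ncol - 1)]
    for cells in itertools.product(*ranges):
        t = np.zeros((nrow, ncol), dtype=int)
        t[: nrow - 1, : ncol - 1] = np.reshape(cells, (nrow - 1, ncol - 1))
        t[: nrow - 1, ncol - 1] = row_margins[: nrow - 1] - t[: nrow - 1, : ncol - 1].sum(axis=1)
        t[nrow - 1] = col_margins - t[: nrow - 1].sum(axis=0)
        if (t < 0).any():
            continue
        pt = prob(t)
        if pt <= p_obs * (1 + 1e-7):
            total += pt
    return total


class TestContingencyTable:
    def test_margins(self):
        t = ContingencyTable(("control", "mutant"), ("Low", "rest"), np.array([[2, 50], [6, 14]]))
        assert t.row_margins.tolist() == [52, 20]
        assert t.col_margins.tolist() == [8, 64]
        assert t.total == 72

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a", "b"), ("x", "y"), np.array([[1, -1], [0, 2]]))

    def test_minimum_shape(self):
        with pytest.raises(ValueError):
            ContingencyTable(("a",), ("x", "y"), np.array([[1, 2]]))


class TestBuildCountTable:
    ROWS = (
        [{"Genotype": "control", "Sex": "female", "skull": "Low"}] * 2
        + [{"Genotype": "control", "Sex": "female", "skull": "Normal"}] * 48
        + [{"Genotype": "control", "Sex": "female", "skull": "High"}] * 2
        + [{"Genotype": "mutant", "Sex": "female", "skull": "Low"}] * 6
        + [{"Genotype": "mutant", "Sex": "female", "skull": "Normal"}] * 14
    )

    def test_classified_counts_match_tally(self):
        pl = make_phenlist(self.ROWS)
        t = build_count_table(pl, "skull", subset="female")
        assert t.row_labels == ("control", "mutant")
        frame = t.to_frame()
        assert frame.loc["control", "Low"] == 2
        assert frame.loc["control", "Normal"] == 48
        assert frame.loc["control", "High"] == 2
        assert frame.loc["mutant", "Low"] == 6
        assert frame.loc["mutant", "High"] == 0

    def test_single_animal_per_cell(self):
        rows = [
            {"Genotype": "control", "Sex": "male", "v": "normal"},
            {"Genotype": "mutant", "Sex": "male", "v": "abnormal"},
        ]
        t = build_count_table(make_phenlist(rows), "v", subset="all")
        assert t.counts.sum() == 2
        assert t.counts.max() == 1

    def test_missing_values_excluded(self):
        rows = self.ROWS + [{"Genotype": "mutant", "Sex": "female", "skull": None}]
        t = build_count_table(make_phenlist(rows), "skull", subset="female")
        assert t.counts.sum() == len(self.ROWS)


class TestFisherExact2x2:
    def test_worked_low_tail_table(self):
        # female Low-vs-rest table: highly significant depletion toward Low
        p = fisher_exact(np.array([[2, 50], [6, 14]]))
        assert p == pytest.approx(4.64e-3, rel=0.05)

    def test_identical_proportions_give_p_one(self):
        assert fisher_exact(np.array([[5, 5], [5, 5]])) == 1.0

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning):
            assert fisher_exact(np.array([[0, 0], [3, 4]])) == 1.0

    @pytest.mark.parametrize(
        "table",
        [[[1, 9], [8, 2]], [[0, 12], [5, 5]], [[3, 3], [3, 3]], [[12, 0], [0, 12]]],
    )
    def test_agrees_with_enumeration_oracle(self, table):
        a, b = table[0]
        c, d = table[1]
        assert fisher_exact(np.array(table)) == pytest.approx(oracle_2x2(a, b, c, d), abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(0, 10), st.integers(0, 10), st.integers(0, 10), st.integers(0, 10))
    def test_row_swap_symmetry(self, a, b, c, d):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            return
        t1 = np.array([[a, b], [c, d]])
        t2 = t1[::-1].copy()
        assert fisher_exact(t1) == pytest.approx(fisher_exact(t2), abs=1e-12)
        e1 = proportion_effect(t1)
        e2 = proportion_effect(t2)
        assert e1 == pytest.approx(-e2, abs=1e-12)

    def test_monotone_in_extremity_with_fixed_margins(self):
        # slide along the hypergeometric axis away from expectation
        r1, r2, c1 = 10, 10, 8
        expect = r1 * c1 / (r1 + r2)
        ps = []
        for a in range(int(np.ceil(expect)), min(r1, c1) + 1):
            ps.append(fisher_exact(np.array([[a, r1 - a], [c1 - a, r2 - (c1 - a)]])))
        assert all(ps[i] >= ps[i + 1] - 1e-12 for i in range(len(ps) - 1))


class TestFreemanHalton:
    @pytest.mark.parametrize(
        "table",
        [
            [[3, 1, 2], [1, 4, 1], [2, 2, 3]],
            [[5, 0], [1, 3], [2, 2]],
            [[1, 2, 3], [3, 2, 1]],
        ],
    )
    def test_enumeration_matches_independent_oracle(self, table):
        counts = np.array(table)
        assert _freeman_halton_enumerate(counts) == pytest.approx(oracle_rxc(counts), abs=1e-10)

    def test_rxc_reduces_to_2x2_convention(self):
        t = np.array([[2, 50], [6, 14]])
        assert _freeman_halton_enumerate(t) == pytest.approx(fisher_exact(t), abs=1e-9)

    def test_monte_carlo_reproducible_and_near_exact(self):
        counts = np.array([[8, 3, 4], [2, 9, 5], [5, 4, 8]])
        exact = _freeman_halton_enumerate(counts)
        draws = 100_000
        mc1 = _freeman_halton_monte_carlo(counts, draws, seed=42)
        mc2 = _freeman_halton_monte_carlo(counts, draws, seed=42)
        assert mc1 == mc2  # same seed, identical estimate
        se = np.sqrt(exact * (1 - exact) / draws)
        assert abs(mc1 - exact) < 3 * se + 2 / draws


class TestProportionEffect:
    def test_worked_penetrance_change(self):
        e = proportion_effect(np.array([[2, 50], [6, 14]]), focal_col=0)
        assert round(100 * e) == 26

    def test_equal_proportions_zero(self):
        assert proportion_effect(np.array([[3, 9], [1, 3]])) == pytest.approx(0.0)

    def test_extreme_difference_is_plus_100(self):
        assert proportion_effect(np.array([[0, 10], [10, 0]]), focal_col=0) == pytest.approx(1.0)

    def test_empty_genotype_undefined(self):
        assert proportion_effect(np.array([[0, 0], [5, 5]])) is None
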