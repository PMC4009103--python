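"""Hypergeometric upper-tail p and BH FDR against independent oracles.

The enumeration oracle counts, over every size-n subset of an N-element
universe with K marked elements, the fraction with at least k marked members
— the definition of the upper-tail probability, computed without any
distribution function.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from deltameth.enrichment import bh_adjust, enrich, hypergeom_upper_tail


def enumeration_upper_tail(N, K, n, k):
    """Exact P(overlap >= k) by exhaustive subset enumeration."""
    marked = set(range(K))
    hits = sum(
        1 for subset in combinations(range(N), n)
        if len(marked.intersection(subset)) >= k
    )
    from math import comb

    return Fraction(hits, comb(N, n))


class TestHypergeomUpperTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_upper_tail(100, 10, 20, 0) == 1.0

    def test_worked_example(self):
        assert hypergeom_upper_tail(10, 4, 5, 3) == pytest.approx(
            66 / 252, rel=1e-12
        )

    def test_fully_degenerate(self):
        assert hypergeom_upper_tail(5, 5, 5, 5) == 1.0

    def test_matches_enumeration_on_small_grid(self):
        # spot-checked here; the full N<=12 sweep runs in the acceptance suite
        for N in (6, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(K, n) + 1):
                        expected = float(enumeration_upper_tail(N, K, n, k))
                        got = hypergeom_upper_tail(N, K, n, k)
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)

    @given(
        st.integers(1, 60).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        ),
        st.data(),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_scipy_survival_function(self, Nkn, data):
        N, K, n = Nkn
        lo = max(0, n + K - N)
        k = data.draw(st.integers(lo, min(K, n)))
        expected = float(stats.hypergeom.sf(k - 1, N, K, n))
        assert hypergeom_upper_tail(N, K, n, k) == pytest.approx(
            expected, rel=1e-9, abs=1e-14
        )

    def test_p_decreases_as_universe_grows(self):
        # fixed K, n, k: a bigger universe makes the observed overlap rarer
        ps = [hypergeom_upper_tail(N, 10, 10, 4) for N in range(25, 200, 25)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    @pytest.mark.parametrize("args", [(10, 11, 5, 0), (10, 4, 5, 5), (10, 4, 11, 0)])
    def test_inconsistent_counts_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(*args)


class TestBhAdjust:
    def test_hand_computed_example(self):
        # step-up: 3*0.01/1=0.03, 3*0.02/2=0.03, 3*0.03/3=0.03
        assert list(bh_adjust([0.01, 0.02, 0.03])) == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.42])[0] == 0.42
        assert list(bh_adjust([1.0, 1.0, 1.0])) == [1.0, 1.0, 1.0]

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_statsmodels_and_is_monotone(self, p_values):
        adjusted = bh_adjust(p_values)
        _, expected, _, _ = multipletests(p_values, method="fdr_bh")
        assert np.allclose(adjusted, expected, atol=1e-12)
        order = np.argsort(p_values, kind="stable")
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    @pytest.mark.parametrize("level", [0.01, 0.05, 0.1])
    def test_thresholding_adjusted_p_equals_step_up_procedure(self, level):
        # the defining property of BH adjusted p-values: adjusted <= alpha
        # iff the raw p is rejected by the step-up procedure at alpha
        rng = np.random.default_rng(4)
        p = np.concatenate([rng.uniform(0, 0.02, 5), rng.uniform(0, 1, 20)])
        adjusted = bh_adjust(p)
        m = len(p)
        order = np.argsort(p, kind="stable")
        below = np.flatnonzero(p[order] <= level * np.arange(1, m + 1) / m)
        rejected_raw = np.zeros(m, bool)
        if below.size:
            rejected_raw[order[: below.max() + 1]] = True
        assert ((adjusted <= level) == rejected_raw).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEnrich:
    universe = [f"G{i}" for i in range(40)]

    def test_selected_equals_universe_gives_p_one(self):
        terms = {"T1": ("d", self.universe[:10]), "T2": ("d", self.universe[5:20])}
        rows, significant = enrich(self.universe, terms, self.universe)
        assert all(r.p_value == 1.0 for r in rows)
        assert significant == []

    def test_planted_term_has_smallest_p(self):
        selected = self.universe[:6]
        terms = {
            "PLANTED": ("planted", selected),
            "RANDOM1": ("r", self.universe[10:25]),
            "RANDOM2": ("r", self.universe[3:30]),
        }
        rows, significant = enrich(selected, terms, self.universe)
        assert rows[0].term_id == "PLANTED"
        assert rows[0].overlap == 6
        assert rows[0].p_value == min(r.p_value for r in rows)
        assert significant and significant[0].term_id == "PLANTED"

    def test_zero_overlap_terms_counted_in_family_but_not_output(self):
        selected = self.universe[:4]
        terms = {
            "HIT": ("d", self.universe[:4]),
            "MISS": ("d", self.universe[30:35]),
        }
        rows, _ = enrich(selected, terms, self.universe)
        assert [r.term_id for r in rows] == ["HIT"]
        # m = 2 tested terms, so FDR = min(1, 2 * p / 1)
        assert rows[0].fdr_adjusted_p == pytest.approx(
            min(1.0, 2 * rows[0].p_value)
        )

    def test_terms_intersected_with_universe(self):
        terms = {"T": ("d", ["G0", "G1", "NOT_ON_ARRAY"])}
        rows, _ = enrich(["G0"], terms, self.universe)
        assert rows[0].term_size == 2

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            enrich(["MISSING"], {"T": ("d", ["G0"])}, self.universe)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            enrich([], {"T": ("d", ["G0"])}, [])
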