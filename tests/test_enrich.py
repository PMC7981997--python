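"""Hypergeometric tails, EASE, BH-FDR and planted-term enrichment."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npharm import enrich
from npharm.enrich import AnnotationTerm


def oracle_upper_tail(N, K, n, k):
    """Exact P(X >= k) as a rational number from the counting formula."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), total)
    return float(acc)


class TestHypergeomTail:
    def test_certain_event(self):
        assert enrich.hypergeom_upper_tail(100, 10, 20, 0) == 1.0

    def test_term_equals_universe(self):
        for k in range(0, 6):
            assert enrich.hypergeom_upper_tail(20, 20, 5, k) == pytest.approx(1.0)

    def test_counting_formula_worked_example(self):
        expected = math.comb(5, 5) * math.comb(15, 5) / math.comb(20, 10)
        assert enrich.hypergeom_upper_tail(20, 5, 10, 5) == pytest.approx(expected)

    def test_exhaustive_small_universe(self):
        """Tail matches the exact rational enumeration for every
        configuration with N <= 12, and a seeded sample up to N = 20."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert enrich.hypergeom_upper_tail(
                            N, K, n, k
                        ) == pytest.approx(oracle_upper_tail(N, K, n, k))
        rng = np.random.default_rng(0)
        for _ in range(300):
            N = int(rng.integers(13, 21))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            assert enrich.hypergeom_upper_tail(N, K, n, k) == pytest.approx(
                oracle_upper_tail(N, K, n, k)
            )

    def test_pmf_sums_to_one_for_small_universes(self):
        """Successive tail differences form a distribution over attainable k."""
        for N in range(1, 21):
            K, n = N // 2, (N + 1) // 2
            lo, hi = max(0, n - (N - K)), min(K, n)
            pmf = [
                enrich.hypergeom_upper_tail(N, K, n, k)
                - (enrich.hypergeom_upper_tail(N, K, n, k + 1) if k < hi else 0.0)
                for k in range(lo, hi + 1)
            ]
            assert sum(pmf) == pytest.approx(1.0)
            assert all(p >= -1e-12 for p in pmf)

    def test_bound_violations_named(self):
        with pytest.raises(ValueError, match="K <= N"):
            enrich.hypergeom_upper_tail(10, 11, 5, 2)
        with pytest.raises(ValueError, match="k <= min"):
            enrich.hypergeom_upper_tail(10, 3, 5, 4)


class TestEase:
    def test_trivial_values(self):
        assert enrich.ease_p(100, 10, 20, 1) == 1.0
        assert enrich.ease_p(100, 10, 20, 0) == 1.0

    @settings(max_examples=200, deadline=None)
    @given(st.data())
    def test_always_at_least_plain_tail(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert enrich.ease_p(N, K, n, k) >= enrich.hypergeom_upper_tail(N, K, n, k)


def oracle_bh(pvalues):
    """Step-up adjustment evaluated directly: min over the tail of p_(j)m/j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    for rank, i in enumerate(order, start=1):
        adjusted[i] = min(
            min(pvalues[j] * m / (1 + order.index(j)) for j in order[rank - 1:]),
            1.0,
        )
    return adjusted


class TestBH:
    def test_all_equal(self):
        assert enrich.bh_fdr([0.3, 0.3, 0.3]) == pytest.approx([0.3, 0.3, 0.3])

    def test_single_p_unchanged(self):
        assert enrich.bh_fdr([0.042]) == pytest.approx([0.042])

    def test_step_up_formula_worked_example(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert enrich.bh_fdr(p) == pytest.approx(oracle_bh(p))
        assert enrich.bh_fdr(p) == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 15)).tolist()
            assert enrich.bh_fdr(p) == pytest.approx(oracle_bh(p))

    def test_pointwise_dominates_and_preserves_order(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-6, 1.0, size=40)
        adj = enrich.bh_fdr(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [float("nan")]):
            with pytest.raises(ValueError):
                enrich.bh_fdr(bad)


def make_term(tid, members, category="KEGG"):
    return AnnotationTerm(tid, tid, category, frozenset(members))


class TestEnrich:
    def test_perfect_overlap_is_minimal_p(self):
        term = make_term("t1", [f"G{i}" for i in range(10)])
        universe = set(term.members) | {f"D{i}" for i in range(100)}
        result = enrich.enrich(term.members, [term], universe=universe)
        row = result.iloc[0]
        assert row["k"] == row["K"] == 10
        assert row["rich_factor"] == 1.0
        assert row["p_value"] == pytest.approx(
            oracle_upper_tail(110, 10, 10, 10)
        )

    def test_disjoint_query_all_p_one(self):
        terms = [make_term(f"t{i}", [f"G{i}_{j}" for j in range(5)]) for i in range(4)]
        universe = {g for t in terms for g in t.members} | {"Q1", "Q2"}
        result = enrich.enrich({"Q1", "Q2"}, terms, universe=universe)
        assert (result["p_value"] == 1.0).all()
        assert not result["significant"].any()

    def test_planted_term_ranks_first(self):
        """Query of 50 with 30 drawn from a 40-gene term, universe 2000,
        100 decoys: the planted term tops the table below FDR 0.01."""
        from npharm import synthetic

        universe = [f"U{i:04d}" for i in range(2000)]
        rng = np.random.default_rng(17)
        query = rng.choice(universe, size=50, replace=False).tolist()
        terms, manifest = synthetic.gen_annotations(
            universe, query, planted_size=40, planted_overlap=30,
            n_decoys=100, seed=17,
        )
        result = enrich.enrich(query, terms, universe=universe)
        assert result.iloc[0]["term_id"] == manifest["planted_term"]
        assert result.iloc[0]["fdr"] < 0.01
        assert bool(result.iloc[0]["significant"])

    def test_bh_applied_per_category(self):
        kegg = [make_term(f"k{i}", [f"G{i}"], "KEGG") for i in range(2)]
        bp = [make_term("b0", ["G0"], "BP")]
        universe = {"G0", "G1", "Q"}
        result = enrich.enrich({"G0"}, kegg + bp, universe=universe)
        by_id = result.set_index("term_id")
        # same raw p in both categories, but KEGG carries two tests
        assert by_id.loc["b0", "fdr"] == pytest.approx(by_id.loc["b0", "p_value"])
        assert by_id.loc["k0", "fdr"] >= by_id.loc["b0", "fdr"]

    def test_query_outside_universe_dropped_with_warning(self, caplog):
        term = make_term("t1", ["G1", "G2"])
        with caplog.at_level("WARNING"):
            result = enrich.enrich({"G1", "ALIEN"}, [term])
        assert "outside the universe" in caplog.text
        assert result.iloc[0]["n"] == 1

    def test_empty_inputs_rejected(self):
        term = make_term("t1", ["G1"])
        with pytest.raises(ValueError):
            enrich.enrich(set(), [term])
        with pytest.raises(ValueError):
            enrich.enrich({"G1"}, [term], universe=set())

    def test_rich_factor_of_significant_terms_beats_background_rate(self):
        from npharm import synthetic

        universe = [f"U{i:04d}" for i in range(2000)]
        rng = np.random.default_rng(5)
        query = rng.choice(universe, size=50, replace=False).tolist()
        terms, _ = synthetic.gen_annotations(universe, query, seed=5)
        result = enrich.enrich(query, terms, universe=universe)
        background = result.iloc[0]["n"] / result.iloc[0]["N"]
        sig = result.loc[result["significant"]]
        assert (sig["rich_factor"] > background).all()


def test_null_calibration_of_raw_p():
    """Queries drawn uniformly from the universe: the fraction of raw
    p-values below 0.05 stays in the conservative band [0.02, 0.09]."""
    rng = np.random.default_rng(123)
    n_universe, n_terms, n_query, n_reps = 2000, 100, 50, 1000
    sizes = rng.integers(10, 81, size=n_terms)
    membership = np.zeros((n_terms, n_universe), dtype=bool)
    for t, size in enumerate(sizes):
        membership[t, rng.choice(n_universe, size=size, replace=False)] = True
    from scipy import stats

    hits = 0
    for rep in range(n_reps):
        query = np.zeros(n_universe, dtype=bool)
        query[rng.choice(n_universe, size=n_query, replace=False)] = True
        k = membership.astype(int) @ query.astype(int)
        p = stats.hypergeom.sf(k - 1, n_universe, sizes, n_query)
        if rep == 0:  # the vectorized tail is the package statistic
            for t in range(0, n_terms, 10):
                assert p[t] == pytest.approx(
                    enrich.hypergeom_upper_tail(
                        n_universe, int(sizes[t]), n_query, int(k[t])
                    )
                )
        hits += int((p < 0.05).sum())
    fraction = hits / (n_reps * n_terms)
    assert 0.02 <= fraction <= 0.09


def test_gmt_round_trip(tmp_path):
    terms = [
        make_term("hsa05210", ["EGFR", "JUN", "TP53"]),
        make_term("hsa04151", ["PIK3CD", "AKT1"]),
    ]
    path = tmp_path / "kegg.gmt"
    enrich.write_gmt(terms, path)
    back = enrich.read_gmt(path, "KEGG")
    assert back == terms


def test_malformed_gmt_rejected(tmp_path):
    path = tmp_path / "bad.gmt"
    path.write_text("only_two\tfields\n")
    with pytest.raises(ValueError, match="malformed"):
        enrich.read_gmt(path, "KEGG")
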