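"""Hypergeometric neighborhood-enrichment encoding."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from genesieve.enrichment import (
    AnnotationCatalog,
    GeneNetwork,
    build_matrix,
    enrichment_score,
    hypergeom_upper_tail,
    neighbors,
)


def exact_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Independent oracle: exact rational tail by direct combinatorics."""
    total = Fraction(0)
    for k in range(m, min(n, M) + 1):
        total += Fraction(comb(M, k) * comb(N - M, n - k), comb(N, n))
    return float(total)


def enumerated_upper_tail(N: int, M: int, n: int, m: int) -> float:
    """Second oracle: brute-force enumeration over all C(N, n) draws."""
    annotated = set(range(M))
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if len(annotated.intersection(draw)) >= m
    )
    return hits / comb(N, n)


class TestHypergeomUpperTail:
    @pytest.mark.parametrize(
        "N,M,n,m,expected",
        [
            (10, 4, 3, 2, 40 / 120),  # (C(4,2)C(6,1)+C(4,3)C(6,0))/C(10,3)
            (10, 4, 3, 3, 4 / 120),
            (10, 4, 3, 0, 1.0),
            (100, 10, 5, 0, 1.0),
        ],
    )
    def test_known_values(self, N, M, n, m, expected):
        assert hypergeom_upper_tail(N, M, n, m) == pytest.approx(expected, abs=1e-12)

    def test_matches_enumeration_small_universe(self):
        for N in range(1, 9):
            for M in range(N + 1):
                for n in range(N + 1):
                    for m in range(min(n, M) + 1):
                        got = hypergeom_upper_tail(N, M, n, m)
                        assert got == pytest.approx(
                            enumerated_upper_tail(N, M, n, m), abs=1e-12
                        ), (N, M, n, m)

    @given(
        st.integers(2, 40).flatmap(
            lambda N: st.tuples(
                st.just(N), st.integers(0, N), st.integers(0, N)
            )
        )
    )
    def test_monotone_in_overlap(self, params):
        """With N, M, n fixed the tail never increases as m grows."""
        N, M, n = params
        tails = [hypergeom_upper_tail(N, M, n, m) for m in range(min(n, M) + 1)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))
        assert all(0 < t <= 1 for t in tails)

    @pytest.mark.parametrize("N,M,n,m", [(10, 11, 3, 2), (10, 4, 11, 2), (10, 4, 3, 4), (5, 2, 3, -1)])
    def test_domain_errors(self, N, M, n, m):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(N, M, n, m)


class TestEnrichmentScore:
    def test_identity_and_example(self):
        assert enrichment_score(1.0) == 0.0
        assert enrichment_score(1 / 3) == pytest.approx(0.47712125, abs=1e-6)

    def test_cap_on_underflow(self):
        assert enrichment_score(1e-310) == 300.0
        assert enrichment_score(1e-310, cap=50.0) == 50.0

    @pytest.mark.parametrize("p", [0.0, -0.1, 1.5])
    def test_domain(self, p):
        with pytest.raises(ValueError):
            enrichment_score(p)


def _net(universe, edges, scores=None):
    es = frozenset(frozenset(e) for e in edges)
    sc = {frozenset(k): v for k, v in (scores or {}).items()}
    return GeneNetwork(universe=frozenset(universe), edges=es, edge_score=sc)


class TestNeighbors:
    def test_triangle(self):
        net = _net("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        assert neighbors(net, "b") == {"a", "c"}

    def test_isolated_gene(self):
        net = _net("abc", [("a", "b")])
        assert neighbors(net, "c") == set()

    def test_score_threshold(self):
        net = _net("abc", [("a", "b"), ("a", "c")], {("a", "b"): 700, ("a", "c"): 150})
        assert neighbors(net, "a", min_score=400) == {"b"}
        assert neighbors(net, "a", min_score=0) == {"b", "c"}

    def test_unknown_gene_named_in_error(self):
        net = _net("ab", [("a", "b")])
        with pytest.raises(KeyError, match="zzz"):
            neighbors(net, "zzz")


class TestBuildMatrix:
    @pytest.fixture()
    def toy(self):
        genes = [f"g{i}" for i in range(1, 11)]
        catalog = AnnotationCatalog(
            terms=(("T", "BP", frozenset({"g1", "g2", "g3", "g4"})),),
            universe=frozenset(genes + ["x"]),
        )
        net = _net(
            genes + ["x"], [("x", "g1"), ("x", "g2"), ("x", "g5")]
        )
        return catalog, net

    def test_ten_gene_example(self, toy):
        catalog, net = toy
        # N=11 with the probe gene itself in the universe would shift the
        # tail; score the 10-gene universe exactly as specified
        genes = [f"g{i}" for i in range(1, 11)]
        catalog10 = AnnotationCatalog(
            terms=catalog.terms, universe=frozenset(genes)
        )
        net10 = _net(genes, [("g9", "g1"), ("g9", "g2"), ("g9", "g5")])
        mat = build_matrix(catalog10, net10, genes=["g9"])
        # neighbors {g1,g2,g5}: N=10, M=4, n=3, m=2 -> p=1/3
        assert mat.scores[0, 0] == pytest.approx(0.4771212, abs=1e-6)

    def test_isolated_gene_zero_row(self, toy):
        catalog, net = toy
        mat = build_matrix(catalog, net)
        row = mat.scores[list(mat.genes).index("g7")]
        assert np.all(row == 0)

    def test_whole_universe_term_scores_zero(self):
        genes = ["a", "b", "c", "d"]
        catalog = AnnotationCatalog(
            terms=(("ALL", "BP", frozenset(genes)),), universe=frozenset(genes)
        )
        net = _net(genes, [("a", "b"), ("b", "c"), ("c", "d")])
        mat = build_matrix(catalog, net)
        assert np.all(mat.scores == 0)  # m = n forces tail probability 1

    def test_universe_mismatch_reported(self, toy):
        catalog, _ = toy
        net = _net(["g1", "g2"], [("g1", "g2")])
        with pytest.raises(ValueError, match="universe"):
            build_matrix(catalog, net)

    def test_row_independent_of_insertion_order(self, small_synthetic):
        _, ds, mat, _ = small_synthetic
        genes = list(mat.genes)
        rev = build_matrix(ds.catalog, ds.network, genes=genes[::-1])
        for i, g in enumerate(genes):
            j = len(genes) - 1 - i
            assert np.array_equal(mat.scores[i], rev.scores[j])

    def test_entries_finite_nonnegative(self, small_synthetic):
        _, _, mat, _ = small_synthetic
        assert np.all(np.isfinite(mat.scores))
        assert np.all(mat.scores >= 0)
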