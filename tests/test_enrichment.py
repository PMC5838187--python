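"""Hypergeometric enrichment, kappa agreement and term clustering."""

from itertools import combinations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hubscreen import (
    AnnotationTable,
    EnrichmentParameters,
    GenePanel,
    TermRecord,
    cluster_terms,
    enrich,
    gen_annotations,
    hypergeometric_test,
    kappa_score,
)


def enumeration_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Oracle: P(X >= k) by exhaustively enumerating all C(N, n) draws."""
    term = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        hits += len(term & set(draw)) >= k
    return hits / total


class TestHypergeometric:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_test(100, 10, 10, 0) == 1.0

    def test_enumerated_small_case(self):
        assert hypergeometric_test(5, 2, 2, 2) == pytest.approx(0.1)
        assert enumeration_upper_tail(5, 2, 2, 2) == pytest.approx(0.1)

    def test_term_equals_universe(self):
        assert hypergeometric_test(10, 10, 3, 3) == pytest.approx(1.0)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_test(10, 12, 3, 2)
        with pytest.raises(ValueError):
            hypergeometric_test(10, 5, 3, 4)

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_exhaustive_enumeration(self, N):
        for K in range(1, N + 1):
            for n in range(1, N + 1):
                for k in range(0, min(K, n) + 1):
                    p = hypergeometric_test(N, K, n, k)
                    assert p == pytest.approx(
                        enumeration_upper_tail(N, K, n, k), abs=1e-12), (N, K, n, k)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(5, 60), st.integers(1, 30), st.integers(1, 30))
    def test_non_increasing_in_overlap(self, N, K, n):
        K, n = min(K, N), min(n, N)
        ps = [hypergeometric_test(N, K, n, k) for k in range(min(K, n) + 1)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrich:
    @pytest.fixture
    def planted(self):
        ann, query = gen_annotations(
            universe_size=200, n_terms=20, planted=[(20, 8), (25, 8)], seed=3)
        return ann, query

    def test_planted_terms_pass_background_fails(self, planted):
        ann, query = planted
        records = enrich(query, ann)
        ids = {r.term_id for r in records}
        assert {"PLANT0001", "PLANT0002"} <= ids
        for r in records:
            assert r.k >= 2  # k < 2 terms can never appear

    def test_every_record_passes_all_filters(self, planted):
        ann, query = planted
        params = EnrichmentParameters()
        for r in enrich(query, ann, params):
            assert r.k >= params.min_query_genes_per_term
            assert r.percent_genes >= params.min_percent_genes_per_term
            assert r.p_value <= params.p_threshold

    def test_single_gene_terms_excluded_regardless_of_p(self):
        universe = frozenset(f"G{i}" for i in range(50))
        ann = AnnotationTable(universe=universe, terms={
            "T1": ("solo", frozenset({"G0"})),
        })
        records = enrich(GenePanel("q", ["G0"]), ann)
        assert records == []  # p = 1/50 * ... tiny but k = 1 < 2

    def test_low_percent_excluded(self):
        universe = frozenset(f"G{i}" for i in range(5000))
        big_term = frozenset(f"G{i}" for i in range(100))
        ann = AnnotationTable(universe=universe, terms={"BIG": ("big", big_term)})
        query = GenePanel("q", ["G0", "G1"])
        # k=2 of K=100 -> 2% < 4%, excluded despite p << 0.01
        assert enrich(query, ann) == []

    def test_disjoint_query_is_error(self):
        ann = AnnotationTable(universe=frozenset({"A"}), terms={"T": ("t", frozenset({"A"}))})
        with pytest.raises(ValueError, match="disjoint"):
            enrich(GenePanel("q", ["ZZZ"]), ann)

    def test_sorted_by_p_then_id(self, planted):
        ann, query = planted
        records = enrich(query, ann)
        keys = [(r.p_value, r.term_id) for r in records]
        assert keys == sorted(keys)

    def test_bonferroni_is_more_conservative(self, planted):
        ann, query = planted
        raw = enrich(query, ann)
        bonf = enrich(query, ann, EnrichmentParameters(correction="bonferroni"))
        assert {r.term_id for r in bonf} <= {r.term_id for r in raw}


class TestKappa:
    UNIVERSE = frozenset(f"g{i}" for i in range(1, 11))

    def test_identical_sets(self):
        a = frozenset({"g1", "g2", "g3"})
        assert kappa_score(a, a, self.UNIVERSE) == 1.0

    def test_hand_computed_table(self):
        a = frozenset(f"g{i}" for i in range(1, 6))
        b = frozenset({"g1", "g2", "g3", "g4", "g6"})
        # 2x2 table: both=4, only-a=1, only-b=1, neither=4 -> po=0.8, pe=0.5
        assert kappa_score(a, b, self.UNIVERSE) == pytest.approx(0.6)

    def test_complementary_sets(self):
        a = frozenset(f"g{i}" for i in range(1, 6))
        assert kappa_score(a, self.UNIVERSE - a, self.UNIVERSE) == pytest.approx(-1.0)

    def test_universe_too_small_is_error(self):
        with pytest.raises(ValueError, match="universe"):
            kappa_score({"a", "b"}, {"c"}, {"a", "b"})

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.sets(st.sampled_from("abcdefghij"), min_size=1),
        st.sets(st.sampled_from("abcdefghij"), min_size=1),
    )
    def test_symmetric_and_one_iff_identical(self, sa, sb):
        universe = frozenset("abcdefghij")
        k_ab = kappa_score(sa, sb, universe)
        k_ba = kappa_score(sb, sa, universe)
        assert k_ab == pytest.approx(k_ba)
        assert (k_ab == 1.0) == (sa == sb)


class TestClusterTerms:
    @staticmethod
    def _records(term_ids):
        return [TermRecord(t, t, 5, 2, 40.0, 0.001) for t in term_ids]

    def test_identical_memberships_form_one_cluster(self):
        members = frozenset({"A", "B", "C"})
        universe = frozenset({"A", "B", "C", "D", "E"})
        ann = AnnotationTable(universe=universe,
                              terms={t: (t, members) for t in ("T1", "T2", "T3")})
        cs = cluster_terms(self._records(["T1", "T2", "T3"]), ann)
        assert len(cs.clusters) == 1

    def test_disjoint_memberships_are_singletons(self):
        universe = frozenset(f"G{i}" for i in range(30))
        ul = sorted(universe)
        ann = AnnotationTable(universe=universe, terms={
            "T1": ("t1", frozenset(ul[0:5])),
            "T2": ("t2", frozenset(ul[10:15])),
            "T3": ("t3", frozenset(ul[20:25])),
        })
        cs = cluster_terms(self._records(["T1", "T2", "T3"]), ann)
        assert len(cs.clusters) == 3
        assert all(len(v) == 1 for v in cs.clusters.values())

    def test_two_planted_blocks_give_two_clusters(self):
        import random

        rng = random.Random(11)
        universe = frozenset(f"G{i:03d}" for i in range(100))
        ul = sorted(universe)
        block_a, block_b = ul[:20], ul[50:70]
        terms = {}
        for i in range(3):
            terms[f"A{i}"] = (f"A{i}", frozenset(rng.sample(block_a, 16)))
            terms[f"B{i}"] = (f"B{i}", frozenset(rng.sample(block_b, 16)))
        ann = AnnotationTable(universe=universe, terms=terms)
        cs = cluster_terms(self._records(sorted(terms)), ann)
        multi = [c for c in cs.clusters.values() if len(c) > 1]
        assert len(multi) == 2
        assert {tuple(sorted(m)) for m in multi} == {
            ("A0", "A1", "A2"), ("B0", "B1", "B2")}

    def test_clustering_partitions_records(self):
        ann, query = gen_annotations(100, 10, [(15, 6), (15, 6)], seed=5, query_size=15)
        records = enrich(query, ann)
        cs = cluster_terms(records, ann)
        assigned = [t for c in cs.clusters.values() for t in c]
        assert sorted(assigned) == sorted(r.term_id for r in records)
        assert all(r.cluster_id is not None for r in records)
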