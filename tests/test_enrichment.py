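import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossmr.enrichment import (
    EnrichmentError,
    _es_from_hit_ranks,
    enrichment_score,
    leading_edge,
    leading_edge_overlap_test,
    pathway_enrichment,
    permutation_nes,
    two_tail_gsea,
)
from crossmr.signatures import GeneSignature


def es_oracle(genes, scores, query, w):
    """Independent exhaustive running-sum oracle (plain Python loop)."""
    qs = set(query)
    n = len(genes)
    k = sum(g in qs for g in genes)
    assert 0 < k < n
    nr = sum(abs(s) ** w for g, s in zip(genes, scores) if g in qs)
    run, best, best_i = 0.0, None, None
    for i, (g, s) in enumerate(zip(genes, scores)):
        if g in qs:
            run += (abs(s) ** w) / nr if nr > 0 else 1.0 / k
        else:
            run -= 1.0 / (n - k)
        if best is None or abs(run) > abs(best):
            best, best_i = run, i + 1
    return best, best_i


def _sig(n, rng=None, scores=None):
    genes = [f"g{i}" for i in range(n)]
    if scores is None:
        scores = rng.normal(size=n)
    return GeneSignature.from_scores(genes, scores)


class TestEnrichmentScore:
    @pytest.mark.parametrize("w", [0.0, 1.0])
    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_matches_oracle_on_every_subset(self, n, w):
        rng = np.random.default_rng(n)
        sig = _sig(n, rng)
        genes = list(sig.genes)
        for r in range(1, n):
            for query in itertools.combinations(genes, r):
                es, _, xi = enrichment_score(sig, query, w)
                es_ref, xi_ref = es_oracle(genes, list(sig.scores), query, w)
                assert es == pytest.approx(es_ref, abs=1e-12)
                assert xi == xi_ref

    def test_single_top_hit_is_one(self):
        sig = _sig(4, scores=[4.0, 3.0, 2.0, 1.0])
        es, _, xi = enrichment_score(sig, {"g0"}, 0.0)
        assert (es, xi) == (1.0, 1)

    def test_two_hit_example(self, toy_signature):
        # hits at ranks 1 and 3 of 5, unweighted: running sum
        # 1/2, 1/6, 2/3, 1/3, 0 -> ES = 2/3 at rank 3
        es, _, xi = enrichment_score(toy_signature, {"g1", "g3"}, 0.0)
        assert es == pytest.approx(2.0 / 3.0)
        assert xi == 3

    def test_bottom_hit_is_negative(self):
        # misses walk the sum to -(3 * 1/3) = -1 before the final hit
        sig = _sig(4, scores=[4.0, 3.0, 2.0, 1.0])
        es, _, xi = enrichment_score(sig, {"g3"}, 0.0)
        assert es == pytest.approx(-1.0)
        assert xi == 3

    def test_degenerate_queries_raise(self, toy_signature):
        with pytest.raises(EnrichmentError):
            enrichment_score(toy_signature, {"zz"})
        with pytest.raises(EnrichmentError):
            enrichment_score(toy_signature, set(toy_signature.genes))

    def test_negating_and_reversing_negates_es(self, rng):
        sig = _sig(30, rng)
        neg = GeneSignature.from_scores(sig.genes, -sig.scores)
        query = set(rng.choice(sig.genes, 6, replace=False))
        es, _, _ = enrichment_score(sig, query, 1.0)
        es_neg, _, _ = enrichment_score(neg, query, 1.0)
        assert es_neg == pytest.approx(-es, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        n=st.integers(3, 12),
        w=st.sampled_from([0.0, 1.0, 2.0]),
        data=st.data(),
    )
    def test_property_bounded_and_oracle_exact(self, n, w, data):
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        sig = _sig(n, rng)
        r = data.draw(st.integers(1, n - 1))
        query = set(rng.choice(sig.genes, r, replace=False))
        es, _, xi = enrichment_score(sig, query, w)
        assert -1.0 <= es <= 1.0
        es_ref, xi_ref = es_oracle(list(sig.genes), list(sig.scores), query, w)
        assert es == pytest.approx(es_ref, abs=1e-12)
        assert xi == xi_ref


class TestFastNullPath:
    def test_rank_formula_matches_full_running_sum(self, rng):
        """The O(k) candidate evaluation used for permutation nulls must
        agree with the full running-sum scan."""
        sig = _sig(200, rng)
        w = np.abs(sig.scores)
        for _ in range(50):
            k = int(rng.integers(1, 40))
            pos = np.sort(rng.choice(200, k, replace=False))
            query = set(sig.genes[pos])
            es_full, _, _ = enrichment_score(sig, query, 1.0)
            es_fast = _es_from_hit_ranks(
                (pos + 1)[None, :], w[pos][None, :], 200
            )[0]
            assert es_fast == pytest.approx(es_full, abs=1e-12)


class TestPermutationNES:
    def test_deterministic_with_fixed_seed(self, rng):
        sig = _sig(50, rng)
        query = set(rng.choice(sig.genes, 5, replace=False))
        a = permutation_nes(sig, query, n_perm=200, seed=42)
        b = permutation_nes(sig, query, n_perm=200, seed=42)
        assert (a.es, a.nes, a.p) == (b.es, b.nes, b.p)

    def test_unbeatable_query_hits_p_floor(self):
        sig = _sig(50, scores=np.arange(50, 0, -1.0))
        res = permutation_nes(sig, {f"g{i}" for i in range(5)}, n_perm=200,
                              seed=1, weight_exponent=0.0)
        assert res.es == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / 201.0)
        assert res.nes > 0

    def test_nes_sign_matches_es(self, rng):
        sig = _sig(80, rng)
        for _ in range(10):
            query = set(rng.choice(sig.genes, 8, replace=False))
            res = permutation_nes(sig, query, n_perm=100, seed=3)
            if res.nes != 0:
                assert np.sign(res.nes) == np.sign(res.es)
            assert res.p >= 1.0 / 101.0



class TestTwoTailGSEA:
    def test_self_enrichment_signs(self, rng):
        sig = _sig(200, rng)
        pos, neg = two_tail_gsea(sig, sig, top_n=20, n_perm=200, seed=5)
        assert pos.nes > 0
        assert neg.nes < 0

    def test_negated_query_flips_signs(self, rng):
        sig = _sig(200, rng)
        pos, neg = two_tail_gsea(sig, sig.negated(), top_n=20, n_perm=200, seed=5)
        assert pos.nes < 0
        assert neg.nes > 0

    def test_top_n_reduced_with_warning(self, rng, caplog):
        sig = _sig(100, rng)
        import logging

        with caplog.at_level(logging.WARNING):
            pos, neg = two_tail_gsea(sig, sig, top_n=200, n_perm=100, seed=1)
        assert any("reducing" in r.message for r in caplog.records)
        assert pos.nes > 0 and neg.nes < 0

    def test_tiny_shared_universe_raises(self, rng):
        a = _sig(5, rng)
        b = _sig(5, rng)
        with pytest.raises(EnrichmentError):
            two_tail_gsea(a, b, top_n=2, n_perm=50, seed=0)


class TestLeadingEdge:
    def test_examples(self, toy_signature):
        assert leading_edge(toy_signature, {"g1", "g3"}, 0.0) == {"g1", "g3"}
        assert leading_edge(toy_signature, {"g1"}, 0.0) == {"g1"}
        assert leading_edge(toy_signature, {"g5"}, 0.0) == {"g5"}


class TestOverlapTest:
    def test_identical_and_disjoint(self):
        uni = [f"g{i}" for i in range(20)]
        frac, _, _ = leading_edge_overlap_test(uni[:5], uni[:5], uni)
        assert frac == 1.0
        frac, _, _ = leading_edge_overlap_test(uni[:5], uni[5:10], uni)
        assert frac == 0.0

    def test_chi_square_matches_hand_computation(self):
        uni = [f"g{i}" for i in range(100)]
        a = set(uni[:10])
        b = set(uni[:8]) | {uni[10], uni[11]}  # |A n B| = 8
        frac, chi2, p = leading_edge_overlap_test(a, b, uni)
        assert frac == pytest.approx(0.8)
        # direct chi-square of [[8, 2], [2, 88]] without continuity correction
        table = np.array([[8.0, 2.0], [2.0, 88.0]])
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2_ref = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(chi2_ref, abs=1e-10)

    def test_empty_universe_raises(self):
        with pytest.raises(EnrichmentError):
            leading_edge_overlap_test({"a"}, {"a"}, [])


class TestPathwayEnrichment:
    def test_planted_set_floors_p(self, rng):
        sig = _sig(200, scores=np.arange(200, 0, -1.0))
        sets = {"planted": frozenset(sig.genes[:20]), "tiny": frozenset(sig.genes[:2])}
        table = pathway_enrichment(sig, sets, n_perm=200, seed=9,
                                   weight_exponent=0.0)
        assert "tiny" not in table.index  # below min_overlap, skipped
        row = table.loc["planted"]
        assert row["nes"] > 0
        assert row["p"] == pytest.approx(1.0 / 201.0)
        assert row["significant"]

    def test_no_overlap_raises(self, rng):
        sig = _sig(50, rng)
        with pytest.raises(EnrichmentError):
            pathway_enrichment(sig, {"s": frozenset({"zz"})}, n_perm=50, seed=0)
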