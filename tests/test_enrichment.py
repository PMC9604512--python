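import numpy as np
import pandas as pd
import pytest

from pirs import (ExpressionMatrix, enrichment_score, leading_edge,
                  nes_and_fdr, rank_genes, union_signature)


def brute_force_es(metrics, hits, weight_p):
    """Independent running-sum oracle: plain python loop, no vectorization."""
    N = len(metrics)
    n_hits = sum(hits)
    hit_total = sum(abs(m) ** weight_p for m, h in zip(metrics, hits) if h)
    running, best, best_pos = 0.0, 0.0, 0
    values = []
    for i, (m, h) in enumerate(zip(metrics, hits)):
        if h:
            if hit_total == 0:
                running += 1.0 / n_hits
            else:
                running += abs(m) ** weight_p / hit_total
        else:
            running -= 1.0 / (N - n_hits)
        values.append(running)
        if abs(running) > abs(best):
            best, best_pos = running, i + 1
    return best, best_pos


def _ranked(metrics, genes=None):
    genes = genes or [f"g{i}" for i in range(1, len(metrics) + 1)]
    return pd.Series(metrics, index=genes)


class TestEnrichmentScore:
    def test_single_member_at_top_is_one(self):
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _, peak = enrichment_score(r, {"g1"})
        assert es == pytest.approx(1.0)
        assert peak == 1

    def test_single_member_at_bottom_is_minus_one(self):
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _, _ = enrichment_score(r, {"g5"})
        assert es == pytest.approx(-1.0)

    def test_hand_evaluated_running_sum(self):
        # hits at ranks 1 and 4, weights 5/7 and 2/7, misses -1/3
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, running, peak = enrichment_score(r, {"g1", "g4"}, weight_p=1.0)
        np.testing.assert_allclose(
            running, [5 / 7, 5 / 7 - 1 / 3, 5 / 7 - 2 / 3, 1 / 3, 0.0],
            atol=1e-12)
        assert es == pytest.approx(5 / 7)
        assert peak == 1

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(_ranked([3.0, 2.0, 1.0]), {"zzz"})

    def test_unweighted_top_block_reaches_one(self):
        r = _ranked(list(range(30, 0, -1)))
        for k in (1, 3, 7):
            es, _, peak = enrichment_score(r, {f"g{i}" for i in range(1, k + 1)},
                                           weight_p=0.0)
            assert es == pytest.approx(1.0, abs=1e-9)
            assert peak == k

    def test_reversed_ranking_negates_es_unweighted(self):
        metrics = [9.0, 7.0, 5.0, 3.0, 1.0, -1.0, -3.0, -5.0]
        genes = [f"g{i}" for i in range(1, 9)]
        fwd = pd.Series(metrics, index=genes)
        rev = fwd.iloc[::-1]
        gene_set = {"g1", "g2"}
        es_f, _, _ = enrichment_score(fwd, gene_set, weight_p=0.0)
        es_r, _, _ = enrichment_score(rev, gene_set, weight_p=0.0)
        assert es_r == pytest.approx(-es_f)

    @pytest.mark.parametrize("weight_p", [0.0, 1.0, 1.5])
    def test_matches_brute_force_oracle(self, weight_p):
        rng = np.random.default_rng(42)
        for _ in range(100):
            N = int(rng.integers(5, 51))
            metrics = np.sort(rng.normal(size=N))[::-1]
            k = int(rng.integers(1, N))
            hit_idx = rng.choice(N, size=k, replace=False)
            genes = [f"g{i}" for i in range(N)]
            gene_set = {genes[i] for i in hit_idx}
            es, _, peak = enrichment_score(pd.Series(metrics, index=genes),
                                           gene_set, weight_p)
            hits = [g in gene_set for g in genes]
            es_o, peak_o = brute_force_es(metrics, hits, weight_p)
            assert es == pytest.approx(es_o, abs=1e-12)
            assert peak == peak_o


class TestLeadingEdge:
    def test_peak_at_one_returns_first_gene(self):
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _, peak = enrichment_score(r, {"g1", "g4"})
        assert leading_edge(r, {"g1", "g4"}, es, peak) == ["g1"]

    def test_whole_set_at_top(self):
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        gene_set = {"g1", "g2", "g3"}
        es, _, peak = enrichment_score(r, gene_set)
        le = leading_edge(r, gene_set, es, peak)
        assert set(le) == gene_set

    def test_negative_es_takes_tail(self):
        r = _ranked([5.0, 4.0, 3.0, 2.0, 1.0])
        es, _, peak = enrichment_score(r, {"g5"})
        assert leading_edge(r, {"g5"}, es, peak) == ["g5"]

    def test_leading_edge_within_peak_for_positive_es(self):
        rng = np.random.default_rng(9)
        metrics = np.sort(rng.normal(size=40))[::-1]
        genes = [f"g{i}" for i in range(40)]
        r = pd.Series(metrics, index=genes)
        gene_set = set(genes[:5]) | set(genes[20:23])
        es, _, peak = enrichment_score(r, gene_set)
        if es > 0:
            ranks = {g: i + 1 for i, g in enumerate(genes)}
            assert all(ranks[g] <= peak for g in leading_edge(r, gene_set, es, peak))


class TestRanking:
    def test_equal_means_give_zero_metric(self):
        data = pd.DataFrame([[1.0, 2.0, 1.0, 2.0]], index=["A"],
                            columns=["a1", "a2", "b1", "b2"])
        m = ExpressionMatrix(data, "log2")
        ranked = rank_genes(m, {"a1": "x", "a2": "x", "b1": "y", "b2": "y"},
                            positive="x")
        assert ranked["A"] == 0.0

    def test_signal_to_noise_value(self):
        # means 2 vs 1, raw SDs 0.5 but floored at max(0.2*|mu|, 0.2)
        a = [1.5, 2.5, 2.0, 2.0]
        b = [0.5, 1.5, 1.0, 1.0]
        data = pd.DataFrame([a + b], index=["A"],
                            columns=[f"s{i}" for i in range(8)])
        labels = {f"s{i}": ("x" if i < 4 else "y") for i in range(8)}
        ranked = rank_genes(ExpressionMatrix(data, "log2"), labels, positive="x")
        sd_a = np.std(a, ddof=1)
        expected = (2.0 - 1.0) / (max(sd_a, 0.4) + max(np.std(b, ddof=1), 0.2))
        assert ranked["A"] == pytest.approx(expected)

    def test_sample_permutation_invariance(self, small_cohort):
        counts, meta, _ = small_cohort
        m = ExpressionMatrix(np.log2(counts.data + 1), "log2")
        labels = meta.set_index("sample_id")["outcome"].map(
            lambda o: "pCR" if o == "pCR" else "other")
        r1 = rank_genes(m, labels, positive="pCR")
        shuffled = m.with_data(m.data.sample(frac=1, axis=1, random_state=0))
        r2 = rank_genes(shuffled, labels, positive="pCR")
        pd.testing.assert_series_equal(r1, r2)

    def test_ties_broken_lexicographically(self):
        data = pd.DataFrame(np.zeros((3, 4)), index=["C", "A", "B"],
                            columns=["a1", "a2", "b1", "b2"])
        labels = {"a1": "x", "a2": "x", "b1": "y", "b2": "y"}
        ranked = rank_genes(ExpressionMatrix(data, "log2"), labels, positive="x")
        assert list(ranked.index) == ["A", "B", "C"]

    def test_small_group_errors(self):
        data = pd.DataFrame(np.ones((2, 3)), index=["A", "B"],
                            columns=["a1", "b1", "b2"])
        labels = {"a1": "x", "b1": "y", "b2": "y"}
        with pytest.raises(ValueError, match="2 samples"):
            rank_genes(ExpressionMatrix(data, "log2"), labels, positive="x")


@pytest.fixture(scope="module")
def planted_ranking():
    rng = np.random.default_rng(17)
    N = 1000
    metrics = np.sort(rng.normal(size=N))[::-1]
    genes = [f"g{i:04d}" for i in range(N)]
    return pd.Series(metrics, index=genes)


class TestNesAndFdr:

    def test_determinism_under_seed(self, planted_ranking):
        sets = {"top": list(planted_ranking.index[:20]),
                "mid": list(planted_ranking.index[400:420])}
        r1 = nes_and_fdr(sets, planted_ranking, n_perm=200, seed=5)
        r2 = nes_and_fdr(sets, planted_ranking, n_perm=200, seed=5)
        for a, b in zip(r1, r2):
            assert (a.nes, a.p_value, a.q_value) == (b.nes, b.p_value, b.q_value)

    def test_planted_top_set_attains_smallest_q(self, planted_ranking):
        rng = np.random.default_rng(23)
        genes = list(planted_ranking.index)
        sets = {"planted": genes[:20]}
        for j in range(50):
            sets[f"rand{j}"] = list(rng.choice(genes, size=20, replace=False))
        results = nes_and_fdr(sets, planted_ranking, n_perm=200, seed=1)
        by_name = {r.set_name: r for r in results}
        planted_q = by_name["planted"].q_value
        assert planted_q == min(r.q_value for r in results)
        assert by_name["planted"].nes == max(r.nes for r in results)

    def test_nes_one_when_es_equals_null_mean(self, planted_ranking):
        # definitional: NES divides by the same-sign null mean
        sets = {"top": list(planted_ranking.index[:20])}
        res = nes_and_fdr(sets, planted_ranking, n_perm=150, seed=2)[0]
        assert res.nes > 1.0  # planted set beats its null mean
        # no null reached the planted ES: p is at its floor 1/(n_same + 1),
        # which can be no larger than 1/(150/2) for a roughly even sign split
        assert res.p_value <= 1 / 50

    def test_rejects_tiny_n_perm(self, planted_ranking):
        with pytest.raises(ValueError, match="n_perm"):
            nes_and_fdr({"s": list(planted_ranking.index[:5])},
                        planted_ranking, n_perm=10)


class TestUnionSignature:
    def test_simple_union(self):
        sig = union_signature([["A", "B"], ["B", "C"], ["C", "D"]])
        assert sig.genes == ["A", "B", "C", "D"]
        assert all(s == 1 for s in sig.signs.values())

    def test_single_list_identity_up_to_order(self):
        sig = union_signature([["B", "A"]])
        assert sig.genes == ["A", "B"]

    def test_inclusion_exclusion_arithmetic(self):
        # three lists of sizes 49, 26, 15 sharing 30 duplicate memberships
        a = [f"x{i:02d}" for i in range(49)]
        b = [f"x{i:02d}" for i in range(20)] + [f"y{i}" for i in range(6)]
        c = [f"x{i:02d}" for i in range(10)] + [f"z{i}" for i in range(5)]
        assert (len(a), len(b), len(c)) == (49, 26, 15)
        sig = union_signature([a, b, c])
        assert len(sig) == 60  # 49 + 26 + 15 - 30 duplicates

    def test_empty_union_errors(self):
        with pytest.raises(ValueError):
            union_signature([[], []])
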