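import numpy as np
import pytest

import spherotype as st
from spherotype.enrich import _running_sum


def brute_force_es(scores, hit, p_weight):
    """Independent running-sum oracle: explicit loop, no vectorization."""
    n = len(scores)
    n_hit = sum(hit)
    denom = sum(abs(scores[i]) ** p_weight for i in range(n) if hit[i])
    run, cur = [], 0.0
    for i in range(n):
        if hit[i]:
            cur += (abs(scores[i]) ** p_weight / denom) if denom > 0 \
                else 1.0 / n_hit
        else:
            cur -= 1.0 / (n - n_hit)
        run.append(cur)
    best = max(run, key=lambda v: (abs(v), v))
    return best


def _ranked(scores, prefix="g"):
    ids = [f"{prefix}{i + 1}" for i in range(len(scores))]
    return st.RankedList(ids, np.array(scores, float))


TOY = _ranked([3, 2, 1, 0.5, 0.1])


class TestRankGenes:
    def _em_two_groups(self, a_vals, b_vals):
        values = np.array([list(a_vals) + list(b_vals)], float)
        cells = [f"a{i}" for i in range(len(a_vals))] + \
                [f"b{i}" for i in range(len(b_vals))]
        em = st.ExpressionMatrix(values, ["g1"], cells, ["D6"] * len(cells))
        return em, cells[:len(a_vals)], cells[len(a_vals):]

    def test_signal_to_noise_with_sd_floor(self):
        em, a, b = self._em_two_groups((3, 3, 3), (1, 1, 1))
        rl = st.rank_genes(em, a, b)
        assert rl.score[0] == pytest.approx(2.5)  # (3-1)/(0.6+0.2)

    def test_swapping_groups_negates_scores(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(20, 10))
        cells = [f"c{i}" for i in range(10)]
        em = st.ExpressionMatrix(values, [f"g{i}" for i in range(20)],
                                 cells, ["D6"] * 10)
        r_ab = st.rank_genes(em, cells[:5], cells[5:])
        r_ba = st.rank_genes(em, cells[5:], cells[:5])
        s_ab = dict(zip(r_ab.gene_ids, r_ab.score))
        s_ba = dict(zip(r_ba.gene_ids, r_ba.score))
        for g in s_ab:
            assert s_ab[g] == pytest.approx(-s_ba[g])

    def test_identical_gene_scores_zero(self):
        em, a, b = self._em_two_groups((2, 3, 4), (4, 3, 2))
        assert st.rank_genes(em, a, b).score[0] == pytest.approx(0.0)

    def test_small_group_rejected(self):
        em, a, b = self._em_two_groups((1, 2), (3, 4, 5))
        with pytest.raises(ValueError, match="3 cells"):
            st.rank_genes(em, a, b)


class TestEnrichmentScore:
    def test_positive_toy(self):
        es, peak, lead = st.enrichment_score(
            TOY, st.GeneSet("s", "", {"g1", "g3"}))
        assert es == pytest.approx(0.75)
        assert lead == frozenset({"g1"})

    def test_negative_toy(self):
        es, peak, lead = st.enrichment_score(
            TOY, st.GeneSet("s", "", {"g4", "g5"}))
        assert es == pytest.approx(-1.0)
        assert peak == 2
        assert lead == frozenset({"g4", "g5"})

    def test_set_equal_to_universe_rejected(self):
        full = st.GeneSet("s", "", set(TOY.gene_ids))
        with pytest.raises(ValueError, match="not all"):
            st.enrichment_score(TOY, full)

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            st.enrichment_score(TOY, st.GeneSet("s", "", {"zz"}))

    def test_running_sum_ends_at_zero(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            scores = -np.sort(-rng.normal(size=n))
            hit = np.zeros(n, bool)
            hit[rng.choice(n, size=int(rng.integers(1, n)), replace=False)] \
                = True
            run = _running_sum(scores, hit, 1.0)
            assert run[-1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(5, 50))
            scores = -np.sort(-rng.normal(size=n))
            rl = _ranked(scores)
            members = rng.choice(n, size=int(rng.integers(1, n)),
                                 replace=False)
            gs = st.GeneSet("s", "", {f"g{i + 1}" for i in members})
            hit = [i in set(members) for i in range(n)]
            for p in (0.0, 1.0, 1.5):
                es, _, _ = st.enrichment_score(rl, gs, p)
                assert es == pytest.approx(brute_force_es(scores, hit, p),
                                           abs=1e-12)

    def test_unweighted_equals_classic_ks(self):
        # p=0: running sum is the difference of hit/miss empirical CDFs
        rng = np.random.default_rng(4)
        n = 30
        scores = -np.sort(-rng.normal(size=n))
        members = {3, 7, 8, 15, 22}
        gs = st.GeneSet("s", "", {f"g{i + 1}" for i in members})
        es, _, _ = st.enrichment_score(_ranked(scores), gs, p_weight=0.0)
        hits = sorted(members)
        deltas = []
        for i in range(n):
            cdf_hit = sum(1 for h in hits if h <= i) / len(hits)
            cdf_miss = (i + 1 - sum(1 for h in hits if h <= i)) / (n - len(hits))
            deltas.append(cdf_hit - cdf_miss)
        expected = max(deltas, key=lambda v: (abs(v), v))
        assert es == pytest.approx(expected, abs=1e-12)

    def test_scale_invariances(self):
        rng = np.random.default_rng(5)
        scores = -np.sort(-np.abs(rng.normal(size=20)) - 0.1)
        gs = st.GeneSet("s", "", {"g2", "g5", "g11"})
        es0, _, _ = st.enrichment_score(_ranked(scores), gs, 0.0)
        es0b, _, _ = st.enrichment_score(_ranked(np.exp(scores)), gs, 0.0)
        assert es0 == pytest.approx(es0b)  # monotone rescaling, p = 0
        es1, _, _ = st.enrichment_score(_ranked(scores), gs, 1.0)
        es1b, _, _ = st.enrichment_score(_ranked(7.3 * scores), gs, 1.0)
        assert es1 == pytest.approx(es1b)  # positive scalar, p = 1


class TestGsea:
    def test_low_n_perm_rejected(self, null_dataset):
        em = st.normalize(null_dataset)
        gsc = st.GeneSetCollection("x", [
            st.GeneSet("s", "", set(null_dataset.gene_ids[:20]))])
        with pytest.raises(ValueError, match="n_perm"):
            st.gsea(em, em.cell_ids[:10], em.cell_ids[10:], gsc, n_perm=10)

    def test_small_group_falls_back_to_gene_set_mode(self, null_dataset):
        em = st.normalize(null_dataset)
        gsc = st.GeneSetCollection("x", [
            st.GeneSet("s", "", set(null_dataset.gene_ids[:20]))])
        with pytest.warns(UserWarning, match="gene_set"):
            st.gsea(em, em.cell_ids[:5], em.cell_ids[5:], gsc,
                    n_perm=100, mode="phenotype", seed=0)

    def test_deterministic_given_seed(self, null_dataset):
        em = st.normalize(null_dataset)
        gsc = st.GeneSetCollection("x", [
            st.GeneSet("s", "", set(null_dataset.gene_ids[:30])),
            st.GeneSet("t", "", set(null_dataset.gene_ids[30:80]))])
        a, b = em.cell_ids[:25], em.cell_ids[25:]
        r1 = st.gsea(em, a, b, gsc, n_perm=100, seed=11)
        r2 = st.gsea(em, a, b, gsc, n_perm=100, seed=11)
        for x, y in zip(r1, r2):
            assert (x.ES, x.NES, x.p_nominal, x.fdr_q) == \
                (y.ES, y.NES, y.p_nominal, y.fdr_q)

    def test_pairwise_antisymmetry_of_es(self, null_dataset):
        em = st.normalize(null_dataset)
        gsc = st.GeneSetCollection("x", [
            st.GeneSet("s", "", set(null_dataset.gene_ids[100:140]))])
        a, b = em.cell_ids[:25], em.cell_ids[25:]
        es_ab = st.gsea(em, a, b, gsc, n_perm=100, seed=1)[0].ES
        es_ba = st.gsea(em, b, a, gsc, n_perm=100, seed=1)[0].ES
        # enrichment toward A in A-vs-B appears as depletion in B-vs-A
        assert np.sign(es_ab) == -np.sign(es_ba)
        assert abs(abs(es_ab) - abs(es_ba)) < 0.15

    def test_size_filter_applied(self, null_dataset):
        em = st.normalize(null_dataset)
        gsc = st.GeneSetCollection("x", [
            st.GeneSet("small", "", set(null_dataset.gene_ids[:5])),
            st.GeneSet("ok", "", set(null_dataset.gene_ids[:40]))])
        res = st.gsea(em, em.cell_ids[:20], em.cell_ids[20:], gsc,
                      n_perm=100, seed=0)
        assert [r.set_name for r in res] == ["ok"]


class TestFilterEnriched:
    def _res(self, es, p, q):
        return st.EnrichmentResult("s", es, es, p, q, frozenset(), 10)

    def test_boundaries_are_strict(self):
        exactly_q = self._res(0.5, 0.001, 0.05)
        exactly_p = self._res(0.5, 0.01, 0.001)
        passing = self._res(0.5, 0.005, 0.04)
        out = st.filter_enriched([exactly_q, exactly_p, passing])
        assert out == [passing]

    def test_direction(self):
        neg = self._res(-0.6, 0.001, 0.01)
        assert st.filter_enriched([neg]) == []
        assert st.filter_enriched([neg], direction="negative") == [neg]

    def test_empty_input(self):
        assert st.filter_enriched([]) == []
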