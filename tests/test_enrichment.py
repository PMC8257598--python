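import numpy as np
import pandas as pd
import pytest

from oncostrat import (
    ExpressionMatrix,
    GeneSet,
    RankedList,
    compare_group_scores,
    enrichment_score,
    gsea_two_group,
    median_split,
    oncoactivity_scores,
    rank_by_group_metric,
    sample_enrichment,
)
from oncostrat.errors import DegenerateDataError
from oncostrat.simulate import HIGH, LOW, SimulationConfig, simulate_cohort
from oncostrat.stratify import StratificationResult

from conftest import random_matrix
from oracles import brute_running_sum, ranksum_exact_p


def _strat(samples, labels):
    return StratificationResult(
        label_of=pd.Series(labels, index=samples), cutoff=0.0, marker_gene="MK"
    )


class TestRankByGroupMetric:
    def test_up_in_high_gene_ranked_first(self, rng):
        m = random_matrix(rng, n_genes=10, n_samples=10)
        m.values.iloc[3, :5] += 50.0
        strat = _strat(m.samples, [HIGH] * 5 + [LOW] * 5)
        ranked = rank_by_group_metric(m, strat)
        assert ranked.genes[0] == m.genes[3]

    def test_label_swap_reverses_order(self, rng):
        m = random_matrix(rng, n_genes=30, n_samples=12)
        labels = [HIGH] * 6 + [LOW] * 6
        flipped = [LOW if l == HIGH else HIGH for l in labels]
        r1 = rank_by_group_metric(m, _strat(m.samples, labels))
        r2 = rank_by_group_metric(m, _strat(m.samples, flipped))
        np.testing.assert_allclose(r1.metric, -r2.metric[::-1], atol=1e-12)

    def test_matches_brute_force_metric(self, rng):
        m = random_matrix(rng, n_genes=100, n_samples=20)
        mask = np.array([True] * 10 + [False] * 10)
        strat = _strat(m.samples, np.where(mask, HIGH, LOW))
        ranked = rank_by_group_metric(m, strat)
        X = m.values.values
        expected = {}
        for g, row in zip(m.genes, X):
            a, b = row[mask], row[~mask]
            sa = max(a.std(ddof=1), 0.2 * abs(a.mean()), 0.2)
            sb = max(b.std(ddof=1), 0.2 * abs(b.mean()), 0.2)
            expected[g] = (a.mean() - b.mean()) / (sa + sb)
        order = sorted(m.genes, key=lambda g: (-expected[g], g))
        assert list(ranked.genes) == order
        np.testing.assert_allclose(
            ranked.metric, [expected[g] for g in order], atol=1e-12
        )


class TestEnrichmentScore:
    def test_single_member_at_top_scores_one(self):
        ranked = RankedList(genes=np.array(["A", "B", "C", "D"]),
                            metric=np.array([3.0, 2.0, 1.0, 0.5]))
        es, _ = enrichment_score(ranked, GeneSet("S", frozenset({"A"})), 1.0)
        assert es == 1.0

    def test_single_member_at_bottom_matches_oracle(self):
        genes = [f"G{i}" for i in range(10)]
        ranked = RankedList(genes=np.array(genes),
                            metric=np.linspace(5, 1, 10))
        gs = GeneSet("S", frozenset({genes[-1]}))
        es, running = enrichment_score(ranked, gs, 0.0)
        oracle_es, oracle_run = brute_running_sum(genes, ranked.metric,
                                                  gs.genes, 0.0)
        assert es == pytest.approx(oracle_es, abs=1e-12)
        np.testing.assert_allclose(running, oracle_run, atol=1e-12)
        # nine miss decrements of 1/9 precede the lone bottom-rank hit
        assert es == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("weight_exp", [0.0, 1.0])
    def test_matches_oracle_on_random_instances(self, weight_exp):
        """Implementation equals the brute-force running sum, 200 draws."""
        rng = np.random.default_rng(321)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            genes = [f"G{i}" for i in range(n)]
            metric = np.sort(rng.normal(0, 2, size=n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False))
            ranked = RankedList(genes=np.array(genes), metric=metric)
            es, running = enrichment_score(
                ranked, GeneSet("S", frozenset(members)), weight_exp
            )
            oracle_es, oracle_run = brute_running_sum(genes, metric, members,
                                                      weight_exp)
            assert es == pytest.approx(oracle_es, abs=1e-12)
            np.testing.assert_allclose(running, oracle_run, atol=1e-12)

    def test_no_overlap_rejected(self):
        ranked = RankedList(genes=np.array(["A", "B"]),
                            metric=np.array([1.0, 0.5]))
        with pytest.raises(DegenerateDataError, match="overlap"):
            enrichment_score(ranked, GeneSet("S", frozenset({"Z"})), 1.0)

    def test_full_overlap_rejected(self):
        ranked = RankedList(genes=np.array(["A", "B"]),
                            metric=np.array([1.0, 0.5]))
        with pytest.raises(DegenerateDataError, match="universe"):
            enrichment_score(ranked, GeneSet("S", frozenset({"A", "B"})), 1.0)


class TestGseaTwoGroup:
    def test_nominal_p_uniform_under_null(self):
        """Random sets on null cohorts give uniform nominal p (KS check)."""
        from scipy.stats import kstest

        pvals = []
        for i in range(100):
            rng = np.random.default_rng(500 + i)
            m = random_matrix(rng, n_genes=60, n_samples=12)
            strat = _strat(m.samples, [HIGH] * 6 + [LOW] * 6)
            gs = GeneSet("S", frozenset(rng.choice(m.genes, 10, replace=False)))
            r = gsea_two_group(m, strat, gs, n_perm=50, seed=i)
            pvals.append(r.p_nominal)
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_power_on_informative_set(self, default_cohort):
        d = default_cohort
        strat = median_split(d["expr"], "ESR1")
        truth = d["truth"]
        genes = sorted(truth.deg_up_in_high)[:30]
        r = gsea_two_group(d["expr"], strat, GeneSet("UP", frozenset(genes)),
                           n_perm=100, seed=1)
        assert r.es > 0
        assert r.p_nominal <= 0.05
        assert np.sign(r.nes) == np.sign(r.es)

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((10, 8)),
                          index=[f"G{i}" for i in range(10)],
                          columns=[f"s{i}" for i in range(8)])
        m = ExpressionMatrix(df)
        strat = _strat(m.samples, [HIGH] * 4 + [LOW] * 4)
        with pytest.raises(DegenerateDataError):
            gsea_two_group(m, strat, GeneSet("S", frozenset({"G1"})),
                           n_perm=20, seed=0)


class TestSampleEnrichment:
    def test_top_block_matches_oracle_maximum(self, rng):
        m = random_matrix(rng, n_genes=20, n_samples=4)
        target = m.samples[1]
        members = sorted(m.genes)[:5]
        m.values.loc[members, target] += 100.0
        es = sample_enrichment(m, GeneSet("S", frozenset(members)), 0.25)
        # oracle: ranks of the target sample with members on top
        order = np.lexsort((np.array(m.genes),
                            -m.values[target].values))
        genes_sorted = np.array(m.genes)[order]
        metric = np.arange(20, 0, -1).astype(float)
        oracle_es, _ = brute_running_sum(genes_sorted, metric, set(members),
                                         0.25)
        assert es[target] == pytest.approx(oracle_es, abs=1e-12)
        assert es[target] == max(es)

    def test_constant_shift_invariance(self, rng):
        m = random_matrix(rng, n_genes=30, n_samples=5)
        gs = GeneSet("S", frozenset(list(m.genes)[:7]))
        base = sample_enrichment(m, gs, 0.25)
        m.values[m.samples[2]] += 42.0
        shifted = sample_enrichment(m, gs, 0.25)
        np.testing.assert_allclose(base.values, shifted.values, atol=1e-12)

    def test_gene_order_invariance(self, rng):
        m = random_matrix(rng, n_genes=30, n_samples=5)
        gs = GeneSet("S", frozenset(list(m.genes)[:7]))
        base = sample_enrichment(m, gs, 0.25)
        perm = np.random.default_rng(1).permutation(30)
        m2 = ExpressionMatrix(m.values.iloc[perm].copy())
        permuted = sample_enrichment(m2, gs, 0.25)
        np.testing.assert_allclose(base.values, permuted.values, atol=1e-12)

    def test_monotone_transform_invariance_weight_zero(self, rng):
        m = random_matrix(rng, n_genes=30, n_samples=5)
        gs = GeneSet("S", frozenset(list(m.genes)[:7]))
        base = sample_enrichment(m, gs, 0.0)
        m2 = ExpressionMatrix(np.exp(m.values / 4.0))
        transformed = sample_enrichment(m2, gs, 0.0)
        np.testing.assert_allclose(base.values, transformed.values, atol=1e-12)


class TestOncoactivity:
    def test_identical_sets_score_zero(self, rng):
        m = random_matrix(rng)
        gs = GeneSet("S", frozenset(list(m.genes)[:10]))
        res = oncoactivity_scores(m, gs, gs)
        np.testing.assert_allclose(res.oncoactivity.values, 0.0, atol=1e-15)

    def test_set_swap_antisymmetry(self, rng):
        m = random_matrix(rng)
        a = GeneSet("A", frozenset(list(m.genes)[:10]))
        b = GeneSet("B", frozenset(list(m.genes)[15:30]))
        r1 = oncoactivity_scores(m, a, b)
        r2 = oncoactivity_scores(m, b, a)
        np.testing.assert_allclose(r1.oncoactivity.values,
                                   -r2.oncoactivity.values, atol=1e-15)

    def test_scores_bounded(self, default_cohort):
        d = default_cohort
        res = oncoactivity_scores(d["expr"], d["onco"], d["tsg"])
        assert (res.scores["es_onco"].abs() <= 1).all()
        assert (res.scores["es_tsg"].abs() <= 1).all()

    def test_low_subtype_scores_higher(self, default_cohort):
        d = default_cohort
        strat = median_split(d["expr"], "ESR1")
        res = oncoactivity_scores(d["expr"], d["onco"], d["tsg"])
        low = strat.label_of == LOW
        assert (res.oncoactivity[low.values].median()
                > res.oncoactivity[(~low).values].median())
        _, p = compare_group_scores(res.oncoactivity, strat)
        assert p < 0.01


class TestCompareGroupScores:
    def test_identical_distributions_p_one(self):
        scores = pd.Series([1.0] * 6, index=[f"s{i}" for i in range(6)])
        strat = _strat(scores.index, [HIGH] * 3 + [LOW] * 3)
        _, p = compare_group_scores(scores, strat)
        assert p == 1.0

    def test_exact_enumeration_small_groups(self):
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                           index=[f"s{i}" for i in range(6)])
        strat = _strat(scores.index, [HIGH] * 3 + [LOW] * 3)
        _, p = compare_group_scores(scores, strat)
        oracle = ranksum_exact_p([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(oracle, abs=1e-12)
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_strong_separation_tiny_p(self, rng):
        scores = pd.Series(
            np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)]),
            index=[f"s{i}" for i in range(100)],
        )
        strat = _strat(scores.index, [HIGH] * 50 + [LOW] * 50)
        _, p = compare_group_scores(scores, strat)
        assert p < 1e-6
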