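"""The three pathway statistics and their permutation nulls."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from pathpower import (
    SimulationDesign,
    gene_t_statistics,
    gsea_enrichment_score,
    hotelling_t2,
    pooled_covariance,
    shrinkage_precision,
    simulate_type2,
    sum_t_square,
)
from pathpower import test_pathways as run_pathway_tests
from pathpower.pathway_tests import (
    gene_label_permutation_p,
    sample_label_permutation_p,
)
from .conftest import make_grouped


class TestGeneT:
    def test_identical_groups_give_zero(self):
        x = np.tile(np.arange(6, dtype=float), (3, 1))
        data = make_grouped(np.hstack([x[:, :3], x[:, :3]]))
        assert np.allclose(gene_t_statistics(data), 0.0)

    def test_zero_variance_gene_warns_and_zeroes(self):
        values = np.array([[0.0, 0.0, 0.0, 1.0, 1.0, 1.0]])
        data = make_grouped(values, gene_ids=["flat"])
        with pytest.warns(RuntimeWarning, match="zero pooled variance"):
            t = gene_t_statistics(data)
        assert t[0] == 0.0

    def test_matches_scipy_pooled_t(self, rng):
        data = make_grouped(rng.standard_normal((10, 10)))
        t = gene_t_statistics(data)
        treat = data.treatment_mask
        expected = sps.ttest_ind(
            data.values[:, treat], data.values[:, ~treat], axis=1, equal_var=True
        ).statistic
        assert np.allclose(t, expected, atol=1e-12)


class TestSumTSquare:
    def test_simple_values(self):
        # t statistics (1, 2, 3) -> 14, checked through the public surface
        values = np.zeros((3, 4))
        data = make_grouped(values)
        # direct check of the composition property instead of stubbing
        full = make_grouped(np.random.default_rng(0).standard_normal((5, 8)))
        t = gene_t_statistics(full)
        genes = full.gene_ids[1:4]
        expected = float(np.sum(t[1:4] ** 2))
        assert sum_t_square(full, genes) == pytest.approx(expected, abs=1e-12)

    def test_empty_set_rejected(self, tiny_data):
        with pytest.raises(ValueError):
            sum_t_square(tiny_data, [])

    def test_gene_order_invariance(self, tiny_data):
        genes = tiny_data.gene_ids[:4]
        assert sum_t_square(tiny_data, genes) == pytest.approx(
            sum_t_square(tiny_data, genes[::-1]), abs=1e-12
        )


class TestPooledCovariance:
    def test_identical_groups(self, rng):
        half = rng.standard_normal((4, 6))
        data = make_grouped(np.hstack([half, half]))
        s = pooled_covariance(data, data.gene_ids)
        assert np.allclose(s, np.cov(half, ddof=1), atol=1e-12)

    def test_equal_sizes_average(self, rng):
        data = make_grouped(rng.standard_normal((5, 12)))
        treat = data.treatment_mask
        s1 = np.cov(data.values[:, ~treat], ddof=1)
        s2 = np.cov(data.values[:, treat], ddof=1)
        s = pooled_covariance(data, data.gene_ids)
        assert np.allclose(s, (s1 + s2) / 2, atol=1e-12)

    def test_direct_formula_oracle(self, rng):
        values = rng.standard_normal((3, 9))
        labels = np.asarray(["control"] * 4 + ["treatment"] * 5)
        from pathpower import GroupedExpression

        data = GroupedExpression(values, ["a", "b", "c"], labels)
        s = pooled_covariance(data, ["a", "b", "c"])
        s1 = np.cov(values[:, :4], ddof=1)
        s2 = np.cov(values[:, 4:], ddof=1)
        assert np.allclose(s, (3 * s1 + 4 * s2) / 7, atol=1e-12)


class TestShrinkage:
    def test_single_gene_precision(self, rng):
        data = make_grouped(rng.standard_normal((3, 20)))
        est = shrinkage_precision(data, data.gene_ids[:1])
        s = pooled_covariance(data, data.gene_ids[:1])
        assert est.precision[0, 0] == pytest.approx(1.0 / s[0, 0], abs=1e-12)

    def test_intensity_clipped_to_unit_interval(self, rng):
        data = make_grouped(rng.standard_normal((6, 8)))
        est = shrinkage_precision(data, data.gene_ids)
        assert 0.0 <= est.shrinkage_intensity <= 1.0

    def test_consistency_at_large_n(self, rng):
        # true covariance diagonal: precision should approach the inverse
        data = make_grouped(rng.standard_normal((10, 4000)))
        est = shrinkage_precision(data, data.gene_ids)
        s = pooled_covariance(data, data.gene_ids)
        true_inv = np.diag(1.0 / np.diag(s))
        assert np.max(np.abs(est.precision - true_inv)) < 0.05

    def test_constant_gene_raises(self):
        values = np.vstack([np.zeros(8), np.random.default_rng(1).standard_normal(8)])
        data = make_grouped(values, gene_ids=["flat", "ok"])
        with pytest.raises(ValueError, match="flat"):
            shrinkage_precision(data, ["flat", "ok"])


class TestHotelling:
    def test_equal_means_give_zero(self, rng):
        half = rng.standard_normal((4, 7))
        data = make_grouped(np.hstack([half, half]))
        assert hotelling_t2(data, data.gene_ids) == pytest.approx(0.0, abs=1e-20)

    def test_univariate_reduction_to_squared_t(self, rng):
        for _ in range(20):
            data = make_grouped(rng.standard_normal((1, 12)), gene_ids=["g"])
            t = gene_t_statistics(data)[0]
            t2 = hotelling_t2(data, ["g"], force_intensity=0.0)
            assert t2 == pytest.approx(t**2, abs=1e-10)

    def test_nonnegative(self, rng):
        data = make_grouped(rng.standard_normal((5, 10)))
        assert hotelling_t2(data, data.gene_ids) >= 0.0


class TestEnrichmentScore:
    def brute_force(self, stats, member, w):
        n = len(stats)
        nr = sum(abs(s) ** w for s, m in zip(stats, member) if m)
        nh = sum(member)
        best, run = 0.0, 0.0
        for s, m in zip(stats, member):
            run += abs(s) ** w / nr if m else -1.0 / (n - nh)
            if abs(run) > abs(best):
                best = run
        return best

    def test_full_membership_gives_one(self):
        stats = np.array([3.0, 2.0, 1.0])
        assert gsea_enrichment_score(stats, np.ones(3, bool), 1.0) == pytest.approx(1.0)

    def test_single_top_member_unweighted(self):
        stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        member = np.array([True, False, False, False, False])
        assert gsea_enrichment_score(stats, member, 0.0) == pytest.approx(1.0)

    def test_matches_brute_force_on_all_patterns(self):
        stats = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        for bits in range(1, 2**6 - 1):
            member = np.array([(bits >> k) & 1 == 1 for k in range(6)])
            es = gsea_enrichment_score(stats, member, 1.0)
            assert es == pytest.approx(self.brute_force(stats, member, 1.0), abs=1e-12)

    def test_all_zero_member_stats_rejected(self):
        stats = np.array([1.0, 0.0, 0.0])
        member = np.array([False, True, True])
        with pytest.raises(ValueError):
            gsea_enrichment_score(stats, member, 1.0)


class TestSampleLabelPermutation:
    def test_maximal_statistic_gives_minimal_p(self, rng):
        values = rng.standard_normal((4, 8))
        values[:, 4:] += 50.0  # observed split dominates every relabeling
        data = make_grouped(values)
        p = sample_label_permutation_p(data, data.gene_ids, sum_t_square, B=19, seed=1)
        assert p == pytest.approx(1.0 / 20.0)

    def test_constant_statistic_gives_one(self, tiny_data):
        p = sample_label_permutation_p(
            tiny_data, tiny_data.gene_ids, lambda d, gs: 1.0, B=25, seed=2
        )
        assert p == 1.0

    def test_matches_exhaustive_enumeration(self, rng):
        data = make_grouped(rng.standard_normal((5, 6)))
        p_exh = sample_label_permutation_p(
            data, data.gene_ids, sum_t_square, exhaustive=True
        )
        # independent oracle: enumerate all 20 treatment assignments directly
        observed = sum_t_square(data, data.gene_ids)
        from pathpower import GroupedExpression

        count = total = 0
        for combo in itertools.combinations(range(6), 3):
            labels = np.asarray(
                ["treatment" if i in combo else "control" for i in range(6)]
            )
            stat = sum_t_square(
                GroupedExpression(data.values, data.gene_ids, labels), data.gene_ids
            )
            total += 1
            count += stat >= observed - 1e-12
        assert p_exh == pytest.approx(count / total, abs=1e-12)
        p_rand = sample_label_permutation_p(
            data, data.gene_ids, sum_t_square, B=400, seed=3
        )
        assert p_rand == pytest.approx(p_exh, abs=0.07)


class TestGeneLabelPermutation:
    def test_top_set_minimal_p(self):
        stats = np.array([9.0, 8.0, 1.0, 0.5, 0.2])
        es = gsea_enrichment_score(
            np.sort(stats)[::-1], np.array([True, True, False, False, False]), 0.0
        )
        p = gene_label_permutation_p(stats, 2, es, B=50, seed=4, weight_exponent=0.0)
        assert p <= 0.3

    def test_exhaustive_matches_enumeration(self):
        stats = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        member = np.array([True, False, True, False, False])
        es = gsea_enrichment_score(stats, member, 1.0)
        p = gene_label_permutation_p(
            stats, 2, es, weight_exponent=1.0, exhaustive=True
        )
        # by-hand enumeration over the 10 subsets of size 2
        count = 0
        for combo in itertools.combinations(range(5), 2):
            mask = np.zeros(5, bool)
            mask[list(combo)] = True
            if abs(gsea_enrichment_score(stats, mask, 1.0)) >= abs(es) - 1e-12:
                count += 1
        assert p == pytest.approx((1 + count) / 11, abs=1e-12)

    def test_seed_reproducibility(self):
        stats = np.arange(1.0, 21.0)
        p1 = gene_label_permutation_p(stats, 5, 0.4, B=100, seed=7)
        p2 = gene_label_permutation_p(stats, 5, 0.4, B=100, seed=7)
        assert p1 == p2


class TestTestPathways:
    @pytest.fixture(scope="class")
    def null_data(self):
        design = SimulationDesign(sim_type="II", n_per_group=10, rho=0.0,
                                  detection_call=0.0, pathway_sizes=(8,),
                                  pathways_per_size=6, seed=20)
        return simulate_type2(design)

    @pytest.mark.parametrize("method", ["sum_t_square", "hotelling", "gsea"])
    def test_one_result_per_pathway_with_valid_p(self, null_data, method):
        expr, pws = null_data
        results = run_pathway_tests(expr, pws, method, B=10, seed=5)
        assert len(results) == len(pws)
        assert all(r.p_value >= 1 / 11 for r in results)
        assert {r.pathway for r in results} == set(pws.names)

    def test_pathway_order_invariance(self, null_data):
        expr, pws = null_data
        from pathpower import PathwayCollection

        reordered = PathwayCollection(list(pws)[::-1])
        a = {r.pathway: r.statistic for r in run_pathway_tests(expr, pws, "sumt2", B=5)}
        b = {r.pathway: r.statistic
             for r in run_pathway_tests(expr, reordered, "sumt2", B=5)}
        assert a == b

    def test_missing_gene_raises(self, null_data):
        expr, _ = null_data
        from pathpower import Pathway, PathwayCollection

        with pytest.raises(KeyError):
            run_pathway_tests(expr, PathwayCollection([Pathway("x", ["q1", "q2"])]),
                          "sumt2", B=5)

    def test_null_p_values_calibrated(self):
        """Under exchangeable null data the p-value distribution is ~uniform."""
        pvals = []
        for run in range(5):
            design = SimulationDesign(sim_type="II", n_per_group=8, rho=0.0,
                                      detection_call=0.0, pathway_sizes=(10,),
                                      pathways_per_size=100, seed=100 + run)
            expr, pws = simulate_type2(design)
            res = run_pathway_tests(expr, pws, "sum_t_square", B=99, seed=run)
            pvals.extend(r.p_value for r in res)
        d = sps.kstest(pvals, "uniform").statistic
        assert d < 0.1
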