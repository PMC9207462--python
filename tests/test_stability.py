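import numpy as np
import pandas as pd
import pytest

from oracles import delta_ct_bruteforce, genorm_bruteforce

from refstab import (
    AnalysisConfig,
    ValidationError,
    bestkeeper,
    cq_to_relative_quantity,
    delta_ct_stability,
    genorm,
    normfinder,
    run_all_methods,
    simulate_cq_experiment,
)
from conftest import make_cq, quantize_dyadic


class TestCqToRelativeQuantity:
    def test_doubling_definition(self):
        q = cq_to_relative_quantity(make_cq({"A": [20, 21, 22], "B": [20, 20, 20]}))
        np.testing.assert_allclose(q.q.loc["A"], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(q.q.loc["B"], [1.0, 1.0, 1.0])

    def test_non_doubling_efficiency(self):
        q = cq_to_relative_quantity(
            make_cq({"A": [20, 21, 22], "B": [20, 20, 20]}), efficiency=1.5)
        assert q.q.loc["A", "S2"] == pytest.approx(1 / 1.5, abs=1e-6)

    def test_missing_propagates(self):
        cq = make_cq({"A": [20, 21, 22, 23], "B": [25, 26, 27, 28]})
        cq.cq.loc["A", "S2"] = np.nan
        q = cq_to_relative_quantity(cq)
        assert np.isnan(q.q.loc["A", "S2"])
        assert q.q.loc["A"].max() == 1.0

    def test_efficiency_at_most_one_rejected(self):
        cq = make_cq({"A": [20, 21, 22], "B": [20, 20, 20]})
        with pytest.raises(ValidationError):
            cq_to_relative_quantity(cq, efficiency=1.0)

    def test_per_gene_efficiency_map(self):
        q = cq_to_relative_quantity(
            make_cq({"A": [20, 21, 22], "B": [20, 21, 20]}),
            efficiency={"A": 2.0, "B": 1.5})
        assert q.q.loc["B", "S2"] == pytest.approx(1 / 1.5)


class TestDeltaCt:
    def test_worked_three_gene_example(self, four_sample_cq):
        """Pairwise SDs 0, 1.1547, 1.1547 give stabilities .5774/.5774/1.1547."""
        res = delta_ct_stability(four_sample_cq)
        np.testing.assert_allclose(
            res.values[["A", "B", "C"]], [0.577350, 0.577350, 1.154701],
            atol=1e-6)
        assert res.extras["pairwise_sd"].loc["A", "B"] == 0.0

    def test_matches_bruteforce(self, four_sample_cq):
        res = delta_ct_stability(four_sample_cq)
        oracle = delta_ct_bruteforce(four_sample_cq.cq)
        for g, v in oracle.items():
            assert res.values[g] == pytest.approx(v, rel=1e-12)

    def test_constant_offset_pair_has_zero_stability(self):
        res = delta_ct_stability(make_cq({"A": [20, 22, 21], "B": [25, 27, 26]}))
        np.testing.assert_allclose(res.values, [0.0, 0.0], atol=1e-12)

    def test_sample_permutation_invariance(self, four_sample_cq):
        perm = four_sample_cq.subset_samples(["S3", "S1", "S4", "S2"])
        pd.testing.assert_frame_equal(
            delta_ct_stability(four_sample_cq).table,
            delta_ct_stability(perm).table)

    def test_fewer_than_two_genes_rejected(self):
        with pytest.raises(ValidationError):
            delta_ct_stability(make_cq({"A": [20, 21, 22]}))

    def test_sparse_pair_skipped_with_warning(self):
        # C and D overlap in one sample only: that pair is skipped, every
        # gene still keeps at least one usable partner
        cq = make_cq({"A": [20, 21, 22, 23, 24, 25],
                      "B": [25, 26, 27, 28, 29, 30],
                      "C": [21, 22, 23, 24, 25, 26],
                      "D": [22, 23, 24, 25, 26, 27]})
        cq.cq.loc["C", ["S1", "S2"]] = np.nan
        cq.cq.loc["D", ["S4", "S5", "S6"]] = np.nan
        with pytest.warns(UserWarning, match="common samples"):
            res = delta_ct_stability(cq)
        assert np.isnan(res.extras["pairwise_sd"].loc["C", "D"])
        assert np.isfinite(res.values).all()


class TestBestKeeper:
    def test_constant_gene_is_most_stable(self):
        res = bestkeeper(make_cq({"A": [25, 25, 25, 25], "B": [20, 22, 21, 23]}))
        assert res.values["A"] == 0.0
        assert res.ranks["A"] == 1.0

    def test_identical_genes_tie_and_correlate_with_index(self):
        res = bestkeeper(make_cq({"A": [24, 26, 25], "B": [24, 26, 25],
                                  "C": [20, 21, 20]}))
        assert res.ranks["A"] == res.ranks["B"]
        descr = res.extras["descriptives"]
        assert descr.loc["A", "r_index"] == pytest.approx(
            descr.loc["B", "r_index"])

    def test_descriptive_formulas(self):
        res = bestkeeper(make_cq({"A": [24, 26, 24, 26], "B": [20, 20, 20, 20]}))
        row = res.extras["descriptives"].loc["A"]
        assert row["mean"] == 25.0
        assert row["sd"] == pytest.approx(1.154701, abs=1e-6)
        assert row["cv_pct"] == pytest.approx(4.618802, abs=1e-6)
        assert row["min"] == 24.0 and row["max"] == 26.0

    def test_mad_variant_behind_flag(self):
        cq = make_cq({"A": [24, 26, 24, 26], "B": [20, 21, 20, 21]})
        res = bestkeeper(cq, use_mad=True)
        assert res.values["A"] == pytest.approx(1.0)  # mean |Cq - mean|

    def test_adding_unstable_gene_keeps_marginal_sd(self):
        base = bestkeeper(make_cq({"A": [24, 26, 25], "B": [20, 21, 20]}))
        ext = bestkeeper(make_cq({"A": [24, 26, 25], "B": [20, 21, 20],
                                  "Z": [15, 30, 22]}))
        for g in ("A", "B"):
            assert ext.values[g] == base.values[g]

    def test_incomplete_cases_dropped_and_counted(self):
        cq = make_cq({"A": [24, 26, 25, 24], "B": [20, 21, 20, 21]})
        cq.cq.loc["A", "S4"] = np.nan
        res = bestkeeper(cq)
        assert len(res.extras["index"]) == 3

    def test_too_few_complete_samples_rejected(self):
        cq = make_cq({"A": [24, 26, 25], "B": [20, 21, 20]})
        cq.cq.loc["A", "S1"] = np.nan
        with pytest.raises(ValidationError, match="complete-case"):
            bestkeeper(cq)


class TestGeNorm:
    def q_from(self, cq_dict):
        return cq_to_relative_quantity(make_cq(cq_dict))

    def test_worked_example_removal_and_ties(self):
        """A,B share log2 profile [0,-1,-2,-3]; C deviates -> M_C = 0.8165."""
        q = self.q_from({"A": [20, 21, 22, 23], "B": [25, 26, 27, 28],
                         "C": [20, 22, 21, 23]})
        res = genorm(q)
        m0 = res.extras["initial_m"]["m"]
        assert m0["A"] == pytest.approx(0.408248, abs=1e-6)
        assert m0["B"] == pytest.approx(0.408248, abs=1e-6)
        assert m0["C"] == pytest.approx(0.816497, abs=1e-6)
        assert res.values["C"] == pytest.approx(0.816497, abs=1e-6)
        assert res.ranks["C"] == 3.0
        assert res.ranks["A"] == res.ranks["B"] == 1.5
        # survivors report their final (pairwise) M
        assert res.values["A"] == pytest.approx(0.0, abs=1e-12)

    def test_proportional_genes_all_zero_m(self):
        q = self.q_from({"A": [20, 21, 23], "B": [25, 26, 28],
                         "C": [18, 19, 21]})
        res = genorm(q)
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)

    def test_constant_cq_shift_of_one_gene_leaves_its_m(self):
        base = self.q_from({"A": [20, 21, 22, 24], "B": [25, 26, 28, 27],
                            "C": [20, 23, 22, 25]})
        shifted = self.q_from({"A": [23, 24, 25, 27], "B": [25, 26, 28, 27],
                               "C": [20, 23, 22, 25]})
        np.testing.assert_allclose(genorm(base).values, genorm(shifted).values,
                                   atol=1e-12)

    def test_matches_bruteforce_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n_g = rng.integers(3, 7)
            n_s = rng.integers(3, 9)
            cq = {f"G{i}": (20 + rng.normal(0, 1.5, n_s)).tolist()
                  for i in range(n_g)}
            q = self.q_from(cq)
            res = genorm(q)
            val, rank = genorm_bruteforce(q.q)
            for g in q.gene_ids:
                assert res.values[g] == pytest.approx(val[g], rel=1e-9, abs=1e-12)
                assert res.ranks[g] == rank[g]

    def test_pairwise_variation_zero_for_proportional_genes(self):
        q = self.q_from({"A": [20, 21, 23], "B": [25, 26, 28],
                         "C": [18, 19, 21], "D": [22, 23, 25]})
        v = genorm(q).extras["pairwise_variation"]
        np.testing.assert_allclose(v["v"], 0.0, atol=1e-12)

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValidationError):
            genorm(self.q_from({"A": [20, 21, 22], "B": [25, 26, 27]}))


class TestNormFinder:
    def test_single_group_no_systematic_preference(self):
        """i.i.d. equal-variance genes earn equal stability on average."""
        top_counts = {g: 0 for g in ["GENE01", "GENE02", "GENE03", "GENE04"]}
        reps = 200
        for rep in range(reps):
            cq, _ = simulate_cq_experiment(
                4, groups=[12], sigma_profile=[0.3] * 4, seed=7000 + rep)
            q = cq_to_relative_quantity(cq)
            res = normfinder(q)
            top_counts[res.ranks.idxmin()] += 1
        freqs = np.array(list(top_counts.values())) / reps
        assert freqs.min() > 0.10 and freqs.max() < 0.45

    def test_noisy_gene_ranks_last_single_group(self):
        cq, _ = simulate_cq_experiment(
            3, groups=[20], sigma_profile=[0.05, 0.1, 0.5], seed=11)
        res = normfinder(cq_to_relative_quantity(cq))
        assert res.ranks["GENE03"] == 3.0

    def test_pure_group_shift_ranks_last(self):
        """A gene shifted +2 cycles in one group dominates intergroup d."""
        shift = np.zeros((4, 2))
        shift[3, 1] = 2.0
        cq, _ = simulate_cq_experiment(
            4, groups=[6, 6], sigma_profile=[0.0] * 4, shifts=shift, seed=3)
        res = normfinder(cq_to_relative_quantity(cq), groups=cq.groups)
        assert res.ranks["GENE04"] == 4.0
        d = res.extras["intergroup_d"]
        assert d.abs().loc["GENE04"].max() == d.abs().max().max()

    def test_small_group_rejected_by_name(self):
        cq, _ = simulate_cq_experiment(3, groups=[5, 1], seed=0)
        with pytest.raises(ValidationError, match="G2"):
            normfinder(cq_to_relative_quantity(cq), groups=cq.groups)

    def test_fewer_than_three_genes_rejected(self):
        cq, _ = simulate_cq_experiment(2, groups=[6], seed=0)
        with pytest.raises(ValidationError):
            normfinder(cq_to_relative_quantity(cq))


class TestCrossMethodProperties:
    def test_gene_permutation_invariance(self):
        cq, _ = simulate_cq_experiment(
            5, groups=[6, 6], sigma_profile=[0.1, 0.2, 0.3, 0.4, 0.5], seed=5)
        perm_genes = ["GENE03", "GENE01", "GENE05", "GENE02", "GENE04"]
        perm = cq.subset_genes(perm_genes)
        for method, res in run_all_methods(cq).items():
            res_p = run_all_methods(perm)[method]
            pd.testing.assert_frame_equal(res.table.sort_index(),
                                          res_p.table.sort_index())

    def test_loading_shift_cancels_bitwise(self):
        """delta-Ct and geNorm see only pairwise differences, so a per-sample
        constant on a dyadic grid cancels exactly."""
        cq, _ = simulate_cq_experiment(4, groups=[8], seed=9)
        base = make_cq({g: quantize_dyadic(cq.cq.loc[g]).tolist()
                        for g in cq.gene_ids})
        delta = quantize_dyadic(np.linspace(-2.0, 3.0, 8))
        shifted = make_cq({g: (base.cq.loc[g].to_numpy() + delta).tolist()
                           for g in base.gene_ids})
        assert (delta_ct_stability(base).values
                == delta_ct_stability(shifted).values).all()
        assert (genorm(cq_to_relative_quantity(base)).values
                == genorm(cq_to_relative_quantity(shifted)).values).all()

    def test_run_all_methods_returns_four_rankings(self):
        cq, _ = simulate_cq_experiment(4, groups=[4, 4], seed=1)
        results = run_all_methods(cq)
        assert sorted(results) == ["bestkeeper", "delta_ct", "genorm",
                                   "normfinder"]
        for res in results.values():
            assert sorted(res.table.index) == sorted(cq.gene_ids)
            assert res.ranks.min() >= 1.0
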