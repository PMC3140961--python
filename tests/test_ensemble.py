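import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

import mcam
from mcam.cluster_engine import MCA, ClusterConfig, ClusterSet
from mcam.ensemble import (
    CoOccurrenceMatrix,
    co_occurrence,
    co_occurrence_summary,
    compare_co_occurrence,
    extreme_differences,
    metric_overlap_bootstrap,
    mi_matrix,
    mutual_information,
    partition_entropy,
    peptide_centric_cluster,
    quartile_parameter_enrichment,
    rank_sets,
    robust_cluster_by_label,
    subset_mean_mi,
)


def make_dataset(n):
    return mcam.QuantDataset(
        [f"p{i}" for i in range(n)],
        ["A"] * n,
        ["Y"] * n,
        ["c1", "c2"],
        np.arange(2 * n, dtype=float).reshape(n, 2) + 1,
    )


def make_set(assignment, **kw):
    defaults = dict(transform="raw", distance="euclidean", algorithm="Hierarchical", K=None)
    defaults.update(kw)
    if defaults["K"] is None and defaults["algorithm"] != "AP":
        defaults["K"] = len(set(assignment))
    return ClusterSet(config=ClusterConfig(**defaults), assignment=np.asarray(assignment))


class TestMutualInformation:
    def test_self_mi_of_equal_halves_is_ln2(self):
        part = [1, 1, 2, 2]
        assert mutual_information(part, part) == pytest.approx(math.log(2))
        assert partition_entropy(part) == pytest.approx(math.log(2))

    def test_independent_splits_have_zero_mi(self):
        assert mutual_information([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(0.0, abs=1e-12)

    def test_hand_built_joint_table(self):
        # X={a,b,c}{d}, Y={a,b}{c,d}: joint p = [[1/2, 1/4], [0, 1/4]]
        expected = (
            0.5 * math.log(0.5 / (0.75 * 0.5))
            + 0.25 * math.log(0.25 / (0.75 * 0.5))
            + 0.25 * math.log(0.25 / (0.25 * 0.5))
        )
        assert mutual_information([1, 1, 1, 2], [1, 1, 2, 2]) == pytest.approx(expected)

    def test_cross_check_against_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.integers(1, 5, 30)
            b = rng.integers(1, 4, 30)
            assert mutual_information(a, b) == pytest.approx(mutual_info_score(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([1, 2], [1, 2, 3])


class TestMIMatrix:
    def test_identical_partitions_all_equal_entropy(self):
        part = [1, 1, 2, 2, 3, 3]
        mca = MCA([make_set(part) for _ in range(3)])
        M = mi_matrix(mca).values
        H = partition_entropy(part)
        np.testing.assert_allclose(M, H)

    def test_symmetry_and_bounds(self, planted_mca):
        mca, _ = planted_mca
        M = mi_matrix(mca).values
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        assert (M >= -1e-12).all()
        H = np.diag(M)
        pairwise_cap = np.minimum.outer(H, H)
        assert (M <= pairwise_cap + 1e-9).all()

    def test_subset_mean_mi_highest_for_shared_transform(self, planted_mca):
        mca, _ = planted_mca
        M = mcam.mi_matrix(mca)
        value = subset_mean_mi(mca, M, "transform", "raw")
        assert value > 0

    def test_subset_of_one_rejected(self):
        mca = MCA([make_set([1, 1, 2, 2]), make_set([1, 2, 1, 2], transform="zscore")])
        M = mi_matrix(mca)
        with pytest.raises(ValueError):
            subset_mean_mi(mca, M, "transform", "zscore")


def quartile_fixture():
    """8 sets; parameter value 'zscore' occupies exactly the top quartile."""
    configs = []
    for i in range(8):
        transform = "zscore" if i < 2 else "raw"
        configs.append(ClusterConfig(transform, "euclidean", "Hierarchical", K=2))
    rows = []
    for set_id in range(8):
        n_sig = 8 - set_id  # set 0 most enriched
        for j in range(n_sig):
            rows.append((set_id, "F", 1, f"lab{j}", 2, 2, 2, 8, 0.01, True))
    enr = pd.DataFrame(
        rows,
        columns=["set_id", "category", "cluster", "label", "k", "n", "K", "N", "p", "significant"],
    )
    return configs, enr


class TestQuartileAnalysis:
    def test_ranking_descending_with_id_ties(self):
        _, enr = quartile_fixture()
        assert rank_sets(enr, "F") == list(range(8))

    def test_top_quartile_enrichment_matches_enumeration(self):
        configs, enr = quartile_fixture()
        ranked = rank_sets(enr, "F")
        table = quartile_parameter_enrichment(ranked, configs)
        row = table[
            (table["axis"] == "transform") & (table["value"] == "zscore") & (table["quartile"] == "top")
        ].iloc[0]
        # both of the 2 zscore carriers fill the 2-set top quartile:
        # p = C(2,2)C(6,0)/C(8,2) = 1/28
        assert row["p"] == pytest.approx(1 / 28)

    def test_exclusive_top_quartile_parameter_significant(self):
        """12 sets, 3 'zscore' sets exactly filling the ceil(12/4)=3-set top
        quartile: p = 1/C(12,3) = 1/220, below the BH step-up threshold of
        its 10-test family."""
        configs = [
            ClusterConfig("zscore" if i < 3 else "raw", "euclidean", "Hierarchical", K=2)
            for i in range(12)
        ]
        rows = []
        for set_id in range(12):
            for j in range(12 - set_id):
                rows.append((set_id, "F", 1, f"lab{j}", 2, 2, 2, 8, 0.01, True))
        enr = pd.DataFrame(
            rows,
            columns=["set_id", "category", "cluster", "label", "k", "n", "K", "N", "p", "significant"],
        )
        table = quartile_parameter_enrichment(rank_sets(enr, "F"), configs)
        row = table[
            (table["axis"] == "transform") & (table["value"] == "zscore") & (table["quartile"] == "top")
        ].iloc[0]
        from math import comb

        assert row["p"] == pytest.approx(1 / comb(12, 3))
        assert bool(row["significant"])

    def test_uniformly_spread_parameter_not_significant(self):
        configs, enr = quartile_fixture()
        ranked = rank_sets(enr, "F")
        table = quartile_parameter_enrichment(ranked, configs)
        row = table[
            (table["axis"] == "distance") & (table["value"] == "euclidean") & (table["quartile"] == "top")
        ].iloc[0]
        assert row["p"] == 1.0 and not bool(row["significant"])

    def test_absent_category_rejected(self):
        _, enr = quartile_fixture()
        with pytest.raises(ValueError, match="absent"):
            rank_sets(enr, "nope")


class TestMetricOverlapBootstrap:
    def test_identical_rankings_positively_significant(self):
        ranked = list(range(100))
        out = metric_overlap_bootstrap(ranked, ranked, "top", seed=1)
        assert out["verdict"] == "pos_sig"
        assert out["observed"] == 25

    def test_null_mean_converges_to_hypergeometric_expectation(self):
        ranked = list(range(100))
        out = metric_overlap_bootstrap(ranked, ranked, "top", n_boot=4000, seed=2)
        assert out["null_mean"] == pytest.approx(25**2 / 100, rel=0.1)

    def test_disjoint_quartiles_negatively_significant(self):
        a = list(range(100))
        b = list(range(25, 100)) + list(range(25))  # a's top 25 at b's bottom
        out = metric_overlap_bootstrap(a, b, "top", seed=3)
        assert out["observed"] == 0
        assert out["verdict"] == "neg_sig"

    def test_independent_rankings_mostly_ns(self):
        rng = np.random.default_rng(4)
        base = list(range(40))
        verdicts = []
        for i in range(20):
            a = list(rng.permutation(base))
            b = list(rng.permutation(base))
            verdicts.append(metric_overlap_bootstrap(a, b, "top", seed=100 + i)["verdict"])
        assert verdicts.count("ns") >= 18  # >= 90%

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError):
            metric_overlap_bootstrap([0, 1, 2, 3], [0, 1, 2, 4])


class TestCoOccurrence:
    def test_identical_partitions_count_m(self):
        ds = make_dataset(4)
        mca = MCA([make_set([1, 1, 2, 2]) for _ in range(3)])
        co = co_occurrence(mca, ds)
        assert co.counts[0, 1] == 3 and co.freq[0, 1] == 1.0
        assert co.counts[0, 2] == 0
        np.testing.assert_array_equal(np.diag(co.counts), 3)

    def test_identical_mca_freq_is_co_membership_indicator(self):
        ds = make_dataset(6)
        part = [1, 1, 2, 2, 3, 3]
        mca = MCA([make_set(part) for _ in range(5)])
        co = co_occurrence(mca, ds)
        indicator = (np.asarray(part)[:, None] == np.asarray(part)[None, :]).astype(float)
        np.testing.assert_array_equal(co.freq, indicator)

    def test_pseudocount_heatmap_rule(self):
        ds = make_dataset(4)
        mca = MCA([make_set([1, 1, 2, 2]) for _ in range(3)])
        co = co_occurrence(mca, ds)
        hm = co.heatmap_values()
        assert hm[0, 2] == pytest.approx(np.log10(0.5 / 3))
        assert hm[0, 1] == pytest.approx(0.0)

    def test_symmetry(self, planted, planted_mca):
        _, dataset, _, _ = planted
        mca, _ = planted_mca
        co = co_occurrence(mca, dataset)
        np.testing.assert_array_equal(co.counts, co.counts.T)
        assert co.freq.min() >= 0 and co.freq.max() <= 1


class TestCoOccurrenceSummary:
    def test_77_peptides_have_2926_pairs(self):
        co = CoOccurrenceMatrix(
            counts=np.ones((77, 77), dtype=int), M=1, peptide_ids=[f"p{i}" for i in range(77)]
        )
        assert co_occurrence_summary(co)["n_pairs"] == 2926

    def test_majority_pair_percentage_arithmetic(self):
        # plant exactly 272 majority pairs among the 2,926
        counts = np.zeros((77, 77), dtype=int)
        iu = np.triu_indices(77, k=1)
        sel = (iu[0][:272], iu[1][:272])
        counts[sel] = 2
        counts += counts.T
        np.fill_diagonal(counts, 3)
        co = CoOccurrenceMatrix(counts=counts, M=3, peptide_ids=[f"p{i}" for i in range(77)])
        assert co_occurrence_summary(co)["pct_majority"] == 9.3

    def test_identical_mca_never_pairs_are_cross_cluster_pairs(self):
        ds = make_dataset(6)
        part = [1, 1, 2, 2, 3, 3]
        mca = MCA([make_set(part) for _ in range(4)])
        summary = co_occurrence_summary(co_occurrence(mca, ds))
        # 3 clusters of 2: within-pairs 3, total 15 -> 12 never co-cluster
        assert summary["n_never"] == 12
        assert summary["n_majority"] == 3


class TestRobustClusters:
    def test_threshold_inclusion_rule(self, planted, planted_mca):
        _, dataset, groups, _ = planted
        mca, enrichment = planted_mca
        group = robust_cluster_by_label(mca, enrichment, dataset, "F", "F:planted0")
        truth = {p for p, g in zip(dataset.peptide_ids, groups) if g == 0}
        recovered = len(group & truth) / len(truth)
        assert recovered >= 0.8

    def test_never_enriched_label_rejected(self, planted, planted_mca):
        _, dataset, _, _ = planted
        mca, enrichment = planted_mca
        with pytest.raises(ValueError, match="never enriched"):
            robust_cluster_by_label(mca, enrichment, dataset, "F", "no-such-label")

    def test_shrinks_with_threshold(self, planted, planted_mca):
        _, dataset, _, _ = planted
        mca, enrichment = planted_mca
        lo = robust_cluster_by_label(mca, enrichment, dataset, "F", "F:planted0", threshold=0.3)
        hi = robust_cluster_by_label(mca, enrichment, dataset, "F", "F:planted0", threshold=0.8)
        assert hi <= lo


class TestPeptideCentric:
    def make_co(self):
        freq = np.array(
            [
                [1.0, 0.6, 0.4],
                [0.6, 1.0, 0.2],
                [0.4, 0.2, 1.0],
            ]
        )
        return CoOccurrenceMatrix(
            counts=(freq * 10).astype(int), M=10, peptide_ids=["a", "b", "c"]
        )

    def test_threshold_selects_partners(self):
        co = self.make_co()
        assert peptide_centric_cluster(co, "a", 0.5) == {"a", "b"}

    def test_threshold_one_leaves_seed_alone(self):
        co = self.make_co()
        assert peptide_centric_cluster(co, "a", 1.0) == {"a"}

    def test_monotone_in_threshold(self):
        co = self.make_co()
        prev = None
        for t in (0.1, 0.3, 0.5, 0.7, 1.0):
            group = peptide_centric_cluster(co, "a", t)
            if prev is not None:
                assert group <= prev
            prev = group

    def test_unknown_peptide_rejected(self):
        with pytest.raises(KeyError):
            peptide_centric_cluster(self.make_co(), "zz")


class TestCrossDataset:
    def make_pair(self):
        rng = np.random.default_rng(0)
        n = 10
        counts = rng.integers(0, 11, size=(n, n))
        counts = np.triu(counts, 1)
        counts = counts + counts.T
        np.fill_diagonal(counts, 10)
        ids = [f"p{i}" for i in range(n)]
        a = CoOccurrenceMatrix(counts=counts, M=10, peptide_ids=ids)
        b = CoOccurrenceMatrix(counts=10 - counts, M=10, peptide_ids=ids)
        np.fill_diagonal(b.counts, 10)
        return a, b, ids

    def test_identical_matrices_correlate_perfectly(self):
        a, _, ids = self.make_pair()
        assert compare_co_occurrence(a, a, ids) == pytest.approx(1.0)

    def test_complementary_matrices_anticorrelate(self):
        a, b, ids = self.make_pair()
        assert compare_co_occurrence(a, b, ids) == pytest.approx(-1.0)

    def test_too_few_shared_rejected(self):
        a, b, ids = self.make_pair()
        with pytest.raises(ValueError):
            compare_co_occurrence(a, b, ids[:2])

    def test_extreme_difference_flagging(self):
        ids = ["x", "y", "z"]
        fa = np.array([[1.0, 0.8, 0.8], [0.8, 1.0, 0.0], [0.8, 0.0, 1.0]])
        fb = np.array([[1.0, 0.2, 0.3], [0.2, 1.0, 0.0], [0.3, 0.0, 1.0]])
        a = CoOccurrenceMatrix(counts=(fa * 10).astype(int), M=10, peptide_ids=ids)
        b = CoOccurrenceMatrix(counts=(fb * 10).astype(int), M=10, peptide_ids=ids)
        diffs = extreme_differences(a, b, ids)
        flagged = set(zip(diffs["peptide_1"], diffs["peptide_2"]))
        assert ("x", "y") in flagged  # 0.8 -> 0.2 crosses both bounds
        assert ("x", "z") not in flagged  # 0.8 -> 0.3 misses the low bound
        assert (diffs["direction"] == "a_to_b").all()
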