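import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import expr
from gbpal import (
    SubtypeSignature,
    assign_subtype,
    cluster_and_project,
    concordant_features,
    detect_degs,
    overlap_genes,
    rank_auc,
)
from helpers_oracle import auc_oracle, bh_oracle


def auc_frame(rows):
    """Minimal AUC-result frame: feature -> (auc, direction, significant)."""
    df = pd.DataFrame(rows, columns=["feature_id", "auc", "direction", "significant"])
    return df.set_index("feature_id")


class TestRankAUC:
    def test_hand_counted_pairs_with_ties(self):
        # pos {2,3,4} vs neg {1,2,3}: 6 wins + 2 ties of 9 pairs -> 7/9
        values = pd.DataFrame([[2, 3, 4, 1, 2, 3]], index=["f"])
        res = rank_auc(values, [True] * 3 + [False] * 3, threshold=0.7)
        assert res.loc["f", "auc"] == pytest.approx(7 / 9)
        assert res.loc["f", "direction"] == "up"
        assert bool(res.loc["f", "significant"])

    def test_identical_groups_score_half(self):
        values = pd.DataFrame([[5, 1, 3, 5, 1, 3]], index=["f"])
        res = rank_auc(values, [True] * 3 + [False] * 3)
        assert res.loc["f", "auc"] == pytest.approx(0.5)
        assert not bool(res.loc["f", "significant"])

    def test_perfect_separation(self):
        values = pd.DataFrame([[4, 5, 6, 1, 2, 3]], index=["f"])
        res = rank_auc(values, [True] * 3 + [False] * 3)
        assert res.loc["f", "auc"] == pytest.approx(1.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            rank_auc(pd.DataFrame([[1, 2]]), [True, True])

    def test_significance_is_two_sided(self):
        values = pd.DataFrame([[1, 2, 3, 7, 8, 9]], index=["f"])
        res = rank_auc(values, [True] * 3 + [False] * 3, threshold=0.7)
        assert res.loc["f", "auc"] == pytest.approx(0.0)
        assert bool(res.loc["f", "significant"])
        assert res.loc["f", "direction"] == "down"

    @settings(max_examples=200, deadline=None)
    @given(
        pos=st.lists(st.integers(0, 8), min_size=1, max_size=12),
        neg=st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_matches_brute_force_and_flip_antisymmetry(self, pos, neg):
        """Midrank AUC equals the all-pairs count with half-credit ties,
        and flipping the labels maps auc to 1 - auc exactly."""
        values = pd.DataFrame([pos + neg], index=["f"], dtype=float)
        labels = [True] * len(pos) + [False] * len(neg)
        res = rank_auc(values, labels)
        expected = auc_oracle(pos, neg)
        assert res.loc["f", "auc"] == pytest.approx(expected, abs=1e-12)
        flipped = rank_auc(values, [not l for l in labels])
        assert flipped.loc["f", "auc"] == pytest.approx(1 - expected, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(rng.normal(size=(5, 14)))
        labels = rng.random(14) < 0.5
        labels[:2], labels[-2:] = True, False
        base = rank_auc(values, labels)["auc"]
        mono = rank_auc(np.exp(values * 3) + 7, labels)["auc"]
        np.testing.assert_allclose(mono, base, atol=1e-12)


class TestDetectDEGs:
    def test_identical_groups_yield_no_calls(self):
        data = np.tile([[10.0, 20, 30, 10, 20, 30]], (5, 1)) + np.arange(5)[:, None]
        m = expr(np.column_stack([data, data]), normalized=True)
        res = detect_degs(m, [True] * 6 + [False] * 6)
        assert not res["significant"].any()

    def test_planted_gene_has_smallest_p(self):
        rng = np.random.default_rng(1)
        data = rng.normal(50, 5, size=(40, 20))
        data[7, :10] += 40.0
        m = expr(data, normalized=True)
        res = detect_degs(m, [True] * 10 + [False] * 10)
        assert res["p_value"].idxmin() == "g7"
        assert bool(res.loc["g7", "significant"])
        assert res.loc["g7", "log_fold_change"] > 0

    def test_bh_matches_hand_stepup(self):
        assert bh_oracle([0.01, 0.02, 0.03, 0.04]) == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )
        rng = np.random.default_rng(2)
        data = rng.normal(10, 1, size=(25, 12))
        m = expr(data, normalized=True)
        res = detect_degs(m, [True] * 6 + [False] * 6)
        np.testing.assert_allclose(
            res["fdr"], bh_oracle(list(res["p_value"])), rtol=1e-10
        )

    def test_small_class_rejected(self):
        m = expr(np.ones((3, 3)), normalized=True)
        with pytest.raises(ValueError, match=">= 2 samples"):
            detect_degs(m, [True, False, False])

    def test_type_one_error_control_under_null(self):
        """On exchangeable null data the fraction of genes called at
        FDR 0.05 stays at or below the nominal level."""
        rng = np.random.default_rng(3)
        m = expr(rng.lognormal(3, 1, size=(1000, 24)), normalized=True)
        res = detect_degs(m, [True] * 12 + [False] * 12, lfc_threshold=0.0)
        assert res["significant"].mean() <= 0.05 + 0.02


class TestConcordance:
    def test_identical_sets_share_everything(self):
        a = auc_frame([("f1", 0.9, "up", True), ("f2", 0.2, "down", True),
                       ("f3", 0.55, "up", False)])
        shared, counts = concordant_features(a, a.copy())
        assert shared == ["f1", "f2"]
        assert counts == {"a_only": 0, "b_only": 0, "shared": 2}

    def test_direction_mismatch_excluded(self):
        a = auc_frame([("f1", 0.9, "up", True)])
        b = auc_frame([("f1", 0.1, "down", True)])
        shared, counts = concordant_features(a, b)
        assert shared == []
        assert counts["shared"] == 0

    def test_disjoint_significant_sets(self):
        a = auc_frame([("f1", 0.9, "up", True), ("f2", 0.5, "up", False)])
        b = auc_frame([("f2", 0.8, "up", True), ("f1", 0.5, "up", False)])
        shared, counts = concordant_features(a, b)
        assert shared == []
        assert counts == {"a_only": 1, "b_only": 1, "shared": 0}


class TestOverlapGenes:
    def deg_frame(self, rows):
        df = pd.DataFrame(rows, columns=["gene_id", "log_fold_change", "significant"])
        return df.set_index("gene_id")

    def test_identity_and_sign_rules(self):
        a = self.deg_frame([("g1", 1.0, True), ("g2", -1.0, True), ("g3", 1.0, False)])
        same = overlap_genes(a, a.copy())
        assert same == {"g1", "g2"}
        flipped = self.deg_frame([("g1", -1.0, True), ("g2", -2.0, True)])
        assert overlap_genes(a, flipped) == {"g2"}
        empty = self.deg_frame([("g9", 1.0, True)])
        assert overlap_genes(a, empty) == set()


class TestSubtype:
    def signatures(self, n=12):
        a = [f"pa{i}" for i in range(n)]
        b = [f"mb{i}" for i in range(n)]
        return [SubtypeSignature("Proneural", a), SubtypeSignature("Mesenchymal", b)]

    def test_sample_equal_to_centroid_recovers_label(self):
        sigs = self.signatures()
        genes = sigs[0].signature_genes + sigs[1].signature_genes
        values = np.array([[1.0] * 12 + [0.0] * 12]).T
        m = expr(values, genes=genes, samples=["s"], normalized=True)
        assert assign_subtype(m, sigs).loc["s"] == "Proneural"

    def test_equidistant_sample_unclassified(self):
        sigs = self.signatures()
        genes = sigs[0].signature_genes + sigs[1].signature_genes
        values = np.array([[0.5] * 24]).T  # constant: correlation undefined
        m = expr(values, genes=genes, samples=["s"], normalized=True)
        assert assign_subtype(m, sigs).loc["s"] == "unclassified"

    def test_planted_signal_beats_other_centroid(self):
        rng = np.random.default_rng(4)
        sigs = self.signatures()
        genes = sigs[0].signature_genes + sigs[1].signature_genes
        values = rng.normal(5, 0.5, size=(24, 1))
        values[:12, 0] += 2.0  # elevate the Proneural genes
        m = expr(values, genes=genes, samples=["s"], normalized=True)
        assert assign_subtype(m, sigs).loc["s"] == "Proneural"

    def test_insufficient_signature_coverage_rejected(self):
        sigs = self.signatures(n=4)
        genes = sigs[0].signature_genes + sigs[1].signature_genes
        m = expr(np.ones((8, 1)), genes=genes, samples=["s"], normalized=True)
        with pytest.raises(ValueError, match="only 4 genes"):
            assign_subtype(m, sigs)

    def test_planted_labels_recovered_on_cohort(self):
        """Nearest-centroid assignment recovers planted subtype labels at
        >= 95% accuracy when signature genes are shifted by 1 ln-unit over
        noise sigma = 0.5."""
        rng = np.random.default_rng(5)
        sigs = self.signatures(n=20)
        genes = sigs[0].signature_genes + sigs[1].signature_genes + [
            f"bg{i}" for i in range(60)
        ]
        n_samples = 60
        truth = rng.integers(0, 2, n_samples)
        base = rng.normal(5, 0.5, size=(len(genes), n_samples))
        for j, t in enumerate(truth):
            block = slice(0, 20) if t == 0 else slice(20, 40)
            base[block, j] += 1.0
        m = expr(base, genes=genes, normalized=True)
        labels = assign_subtype(m, sigs)
        expected = np.where(truth == 0, "Proneural", "Mesenchymal")
        assert (labels.to_numpy() == expected).mean() >= 0.95


class TestClusterAndProject:
    def test_planted_clusters_split_at_top(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, size=(30, 6))
        b = rng.normal(4, 0.3, size=(30, 6))
        values = pd.DataFrame(
            np.column_stack([a, b]), columns=[f"s{i}" for i in range(12)]
        )
        out = cluster_and_project(values)
        order = out["leaf_order"]
        first_half = {order[i] for i in range(6)}
        assert first_half in ({f"s{i}" for i in range(6)},
                              {f"s{i}" for i in range(6, 12)})

    def test_duplicated_sample_merges_at_zero_distance(self):
        rng = np.random.default_rng(7)
        values = pd.DataFrame(rng.normal(size=(10, 4)))
        values[4] = values[3]
        out = cluster_and_project(values)
        assert out["linkage"][0, 2] == pytest.approx(0.0)
        assert {int(out["linkage"][0, 0]), int(out["linkage"][0, 1])} == {3, 4}

    def test_variance_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(8)
        values = pd.DataFrame(rng.normal(size=(20, 8)))
        out = cluster_and_project(values)
        assert out["variance_pct"].sum() == pytest.approx(100.0)
        assert out["pc_scores"].shape == (8, 2)
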