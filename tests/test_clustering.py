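"""UPGMA, gap-statistic model selection, recursive partitioning,
consensus and PCA ordination."""

import numpy as np
import pandas as pd
import pytest

from numobat import clustering as cl


def _dist(points):
    from scipy.spatial.distance import pdist, squareform

    return squareform(pdist(np.asarray(points, dtype=float)))


class TestUPGMA:
    def test_hand_computed_three_point_tree(self):
        # d(a,b)=1, d(a,c)=d(b,c)=4: (a,b) merge at height 1, c joins at 4
        D = np.array([[0, 1, 4], [1, 0, 4], [4, 4, 0]], dtype=float)
        dendro = cl.upgma(D, ids=["a", "b", "c"])
        heights = sorted(dendro.linkage_matrix[:, 2])
        assert heights == pytest.approx([1.0, 4.0])
        coph = dendro.cophenetic()
        assert coph.loc["a", "b"] == pytest.approx(1.0)
        assert coph.loc["a", "c"] == pytest.approx(4.0)

    def test_identical_rows_merge_at_zero(self):
        D = _dist([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]])
        dendro = cl.upgma(D)
        assert dendro.linkage_matrix[:, 2].min() == pytest.approx(0.0)

    def test_cophenetic_is_ultrametric(self, rng):
        X = rng.normal(size=(12, 4))
        coph = cl.upgma(_dist(X)).cophenetic().to_numpy()
        n = len(coph)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9

    def test_newick_export_parses_and_preserves_leaves(self, rng):
        import io

        from Bio import Phylo

        X = rng.normal(size=(6, 3))
        ids = [f"nest{i}" for i in range(6)]
        nwk = cl.upgma(_dist(X), ids=ids).to_newick()
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(ids)

    def test_asymmetric_and_nan_rejected(self):
        bad = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            cl.upgma(bad)
        with pytest.raises(ValueError):
            cl.upgma(np.array([[0.0, np.nan], [np.nan, 0.0]]))


class TestGapSelectK:
    def test_two_separated_clusters(self):
        hits = 0
        for s in range(10):
            r = np.random.default_rng(s)
            X = np.vstack([r.normal(0, 1, (20, 3)), r.normal(10, 1, (20, 3))])
            k, _ = cl.gap_select_k(X, kmax=6, B=50, engine="kmeans", rng=s)
            hits += k == 2
        assert hits >= 9  # ≥95% nominal; 10 seeds

    def test_single_gaussian_cloud(self):
        hits = 0
        for s in range(10):
            X = np.random.default_rng(100 + s).normal(0, 1, (40, 3))
            k, _ = cl.gap_select_k(X, kmax=6, B=50, engine="kmeans", rng=s)
            hits += k == 1
        assert hits >= 6  # majority

    def test_degenerate_identical_rows(self):
        X = np.ones((10, 3))
        k, _ = cl.gap_select_k(X, kmax=4, B=10, engine="kmeans", rng=0)
        assert k == 1

    def test_hierarchical_engine_agrees_on_clear_structure(self):
        r = np.random.default_rng(5)
        X = np.vstack([r.normal(0, 1, (15, 3)), r.normal(12, 1, (15, 3))])
        k, _ = cl.gap_select_k(X, kmax=5, B=50, engine="hierarchical", rng=1)
        assert k == 2

    def test_config_guards(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError):
            cl.gap_select_k(X, kmax=1, B=10)
        with pytest.raises(ValueError):
            cl.gap_select_k(X, kmax=3, B=0)


class TestPart:
    def test_recovers_well_separated_clusters(self):
        r = np.random.default_rng(42)
        centers = r.normal(0, 30, (6, 5))
        X = np.vstack([c + r.normal(0, 1, (10, 5)) for c in centers])
        p = cl.part(X, engine="kmeans", B=50, min_size=5, seed=1)
        assert p.k == 6
        assert (p.labels != 0).all()
        truth = np.repeat(np.arange(6), 10)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, p.labels) == 1.0

    def test_min_size_limits_cluster_count(self):
        X = np.random.default_rng(0).normal(size=(9, 3))
        p = cl.part(X, engine="kmeans", B=20, min_size=5, seed=0)
        assert p.k <= 1

    def test_no_cluster_below_min_size(self):
        r = np.random.default_rng(3)
        X = np.vstack([r.normal(0, 1, (12, 3)), r.normal(8, 1, (7, 3)),
                       r.normal(-9, 1, (3, 3))])
        p = cl.part(X, engine="kmeans", B=50, min_size=5, seed=2)
        counts = p.labels[p.labels != 0].value_counts()
        assert (counts >= 5).all()

    def test_row_order_invariance(self):
        r = np.random.default_rng(9)
        X = np.vstack([r.normal(0, 1, (10, 4)), r.normal(10, 1, (10, 4))])
        ids = [f"s{i}" for i in range(20)]
        p1 = cl.part(pd.DataFrame(X, index=ids), engine="kmeans", B=30, seed=5)
        perm = np.random.default_rng(1).permutation(20)
        p2 = cl.part(pd.DataFrame(X[perm], index=np.array(ids)[perm]),
                     engine="kmeans", B=30, seed=5)
        from sklearn.metrics import adjusted_rand_score

        joined = pd.concat([p1.labels.rename("a"), p2.labels.rename("b")], axis=1)
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_kmax_guard(self):
        with pytest.raises(ValueError):
            cl.part(np.zeros((10, 2)), kmax=1)


class TestConsensus:
    def _partition(self, labels, engine="kmeans"):
        s = pd.Series(labels, index=[f"n{i}" for i in range(len(labels))])
        k = len(set(labels) - {0})
        return cl.PartitionResult(engine, s, k, 10, 5, 0)

    def test_self_consensus_always_accepted(self):
        a = self._partition([1, 1, 2, 2, 2, 1])
        v = cl.consensus(a, a)
        assert v.accepted and v.ari == 1.0

    def test_permuted_labels_accepted(self):
        a = self._partition([1, 1, 2, 2, 3, 3], "hierarchical")
        b = self._partition([3, 3, 1, 1, 2, 2])
        v = cl.consensus(a, b)
        assert v.accepted and v.ari == 1.0
        # merged labels come from the hierarchical engine
        assert (v.merged_labels == a.labels).all()

    def test_different_k_rejected(self):
        a = self._partition([1, 1, 1, 2, 2, 2])
        b = self._partition([1, 1, 2, 2, 3, 3])
        assert not cl.consensus(a, b).accepted

    def test_equal_k_but_different_partition_rejected_in_strict_mode(self):
        # brute-force check over every relabeling: these two 2-cluster
        # partitions of 6 samples differ as set partitions
        a = self._partition([1, 1, 1, 2, 2, 2])
        b = self._partition([1, 1, 2, 2, 1, 2])
        v = cl.consensus(a, b, strict=True)
        assert not v.accepted and v.ari < 1.0

    def test_id_mismatch_is_error(self):
        a = self._partition([1, 1, 2, 2, 2])
        b = cl.PartitionResult(
            "kmeans", pd.Series([1, 1, 2, 2, 2], index=list("vwxyz")), 2, 10, 5, 0
        )
        with pytest.raises(ValueError):
            cl.consensus(a, b)

    def test_outliers_excluded_from_agreement(self):
        a = self._partition([0, 1, 1, 1, 2, 2, 2], "hierarchical")
        b = self._partition([1, 1, 1, 1, 2, 2, 2])
        v = cl.consensus(a, b)
        assert v.accepted  # sample 0 is an outlier in a; ignored


class TestPCAOrdination:
    def test_variance_ordering_and_centering(self, rng):
        base = rng.normal(size=(40, 1))
        X = pd.DataFrame(
            np.hstack([base * 3, base * 1.5 + rng.normal(0, 0.1, (40, 1))]),
            columns=["a", "b"],
        )
        ord_ = cl.pca_ordination(X, n_components=2)
        evr = ord_.explained_variance_ratio
        assert evr[0] >= evr[1]
        mean_point = pd.DataFrame([X.mean()], index=["m"])
        assert np.allclose(ord_.transform(mean_point), 0, atol=1e-10)

    def test_peripheral_point_flagged(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        ord_ = cl.pca_ordination(X, n_components=2)
        far = pd.DataFrame([X.mean() + 30 * X.std()], index=["type_specimen"])
        near = pd.DataFrame([X.mean()], index=["typical"])
        report = ord_.peripheral_report(pd.concat([far, near]))
        assert bool(report.loc["type_specimen", "peripheral"])
        assert not bool(report.loc["typical", "peripheral"])

    def test_rank_deficient_truncates_with_warning(self, rng):
        col = rng.normal(size=40)
        X = pd.DataFrame({"a": col, "b": 2 * col, "c": -col})
        with pytest.warns(UserWarning, match="rank-deficient"):
            ord_ = cl.pca_ordination(X, n_components=3)
        assert ord_.scores.shape[1] == 1
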