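"""PCA embedding, optimal-k voting, k-means, and detection."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import blob_embedding

from coevoclust.autocluster import (
    ClusterResult,
    DistanceMatrixClusterer,
    Embedding,
    PipelineConfig,
    cluster_table,
    detected_genes,
    index_votes,
    kmeans_cluster,
    optimal_k,
    pca_scores,
    predict_clusters,
)
from coevoclust.treedist import DistanceMatrixSet


def block_matrix(sizes=(3, 3), within=0.1, between=0.9):
    d = sum(sizes)
    m = np.full((d, d), between)
    start = 0
    for s in sizes:
        m[start:start + s, start:start + s] = within
        start += s
    np.fill_diagonal(m, 0.0)
    return m


class TestPcaScores:
    def test_identical_rows_give_zero_scores(self):
        m = np.full((5, 5), 0.3)
        np.fill_diagonal(m, 0.0)
        m = np.full((5, 5), 0.0)  # strictly identical rows
        emb = pca_scores(m)
        assert np.allclose(emb.scores, 0.0)
        assert np.allclose(emb.variance_explained, 0.0)

    def test_two_blocks_separate_on_pc1(self):
        emb = pca_scores(block_matrix((3, 3)))
        pc1 = emb.scores[:, 0]
        assert np.sign(pc1[:3]).min() != np.sign(pc1[3:]).max() or (
            np.all(pc1[:3] * pc1[3:].mean() < 0)
        )
        assert set(np.sign(pc1[:3])) != set(np.sign(pc1[3:]))

    def test_variance_explained_non_increasing(self):
        rng = np.random.default_rng(0)
        a = rng.random((8, 8))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 0)
        ve = pca_scores(m).variance_explained
        assert all(x >= y for x, y in zip(ve, ve[1:]))
        assert ve.sum() <= 1.0 + 1e-12

    def test_scores_column_centred(self):
        m = block_matrix((4, 3))
        emb = pca_scores(m)
        assert np.allclose(emb.scores.mean(axis=0), 0.0, atol=1e-12)

    def test_sign_convention_deterministic(self):
        m = block_matrix((4, 3))
        a = pca_scores(m).scores
        b = pca_scores(m).scores
        assert np.array_equal(a, b)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            pca_scores(np.zeros((2, 2)))

    def test_na_imputed_by_column_mean(self):
        m = block_matrix((3, 3))
        m[0, 5] = m[5, 0] = np.nan
        emb = pca_scores(m)
        assert np.all(np.isfinite(emb.scores))


class TestIndexVotes:
    def test_clean_blobs_supermajority_for_three(self):
        emb, _ = blob_embedding(seed=1)
        votes = index_votes(emb, 2, 5)
        assert len(votes) >= 15  # nearly full electorate participates
        frac3 = sum(1 for v in votes.values() if v == 3) / len(votes)
        assert frac3 >= 0.8

    def test_kmax_capped_for_small_d(self):
        emb = Embedding(
            gene_ids=list("abcd"),
            scores=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0.5]], float),
            variance_explained=np.array([0.6, 0.3, 0.1]),
        )
        votes = index_votes(emb, 2, 5)  # capped to [2, 3]
        assert set(votes.values()) <= {2, 3}

    def test_degenerate_geometry_all_abstain(self):
        emb = Embedding(
            gene_ids=[f"g{i}" for i in range(6)],
            scores=np.zeros((6, 3)),
            variance_explained=np.zeros(3),
        )
        assert index_votes(emb, 2, 5) == {}


class TestOptimalK:
    def test_majority(self):
        assert optimal_k({"a": 3, "b": 3, "c": 3, "d": 2}) == 3

    def test_tie_breaks_to_smaller_k(self):
        assert optimal_k({"a": 2, "b": 2, "c": 3, "d": 3}) == 2

    def test_empty_votes_signal_failure(self):
        assert optimal_k({}) is None


class TestKMeans:
    def test_k1_single_cluster(self):
        emb, _ = blob_embedding(seed=2)
        res = kmeans_cluster(emb, 1, seed=0)
        assert set(res.assignment.values()) == {1}

    def test_blob_recovery_ari_one(self):
        emb, truth = blob_embedding(seed=3)
        res = kmeans_cluster(emb, 3, seed=0)
        labels = [res.assignment[g] for g in emb.gene_ids]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_given_seed(self):
        emb, _ = blob_embedding(seed=4)
        r1 = kmeans_cluster(emb, 3, seed=11)
        r2 = kmeans_cluster(emb, 3, seed=11)
        assert r1.assignment == r2.assignment

    def test_k_out_of_range_rejected(self):
        emb, _ = blob_embedding(seed=5)
        with pytest.raises(ValueError):
            kmeans_cluster(emb, 30, seed=0)


class TestEstimator:
    def test_fit_attributes_and_sklearn_api(self):
        est = DistanceMatrixClusterer(random_state=0)
        m = block_matrix((4, 4, 4), within=0.05, between=0.95)
        est.fit(m)
        assert est.labels_.shape == (12,)
        assert est.k_ == len(set(est.labels_))
        assert est.method_ in ("predicted", "fallback3")
        assert est.embedding_.shape == (12, 3)
        params = est.get_params()
        assert params["k_max"] == 5
        est.set_params(k_max=4)
        assert est.get_params()["k_max"] == 4

    def test_fit_predict_matches_labels(self):
        m = block_matrix((4, 4), within=0.05, between=0.95)
        est = DistanceMatrixClusterer(random_state=1)
        labels = est.fit_predict(m)
        assert np.array_equal(labels, est.labels_)

    def test_degenerate_matrix_falls_back(self):
        m = np.zeros((6, 6))
        est = DistanceMatrixClusterer(fallback_k=3, random_state=0).fit(m)
        assert est.method_ == "fallback3"
        assert est.k_ == 3


class TestPredictClusters:
    def make_set(self, strict, evo=None):
        d = strict.shape[0]
        return DistanceMatrixSet(
            gene_ids=[f"g{i}" for i in range(d)],
            strict=strict,
            evolutionary=evo if evo is not None else strict.copy(),
        )

    def test_two_block_matrix_predicted(self):
        mats = self.make_set(block_matrix((4, 4), within=0.05, between=0.95))
        rs, rc = predict_clusters(mats, PipelineConfig(seed=0))
        assert rs.source == "strict" and rc.source == "combined"
        assert rs.method == "predicted"
        # blocks end up in distinct clusters
        labs = [rs.assignment[f"g{i}"] for i in range(8)]
        assert len(set(labs[:4])) == 1 and len(set(labs[4:])) == 1
        assert labs[0] != labs[4]

    def test_degenerate_matrix_uses_fallback_three(self):
        mats = self.make_set(np.zeros((6, 6)))
        rs, rc = predict_clusters(mats, PipelineConfig(seed=0))
        assert rs.method == "fallback3" and rc.method == "fallback3"
        assert rs.k == 3

    def test_small_d_fallback_capped(self):
        mats = self.make_set(np.zeros((4, 4)))
        rs, _ = predict_clusters(mats, PipelineConfig(seed=0))
        assert rs.k == 3  # min(3, d-1) with d=4

    def test_too_few_genes_rejected(self):
        mats = self.make_set(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            predict_clusters(mats, PipelineConfig(seed=0))

    def test_bit_reproducible(self):
        m = block_matrix((5, 4), within=0.1, between=0.8)
        mats1 = self.make_set(m)
        mats2 = self.make_set(m.copy())
        cfg = PipelineConfig(seed=7)
        r1 = predict_clusters(mats1, cfg)
        r2 = predict_clusters(mats2, cfg)
        for a, b in zip(r1, r2):
            assert a.assignment == b.assignment
            assert a.k == b.k and a.votes == b.votes


class TestDetectedGenes:
    def res(self, assignment, source="strict"):
        return ClusterResult(
            source=source, k=len(set(assignment.values())),
            assignment=assignment, votes={}, method="predicted",
        )

    def test_core_cluster_members_detected(self):
        r = self.res({"core": 1, "g1": 1, "g2": 1, "g3": 2})
        assert detected_genes(r, {"core"}) == {"g1", "g2"}

    def test_single_cluster_detects_everything(self):
        r = self.res({"core": 1, "g1": 1, "g2": 1})
        assert detected_genes(r, {"core"}) == {"g1", "g2"}

    def test_two_cores_in_different_clusters(self):
        r = self.res({"c1": 1, "c2": 2, "g1": 1, "g2": 2, "g3": 3})
        assert detected_genes(r, {"c1", "c2"}) == {"g1", "g2"}

    def test_unknown_core_rejected(self):
        r = self.res({"g1": 1})
        with pytest.raises(ValueError, match="unknown core"):
            detected_genes(r, {"nope"})

    def test_aggregations(self):
        rs = self.res({"core": 1, "a": 1, "b": 2}, source="strict")
        rc = self.res({"core": 1, "a": 2, "b": 1}, source="combined")
        assert detected_genes([rs, rc], {"core"}, "union") == {"a", "b"}
        assert detected_genes([rs, rc], {"core"}, "intersection") == set()
        assert detected_genes([rs, rc], {"core"}, "strict") == {"a"}
        assert detected_genes([rs, rc], {"core"}, "combined") == {"b"}


def test_cluster_table_shape():
    r1 = ClusterResult("strict", 2, {"a": 1, "b": 2}, {}, "predicted")
    r2 = ClusterResult("combined", 2, {"a": 1, "b": 1}, {}, "predicted")
    df = cluster_table([r1, r2])
    assert list(df.columns) == ["gene_id", "source_matrix", "cluster", "method", "k"]
    assert len(df) == 4
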