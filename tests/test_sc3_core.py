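import numpy as np
import pytest

from sc3e.expr_io import ExpressionMatrix
from sc3e.metrics import adjusted_rand_index
from sc3e.preprocess import PreprocessedMatrix, log_transform
from sc3e.sc3_core import (
    ClusterLabels,
    ConsensusMatrix,
    SC3Config,
    cell_distances,
    cluster_consensus,
    consensus_from_ensemble,
    filter_genes,
    kmeans_ensemble,
    run_consensus,
    spectral_transform,
)
from sc3e.synthetic import SimConfig, simulate_counts, simulate_consensus


def make_pre(values, detected=None):
    values = np.asarray(values, dtype=float)
    if detected is None:
        detected = values > 0
    return PreprocessedMatrix(
        values=values,
        method="none",
        gene_ids=tuple(f"g{i}" for i in range(values.shape[0])),
        cell_ids=tuple(f"c{j}" for j in range(values.shape[1])),
        detected=detected,
    )


class TestFilterGenes:
    def test_undetected_gene_removed(self):
        mid = np.zeros(100)
        mid[:50] = 1.0
        values = np.vstack([np.zeros(100), mid])
        out = filter_genes(make_pre(values), 0.06, 0.94)
        assert out.gene_ids == ("g1",)

    def test_ubiquitous_gene_kept_at_upper_one(self):
        values = np.ones((1, 10))
        out = filter_genes(make_pre(values), 0.0, 1.0)
        assert out.gene_ids == ("g0",)

    def test_exact_surviving_set(self):
        # detection counts per gene: 0, 2, 5, 9, 10 of n=10 cells
        n = 10
        rows = []
        for det in (0, 2, 5, 9, 10):
            row = np.zeros(n)
            row[:det] = 1.0
            rows.append(row)
        P = make_pre(np.array(rows))
        out = filter_genes(P, lower_pct=0.25, upper_pct=0.92)
        # keep if 2.5 <= det <= 9.2 -> genes with 5 and 9
        assert out.gene_ids == ("g2", "g3")

    def test_all_filtered_raises(self):
        with pytest.raises(ValueError, match="relax"):
            filter_genes(make_pre(np.zeros((3, 10))), 0.06, 0.94)

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            filter_genes(make_pre(np.ones((2, 4))), 0.9, 0.1)


class TestCellDistances:
    def test_identical_columns_zero(self):
        P = make_pre(np.tile([[1.0], [2.0], [3.0]], (1, 3)))
        for metric in ("euclidean", "pearson", "spearman"):
            D = cell_distances(P, metric)
            np.testing.assert_allclose(D, 0.0, atol=1e-12)

    def test_pearson_anticorrelated(self):
        P = make_pre(np.array([[1.0, 3.0], [2.0, 2.0], [3.0, 1.0]]))
        D = cell_distances(P, "pearson")
        assert D[0, 1] == pytest.approx(2.0)

    def test_euclidean_345(self):
        P = make_pre(np.array([[0.0, 3.0], [0.0, 4.0]]))
        D = cell_distances(P, "euclidean")
        assert D[0, 1] == pytest.approx(5.0)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.random((10, 6))
        D1 = cell_distances(make_pre(base), "spearman")
        D2 = cell_distances(make_pre(np.exp(3 * base)), "spearman")
        np.testing.assert_allclose(D1, D2, atol=1e-12)

    def test_zero_variance_column_distance_one(self):
        # first cell column is constant
        values = np.array([[1.0, 4.0, 2.0], [1.0, 5.0, 3.0], [1.0, 6.0, 1.0]])
        P = make_pre(values)
        D = cell_distances(P, "pearson")
        assert D[0, 1] == 1.0 and D[0, 2] == 1.0
        assert D[0, 0] == 0.0

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(1)
        P = make_pre(rng.random((8, 7)))
        for metric in ("euclidean", "pearson", "spearman"):
            D = cell_distances(P, metric)
            np.testing.assert_allclose(D, D.T)
            np.testing.assert_allclose(np.diag(D), 0.0, atol=1e-12)


class TestSpectralTransform:
    def _distance(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 3))
        from scipy.spatial.distance import pdist, squareform

        return squareform(pdist(X))

    @pytest.mark.parametrize("kind", ["pca", "laplacian"])
    def test_shape(self, kind):
        D = self._distance()
        emb = spectral_transform(D, kind, 4)
        assert emb.shape == (10, 4)

    def test_pca_orthogonal_columns(self):
        emb = spectral_transform(self._distance(), "pca", 5)
        gram = emb.T @ emb
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_laplacian_separates_two_blobs(self):
        # 6-point distance matrix with two tight blobs far apart
        D = np.full((6, 6), 10.0)
        D[:3, :3] = 1.0
        D[3:, 3:] = 1.0
        np.fill_diagonal(D, 0.0)
        emb = spectral_transform(D, "laplacian", 2)
        # second eigenvector (first is trivial) splits blobs by sign
        signs = np.sign(emb[:, 1])
        assert len(set(signs[:3])) == 1 and len(set(signs[3:])) == 1
        assert signs[0] != signs[3]

    def test_degenerate_distance_errors(self):
        D = np.zeros((4, 4))
        with pytest.raises(ValueError):
            spectral_transform(D, "laplacian", 2)
        with pytest.raises(ValueError):
            spectral_transform(D, "pca", 2)

    def test_bad_d(self):
        with pytest.raises(ValueError):
            spectral_transform(self._distance(), "pca", 11)


class TestKmeansEnsemble:
    def _pre(self, n=100, seed=0):
        M, _ = simulate_counts(SimConfig(n_cells=n, n_genes=40, k_clusters=3, seed=seed))
        return log_transform(M)

    def test_grid_size(self):
        # n=100, d_range [0.04, 0.07] -> d in {4,5,6,7}: 3 metrics x 2 kinds x 4
        ensemble = kmeans_ensemble(self._pre(100), k=3, seed=1)
        assert len(ensemble) == 24

    def test_labels_in_range(self):
        for lab in kmeans_ensemble(self._pre(50), k=4, seed=2):
            assert lab.labels.min() >= 1 and lab.labels.max() <= 4

    def test_deterministic(self):
        a = kmeans_ensemble(self._pre(40), k=3, seed=9)
        b = kmeans_ensemble(self._pre(40), k=3, seed=9)
        assert all(np.array_equal(x.labels, y.labels) for x, y in zip(a, b))

    def test_empty_grid_fallback_warns(self):
        P = self._pre(12)
        with pytest.warns(UserWarning, match="falling back"):
            ensemble = kmeans_ensemble(
                P, k=2, seed=0, config=SC3Config(d_range=(0.001, 0.002))
            )
        assert len(ensemble) == 6  # one d value x 3 metrics x 2 kinds

    def test_k_must_be_small_enough(self):
        with pytest.raises(ValueError):
            kmeans_ensemble(self._pre(12), k=12, seed=0)


class TestConsensus:
    def test_hand_counted_pair_fractions(self):
        ens = [
            ClusterLabels(labels=[1, 1, 2], num_clusters=2),
            ClusterLabels(labels=[1, 2, 2], num_clusters=2),
        ]
        C = consensus_from_ensemble(ens)
        assert C.values[0, 1] == pytest.approx(0.5)
        assert C.values[0, 2] == pytest.approx(0.0)
        assert C.values[1, 2] == pytest.approx(0.5)

    def test_unanimous_block_structure(self):
        lab = ClusterLabels(labels=[1, 1, 2, 2], num_clusters=2)
        C = consensus_from_ensemble([lab, lab, lab])
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        np.testing.assert_array_equal(C.values, expected)

    def test_entries_times_size_integer(self):
        rng = np.random.default_rng(4)
        ens = [
            ClusterLabels(labels=rng.integers(1, 4, 12), num_clusters=3)
            for _ in range(7)
        ]
        C = consensus_from_ensemble(ens)
        scaled = C.values * len(ens)
        np.testing.assert_allclose(scaled, np.round(scaled), atol=1e-9)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError, match="different"):
            consensus_from_ensemble(
                [
                    ClusterLabels(labels=[1, 2], num_clusters=2),
                    ClusterLabels(labels=[1, 2, 2], num_clusters=2),
                ]
            )

    def test_tsv_round_trip(self, tmp_path):
        C, _ = simulate_consensus(8, 2, 0.9, 0.1, 0.05, seed=0)
        path = tmp_path / "c.tsv"
        C.to_tsv(str(path))
        back = ConsensusMatrix.from_tsv(str(path))
        np.testing.assert_array_equal(back.values, C.values)
        assert back.cell_ids == C.cell_ids


class TestClusterConsensus:
    def test_perfect_blocks_recovered(self):
        C, truth = simulate_consensus(12, 2, 1.0, 0.0, 0.0, seed=0)
        T = cluster_consensus(C, 2)
        assert adjusted_rand_index(T, truth) == 1.0

    def test_k_equals_n(self):
        C, _ = simulate_consensus(5, 2, 1.0, 0.0, 0.0, seed=0)
        T = cluster_consensus(C, 5)
        assert sorted(T.labels) == [1, 2, 3, 4, 5]

    def test_noisy_blocks_recovered(self):
        C, truth = simulate_consensus(20, 2, 0.9, 0.1, 0.05, seed=3)
        T = cluster_consensus(C, 2)
        assert adjusted_rand_index(T, truth) == 1.0

    def test_labels_first_appearance_order(self):
        C, _ = simulate_consensus(9, 3, 1.0, 0.0, 0.0, seed=0)
        T = cluster_consensus(C, 3)
        firsts = [int(np.argmax(T.labels == c)) for c in (1, 2, 3)]
        assert firsts == sorted(firsts)

    def test_k_too_large(self):
        C, _ = simulate_consensus(4, 2, 1.0, 0.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            cluster_consensus(C, 5)


class TestEndToEnd:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_separable_data_recovered(self, seed):
        M, truth = simulate_counts(
            SimConfig(
                n_cells=60,
                n_genes=100,
                k_clusters=3,
                log2_fold_change=2.5,
                de_fraction=0.3,
                dropout_rate=0.2,
                seed=seed,
            )
        )
        P = log_transform(M)
        C, T = run_consensus(P, k=3, seed=seed, config=SC3Config(upper_pct=1.0))
        assert adjusted_rand_index(T, truth) >= 0.9
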