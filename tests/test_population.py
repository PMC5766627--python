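import numpy as np
import pandas as pd
import pytest

import trascope as ts


def _matrix(values, genes=None, cells=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{j}" for j in range(values.shape[1])]
    return ts.ExpressionMatrix(values, pd.Index(genes), pd.Index(cells))


class TestPCA:
    def test_scores_match_covariance_eigendecomposition(self):
        """5-cell x 4-gene toy: scores agree with projecting the centred
        data on the eigenvectors of the 4x4 gene covariance matrix."""
        rng = np.random.default_rng(0)
        X = rng.gamma(2.0, 50.0, size=(4, 5))  # genes x cells
        m = _matrix(X)
        pca = ts.run_pca(m, n_components=3)
        Y = np.log2(X + 1).T
        Yc = Y - Y.mean(axis=0)
        cov = Yc.T @ Yc / (Yc.shape[0])
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        v = v[:, order]
        expected = Yc @ v[:, :3]
        assert np.allclose(np.abs(pca.scores), np.abs(expected), atol=1e-8)

    def test_rank_one_gene_dominates_first_loading(self):
        values = np.ones((4, 5)) * 10
        values[2] = [1, 100, 1, 100, 50]  # only varying gene
        pca = ts.run_pca(_matrix(values), n_components=2)
        assert pytest.approx(abs(pca.loadings[2, 0]), abs=1e-9) == 1.0

    def test_duplicating_every_cell_leaves_loadings_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.gamma(2.0, 50.0, size=(6, 8))
        p1 = ts.run_pca(_matrix(X), n_components=3)
        p2 = ts.run_pca(_matrix(np.hstack([X, X])), n_components=3)
        assert np.allclose(np.abs(p1.loadings), np.abs(p2.loadings), atol=1e-8)

    def test_sign_convention_and_variance_fractions(self):
        rng = np.random.default_rng(2)
        pca = ts.run_pca(_matrix(rng.gamma(2.0, 40.0, size=(10, 12))))
        for j in range(pca.loadings.shape[1]):
            col = pca.loadings[:, j]
            assert col[np.argmax(np.abs(col))] > 0
        evr = pca.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-9

    def test_too_many_components_or_too_few_cells_rejected(self):
        rng = np.random.default_rng(3)
        m = _matrix(rng.gamma(2.0, 40.0, size=(5, 4)))
        with pytest.raises(ValueError, match="components"):
            ts.run_pca(m, n_components=4)
        with pytest.raises(ValueError, match="at least 3 cells"):
            ts.run_pca(_matrix(np.ones((5, 2))))


class TestLoadingSelection:
    def test_threshold_is_strict(self):
        pca = ts.PCAResult(
            scores=np.zeros((3, 3)),
            loadings=np.array(
                [[0.5, 0.021, 0.0], [0.5, -0.020, -0.020], [0.5, 0.0, 0.5]]
            ),
            explained_variance_ratio=np.array([0.5, 0.3, 0.2]),
            gene_ids=pd.Index(["a", "b", "c"]),
            cell_ids=pd.Index(["x", "y", "z"]),
        )
        sel = ts.select_loading_genes(pca, components=(2, 3), threshold=0.02)
        assert list(sel) == ["a", "c"]  # +0.021 in; -0.020 out (strict)
        everything = ts.select_loading_genes(pca, components=(2, 3), threshold=0.0)
        assert list(everything) == ["a", "b", "c"]
        with pytest.raises(ValueError, match="component 5"):
            ts.select_loading_genes(pca, components=(5,))


class TestCellSizeCorrelation:
    def _pca_with_scores(self, scores):
        scores = np.asarray(scores, dtype=float)
        return ts.PCAResult(
            scores=scores,
            loadings=np.eye(scores.shape[1]),
            explained_variance_ratio=np.ones(scores.shape[1]) / scores.shape[1],
            gene_ids=pd.Index([f"g{i}" for i in range(scores.shape[1])]),
            cell_ids=pd.Index([f"c{i}" for i in range(scores.shape[0])]),
        )

    def _qc(self, counts):
        return pd.DataFrame(
            {
                "n_detected_genes": counts,
                "exon_mapped_reads": [1_000_000] * len(counts),
                "mito_fraction": [0.05] * len(counts),
            },
            index=[f"c{i}" for i in range(len(counts))],
        )

    def test_perfect_and_inverted_and_hand_case(self):
        counts = [1, 3, 2, 4]
        scores = np.column_stack([[1, 3, 2, 4], [-1, -3, -2, -4], [1, 2, 3, 4]])
        rho = ts.pc_cellsize_correlation(self._pca_with_scores(scores), self._qc(counts))
        assert rho["PC1"] == pytest.approx(1.0)
        assert rho["PC2"] == pytest.approx(-1.0)
        # ranks (1,2,3,4) vs (1,3,2,4): rho = 1 - 6*2/(4*15) = 0.8
        assert rho["PC3"] == pytest.approx(0.8)

    def test_constant_scores_yield_nan_with_warning(self):
        scores = np.column_stack([[1.0, 1.0, 1.0, 1.0]])
        with pytest.warns(UserWarning, match="constant"):
            rho = ts.pc_cellsize_correlation(self._pca_with_scores(scores), self._qc([1, 2, 3, 4]))
        assert np.isnan(rho["PC1"])


class TestConsensus:
    def _blobs(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 0.3, size=(10, n // 2)) + 2
        b = rng.normal(0, 0.3, size=(10, n // 2)) + 9
        return _matrix(np.abs(np.hstack([a, b])))

    def test_two_separated_blobs_give_binary_consensus(self):
        m = self._blobs()
        res = ts.consensus_cluster(m, k_range=[2], n_resamples=60, rng=ts.seeded_rng(0))[2]
        lab = res.assignments
        same = lab.loc[m.cell_ids].to_numpy()
        within = same[:, None] == same[None, :]
        c = res.consensus
        order = np.argsort(m.cell_ids)
        inv = np.empty_like(order); inv[order] = np.arange(len(order))
        cc = c[np.ix_(inv, inv)]
        assert cc[within].min() >= 0.95
        assert cc[~within].max() <= 0.05

    def test_single_full_resample_reduces_to_plain_hierarchical_cut(self):
        import scipy.cluster.hierarchy as sch

        m = self._blobs(n=16, seed=1)
        res = ts.consensus_cluster(
            m, k_range=[2], n_resamples=1, cell_frac=1.0, gene_frac=1.0, rng=ts.seeded_rng(0)
        )[2]
        order = np.argsort(m.cell_ids)
        X = m.log2p1()[:, order].T
        lab = sch.fcluster(sch.linkage(X, method="ward"), 2, "maxclust")
        expected = lab[:, None] == lab[None, :]
        assert np.array_equal(res.consensus == 1.0, expected)

    def test_consensus_invariants_and_permutation_equivariance(self):
        m = self._blobs(n=20, seed=2)
        res = ts.consensus_cluster(m, k_range=[2, 3], n_resamples=40, rng=ts.seeded_rng(5))
        for r in res.values():
            c = r.consensus
            assert np.allclose(c, c.T) and np.allclose(np.diag(c), 1.0)
            assert c.min() >= 0 and c.max() <= 1
        # permuting the input cell order permutes assignments identically
        perm = np.random.default_rng(3).permutation(m.n_cells)
        m2 = m.subset_cells(m.cell_ids[perm])
        res2 = ts.consensus_cluster(m2, k_range=[2, 3], n_resamples=40, rng=ts.seeded_rng(5))
        for k in (2, 3):
            pd.testing.assert_series_equal(
                res[k].assignments.sort_index(), res2[k].assignments.sort_index()
            )


class TestLabeling:
    def _matrix_with_markers(self):
        cells = [f"c{i}" for i in range(9)]
        genes = ["Pdpn", "Ccl21", "Aire", "other"]
        values = np.ones((4, 9))
        values[0, 0:3] = 50  # Pdpn high in cluster 1
        values[1, 0:3] = 50
        values[2, 3:6] = 80  # Aire high in cluster 2
        return ts.ExpressionMatrix(values, pd.Index(genes), pd.Index(cells))

    def _assign(self):
        return pd.Series([1] * 3 + [2] * 3 + [3] * 3, index=[f"c{i}" for i in range(9)])

    def test_marker_based_labelling(self):
        labels = ts.label_clusters(self._assign(), self._matrix_with_markers())
        assert list(labels[:3].unique()) == ["jTEC"]
        assert list(labels[3:6].unique()) == ["mTEChi"]
        assert list(labels[6:].unique()) == ["mTEClo"]

    def test_all_zero_maturation_marker_is_a_tie_error(self):
        m = self._matrix_with_markers()
        m.values[2] = 0.0  # Aire identically zero
        with pytest.raises(ValueError, match="tie"):
            ts.label_clusters(self._assign(), m)

    def test_absent_marker_named_in_error(self):
        m = self._matrix_with_markers()
        with pytest.raises(KeyError, match="Krt5"):
            ts.label_clusters(self._assign(), m, jtec_markers=("Krt5",))
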