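import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from scdimorph.io import CountMatrix
from scdimorph.preprocess import (
    ClusterAssignment,
    NormalizedMatrix,
    QCThresholds,
    annotate_clusters,
    build_snn_graph,
    choose_clustering,
    clr_normalize,
    cluster_cells,
    embed_cells,
    jaccard_index,
    qc_filter,
    select_variable_genes,
)


def _counts(mat, genes=None, cells=None):
    mat = np.asarray(mat)
    genes = genes or [f"G{i}" for i in range(mat.shape[0])]
    cells = cells or [f"c{i}" for i in range(mat.shape[1])]
    return CountMatrix(mat, np.array(genes, dtype=object), np.array(cells, dtype=object))


class TestQCFilter:
    def _feature_count_matrix(self, n_detected_per_cell, n_genes=300):
        cols = []
        for nd in n_detected_per_cell:
            col = np.zeros(n_genes, dtype=int)
            col[:nd] = 1
            cols.append(col)
        return _counts(np.column_stack(cols))

    def test_min_features_strict_boundary(self):
        counts = self._feature_count_matrix([199, 200, 250])
        kept, report = qc_filter(counts, QCThresholds(min_features=200, max_features=260))
        assert list(kept.cell_ids) == ["c1", "c2"]
        assert report.removed_low_features == 1

    def test_max_features_strict_boundary(self):
        counts = self._feature_count_matrix([250, 260, 261])
        kept, report = qc_filter(counts, QCThresholds(min_features=200, max_features=260))
        assert list(kept.cell_ids) == ["c0", "c1"]
        assert report.removed_high_features == 1

    def test_mito_strict_boundary(self):
        # 210 detected features; tune mito fraction via the mt- gene's count
        base = np.ones((209, 3), dtype=int)
        mito_counts = np.array([[11, 15, 4]])  # totals 220/224/213
        mat = np.vstack([base, mito_counts])
        genes = [f"G{i}" for i in range(209)] + ["mt-X"]
        counts = _counts(mat, genes=genes)
        fracs = mat[-1] / mat.sum(axis=0)
        th = QCThresholds(max_mito_frac=round(float(fracs[0]), 10))
        kept, report = qc_filter(counts, th)
        # cell 0 sits exactly at the threshold -> kept; cell 1 above -> removed
        assert "c0" in list(kept.cell_ids)
        assert "c1" not in list(kept.cell_ids)
        assert report.removed_mito == 1

    def test_ordinary_cell_kept(self):
        base = np.ones((1000, 1), dtype=int)
        base[500:, 0] = 0
        counts = _counts(base)
        kept, _ = qc_filter(counts, QCThresholds())
        assert kept.n_cells == 1

    def test_idempotent(self, small_bundle):
        th = QCThresholds()
        once, _ = qc_filter(small_bundle.counts, th)
        twice, report = qc_filter(once, th)
        assert twice.n_cells == once.n_cells
        assert report.n_retained == report.n_input

    def test_all_removed_errors(self):
        counts = self._feature_count_matrix([10, 20])
        with pytest.raises(ValueError, match="review the thresholds"):
            qc_filter(counts, QCThresholds())

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            QCThresholds(min_features=0)
        with pytest.raises(ValueError):
            QCThresholds(min_features=300, max_features=200)
        with pytest.raises(ValueError):
            QCThresholds(max_mito_frac=1.5)


class TestCLR:
    def test_equal_counts_give_zero_column(self):
        counts = _counts([[7], [7], [7]])
        norm = clr_normalize(counts)
        assert np.allclose(norm.values[:, 0], 0.0)

    def test_two_gene_example(self):
        counts = _counts([[0], [8]])
        norm = clr_normalize(counts)
        # ln(1) - ln(9)/2 = -1.0986, ln(9) - ln(9)/2 = +1.0986
        assert norm.values[0, 0] == pytest.approx(-1.0986, abs=1e-4)
        assert norm.values[1, 0] == pytest.approx(+1.0986, abs=1e-4)

    def test_per_cell_mean_zero_contract(self, small_bundle):
        norm = clr_normalize(small_bundle.counts)
        assert np.abs(norm.values.mean(axis=0)).max() < 1e-9

    def test_not_scale_invariant_but_mean_zero(self):
        a = clr_normalize(_counts([[1], [4], [9]]))
        b = clr_normalize(_counts([[2], [8], [18]]))
        assert not np.allclose(a.values, b.values)  # documented non-invariance
        assert abs(b.values[:, 0].mean()) < 1e-9


class TestVariableGenes:
    def _norm(self, values, genes=None):
        values = np.asarray(values, dtype=float)
        genes = genes or [f"G{i}" for i in range(values.shape[0])]
        cells = [f"c{i}" for i in range(values.shape[1])]
        return NormalizedMatrix(values, np.array(genes, dtype=object), np.array(cells, dtype=object))

    def test_planted_difference_ranks_first(self):
        rng = np.random.default_rng(0)
        flat = rng.normal(1.0, 0.05, size=(30, 200))
        planted = np.concatenate(
            [rng.normal(0.3, 0.05, 100), rng.normal(1.7, 0.05, 100)]
        )[None, :]  # ~4x arm difference around the same grand mean
        norm = self._norm(np.vstack([flat, planted]), genes=[f"G{i:02d}" for i in range(30)] + ["HIT"])
        top = select_variable_genes(norm, n_top=5)
        assert top[0] == "HIT"

    def test_n_top_equals_n_genes(self):
        rng = np.random.default_rng(1)
        norm = self._norm(rng.normal(size=(10, 20)))
        assert sorted(select_variable_genes(norm, 10)) == sorted(norm.gene_ids)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(15, 30))
        a = select_variable_genes(self._norm(vals), 8)
        b = select_variable_genes(self._norm(vals.copy()), 8)
        assert a == b

    def test_constant_matrix_errors(self):
        norm = self._norm(np.ones((5, 10)))
        with pytest.raises(ValueError, match="constant"):
            select_variable_genes(norm, 3)

    def test_n_top_too_large_errors(self):
        norm = self._norm(np.random.default_rng(3).normal(size=(5, 10)))
        with pytest.raises(ValueError):
            select_variable_genes(norm, 6)


class TestEmbed:
    def _norm_from(self, values):
        genes = [f"G{i}" for i in range(values.shape[0])]
        cells = [f"c{i}" for i in range(values.shape[1])]
        return NormalizedMatrix(values, np.array(genes, dtype=object), np.array(cells, dtype=object))

    def test_variances_non_increasing_and_orthonormal(self):
        rng = np.random.default_rng(4)
        norm = self._norm_from(rng.normal(size=(20, 100)))
        emb = embed_cells(norm, list(norm.gene_ids), n_pcs=6)
        assert np.all(np.diff(emb.explained_variance) <= 1e-10)
        gram = emb.components @ emb.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-10)

    def test_two_blobs_separate_in_pc_space(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 0.2, size=(10, 60))
        b = rng.normal(3, 0.2, size=(10, 60))
        norm = self._norm_from(np.hstack([a, b]))
        emb = embed_cells(norm, list(norm.gene_ids), n_pcs=3)
        centers = emb.scores[:60].mean(axis=0), emb.scores[60:].mean(axis=0)
        between = np.linalg.norm(centers[0] - centers[1])
        within = np.linalg.norm(emb.scores[:60] - centers[0], axis=1).mean()
        assert between > 3 * within

    def test_reconstruction_error_monotone(self):
        rng = np.random.default_rng(6)
        norm = self._norm_from(rng.normal(size=(15, 40)))
        errs = []
        for k in (1, 3, 5, 8):
            emb = embed_cells(norm, list(norm.gene_ids), n_pcs=k)
            recon = emb.scores @ emb.components
            # compare against the z-scored input implied by a full embedding
            full = embed_cells(norm, list(norm.gene_ids), n_pcs=15)
            z = full.scores @ full.components
            errs.append(np.linalg.norm(z - recon))
        assert all(e1 >= e2 - 1e-9 for e1, e2 in zip(errs, errs[1:]))

    def test_n_pcs_too_large_errors(self):
        rng = np.random.default_rng(7)
        norm = self._norm_from(rng.normal(size=(5, 30)))
        with pytest.raises(ValueError, match="n_pcs"):
            embed_cells(norm, list(norm.gene_ids), n_pcs=6)


class TestSNN:
    def test_jaccard_arithmetic(self):
        assert jaccard_index({1, 2, 3, 4}, {3, 4, 5, 6}) == pytest.approx(1 / 3)
        assert jaccard_index(set(), set()) == 0.0
        assert jaccard_index({1}, {2}) == 0.0

    def test_identical_knn_sets_weight_one(self):
        # two coincident points in a tight pair, far from a background cloud
        rng = np.random.default_rng(8)
        pts = np.vstack([[0, 0], [0, 0], rng.normal(100, 1, size=(20, 2))])
        g = build_snn_graph(pts, k=3)
        eid = g.get_eid(0, 1, error=False)
        assert eid >= 0
        assert g.es[eid]["weight"] == pytest.approx(1.0)

    def test_disjoint_neighborhoods_no_edge(self):
        rng = np.random.default_rng(9)
        a = rng.normal(0, 0.1, size=(10, 2))
        b = rng.normal(50, 0.1, size=(10, 2))
        g = build_snn_graph(np.vstack([a, b]), k=5)
        for i in range(10):
            for j in range(10, 20):
                assert g.get_eid(i, j, error=False) == -1

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            build_snn_graph(np.zeros((5, 2)), k=5)


class TestClustering:
    def _two_cliques_graph(self):
        import igraph as ig

        g = ig.Graph.Full(10) + ig.Graph.Full(10)
        g.es["weight"] = [1.0] * g.ecount()
        return g

    def test_two_cliques_two_clusters(self):
        g = self._two_cliques_graph()
        for cand in cluster_cells(g, resolutions=(0.2, 1.0, 2.0), seed=0):
            assert cand.n_clusters == 2

    def test_permutation_invariance_up_to_relabeling(self):
        rng = np.random.default_rng(10)
        pts = np.vstack(
            [rng.normal(0, 0.3, (40, 3)), rng.normal(6, 0.3, (40, 3))]
        )
        perm = rng.permutation(80)
        g1 = build_snn_graph(pts, k=10)
        g2 = build_snn_graph(pts[perm], k=10)
        c1 = cluster_cells(g1, resolutions=(1.0,), seed=0)[0]
        c2 = cluster_cells(g2, resolutions=(1.0,), seed=0)[0]
        unpermuted = np.empty(80, dtype=int)
        unpermuted[perm] = c2.labels
        assert adjusted_rand_score(c1.labels, unpermuted) == pytest.approx(1.0)

    def test_empty_graph_errors(self):
        import igraph as ig

        with pytest.raises(ValueError, match="empty"):
            cluster_cells(ig.Graph(), resolutions=(1.0,))


class TestChooseClustering:
    def test_silhouette_zero_for_equidistant_point(self):
        # point at the midpoint: a == b -> s = 0
        pts = np.array([[0.0], [0.0], [2.0], [4.0], [4.0]])
        labels = np.array([0, 0, 0, 1, 1])
        s = silhouette_samples(pts, labels)
        assert s[2] == pytest.approx(0.0, abs=1e-12)

    def _blobs(self, seed, n_types=3, n=120, sep=6.0, sd=1.0, d=5):
        rng = np.random.default_rng(seed)
        parts = [
            rng.normal(i * sep * sd, sd, size=(n, d)) for i in range(n_types)
        ]
        truth = np.repeat(np.arange(n_types), n)
        return np.vstack(parts), truth

    def test_three_blob_recovery(self):
        hits = 0
        for seed in range(3):
            pts, truth = self._blobs(seed)
            g = build_snn_graph(pts, k=15)
            cands = cluster_cells(g, resolutions=(0.2, 0.6, 1.0, 1.4), seed=seed)
            best = choose_clustering(cands, pts)
            if best.n_clusters == 3 and adjusted_rand_score(truth, best.labels) >= 0.9:
                hits += 1
        assert hits >= 2

    def test_single_blob_warns_low_silhouette(self):
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(150, 5))
        g = build_snn_graph(pts, k=15)
        cands = cluster_cells(g, resolutions=(0.8, 1.2, 1.6), seed=0)
        if all(c.n_clusters < 2 for c in cands):
            pytest.skip("single-community partition at every resolution")
        with pytest.warns(UserWarning, match="silhouette"):
            best = choose_clustering(cands, pts)
        assert best.mean_silhouette < 0.3

    def test_ties_prefer_fewer_clusters(self, monkeypatch):
        import scdimorph.preprocess as pp

        monkeypatch.setattr(pp, "silhouette_score", lambda *a, **k: 0.5)
        pts = np.random.default_rng(0).normal(size=(12, 2))
        a = ClusterAssignment(np.arange(12) % 2, np.arange(12), 2, 0.5)
        b = ClusterAssignment(np.arange(12) % 4, np.arange(12), 4, 0.5)
        best = choose_clustering([b, a], pts)
        assert best.n_clusters == 2

    def test_all_single_cluster_errors(self):
        pts = np.zeros((5, 2))
        only = ClusterAssignment(np.zeros(5, dtype=int), np.arange(5), 1, 0.1)
        with pytest.raises(ValueError):
            choose_clustering([only], pts)

    def test_silhouette_in_range(self):
        pts, truth = self._blobs(3)
        g = build_snn_graph(pts, k=15)
        cands = cluster_cells(g, resolutions=(0.4, 1.0), seed=1)
        best = choose_clustering(cands, pts)
        assert -1.0 <= best.mean_silhouette <= 1.0


class TestAnnotate:
    def _norm_with_clusters(self):
        rng = np.random.default_rng(13)
        n_genes, n_cells = 60, 80
        vals = rng.normal(0, 0.1, size=(n_genes, n_cells))
        labels = np.array([0] * 40 + [1] * 40)
        vals[:5, labels == 0] += 3.0  # genes G0..G4 mark cluster 0
        vals[5:10, labels == 1] += 3.0  # genes G5..G9 mark cluster 1
        genes = np.array([f"G{i}" for i in range(n_genes)], dtype=object)
        cells = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
        norm = NormalizedMatrix(vals, genes, cells)
        assign = ClusterAssignment(labels, cells, 2, 1.0)
        return norm, assign

    def test_exact_marker_match_assigns_label(self):
        norm, assign = self._norm_with_clusters()
        markers = {
            "alpha": [f"G{i}" for i in range(5)],
            "beta": [f"G{i}" for i in range(5, 10)],
        }
        out = annotate_clusters(assign, norm, markers)
        assert out[0]["label"] == "alpha"
        assert out[1]["label"] == "beta"

    def test_no_overlap_gives_unknown(self):
        norm, assign = self._norm_with_clusters()
        markers = {"gamma": [f"G{i}" for i in range(50, 60)]}
        out = annotate_clusters(assign, norm, markers)
        assert out[0]["label"] == "unknown"

    def test_tie_larger_overlap_wins(self):
        norm, assign = self._norm_with_clusters()
        # both sets perfectly inside the upregulated genes of cluster 0;
        # same size -> same q; overlap differs via absent genes
        markers = {
            "small": [f"G{i}" for i in range(3)] + ["NOT1", "NOT2"],
            "large": [f"G{i}" for i in range(5)],
        }
        with pytest.warns(UserWarning, match="absent"):
            out = annotate_clusters(assign, norm, markers)
        assert out[0]["label"] == "large"

    def test_empty_markers_error(self):
        norm, assign = self._norm_with_clusters()
        with pytest.raises(ValueError):
            annotate_clusters(assign, norm, {})


def test_count_level_clustering_recovery():
    """ARI >= 0.9 against true cell types on an effect-free simulated mixture."""
    from scdimorph.synthetic_data import SimConfig, generate_counts

    cfg = SimConfig(
        n_genes=200,
        cell_types={"a": 30, "b": 30, "c": 30},  # 120 cells per type
        baseline_log_mean_range=(0.0, 1.0),
        marker_genes_per_type=12,
        marker_log_shift=2.5,
        seed=21,
    )
    counts, meta = generate_counts(cfg, [])
    filtered, _ = qc_filter(counts, QCThresholds(min_features=20, max_features=250))
    norm = clr_normalize(filtered)
    genes = select_variable_genes(norm, 150)
    emb = embed_cells(norm, genes, n_pcs=10)
    g = build_snn_graph(emb.scores, k=20)
    cands = cluster_cells(
        g, resolutions=(0.2, 0.6, 1.0), seed=0, cell_ids=filtered.cell_ids
    )
    best = choose_clustering(cands, emb.scores)
    truth = (
        meta.set_index("barcode").loc[list(filtered.cell_ids), "cell_type"].to_numpy()
    )
    assert adjusted_rand_score(truth, best.labels) >= 0.9
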