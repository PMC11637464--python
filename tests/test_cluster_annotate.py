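"""Embedding, residualization, clustering, annotation, specificity, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData
from scipy.spatial.distance import jensenshannon
from sklearn.metrics import silhouette_score

from plexscreen import cluster_annotate as ca
from plexscreen import demux as dx
from plexscreen import synthdata as sd


def _filtered(ds):
    qc = dx.QC_PRESETS["screen"]
    res = dx.call_hashes(ds.hashes, qc.ratio_min, qc.ratio_strict)
    cells, _ = dx.filter_cells(ds.expr, res, qc, ds.manifest)
    return cells


class TestResidualize:
    def test_orthogonal_covariate_leaves_pcs_unchanged(self):
        rng = np.random.default_rng(0)
        cov = rng.normal(size=200)
        pcs = rng.normal(size=(200, 4))
        # project out intercept+cov so the PCs are exactly orthogonal to both
        X = np.column_stack([np.ones(200), cov])
        pcs -= X @ np.linalg.lstsq(X, pcs, rcond=None)[0]
        out = ca.residualize(pcs, cov)
        np.testing.assert_allclose(out, pcs, atol=1e-8)

    def test_removes_covariate_loading(self):
        rng = np.random.default_rng(1)
        umi = rng.uniform(500, 20_000, 500)
        cov = np.log10(umi)
        pcs = np.column_stack([2 * cov + rng.normal(0, 0.1, 500), rng.normal(size=500)])
        out = ca.residualize(pcs, cov)
        assert abs(np.corrcoef(out[:, 0], cov)[0, 1]) < 0.05
        np.testing.assert_allclose(out.mean(axis=0), 0, atol=1e-10)

    def test_constant_covariate_only_centers(self):
        rng = np.random.default_rng(2)
        pcs = rng.normal(size=(100, 3)) + 5.0
        out = ca.residualize(pcs, np.full(100, 3.3))
        np.testing.assert_allclose(out, pcs - pcs.mean(axis=0), atol=1e-8)

    def test_batch_indicator_removes_batch_shift(self):
        rng = np.random.default_rng(3)
        batch = np.repeat(["a", "b"], 100)
        pcs = rng.normal(size=(200, 2))
        pcs[100:, 0] += 4.0
        out = ca.residualize(pcs, rng.normal(size=200), batch=batch)
        assert abs(out[:100, 0].mean() - out[100:, 0].mean()) < 1e-8


class TestEmbedCluster:
    def test_two_types_separate_in_pc_space(self, small_screen):
        cells = _filtered(small_screen)
        emb = ca.embed(
            small_screen.expr, cells,
            ca.EmbedConfig(n_pcs=10, n_neighbors=15), compute_layout=False,
        )
        truth = small_screen.truth.cells["cell_type"].reindex(cells.index)
        two = truth.isin(["MG", "BP"]).to_numpy()
        score = silhouette_score(emb.pcs[two][:, :2], truth[two])
        assert score > 0.5

    def test_identical_cells_collapse_to_a_point(self):
        X = sp.csr_matrix(np.tile([5, 3, 2, 8, 1, 4, 9, 2, 3, 1], (30, 1)))
        adata = AnnData(X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(30)]),
                        var=pd.DataFrame(index=[f"g{i}" for i in range(10)]))
        cells = pd.DataFrame({"n_umi": np.full(30, X[0].sum())}, index=adata.obs_names)
        emb = ca.embed(adata, cells, ca.EmbedConfig(n_pcs=2, n_neighbors=5),
                       compute_layout=False)
        assert np.allclose(emb.pcs, emb.pcs[0], atol=1e-8)

    def test_n_pcs_too_large_rejected(self, small_screen):
        cells = _filtered(small_screen)
        with pytest.raises(ValueError, match="n_pcs"):
            ca.embed(small_screen.expr, cells, ca.EmbedConfig(n_pcs=200),
                     compute_layout=False)

    def test_two_disconnected_cliques_give_two_clusters(self):
        block = np.ones((5, 5)) - np.eye(5)
        adj = sp.block_diag([block, block], format="csr")
        labels = ca.cluster(adj, resolution=0.1, seed=0)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:5])) == 1
        assert len(np.unique(labels[5:])) == 1

    def test_cluster_count_monotone_in_resolution(self, small_screen):
        cells = _filtered(small_screen)
        emb = ca.embed(small_screen.expr, cells,
                       ca.EmbedConfig(n_pcs=10, n_neighbors=15), compute_layout=False)
        counts = [
            len(np.unique(ca.cluster(emb.graph, r, seed=0)))
            for r in (1e-4, 1e-2, 1.0)
        ]
        assert counts == sorted(counts)

    def test_cluster_seed_determinism(self, small_screen):
        cells = _filtered(small_screen)
        emb = ca.embed(small_screen.expr, cells,
                       ca.EmbedConfig(n_pcs=10, n_neighbors=15), compute_layout=False)
        a = ca.cluster(emb.graph, 1e-3, seed=4)
        b = ca.cluster(emb.graph, 1e-3, seed=4)
        np.testing.assert_array_equal(a, b)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ca.cluster(sp.csr_matrix((0, 0)), 1.0)


class TestAnnotate:
    def _setup(self, small_screen):
        cells = _filtered(small_screen)
        emb = ca.embed(small_screen.expr, cells,
                       ca.EmbedConfig(n_pcs=10, n_neighbors=15), compute_layout=False)
        labels = ca.cluster(emb.graph, 1e-3, seed=0)
        return cells, labels

    def test_clusters_labelled_with_majority_true_type(self, small_screen):
        cells, labels = self._setup(small_screen)
        table, per_cell = ca.annotate_clusters(
            small_screen.expr, cells, labels, small_screen.markers
        )
        truth = small_screen.truth.cells["cell_type"].reindex(cells.index)
        ok = 0
        for c in table.index:
            majority = truth[labels == c].mode().iloc[0]
            ok += table.loc[c, "cell_type"] == majority
        assert ok / len(table) >= 0.95

    def test_cluster_with_no_panel_genes_is_unknown(self):
        rng = np.random.default_rng(0)
        X = sp.csr_matrix(rng.poisson(3.0, (40, 6)).astype(float))
        adata = AnnData(X=X, obs=pd.DataFrame(index=[f"c{i}" for i in range(40)]),
                        var=pd.DataFrame(index=[f"g{i}" for i in range(6)]))
        cells = pd.DataFrame(index=adata.obs_names)
        # markers exist in the matrix but only mark genes the cluster lacks
        X2 = X.toarray()
        X2[:20, 5] = 0  # cluster 0 never expresses the only panel gene
        adata.X = sp.csr_matrix(X2)
        table, _ = ca.annotate_clusters(
            adata, cells, np.repeat([0, 1], 20), {"T": ["g5"]}
        )
        assert table.loc[0, "cell_type"] == "Unknown"
        assert table.loc[1, "cell_type"] == "T"

    def test_empty_marker_panel_rejected(self, small_screen):
        cells, labels = self._setup(small_screen)
        with pytest.raises(ValueError, match="empty"):
            ca.annotate_clusters(small_screen.expr, cells, labels, {})

    def test_annotation_invariant_to_label_permutation(self, small_screen):
        cells, labels = self._setup(small_screen)
        table, per_cell = ca.annotate_clusters(
            small_screen.expr, cells, labels, small_screen.markers
        )
        permuted = np.max(labels) - labels  # relabel clusters
        table2, per_cell2 = ca.annotate_clusters(
            small_screen.expr, cells, permuted, small_screen.markers
        )
        pd.testing.assert_series_equal(per_cell, per_cell2)


class TestSpecificity:
    def _adata(self, X):
        X = np.asarray(X, dtype=float)
        return AnnData(
            X=sp.csr_matrix(X),
            obs=pd.DataFrame(index=[f"c{i}" for i in range(X.shape[0])]),
            var=pd.DataFrame(index=[f"g{i}" for i in range(X.shape[1])]),
        )

    def test_one_hot_gene_scores_exactly_one(self):
        # g0 expressed only in type A cells
        X = [[5, 1], [6, 1], [0, 1], [0, 1]]
        adata = self._adata(X)
        types = pd.Series(["A", "A", "B", "B"], index=adata.obs_names)
        tab = ca.specificity_scores(adata, types)
        sA = tab[(tab.gene == "g0") & (tab.cell_type == "A")]["specificity"].iloc[0]
        assert sA == pytest.approx(1.0, abs=1e-12)

    def test_uniform_two_type_gene_closed_form(self):
        """A gene expressed equally in 2 types scored against either:
        S = 1 - sqrt(JS((1/2,1/2),(1,0))) = 0.4421 (base-2)."""
        X = [[4, 1], [4, 1], [4, 1], [4, 1]]
        adata = self._adata(X)
        types = pd.Series(["A", "A", "B", "B"], index=adata.obs_names)
        tab = ca.specificity_scores(adata, types)
        expected = 1 - jensenshannon([0.5, 0.5], [1.0, 0.0], base=2)
        for t in ("A", "B"):
            s = tab[(tab.gene == "g0") & (tab.cell_type == t)]["specificity"].iloc[0]
            assert s == pytest.approx(expected, abs=1e-3)
            assert s == pytest.approx(0.4421, abs=1e-3)

    def test_low_detection_fraction_blocks_specific_flag(self):
        # g0 detected in 2/50 = 4% of type-A cells but, when present, huge
        X = np.ones((100, 2))
        X[:, 0] = 0.0
        X[:2, 0] = 500.0
        adata = self._adata(X)
        types = pd.Series(["A"] * 50 + ["B"] * 50, index=adata.obs_names)
        tab = ca.specificity_scores(adata, types)
        row = tab[(tab.gene == "g0") & (tab.cell_type == "A")].iloc[0]
        assert row["f"] == pytest.approx(0.04)
        assert row["specificity"] > 0.3
        assert not row["is_specific"]

    def test_p_rows_sum_to_one_and_argmax_matches(self, small_screen):
        truth = small_screen.truth.cells["cell_type"]
        tab = ca.specificity_scores(small_screen.expr, truth)
        sums = tab.groupby("gene")["p"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)
        best_p = tab.loc[tab.groupby("gene")["p"].idxmax()].set_index("gene")
        best_s = tab.loc[tab.groupby("gene")["specificity"].idxmax()].set_index("gene")
        assert (best_p["cell_type"] == best_s["cell_type"]).all()

    def test_jsd_matches_scipy_on_random_distributions(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            ours = ca.jensen_shannon_distance(p, q)
            ref = jensenshannon(p, q, base=2)
            assert ours == pytest.approx(ref, abs=1e-10)
            assert ours == pytest.approx(ca.jensen_shannon_distance(q, p), abs=1e-12)
            assert 0.0 <= ours <= 1.0


class TestEnrichment:
    def test_zero_overlap_gives_p_one(self):
        uni = [f"g{i}" for i in range(50)]
        out = ca.enrich_gene_sets(uni[:5], {"s": uni[40:]}, uni)
        assert out["p"].iloc[0] == pytest.approx(1.0)

    def test_full_overlap_combinatorial_identity(self):
        uni = [f"g{i}" for i in range(100)]
        out = ca.enrich_gene_sets(uni[:10], {"s": uni[:10]}, uni)
        assert out["p"].iloc[0] == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_tail_probability_matches_enumeration(self):
        """Brute-force oracle: enumerate every 6-subset of a 12-gene
        universe and count those overlapping the set by >= k."""
        uni = [f"g{i}" for i in range(12)]
        gene_set = set(uni[:5])
        query = uni[3:9]  # overlap 2
        k = len(gene_set & set(query))
        hits = sum(
            1 for combo in itertools.combinations(uni, len(query))
            if len(gene_set & set(combo)) >= k
        )
        expected = hits / math.comb(12, len(query))
        out = ca.enrich_gene_sets(query, {"s": sorted(gene_set)}, uni)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_duplicate_sets_get_identical_p_and_q(self):
        uni = [f"g{i}" for i in range(30)]
        out = ca.enrich_gene_sets(
            uni[:6], {"a": uni[:8], "b": uni[:8], "c": uni[20:]}, uni
        ).set_index("set")
        assert out.loc["a", "p"] == out.loc["b", "p"]
        assert out.loc["a", "q"] == out.loc["b", "q"]

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ca.enrich_gene_sets(["x"], {"s": ["g1"]}, ["g1", "g2"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            ca.enrich_gene_sets([], {"s": ["g1"]}, [])
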