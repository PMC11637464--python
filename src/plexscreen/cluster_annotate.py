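"""Embedding, clustering, marker-based annotation and gene specificity.

The embedding follows the standard single-cell recipe: size-factor
normalization, log1p, PCA, linear residualization of the PCs against
log10(UMIs) plus batch indicators, a k-nearest-neighbor graph, and a 2-D
UMAP layout. Clusters come from Leiden community detection on the graph.
Cluster annotation scores marker panels; per-cell-type gene specificity is
one minus the base-2 Jensen-Shannon distance between a gene's across-type
normalized mean-expression profile and the candidate type's one-hot
profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.stats import hypergeom
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests


@dataclass
class EmbedConfig:
    """Dimensionality-reduction and clustering parameters.

    Defaults match the timecourse/pulse analysis (20 PCs, 50 neighbors,
    min_dist 0.1, Leiden resolution 6e-4); the ``screen`` preset uses
    30 PCs / 100 neighbors / resolution 1e-4 and the ``subcluster`` preset
    30 PCs / 12 neighbors / resolution 5e-4.
    """

    n_pcs: int = 20
    n_neighbors: int = 50
    min_dist: float = 0.1
    cluster_resolution: float = 6e-4
    batch_key: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_pcs < 2:
            raise ValueError("n_pcs must be >= 2")
        if self.cluster_resolution <= 0:
            raise ValueError("cluster_resolution must be > 0")


EMBED_PRESETS: Mapping[str, EmbedConfig] = {
    "timecourse": EmbedConfig(20, 50, 0.1, 6e-4),
    "pulse": EmbedConfig(20, 50, 0.1, 6e-4),
    "screen": EmbedConfig(30, 100, 0.1, 1e-4),
    "subcluster": EmbedConfig(30, 12, 0.1, 5e-4),
    "invivo": EmbedConfig(20, 50, 0.1, 6e-4),
}


@dataclass
class Embedding:
    """PCs (after residualization), kNN graph and optional 2-D layout."""

    cell_ids: pd.Index
    pcs: np.ndarray
    graph: sp.csr_matrix  # symmetric, Euclidean edge weights in PC space
    layout: Optional[np.ndarray]


def cell_size_factors(totals: np.ndarray) -> np.ndarray:
    """Per-cell size factors: UMI total over the geometric mean of totals."""
    totals = np.asarray(totals, dtype=float)
    if (totals <= 0).any():
        raise ValueError("all cells must have positive UMI totals")
    return totals / np.exp(np.mean(np.log(totals)))


def normalized_counts(X: sp.spmatrix, size_factors: np.ndarray) -> sp.csr_matrix:
    """Counts divided by per-cell size factors (rows = cells)."""
    inv = sp.diags(1.0 / np.asarray(size_factors, dtype=float))
    return (inv @ X).tocsr()


def residualize(
    pcs: np.ndarray,
    covariate: np.ndarray,
    batch: Optional[Sequence] = None,
) -> np.ndarray:
    """Replace each PC by its least-squares residual on the covariate.

    The design is an intercept, the covariate (log10 UMIs in the standard
    pipeline) and, when ``batch`` labels hold more than one level, one
    indicator per non-reference batch. Residual columns have mean zero.
    """
    cov = np.asarray(covariate, dtype=float)
    if not np.isfinite(cov).all():
        raise ValueError("covariate must be finite")
    cols = [np.ones(len(cov)), cov]
    if batch is not None:
        levels = pd.unique(np.asarray(batch, dtype=object))
        if len(levels) > 1:
            barr = np.asarray(batch, dtype=object)
            cols.extend((barr == lv).astype(float) for lv in levels[1:])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, pcs, rcond=None)
    return pcs - X @ beta


def embed(
    expr: AnnData,
    cells: pd.DataFrame,
    cfg: EmbedConfig,
    seed: int = 0,
    compute_layout: bool = True,
) -> Embedding:
    """Normalize, project onto PCs, residualize, and build the kNN graph.

    ``cells`` (a filtered QC table) selects and orders the cells; its
    ``n_umi`` column provides the residualization covariate and
    ``cfg.batch_key`` names an optional column of batch labels.
    """
    sub = expr[cells.index.to_numpy()]
    X = sp.csr_matrix(sub.X)
    n_cells, n_genes = X.shape
    if cfg.n_pcs >= min(n_cells, n_genes):
        raise ValueError(
            f"n_pcs={cfg.n_pcs} must be < min(n_cells={n_cells}, n_genes={n_genes})"
        )
    totals = np.asarray(X.sum(axis=1)).ravel()
    norm = normalized_counts(X, cell_size_factors(totals))
    logged = norm.copy()
    logged.data = np.log1p(logged.data)
    pca = PCA(n_components=cfg.n_pcs, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(np.asarray(logged.todense()))
    batch = cells[cfg.batch_key] if cfg.batch_key else None
    pcs = residualize(pcs, np.log10(totals), batch)

    k = min(cfg.n_neighbors, n_cells - 1)
    graph = kneighbors_graph(pcs, n_neighbors=k, mode="distance")
    graph = graph.maximum(graph.T).tocsr()

    layout = None
    if compute_layout:
        import umap  # deferred: heavy numba compilation

        layout = umap.UMAP(
            n_neighbors=k,
            min_dist=cfg.min_dist,
            n_components=2,
            random_state=seed,
        ).fit_transform(pcs)
    return Embedding(cells.index, pcs, graph, layout)


def cluster(
    graph: sp.spmatrix, resolution: float, seed: int = 0
) -> np.ndarray:
    """Leiden community detection on the neighbor graph.

    Disconnected components are clustered jointly (Leiden never merges
    across components). Returns integer labels, deterministic under a seed.
    """
    graph = sp.csr_matrix(graph)
    if graph.shape[0] == 0:
        raise ValueError("empty graph")
    sym = graph.maximum(graph.T).tocoo()
    mask = sym.row < sym.col
    g = ig.Graph(
        n=graph.shape[0],
        edges=list(zip(sym.row[mask], sym.col[mask])),
        directed=False,
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def annotate_clusters(
    expr: AnnData,
    cells: pd.DataFrame,
    labels: np.ndarray,
    markers: Mapping[str, Sequence[str]],
    score_floor: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign a cell type to each cluster from marker-panel scores.

    Per cluster and type the score is the mean over the type's markers of
    (fraction of the cluster's cells expressing the marker) x (the marker's
    mean normalized expression in the cluster, normalized to sum to one
    across clusters). The argmax type wins; ties break lexicographically
    and are flagged; clusters scoring below ``score_floor`` for every type
    are labelled "Unknown".

    Returns ``(cluster_table, per_cell_types)``.
    """
    if not markers:
        raise ValueError("empty marker panel")
    sub = expr[cells.index.to_numpy()]
    X = sp.csr_matrix(sub.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    norm = normalized_counts(X, cell_size_factors(totals))
    var_index = pd.Index(sub.var_names)

    missing = sorted(
        {g for panel in markers.values() for g in panel} - set(var_index)
    )
    if missing:
        warnings.warn(f"marker genes absent from the matrix: {missing}", stacklevel=2)

    labels = np.asarray(labels)
    clusters = np.unique(labels)
    rows = []
    # per gene x cluster: fraction expressing and mean normalized expression
    panel_genes = sorted(
        {g for panel in markers.values() for g in panel if g in set(var_index)}
    )
    if not panel_genes:
        raise ValueError("no marker gene is present in the matrix")
    gidx = var_index.get_indexer(panel_genes)
    Xp = X[:, gidx]
    Np = norm[:, gidx]
    frac = np.zeros((len(clusters), len(panel_genes)))
    meanx = np.zeros_like(frac)
    for ci, c in enumerate(clusters):
        rows_c = np.flatnonzero(labels == c)
        frac[ci] = np.asarray((Xp[rows_c] > 0).mean(axis=0)).ravel()
        meanx[ci] = np.asarray(Np[rows_c].mean(axis=0)).ravel()
    colsum = meanx.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(colsum > 0, meanx / np.maximum(colsum, 1e-300), 0.0)

    gene_pos = {g: j for j, g in enumerate(panel_genes)}
    type_names = sorted(markers)
    scores = np.zeros((len(clusters), len(type_names)))
    for ti, t in enumerate(type_names):
        js = [gene_pos[g] for g in markers[t] if g in gene_pos]
        if js:
            scores[:, ti] = (frac[:, js] * p[:, js]).mean(axis=1)

    for ci, c in enumerate(clusters):
        best = scores[ci].max()
        winners = [type_names[ti] for ti in np.flatnonzero(scores[ci] == best)]
        label = "Unknown" if best < score_floor else winners[0]
        rows.append(
            {
                "cluster": c,
                "cell_type": label,
                "score": best,
                "tied": len(winners) > 1 and best >= score_floor,
            }
        )
    table = pd.DataFrame(rows).set_index("cluster")
    per_cell = pd.Series(
        table["cell_type"].reindex(labels).to_numpy(),
        index=cells.index,
        name="cell_type",
    )
    return table, per_cell


def jensen_shannon_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon distance (square root of the divergence)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    m = 0.5 * (p + q)

    def _kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    div = 0.5 * _kl(p, m) + 0.5 * _kl(q, m)
    return float(np.sqrt(max(div, 0.0)))


def specificity_scores(
    expr: AnnData,
    type_labels: pd.Series,
    frac_min: float = 0.05,
    spec_min: float = 0.3,
) -> pd.DataFrame:
    """Per gene x cell type specificity table.

    For each gene, mean size-factor-normalized expression per type is
    normalized to sum to one across types (``p``); the specificity for type
    k is S = 1 - JSD(p, e_k) with e_k the one-hot profile of k and JSD the
    base-2 Jensen-Shannon distance. ``f`` is the fraction of the type's
    cells with at least one UMI of the gene, and ``is_specific`` requires
    f > ``frac_min`` and S > ``spec_min``. Genes with zero total expression
    are excluded.
    """
    types = pd.unique(type_labels.dropna())
    if len(types) < 2:
        raise ValueError("specificity requires >= 2 cell types")
    sub = expr[type_labels.index.to_numpy()]
    X = sp.csr_matrix(sub.X)
    totals = np.asarray(X.sum(axis=1)).ravel()
    norm = normalized_counts(X, cell_size_factors(totals))

    types = sorted(types)
    mean_by_type = np.zeros((len(types), X.shape[1]))
    frac_by_type = np.zeros_like(mean_by_type)
    for ti, t in enumerate(types):
        rows = np.flatnonzero((type_labels == t).to_numpy())
        mean_by_type[ti] = np.asarray(norm[rows].mean(axis=0)).ravel()
        frac_by_type[ti] = np.asarray((X[rows] > 0).mean(axis=0)).ravel()

    total = mean_by_type.sum(axis=0)
    expressed = total > 0
    p = mean_by_type[:, expressed] / total[expressed]  # types x genes

    # closed-form base-2 JSD against one-hot: m = (p + e_k)/2
    # KL(p||m) summed over all entries; KL(e_k||m) = -log2((p_k+1)/2)
    K, G = p.shape
    S = np.zeros((G, K))
    for ki in range(K):
        e = np.zeros(K)
        e[ki] = 1.0
        m = 0.5 * (p + e[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            kl_pm = np.where(p > 0, p * (np.log2(np.maximum(p, 1e-300)) - np.log2(m)), 0.0).sum(axis=0)
        kl_em = -np.log2(0.5 * (p[ki] + 1.0))
        div = 0.5 * kl_pm + 0.5 * kl_em
        S[:, ki] = 1.0 - np.sqrt(np.maximum(div, 0.0))

    gene_names = np.asarray(sub.var_names)[expressed]
    recs = []
    for ki, t in enumerate(types):
        f = frac_by_type[ki, expressed]
        recs.append(
            pd.DataFrame(
                {
                    "gene": gene_names,
                    "cell_type": t,
                    "f": f,
                    "p": p[ki],
                    "specificity": S[:, ki],
                    "is_specific": (f > frac_min) & (S[:, ki] > spec_min),
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def enrich_gene_sets(
    query_genes: Sequence[str],
    gene_sets: Mapping[str, Sequence[str]],
    universe: Sequence[str],
    p_cutoff: float = 0.01,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a gene list against sets.

    For each set, p = P(X >= overlap) with X hypergeometric(|universe|,
    |set n universe|, |query|); q-values are Benjamini-Hochberg across
    sets. ``significant`` marks sets with p <= p_cutoff and q <= q_cutoff.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(query)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & universe
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, len(members), N)) if members else 1.0
        rows.append({"set": name, "set_size": len(members), "overlap": k, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["p"] <= p_cutoff) & (out["q"] <= q_cutoff)
    return out
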