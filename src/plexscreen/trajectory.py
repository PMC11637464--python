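"""Pseudotime trajectory analysis.

Pseudotime is the geodesic (shortest-path) distance from a root cell over
the k-nearest-neighbor graph with Euclidean edge weights in residualized
PC space; the root is the cell nearest the source (glial) cluster's
centroid. The commitment point is the local minimum of a Gaussian kernel
density estimate of pseudotime inside a fixed window; windowed
differential expression regresses UMI counts on pseudotime with a
log-link count model, and the retained genes are grouped into trend
modules by k-means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra
from scipy.stats import gaussian_kde, norm
from sklearn.cluster import KMeans
from sklearn.neighbors import kneighbors_graph
from statsmodels.stats.multitest import multipletests


@dataclass
class PseudotimeResult:
    """Per-cell pseudotime (+inf when unreachable from the root)."""

    tau: pd.Series
    root_cell: str

    @property
    def finite(self) -> pd.Series:
        return self.tau[np.isfinite(self.tau)]


def pseudotime(
    pcs: np.ndarray,
    cell_ids: pd.Index,
    root_mask: np.ndarray,
    graph: Optional[sp.spmatrix] = None,
    n_neighbors: int = 15,
) -> PseudotimeResult:
    """Geodesic pseudotime from the root cluster's central cell.

    The root is the cell in ``root_mask`` (the source/glial cluster)
    closest to that cluster's PC centroid. ``graph`` may carry a
    precomputed kNN distance graph; otherwise one is built from ``pcs``.
    Cells not connected to the root get tau = +inf.
    """
    root_mask = np.asarray(root_mask, dtype=bool)
    if root_mask.sum() == 0:
        raise ValueError("root cluster is empty")
    centroid = pcs[root_mask].mean(axis=0)
    root_candidates = np.flatnonzero(root_mask)
    d2 = ((pcs[root_candidates] - centroid) ** 2).sum(axis=1)
    root = int(root_candidates[np.argmin(d2)])

    if graph is None:
        k = min(n_neighbors, pcs.shape[0] - 1)
        graph = kneighbors_graph(pcs, n_neighbors=k, mode="distance")
    graph = sp.csr_matrix(graph)
    graph = graph.maximum(graph.T)
    tau = dijkstra(graph, directed=False, indices=root)
    return PseudotimeResult(
        pd.Series(tau, index=cell_ids, name="pseudotime"), str(cell_ids[root])
    )


def commitment_point(
    tau: Sequence[float],
    lo: float = 10.0,
    hi: float = 20.0,
    grid_size: int = 512,
) -> Optional[float]:
    """Local minimum of the pseudotime density inside (lo, hi).

    A Gaussian KDE (Silverman bandwidth) is fit to the finite pseudotime
    values falling in the window and evaluated on a fixed grid; the
    returned commitment point is the interior argmin of the density.
    Returns ``None`` with a warning when the density is monotone on the
    window (its minimum sits on a boundary), i.e. there is no interior
    minimum.
    """
    tau = np.asarray(tau, dtype=float)
    vals = tau[np.isfinite(tau)]
    vals = vals[(vals > lo) & (vals < hi)]
    if len(vals) < 2:
        raise ValueError(f"need >= 2 finite pseudotime values in ({lo}, {hi})")
    kde = gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    i = int(np.argmin(dens))
    if i == 0 or i == grid_size - 1:
        warnings.warn(
            "pseudotime density is monotone on the window; no interior minimum",
            stacklevel=2,
        )
        return None
    return float(grid[i])


def _irls_count_glm(
    y: np.ndarray,
    x: np.ndarray,
    offset: np.ndarray,
    alpha: Optional[np.ndarray] = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized log-link count regression for many genes at once.

    Fits y_g ~ exp(offset + b0 + b1 * x) per gene g by iteratively
    reweighted least squares. ``alpha`` (per-gene NB2 dispersion, Var =
    mu + alpha mu^2) switches the working weights from Poisson (mu) to
    negative binomial (mu / (1 + alpha mu)). Returns (B, SE, converged)
    with B and SE of shape (2, n_genes).
    """
    n, G = y.shape
    X = np.column_stack([np.ones(n), x])
    B = np.zeros((2, G))
    B[0] = np.log(np.maximum(y.mean(axis=0), 1e-8)) - offset.mean()
    converged = np.zeros(G, dtype=bool)
    XWX = np.empty((G, 2, 2))
    for _ in range(max_iter):
        eta = offset[:, None] + X @ B
        eta = np.clip(eta, -30, 30)
        mu = np.exp(eta)
        W = mu if alpha is None else mu / (1.0 + alpha[None, :] * mu)
        z = (eta - offset[:, None]) + (y - mu) / mu
        XWX = np.einsum("ni,ng,nj->gij", X, W, X)
        XWz = np.einsum("ni,ng,ng->gi", X, W, z)
        # guard singular systems (e.g. all-zero genes)
        det = XWX[:, 0, 0] * XWX[:, 1, 1] - XWX[:, 0, 1] * XWX[:, 1, 0]
        ok = np.abs(det) > 1e-12
        newB = B.copy()
        if ok.any():
            sol = np.linalg.solve(XWX[ok], XWz[ok][:, :, None])[:, :, 0]
            newB[:, ok] = sol.T
        step = np.abs(newB - B).max(axis=0)
        converged = converged | (step < tol)
        B = newB
        if converged.all():
            break
    eta = np.clip(offset[:, None] + X @ B, -30, 30)
    mu = np.exp(eta)
    W = mu if alpha is None else mu / (1.0 + alpha[None, :] * mu)
    XWX = np.einsum("ni,ng,nj->gij", X, W, X)
    det = XWX[:, 0, 0] * XWX[:, 1, 1] - XWX[:, 0, 1] * XWX[:, 1, 0]
    se = np.full((2, G), np.nan)
    ok = det > 1e-12
    se[0, ok] = np.sqrt(XWX[ok, 1, 1] / det[ok])
    se[1, ok] = np.sqrt(XWX[ok, 0, 0] / det[ok])
    converged &= ok
    return B, se, converged


def pseudotime_deg(
    counts: sp.spmatrix | np.ndarray,
    gene_names: Sequence[str],
    tau: Sequence[float],
    size_factors: Optional[np.ndarray] = None,
    lo: float = 10.0,
    hi: float = 20.0,
    min_cells: int = 50,
    beta_min: float = 0.08,
    top_n: int = 250,
) -> pd.DataFrame:
    """Differential expression across a pseudotime window.

    Cells with lo < tau < hi enter a per-gene log-link count regression of
    UMIs on pseudotime with log size factor as offset: negative binomial
    with method-of-moments dispersion, falling back to Poisson when the
    moment estimate is <= 0. ``beta`` is the pseudotime coefficient (per
    unit pseudotime, natural-log scale); q-values are Benjamini-Hochberg
    over all converged genes. Genes with |beta| < ``beta_min`` are dropped
    and the ``top_n`` lowest-q survivors are flagged ``retained``.
    Non-converged fits are flagged and excluded, never silently kept.
    """
    tau = np.asarray(tau, dtype=float)
    window = np.isfinite(tau) & (tau > lo) & (tau < hi)
    n_win = int(window.sum())
    if n_win < min_cells:
        raise ValueError(
            f"only {n_win} cells have pseudotime in ({lo}, {hi}); need >= {min_cells}"
        )
    Y = counts[window]
    Y = np.asarray(Y.todense() if sp.issparse(Y) else Y, dtype=float)
    x = tau[window]
    if size_factors is None:
        sf = np.ones(n_win)
    else:
        sf = np.asarray(size_factors, dtype=float)[window]
    offset = np.log(sf)

    nonzero = Y.sum(axis=0) > 0
    beta = np.full(Y.shape[1], np.nan)
    se = np.full(Y.shape[1], np.nan)
    conv = np.zeros(Y.shape[1], dtype=bool)
    if nonzero.any():
        Yn = Y[:, nonzero]
        B0, S0, c0 = _irls_count_glm(Yn, x, offset, alpha=None)
        # method-of-moments NB2 dispersion from the Poisson fit
        eta = np.clip(offset[:, None] + np.column_stack([np.ones(n_win), x]) @ B0, -30, 30)
        mu = np.exp(eta)
        num = ((Yn - mu) ** 2 - mu).sum(axis=0)
        den = (mu**2).sum(axis=0)
        alpha = np.maximum(num / np.maximum(den, 1e-300), 0.0)
        B, S, c = _irls_count_glm(Yn, x, offset, alpha=alpha)
        use_nb = alpha > 0
        beta_n = np.where(use_nb, B[1], B0[1])
        se_n = np.where(use_nb, S[1], S0[1])
        conv_n = np.where(use_nb, c, c0) & np.isfinite(se_n)
        beta[nonzero] = beta_n
        se[nonzero] = se_n
        conv[nonzero] = conv_n

    with np.errstate(invalid="ignore", divide="ignore"):
        zstat = beta / se
    p = np.where(conv, 2.0 * norm.sf(np.abs(zstat)), np.nan)
    out = pd.DataFrame(
        {
            "gene": list(gene_names),
            "beta": beta,
            "se": se,
            "p": p,
            "converged": conv,
        }
    )
    out["q"] = np.nan
    tested = out["converged"].to_numpy()
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    passing = tested & (np.abs(out["beta"].to_numpy()) >= beta_min)
    out["passes_effect_size"] = passing
    out["retained"] = False
    if passing.any():
        ranked = out.loc[passing].sort_values(["q", "p", "gene"], kind="mergesort")
        out.loc[ranked.index[:top_n], "retained"] = True
    out["n_cells"] = n_win
    return out


def gene_modules(
    counts: sp.spmatrix | np.ndarray,
    gene_names: Sequence[str],
    tau: Sequence[float],
    size_factors: Optional[np.ndarray] = None,
    k: int = 3,
    smooth_window: int = 51,
    seed: int = 0,
) -> tuple[pd.Series, pd.DataFrame]:
    """k-means trend modules over pseudotime-ordered expression.

    Cells with finite pseudotime are ordered by tau; each gene's
    size-factor-normalized expression is smoothed by a centered rolling
    mean and z-scored, then genes are clustered by k-means (fixed seed,
    restarts). Module labels are canonical by the position of each
    module's peak: 1 = increasing (late peak), 2 = transient (middle),
    3 = decreasing (early peak). Returns (labels, heatmap) where the
    heatmap rows are genes ordered by module then peak position and the
    columns are tau-ordered cells.
    """
    gene_names = list(gene_names)
    if k > len(gene_names):
        raise ValueError(f"k={k} exceeds the number of genes ({len(gene_names)})")
    tau = np.asarray(tau, dtype=float)
    finite = np.isfinite(tau)
    order = np.argsort(tau[finite], kind="stable")
    Y = counts[finite]
    Y = np.asarray(Y.todense() if sp.issparse(Y) else Y, dtype=float)[order]
    sf = np.ones(Y.shape[0]) if size_factors is None else np.asarray(size_factors, float)[finite][order]
    norm_expr = Y / sf[:, None]

    smoothed = (
        pd.DataFrame(norm_expr)
        .rolling(window=smooth_window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    mean = smoothed.mean(axis=0)
    std = smoothed.std(axis=0)
    std[std == 0] = 1.0
    z = ((smoothed - mean) / std).T  # genes x cells

    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    raw = km.fit_predict(z)
    peaks = [np.argmax(km.cluster_centers_[c]) for c in range(k)]
    # later peak -> lower module number (increasing=1 ... decreasing=k)
    order_by_peak = np.argsort(peaks, kind="stable")[::-1]
    relabel = {int(c): i + 1 for i, c in enumerate(order_by_peak)}
    labels = pd.Series([relabel[int(c)] for c in raw], index=gene_names, name="module")

    gene_peak = np.argmax(z, axis=1)
    row_order = np.lexsort((gene_peak, labels.to_numpy()))
    heat = pd.DataFrame(
        z[row_order],
        index=[gene_names[i] for i in row_order],
        columns=np.asarray(np.sort(tau[finite], kind="stable"), dtype=float),
    )
    return labels, heat
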