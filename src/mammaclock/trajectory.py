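"""Pseudotime ordering and four-state segmentation along the aging axis.

The published trajectory of this cell population is linear, so a 1-D
pseudotime suffices: cells are embedded with PCA (10 components), connected
by a Gaussian-kernel k-nearest-neighbor graph, ordered by the leading
nontrivial diffusion-map coordinate, and refined by projection onto a
principal curve fitted through the PCA cloud.  The ordering is oriented so
the designated root age group sits early, then min-max rescaled to [0, 1].

Pseudotime-dependent genes are selected by a per-gene likelihood-ratio test
of a natural-cubic-spline model (3 df) in t against an intercept-only model
(Gaussian working likelihood on log-normalized values, chi-square with 3 df,
Benjamini-Hochberg correction).  Selected genes are smoothed on a grid,
log10(x+1)-transformed, standardized per gene, clamped to [-3, 3], and
clustered hierarchically (Euclidean/Ward) into four groups; cells are then
segmented into four states at the points where the dominant cluster-average
curve changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.sparse.csgraph import connected_components
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from ._splines import fit_smooth_curves, spline_design


@dataclass
class Pseudotime:
    """Per-cell position on the aging axis, rescaled to [0, 1]."""

    t: pd.Series  # indexed by cell barcode
    root_age_months: float

    def values_for(self, adata: ad.AnnData) -> np.ndarray:
        return self.t.reindex(adata.obs_names).to_numpy()


@dataclass
class SmoothedCurves:
    """Smoothed, log10(x+1), standardized, +/-3-truncated gene curves."""

    grid: np.ndarray  # G pseudotime points in [0, 1]
    values: pd.DataFrame  # genes x G
    truncation_bound: float = 3.0


@dataclass
class StateMap:
    """Four-state segmentation of the pseudotime axis."""

    boundaries: tuple[float, float, float]
    states: pd.Series  # per-cell state in {1..4}
    state_names: tuple[str, ...] = ("a-Young", "q-Young", "e-Sen", "l-Sen")
    cluster_order: tuple[int, ...] = (1, 2, 3, 4)

    def counts(self) -> pd.Series:
        return self.states.value_counts().sort_index()

    def state_of_t(self, t: np.ndarray) -> np.ndarray:
        return 1 + np.searchsorted(np.asarray(self.boundaries), np.asarray(t))


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def _diffusion_coordinate(pcs: np.ndarray, n_neighbors: int) -> np.ndarray:
    """Leading nontrivial eigenvector of the diffusion operator on a kNN graph."""
    n = pcs.shape[0]
    nn = NearestNeighbors(n_neighbors=min(n_neighbors, n - 1)).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    sigma = np.maximum(dist[:, -1], 1e-12)  # adaptive bandwidth
    rows = np.repeat(np.arange(n), idx.shape[1])
    cols = idx.ravel()
    w = np.exp(-(dist.ravel() ** 2) / (sigma[rows] * sigma[cols]))
    W = sparse.csr_matrix((w, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)
    n_comp, _ = connected_components(W, directed=False)
    if n_comp > 1:
        raise ValueError(
            f"neighbor graph has {n_comp} components; no single ordering exists "
            "(increase n_neighbors or check for contaminant populations)"
        )
    d = np.asarray(W.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(d)
    S = sparse.diags(d_inv_sqrt) @ W @ sparse.diags(d_inv_sqrt)
    vals, vecs = sparse.linalg.eigsh(S, k=2, which="LA", v0=np.ones(n))
    order = np.argsort(vals)[::-1]
    dc1 = vecs[:, order[1]] * d_inv_sqrt  # right eigenvector of the walk matrix
    return dc1


def _principal_curve_refine(
    pcs: np.ndarray, t0: np.ndarray, n_grid: int = 200, n_iter: int = 2
) -> np.ndarray:
    """Project cells onto a principal curve parameterized by an initial order."""
    t = t0.copy()
    for _ in range(n_iter):
        grid = np.linspace(0.0, 1.0, n_grid)
        curve = fit_smooth_curves(t, pcs.T, grid, df=5)  # dims x grid
        d2 = ((pcs[:, :, None] - curve[None, :, :]) ** 2).sum(axis=1)
        nearest = d2.argmin(axis=1)
        seg = np.linalg.norm(np.diff(curve, axis=1), axis=0)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        t = arc[nearest] / max(arc[-1], 1e-12)
        t = _rank01(t)
    return t


def _rank01(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x, method="average") - 1.0
    return r / max(len(x) - 1.0, 1.0)


def infer_pseudotime(
    adata: ad.AnnData,
    root_age_months: float = 2.0,
    n_pcs: int = 10,
    n_neighbors: int = 15,
    refine: bool = True,
) -> Pseudotime:
    """Order cells along a 1-D aging axis from log-normalized expression.

    Orientation: the root age group (youngest batch) must have lower mean t
    than the oldest group; otherwise the axis is flipped.  Requires >= 50
    cells and the root age in ``obs["age_months"]``.
    """
    if adata.n_obs < 50:
        raise ValueError("need at least 50 cells to infer a trajectory")
    ages = adata.obs["age_months"].to_numpy(dtype=float)
    if not np.any(ages == root_age_months):
        raise ValueError(f"no cells with age_months == {root_age_months}")
    Y = _dense(adata.X).astype(float)
    mu = Y.mean(axis=0)
    sd = Y.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Y - mu) / sd
    pcs = PCA(n_components=min(n_pcs, min(Z.shape) - 1), random_state=0).fit_transform(Z)
    dc1 = _diffusion_coordinate(pcs, n_neighbors)
    t = _rank01(dc1)
    if refine:
        t = _principal_curve_refine(pcs, t)
    root_mean = t[ages == root_age_months].mean()
    old_mean = t[ages == ages.max()].mean()
    if root_mean > old_mean:
        t = 1.0 - t
    t = (t - t.min()) / max(t.max() - t.min(), 1e-12)
    return Pseudotime(
        t=pd.Series(t, index=adata.obs_names, name="pseudotime"),
        root_age_months=root_age_months,
    )


def test_pseudotime_genes(
    adata: ad.AnnData,
    pseudotime: Pseudotime,
    q_cutoff: float = 0.05,
    df: int = 3,
) -> pd.DataFrame:
    """Likelihood-ratio test per gene: spline-in-t vs intercept model.

    Returns a gene-indexed table with ``p``, ``q`` (Benjamini-Hochberg) and
    ``selected``.  Zero-variance genes get p = 1 by definition.
    """
    t = pseudotime.values_for(adata)
    Y = _dense(adata.X).astype(float)
    n = Y.shape[0]
    X = spline_design(t, df=df)
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    rss1 = (resid**2).sum(axis=0)
    rss0 = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = n * np.log(rss0 / np.maximum(rss1, 1e-300))
    p = stats.chi2.sf(lrt, df)
    p = np.where(rss0 <= 1e-300, 1.0, p)  # constant genes
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = pd.DataFrame(
        {"p": p, "q": q, "selected": q < q_cutoff}, index=adata.var_names
    )
    return out


def smooth_scale_truncate(
    adata: ad.AnnData,
    pseudotime: Pseudotime,
    genes: list[str],
    grid_size: int = 100,
    df: int = 6,
    bound: float = 3.0,
) -> SmoothedCurves:
    """Spline-smooth genes over t, then log10(x+1), z-score and clamp to +/-3.

    Negative spline fits are clamped to 0 before the log transform; values
    standardized per gene across the grid; entries outside [-bound, bound]
    are set to the bound, following the published truncation rule.
    """
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    t = pseudotime.values_for(adata)
    grid = np.linspace(0.0, 1.0, grid_size)
    sub = adata[:, genes]
    Y = _dense(sub.X).astype(float).T  # genes x cells
    curves = fit_smooth_curves(t, Y, grid, df=df)
    curves = np.log10(np.clip(curves, 0.0, None) + 1.0)
    mu = curves.mean(axis=1, keepdims=True)
    sd = curves.std(axis=1, keepdims=True)
    flat = sd <= 1e-10 * np.maximum(np.abs(mu), 1.0)  # numerically constant
    sd[flat] = 1.0
    curves = np.clip((curves - mu) / sd, -bound, bound)
    curves[flat[:, 0]] = 0.0
    return SmoothedCurves(
        grid=grid,
        values=pd.DataFrame(curves, index=pd.Index(genes, name="gene"), columns=grid),
        truncation_bound=bound,
    )


def cluster_genes(curves: SmoothedCurves, k: int = 4, method: str = "ward") -> pd.Series:
    """Agglomerative clustering of gene curves (Euclidean, Ward), cut at k."""
    n = curves.values.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        Z = linkage(curves.values.to_numpy(), method=method, metric="euclidean")
        labels = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(labels, index=curves.values.index, name="cluster")


def _majority_filter(labels: np.ndarray, window: int = 5) -> np.ndarray:
    half = window // 2
    out = labels.copy()
    n = len(labels)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = labels[lo:hi]
        vals, cnt = np.unique(seg, return_counts=True)
        out[i] = vals[cnt.argmax()]
    return out


def _collapse_short_runs(labels: np.ndarray, min_run: int = 3) -> np.ndarray:
    out = labels.copy()
    changed = True
    while changed:
        changed = False
        runs = []
        start = 0
        for i in range(1, len(out) + 1):
            if i == len(out) or out[i] != out[start]:
                runs.append((start, i))
                start = i
        for s, e in runs:
            if e - s < min_run and len(runs) > 1:
                fill = out[s - 1] if s > 0 else out[e]
                out[s:e] = fill
                changed = True
                break
    return out


def assign_states(
    curves: SmoothedCurves,
    clusters: pd.Series,
    pseudotime: Pseudotime,
    majority_window: int = 5,
) -> StateMap:
    """Segment cells into four states at dominant-cluster transitions.

    Each grid point is labeled by the cluster whose average curve is maximal
    there; the label sequence is smoothed by a majority filter and short runs
    are collapsed.  Exactly four dominance intervals are required; their three
    transition midpoints become the state boundaries, and clusters are
    renumbered 1..4 by order of dominance along t.
    """
    ids = np.unique(clusters.to_numpy())
    if len(ids) != 4:
        raise ValueError(f"need exactly 4 clusters, got {len(ids)}")
    grid = curves.grid
    means = np.vstack(
        [curves.values.loc[clusters.index[clusters == c]].mean(axis=0) for c in ids]
    )
    lab = ids[means.argmax(axis=0)]
    lab = _majority_filter(lab, window=majority_window)
    lab = _collapse_short_runs(lab)
    change = np.nonzero(lab[1:] != lab[:-1])[0]
    run_order = [lab[0]] + [lab[i + 1] for i in change]
    if len(run_order) != 4 or len(set(run_order)) != 4:
        raise ValueError(
            f"expected 4 dominance intervals along pseudotime, found run order "
            f"{run_order}; consider re-clustering or a larger majority window"
        )
    boundaries = tuple((grid[i] + grid[i + 1]) / 2.0 for i in change)
    t = pseudotime.t.to_numpy()
    states = 1 + np.searchsorted(np.asarray(boundaries), t)
    return StateMap(
        boundaries=boundaries,
        states=pd.Series(states, index=pseudotime.t.index, name="state"),
        cluster_order=tuple(int(c) for c in run_order),
    )


def technical_covariates(
    adata: ad.AnnData, cell_cycle_scores: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Nuisance covariates: ERCC/mito fractions, batch, gene count, cycle.

    Computed from the raw counts layer when present (the matrix itself
    otherwise).  Mirrors the covariates conventionally regressed out of
    normalized single-cell data before trajectory inference.  Cell-cycle
    scores (e.g. the per-phase z-scores of the phase caller, computed on
    unregressed data — a fixed two-pass order that breaks the circularity)
    are appended when provided.
    """
    counts = adata.layers.get("counts", adata.X)
    X = _dense(counts).astype(float)
    total = X.sum(axis=1)
    safe = np.where(total > 0, total, 1.0)
    cov = pd.DataFrame(index=adata.obs_names)
    if "is_ercc" in adata.var:
        cov["ercc_fraction"] = X[:, adata.var["is_ercc"].to_numpy()].sum(axis=1) / safe
    if "is_mito" in adata.var:
        cov["mito_fraction"] = X[:, adata.var["is_mito"].to_numpy()].sum(axis=1) / safe
    cov["n_genes_detected"] = (X > 0).sum(axis=1)
    if "batch" in adata.obs:
        cov["batch"] = adata.obs["batch"].astype(str).to_numpy()
    if cell_cycle_scores is not None:
        cc = cell_cycle_scores.reindex(adata.obs_names)
        for col in cc.columns:
            cov[f"cc_{col}".replace("/", "")] = cc[col].to_numpy(dtype=float)
    return cov


def run_trajectory_stages(
    adata: ad.AnnData,
    root_age_months: float = 2.0,
    q_cutoff: float = 0.05,
    grid_size: int = 100,
    k: int = 4,
    regress: bool = True,
    cell_cycle_scores: pd.DataFrame | None = None,
) -> tuple[Pseudotime, pd.DataFrame, SmoothedCurves, pd.Series, StateMap]:
    """Convenience composition: pseudotime -> gene test -> curves -> states.

    With ``regress=True`` technical covariates (plus cell-cycle scores when
    given) are regressed out of the normalized matrix before pseudotime
    inference and gene selection — removing library-composition drift and
    the phase program, which otherwise contaminate the aging axis; curves
    are smoothed on the normalized, unregressed values, matching the
    convention of smoothing the selected genes' expression directly.
    """
    from .qc import regress_covariates  # local import to avoid a cycle

    working = (
        regress_covariates(adata, technical_covariates(adata, cell_cycle_scores))
        if regress
        else adata
    )
    pt = infer_pseudotime(working, root_age_months=root_age_months)
    gene_table = test_pseudotime_genes(working, pt, q_cutoff=q_cutoff)
    genes = list(gene_table.index[gene_table["selected"]])
    if len(genes) < k:
        raise ValueError(f"only {len(genes)} pseudotime-dependent genes found")
    curves = smooth_scale_truncate(adata, pt, genes, grid_size=grid_size)
    clusters = cluster_genes(curves, k=k)
    states = assign_states(curves, clusters, pt)
    return pt, gene_table, curves, clusters, states
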