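"""Single-cell signaling entropy over a gene co-expression network.

A cell's expression profile x weights a random walk on a fixed co-expression
graph with adjacency A:

    P_ij = A_ij x_j / sum_k A_ik x_k          (transition matrix)
    pi_i  proportional to  x_i (A x)_i        (stationary distribution,
                                               exact for this reversible chain)
    S_i  = - sum_j P_ij ln P_ij               (local entropy)
    SR   = sum_i pi_i S_i                     (entropy rate)

SR is normalized by ln(lambda_max(A)), the entropy rate of the maximum-
entropy walk, so normalized SR lies in [0, 1].  High values mark promiscuous,
disordered transcriptional states; the late-senescence state shows the
highest entropy in this system.

The network is built once on a reference (aging wild-type) dataset —
thresholded Pearson correlation, restricted to its largest connected
component — and then frozen before being applied to perturbed (e.g.
knockout or drug-treated) cells.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


@dataclass
class CoexpressionNetwork:
    adjacency: sparse.csr_matrix  # symmetric 0/1, zero diagonal
    genes: list[str]  # genes of the largest connected component
    r_min: float

    def __post_init__(self) -> None:
        A = self.adjacency
        if (abs(A - A.T)).nnz:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")

    @property
    def log_spectral_radius(self) -> float:
        A = self.adjacency.astype(float)
        if A.shape[0] <= 2:
            lam = np.linalg.eigvalsh(A.toarray()).max()
        else:
            v0 = np.ones(A.shape[0])  # deterministic ARPACK start
            lam = sparse.linalg.eigsh(
                A, k=1, which="LA", v0=v0, return_eigenvectors=False
            )[0]
        return float(np.log(lam))


def build_network(adata: ad.AnnData, r_min: float = 0.3) -> CoexpressionNetwork:
    """Threshold the gene-gene Pearson correlation at r >= r_min.

    Keeps the largest connected component.  Requires >= 50 cells so the
    correlations are stable; raises when no edges survive the threshold.
    """
    if adata.n_obs < 50:
        raise ValueError("need at least 50 cells to estimate co-expression")
    Y = _dense(adata.X).astype(float)
    sd = Y.std(axis=0)
    keep = sd > 0
    Y = Y[:, keep]
    names = np.asarray(adata.var_names)[keep]
    R = np.corrcoef(Y.T)
    np.fill_diagonal(R, 0.0)
    A = (R >= r_min).astype(np.int8)
    A = np.maximum(A, A.T)
    if A.sum() == 0:
        raise ValueError(
            f"no gene pair reaches r >= {r_min}; lower the threshold"
        )
    Asp = sparse.csr_matrix(A)
    n_comp, labels = connected_components(Asp, directed=False)
    sizes = np.bincount(labels)
    main = labels == sizes.argmax()
    Asp = Asp[main][:, main]
    return CoexpressionNetwork(
        adjacency=sparse.csr_matrix(Asp), genes=list(names[main]), r_min=r_min
    )


def signaling_entropy(
    x: np.ndarray, net: CoexpressionNetwork, zero_eps_scale: float = 1e-3
) -> tuple[float, float]:
    """Entropy rate (SR) and normalized SR of one cell's profile on the network.

    ``x`` must be aligned to ``net.genes``.  Exact zeros are replaced by
    ``zero_eps_scale`` times the smallest positive entry, since the walk is
    undefined on zero-weight nodes.  Returns (SR, SR / ln lambda_max).
    """
    x = np.asarray(x, dtype=float).copy()
    if x.shape[0] != len(net.genes):
        raise ValueError("profile length does not match network genes")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    pos = x[x > 0]
    if pos.size == 0:
        raise ValueError("all-zero profile")
    x[x == 0] = zero_eps_scale * pos.min()

    A = net.adjacency.astype(float)
    Ax = A @ x
    if (Ax == 0).any():
        raise ValueError("isolated node encountered; network invariant violated")
    # local entropies S_i = -sum_j P_ij ln P_ij with P_ij = A_ij x_j / (Ax)_i
    S = np.zeros(x.size)
    indptr, indices = A.indptr, A.indices
    for i in range(x.size):
        nbrs = indices[indptr[i] : indptr[i + 1]]
        p = x[nbrs] / Ax[i]
        S[i] = -(p * np.log(p)).sum()
    pi = x * Ax
    pi = pi / pi.sum()
    sr = float((pi * S).sum())
    return sr, sr / net.log_spectral_radius


def entropy_profile(
    adata: ad.AnnData, net: CoexpressionNetwork, zero_eps_scale: float = 1e-3
) -> pd.DataFrame:
    """Per-cell SR and normalized SR for every cell of a dataset."""
    sub = adata[:, [g for g in net.genes]]
    X = _dense(sub.X).astype(float)
    rows = []
    for i in range(X.shape[0]):
        sr, nsr = signaling_entropy(X[i], net, zero_eps_scale=zero_eps_scale)
        rows.append((sr, nsr))
    return pd.DataFrame(
        rows, columns=["SR", "normalized_SR"], index=adata.obs_names
    )


def compare_entropy_by_group(
    profiles: pd.DataFrame, groups: pd.Series, min_cells: int = 5
) -> pd.DataFrame:
    """All pairwise two-sided Wilcoxon rank-sum tests on normalized SR.

    Groups with fewer than ``min_cells`` cells are excluded with a warning;
    p-values are Benjamini-Hochberg adjusted across pairs.
    """
    groups = groups.reindex(profiles.index)
    counts = groups.value_counts()
    usable = [g for g in counts.index if counts[g] >= min_cells]
    dropped = [g for g in counts.index if counts[g] < min_cells]
    if dropped:
        warnings.warn(f"groups excluded (fewer than {min_cells} cells): {dropped}",
                      stacklevel=2)
    if len(usable) < 2:
        raise ValueError("need at least two groups with enough cells")
    rows = []
    vals = profiles["normalized_SR"]
    for i, ga in enumerate(usable):
        for gb in usable[i + 1 :]:
            a = vals[groups == ga]
            b = vals[groups == gb]
            stat, p = stats.ranksums(a, b)
            rows.append({"group_a": ga, "group_b": gb, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    _, q, _, _ = multipletests(out["p"], method="fdr_bh")
    out["q"] = q
    return out
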