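"""Cell/gene quality control and normalization.

The cell sieve applies, in one pass, the four published criteria for this
assay: (i) barcode must rank in the top N by read counts within its
sequencing batch (the whitelist step, represented here as a rank filter on
the matrix); (ii) ERCC count fraction <= 10% and mitochondrial fraction
<= 5%; (iii) detected genes within [200, 6000]; (iv) no stromal marker
(Pecam1, Ptprc, Lyve1, Col1a1) above 0.1 on the log-normalized scale.  Genes
detected in fewer than 10 surviving cells are then dropped.

Normalization is counts-per-``scale_factor`` followed by natural log1p, and
covariates (cell-cycle scores, ERCC/mito fractions, batch, detected-gene
count) can be regressed out gene-wise by OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

STROMAL_MARKERS = ("Pecam1", "Ptprc", "Lyve1", "Col1a1")


@dataclass
class QCThresholds:
    """Published cell- and gene-level QC cutoffs."""

    max_ercc_fraction: float = 0.10
    max_mito_fraction: float = 0.05
    min_genes: int = 200
    max_genes: int = 6000
    stromal_expression_cutoff: float = 0.1
    min_cells_per_gene: int = 10
    barcode_top_n: int = 100

    def __post_init__(self) -> None:
        vals = (
            self.max_ercc_fraction,
            self.max_mito_fraction,
            self.min_genes,
            self.max_genes,
            self.stromal_expression_cutoff,
            self.min_cells_per_gene,
            self.barcode_top_n,
        )
        if any(v < 0 for v in vals):
            raise ValueError("thresholds must be non-negative")
        if self.min_genes >= self.max_genes:
            raise ValueError("min_genes must be below max_genes")


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def cell_qc_flags(adata: ad.AnnData, thresholds: QCThresholds) -> pd.DataFrame:
    """Per-cell boolean pass/fail for each of the four cell criteria."""
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    ercc = adata.var["is_ercc"].to_numpy()
    mito = adata.var["is_mito"].to_numpy()
    markers = adata.var["is_stromal_marker"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc_frac = np.where(total > 0, X[:, ercc].sum(axis=1) / total, 0.0)
        mito_frac = np.where(total > 0, X[:, mito].sum(axis=1) / total, 0.0)
    n_genes = (X > 0).sum(axis=1)

    # whitelist: top-N barcodes per sequencing batch, ranked by read counts
    reads = adata.obs["total_reads"].to_numpy()
    in_top = np.zeros(adata.n_obs, dtype=bool)
    for _, idx in adata.obs.groupby("batch", observed=True).indices.items():
        order = idx[np.argsort(reads[idx], kind="stable")[::-1]]
        in_top[order[: thresholds.barcode_top_n]] = True

    # stromal rule evaluated on the log-normalized scale
    safe_total = np.where(total > 0, total, 1.0)
    marker_norm = np.log1p(X[:, markers] / safe_total[:, None] * 1e4)
    stromal_ok = (marker_norm <= thresholds.stromal_expression_cutoff).all(axis=1)

    return pd.DataFrame(
        {
            "pass_whitelist": in_top,
            "pass_spikein": (ercc_frac <= thresholds.max_ercc_fraction)
            & (mito_frac <= thresholds.max_mito_fraction),
            "pass_gene_count": (n_genes >= thresholds.min_genes)
            & (n_genes <= thresholds.max_genes),
            "pass_stromal": stromal_ok,
            "ercc_fraction": ercc_frac,
            "mito_fraction": mito_frac,
            "n_genes_detected": n_genes,
        },
        index=adata.obs_names,
    )


def filter_cells_and_genes(
    adata: ad.AnnData, thresholds: QCThresholds | None = None
) -> ad.AnnData:
    """Apply the four cell criteria, then drop rarely detected genes.

    Gene detection is counted among surviving cells.  Per-rule exclusion
    counts are logged and stored in ``.uns["qc_report"]`` of the result.
    Raises if no cell survives, naming the most exclusionary rule.
    """
    thresholds = thresholds or QCThresholds()
    flags = cell_qc_flags(adata, thresholds)
    rule_cols = ["pass_whitelist", "pass_spikein", "pass_gene_count", "pass_stromal"]
    keep_cells = flags[rule_cols].all(axis=1).to_numpy()
    excl = {c: int((~flags[c]).sum()) for c in rule_cols}
    if not keep_cells.any():
        worst = max(excl, key=excl.get)
        raise ValueError(
            f"no cell passed QC; dominant filter: {worst} "
            f"(exclusion counts: {excl})"
        )
    out = adata[keep_cells].copy()
    detected = (_dense(out.X) > 0).sum(axis=0)
    keep_genes = detected >= thresholds.min_cells_per_gene
    out = out[:, keep_genes].copy()
    report = {
        "n_cells_in": int(adata.n_obs),
        "n_cells_out": int(out.n_obs),
        "n_genes_in": int(adata.n_vars),
        "n_genes_out": int(out.n_vars),
        "excluded_by_rule": excl,
        "genes_dropped": int((~keep_genes).sum()),
    }
    out.uns["qc_report"] = report
    logger.info("QC: %s", report)
    return out


def normalize(adata: ad.AnnData, scale_factor: int = 10_000) -> ad.AnnData:
    """Log-normalize counts: value = ln(1 + count / cell_total * scale_factor).

    Raw counts are preserved in ``.layers["counts"]``.  Cells with zero total
    counts are an upstream QC failure and raise.
    """
    X = _dense(adata.X).astype(float)
    total = X.sum(axis=1)
    if (total == 0).any():
        bad = list(adata.obs_names[total == 0][:5])
        raise ValueError(f"zero-total cells present (should be filtered): {bad}")
    out = adata.copy()
    out.layers["counts"] = sparse.csr_matrix(X)
    out.X = np.log1p(X / total[:, None] * scale_factor)
    out.uns["normalization"] = {"scale_factor": scale_factor, "log": "natural"}
    return out


def _design_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + numeric columns + one-hot categoricals, full-rank."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in covariates.columns:
        col = covariates[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            for d in dummies.columns:
                cols.append(dummies[d].to_numpy(dtype=float))
                names.append(d)
    X = np.column_stack(cols)
    # drop collinear columns (QR with column pivoting via rank-revealing loop)
    keep = [0]
    for j in range(1, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
        else:
            logger.warning("dropping collinear covariate column %r", names[j])
    return X[:, keep], [names[j] for j in keep]


def regress_covariates(adata: ad.AnnData, covariates: pd.DataFrame) -> ad.AnnData:
    """Replace ``X`` by per-gene OLS residuals against the covariate design.

    The design always includes an intercept; categorical covariates are
    one-hot encoded and collinear columns are dropped with a warning.
    """
    if not covariates.index.equals(adata.obs_names):
        covariates = covariates.reindex(adata.obs_names)
        if covariates.isna().any().any():
            raise ValueError("covariate table does not cover all cells")
    X, used = _design_matrix(covariates)
    Y = _dense(adata.X).astype(float)
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    out = adata.copy()
    out.X = resid
    out.uns["covariates_removed"] = used[1:]
    return out
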