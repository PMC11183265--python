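"""Transcription-factor regulon enrichment and activity scoring.

State gene clusters are tested for enrichment of each TF's target set with
an upper-tail hypergeometric test, independently within each target-database
source; Benjamini-Hochberg correction is applied within source across TFs,
and a TF is a *reliable* candidate for a cluster when it is significant in at
least two sources.  TF activity per cell is the module score of the union of
the TF's targets across sources.  The directional repressor score (the
Bcl11b-style activity) is the sign-flipped weighted mean expression of the
TF's negatively regulated targets, so that strong repression of those
targets reads as high TF activity.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats
from statsmodels.stats.multitest import multipletests

from ._splines import fit_smooth_curves
from .scoring import module_score
from .trajectory import Pseudotime

logger = logging.getLogger(__name__)


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


def enrich_tfs(
    cluster_genes: list[str],
    db: pd.DataFrame,
    matrix_genes: list[str],
    q_cutoff: float = 0.05,
    min_sources: int = 2,
) -> pd.DataFrame:
    """Per-source hypergeometric enrichment of TF targets in a gene cluster.

    ``db`` is a tidy (tf, target, source) table.  For each source the
    universe is the intersection of matrix genes with that source's target
    table; p = P(overlap >= k) under the hypergeometric law with universe
    size N, TF target count K and cluster size n.  Returns one row per
    (tf, source) plus per-TF ``n_supporting_sources`` and ``reliable``.
    """
    db = db.drop_duplicates(subset=["tf", "target", "source"])
    matrix_genes = set(matrix_genes)
    rows = []
    for source, sub in db.groupby("source"):
        universe = set(sub["target"]) & matrix_genes
        n_univ = len(universe)
        cluster_in = set(cluster_genes) & universe
        n_clust = len(cluster_in)
        for tf, targets in sub.groupby("tf")["target"]:
            k_targets = set(targets) & universe
            if not k_targets:
                logger.info("TF %s has no targets in the %s universe; skipped", tf, source)
                continue
            overlap = len(k_targets & cluster_in)
            p = stats.hypergeom.sf(overlap - 1, n_univ, len(k_targets), n_clust)
            rows.append(
                {
                    "tf": tf,
                    "source": source,
                    "universe": n_univ,
                    "tf_targets": len(k_targets),
                    "cluster_size": n_clust,
                    "overlap": overlap,
                    "p": float(min(p, 1.0)),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(q=[], n_supporting_sources=[], reliable=[])
    out["q"] = np.nan
    for source, idx in out.groupby("source").groups.items():
        _, q, _, _ = multipletests(out.loc[idx, "p"], method="fdr_bh")
        out.loc[idx, "q"] = q
    support = (
        out[out["q"] < q_cutoff].groupby("tf")["source"].nunique().rename("n_supporting_sources")
    )
    out = out.merge(support, on="tf", how="left")
    out["n_supporting_sources"] = out["n_supporting_sources"].fillna(0).astype(int)
    out["reliable"] = out["n_supporting_sources"] >= min_sources
    return out.sort_values(["q", "tf"]).reset_index(drop=True)


def tf_targets(db: pd.DataFrame, tf: str) -> list[str]:
    """Union of a TF's targets across all sources."""
    hits = db.loc[db["tf"] == tf, "target"].unique().tolist()
    if not hits:
        raise ValueError(f"TF {tf!r} absent from the target database")
    return hits


def tf_activity_profile(
    adata: ad.AnnData,
    pseudotime: Pseudotime,
    tf: str,
    db: pd.DataFrame,
    seed: int = 0,
    grid_size: int = 100,
    n_bins: int = 24,
    n_controls: int = 100,
) -> tuple[pd.Series, pd.Series]:
    """Per-cell TF activity (module score of its target union) + smoothed curve."""
    targets = tf_targets(db, tf)
    score = module_score(
        adata, targets, set_name=tf, n_bins=n_bins, n_controls=n_controls, seed=seed
    ).scores
    t = pseudotime.values_for(adata)
    grid = np.linspace(0.0, 1.0, grid_size)
    curve = fit_smooth_curves(t, score.to_numpy()[None, :], grid, df=3)[0]
    return score, pd.Series(curve, index=grid, name=tf)


@dataclass
class RegulonDirection:
    """A TF's targets split by regulatory direction, with per-gene weights."""

    positively_regulated: list[str]  # down in KO (KO < WT)
    negatively_regulated: list[str]  # up in KO (KO > WT): repressed targets
    weights: pd.Series  # indexed by gene

    def __post_init__(self) -> None:
        overlap = set(self.positively_regulated) & set(self.negatively_regulated)
        if overlap:
            raise ValueError(f"direction sets must be disjoint; shared: {sorted(overlap)[:5]}")


def derive_regulon_direction(
    wt: ad.AnnData,
    ko: ad.AnnData,
    binding_targets: list[str],
    p_cutoff: float = 0.05,
    weights: str = "stat",
) -> RegulonDirection:
    """Split binding targets by WT-vs-KO differential direction.

    Per-gene two-sided Wilcoxon rank-sum test between WT and KO cells; genes
    with p < cutoff and KO < WT go to ``positively_regulated``, KO > WT to
    ``negatively_regulated``, both intersected with the binding-target list.
    ``weights='stat'`` uses |standardized rank-sum statistic| (renormalized);
    ``'uniform'`` weights all genes equally.
    """
    if wt.n_obs < 20 or ko.n_obs < 20:
        raise ValueError("need >= 20 cells per group")
    genes = [g for g in binding_targets if g in wt.var_names and g in ko.var_names]
    if not genes:
        raise ValueError("no binding targets present in both matrices")
    Xw = _dense(wt[:, genes].X).astype(float)
    Xk = _dense(ko[:, genes].X).astype(float)
    pos, neg, w = [], [], {}
    for j, g in enumerate(genes):
        a, b = Xw[:, j], Xk[:, j]
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            continue
        stat, p = stats.ranksums(b, a)  # positive stat -> KO > WT
        if p >= p_cutoff:
            continue
        if stat > 0:
            neg.append(g)
        elif stat < 0:
            pos.append(g)
        else:
            continue
        w[g] = abs(stat) if weights == "stat" else 1.0
    if not pos and not neg:
        raise ValueError("no differential binding targets in either direction")
    weights_s = pd.Series(w, dtype=float)
    if weights_s.sum() > 0:
        weights_s /= weights_s.sum()
    return RegulonDirection(
        positively_regulated=pos, negatively_regulated=neg, weights=weights_s
    )


def repressor_activity(
    adata: ad.AnnData, direction: RegulonDirection
) -> pd.Series:
    """Directional activity score of a transcriptional repressor.

    score = - sum_g w_g * expr_g / sum_g w_g over the negatively regulated
    targets: when the repressed targets are silent the score is high,
    matching the convention that a functional repressor has high activity.
    """
    genes = [g for g in direction.negatively_regulated if g in adata.var_names]
    if not genes:
        raise ValueError("no negatively regulated genes present in matrix")
    w = direction.weights.reindex(genes).fillna(0.0).to_numpy()
    if w.sum() == 0:
        raise ValueError("all weights are zero for the negatively regulated set")
    X = _dense(adata[:, genes].X).astype(float)
    score = -(X @ w) / w.sum()
    return pd.Series(score, index=adata.obs_names, name="repressor_activity")
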