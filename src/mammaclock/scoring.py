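"""Gene-set module scores, cell-cycle phase calls and pathway dynamics.

The module score follows the expression-bin-matched control convention:
genes are binned by mean expression, each set gene draws control genes from
its own bin, and the score is the per-cell mean over set genes minus the mean
over the pooled controls.  Cell-cycle phases are called from per-phase
average scores (genes kept only if they correlate with their phase average at
r >= 0.25, refined over two rounds) with the quiescence rule: a cell is G0
iff both its G1/S and G2/M z-scores are negative; otherwise the phase with
the maximal z-score is called.

Pathway activities over pseudotime are summarized per state and classified
into the six dynamic patterns (decline, early peak, e-Sen peak, senescence
plateau, continuous late rise, late-only activation).
"""

from __future__ import annotations

from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, stats

from ._splines import fit_smooth_curves
from .trajectory import Pseudotime, StateMap

PHASE_ORDER = ("G1/S", "S", "G2", "G2/M", "M/G1")


def _dense(X) -> np.ndarray:
    return X.toarray() if sparse.issparse(X) else np.asarray(X)


@dataclass
class ModuleScoreResult:
    scores: pd.Series  # per cell
    set_name: str
    n_bins: int
    n_controls: int
    seed: int
    matched_genes: list[str]
    unmatched_genes: list[str]


def match_genes(gene_set: list[str], var_names) -> tuple[list[str], list[str]]:
    """Case-insensitive matching of a gene set to matrix gene names."""
    lookup = {g.lower(): g for g in var_names}
    matched, unmatched = [], []
    for g in gene_set:
        hit = lookup.get(g.lower())
        (matched if hit is not None else unmatched).append(hit or g)
    return matched, unmatched


def module_score(
    adata: ad.AnnData,
    gene_set: list[str],
    set_name: str = "set",
    n_bins: int = 24,
    n_controls: int = 100,
    seed: int = 0,
) -> ModuleScoreResult:
    """Expression-bin-matched module score per cell.

    Genes are ranked by mean expression and cut into ``n_bins`` equal-
    frequency bins; for every set gene, ``n_controls`` genes are sampled
    without replacement from its bin and pooled (duplicates collapsed).
    Score = mean(set genes) - mean(control pool) per cell.
    """
    matched, unmatched = match_genes(gene_set, adata.var_names)
    if not matched:
        raise ValueError(f"no genes of set {set_name!r} in matrix: {unmatched[:10]}")
    rng = np.random.default_rng(seed)
    Y = _dense(adata.X).astype(float)
    gene_mean = Y.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = (ranks * n_bins) // len(order)  # equal-frequency bins

    name_to_idx = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = np.array([name_to_idx[g] for g in matched])
    control: set[int] = set()
    for gi in set_idx:
        pool = np.nonzero(bins == bins[gi])[0]
        pool = pool[pool != gi]
        take = min(n_controls, pool.size)
        control.update(rng.choice(pool, size=take, replace=False).tolist())
    control_idx = np.array(sorted(control - set(set_idx.tolist())))
    if control_idx.size == 0:
        raise ValueError("empty control pool; reduce n_bins or enlarge matrix")
    scores = Y[:, set_idx].mean(axis=1) - Y[:, control_idx].mean(axis=1)
    return ModuleScoreResult(
        scores=pd.Series(scores, index=adata.obs_names, name=set_name),
        set_name=set_name,
        n_bins=n_bins,
        n_controls=n_controls,
        seed=seed,
        matched_genes=matched,
        unmatched_genes=unmatched,
    )


def counts_to_log2_tpm(adata: ad.AnnData) -> pd.DataFrame:
    """log2(TPM + 1) from UMI counts with equal effective gene lengths."""
    X = _dense(adata.layers.get("counts", adata.X)).astype(float)
    total = X.sum(axis=1)
    if (total == 0).any():
        raise ValueError("zero-total cells cannot be TPM-normalized")
    tpm = X / total[:, None] * 1e6
    return pd.DataFrame(
        np.log2(tpm + 1.0), index=adata.obs_names, columns=adata.var_names
    )


@dataclass
class CellCyclePhaseCall:
    phases: pd.Series  # per cell in {G0} | PHASE_ORDER
    z_scores: pd.DataFrame  # cells x phases
    retained_genes: dict[str, list[str]]
    correlation_threshold: float


def call_cell_cycle(
    log_tpm: pd.DataFrame,
    phase_genes: pd.DataFrame,
    rho: float = 0.25,
    n_refinement_rounds: int = 2,
) -> CellCyclePhaseCall:
    """Call cell-cycle phases from log2(TPM+1) and per-phase gene lists.

    ``phase_genes`` has columns (gene, phase) covering the five cycling
    phases.  Per phase, genes must correlate with the phase-average profile
    at Pearson r >= rho; the average is recomputed over the retained genes
    for ``n_refinement_rounds`` rounds.  Phase scores (mean of retained
    genes) are z-scored across cells; G0 iff z(G1/S) < 0 and z(G2/M) < 0,
    else argmax.
    """
    missing = set(PHASE_ORDER) - set(phase_genes["phase"])
    if missing:
        raise ValueError(f"phase lists must cover all cycling phases; missing {missing}")
    retained: dict[str, list[str]] = {}
    scores = {}
    for phase in PHASE_ORDER:
        genes = [g for g in phase_genes.loc[phase_genes["phase"] == phase, "gene"]
                 if g in log_tpm.columns]
        current = list(genes)
        for _ in range(n_refinement_rounds):
            if not current:
                break
            avg = log_tpm[current].mean(axis=1)
            keep = []
            for g in current:
                x = log_tpm[g]
                if x.std() == 0 or avg.std() == 0:
                    continue
                if np.corrcoef(x, avg)[0, 1] >= rho:
                    keep.append(g)
            current = keep
        if not current:
            survival = {p: int((phase_genes["phase"] == p).sum()) for p in PHASE_ORDER}
            raise ValueError(
                f"phase {phase!r} retained zero genes at rho={rho}; "
                f"input list sizes: {survival}"
            )
        retained[phase] = current
        scores[phase] = log_tpm[current].mean(axis=1)
    score_df = pd.DataFrame(scores)
    z = (score_df - score_df.mean()) / score_df.std(ddof=0).replace(0, 1.0)
    is_g0 = (z["G1/S"] < 0) & (z["G2/M"] < 0)
    called = z.idxmax(axis=1).where(~is_g0, "G0")
    return CellCyclePhaseCall(
        phases=called.rename("phase"),
        z_scores=z,
        retained_genes=retained,
        correlation_threshold=rho,
    )


@dataclass
class PathwayDynamics:
    name: str
    state_means: tuple[float, float, float, float]  # range-normalized a1..a4
    curve: pd.Series  # smoothed activity over the pseudotime grid
    pattern: int | None  # 1..6, or None when unclassified


def classify_pattern(a: tuple[float, float, float, float], epsilon: float = 0.1) -> int | None:
    """Map range-normalized state activities (a1..a4 in [0,1]) to a pattern.

    Precedence 6 -> 4 -> 5 -> 3 -> 2 -> 1; a tuple matching no rule is
    unclassified (None).  Rules, with tolerance eps:

    * P6: maximal in state 4, near-silent (<= eps) in states 1-3.
    * P4: states 3 and 4 both >= max(a1, a2) + 3 eps and within eps of
      each other (plateau into state 4).
    * P5: strictly rising a2 < a3 < a4 with a4 - a2 >= 3 eps.
    * P3: maximal in state 3 with a4 <= a3 - 3 eps (peak then drop).
    * P2: maximal in state 2 (transient early peak).
    * P1: maximal in state 1, a4 <= a1 - 3 eps, near-monotone decline.
    """
    a1, a2, a3, a4 = (float(x) for x in a)
    eps = epsilon
    if a4 >= max(a1, a2, a3) and max(a1, a2, a3) <= eps:
        return 6
    if min(a3, a4) >= max(a1, a2) + 3 * eps and abs(a3 - a4) <= eps:
        return 4
    if a4 > a3 > a2 and a4 - a2 >= 3 * eps:
        return 5
    if a3 >= max(a1, a2, a4) and a4 <= a3 - 3 * eps:
        return 3
    if a2 >= max(a1, a3, a4) and (a2 > min(a1, a3, a4)):
        return 2
    if a1 >= max(a2, a3, a4) and a4 <= a1 - 3 * eps and all(
        nxt <= prev + eps for prev, nxt in ((a1, a2), (a2, a3), (a3, a4))
    ):
        return 1
    return None


def pathway_dynamics(
    adata: ad.AnnData,
    pseudotime: Pseudotime,
    states: StateMap,
    gene_sets: dict[str, list[str]],
    epsilon: float = 0.1,
    grid_size: int = 100,
    seed: int = 0,
    n_bins: int = 24,
    n_controls: int = 100,
) -> list[PathwayDynamics]:
    """Score each set per cell, smooth over t, and classify its dynamics."""
    t = pseudotime.values_for(adata)
    grid = np.linspace(0.0, 1.0, grid_size)
    edges = np.concatenate([[0.0], np.asarray(states.boundaries), [1.0 + 1e-12]])
    out = []
    for name, genes in gene_sets.items():
        score = module_score(
            adata, genes, set_name=name, n_bins=n_bins, n_controls=n_controls, seed=seed
        ).scores.to_numpy()
        curve = fit_smooth_curves(t, score[None, :], grid, df=3)[0]
        a = []
        for s in range(4):
            mask = (grid >= edges[s]) & (grid < edges[s + 1])
            a.append(curve[mask].mean() if mask.any() else np.nan)
        a = np.asarray(a)
        rng_span = a.max() - a.min()
        if not np.isfinite(rng_span) or rng_span < 1e-12:
            norm = np.full(4, 0.25)
            pattern = None
        else:
            norm = (a - a.min()) / rng_span
            pattern = classify_pattern(tuple(norm), epsilon=epsilon)
        out.append(
            PathwayDynamics(
                name=name,
                state_means=tuple(norm),
                curve=pd.Series(curve, index=grid, name=name),
                pattern=pattern,
            )
        )
    return out


def paired_pathway_compare(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
    gene_set: list[str],
) -> dict:
    """Paired two-sided t-test of mean set expression between matched samples.

    ``expr_a``/``expr_b`` are samples x genes with matched row order (e.g.
    tumor vs adjacent normal per patient).  The per-sample score is the mean
    over set genes.  With zero variance of the paired differences the t
    statistic is degenerate: p is reported as 1 for all-zero differences and
    flagged below machine epsilon otherwise.
    """
    if len(expr_a) != len(expr_b):
        raise ValueError("paired tables must have equal numbers of samples")
    if len(expr_a) < 2:
        raise ValueError("need at least 2 pairs")
    genes = [g for g in gene_set if g in expr_a.columns and g in expr_b.columns]
    if not genes:
        raise ValueError("no set genes shared by both tables")
    score_a = expr_a[genes].mean(axis=1).to_numpy()
    score_b = expr_b[genes].mean(axis=1).to_numpy()
    diff = score_a - score_b
    sd = diff.std(ddof=1)
    scale = max(np.abs(diff).max(), np.abs(score_a).max(), 1.0)
    zero_variance = sd <= 1e-12 * scale
    if zero_variance:
        if np.allclose(diff, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat = np.inf if diff.mean() > 0 else -np.inf
            p = np.finfo(float).tiny
    else:
        t_stat, p = stats.ttest_rel(score_a, score_b)
    return {
        "score_a": pd.Series(score_a, index=expr_a.index),
        "score_b": pd.Series(score_b, index=expr_b.index),
        "t": float(t_stat),
        "p": float(p),
        "n_pairs": len(diff),
        "zero_variance": bool(zero_variance),
    }
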