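# mammaclock

Chronological single-cell "aging clock" analysis for a mammary stem-cell-
enriched population (CD49f^high EpCAM^low basal cells), implemented as a
tested, reusable Python pipeline with a synthetic-data generator that
carries full ground truth.

Mammary aging in mice is not a binary young/old switch: along a single
latent aging axis, cells occupy four states — active young (a-Young),
quiescent young (q-Young), early senescence (e-Sen) and late senescence
(l-Sen) — whose mixture drifts with age (the a-Young share falls, the l-Sen
share rises). This package reconstructs that axis and everything the
downstream biology hangs on it:

- **QC and normalization** — the four published cell criteria (per-batch
  top-100 barcode whitelist; ERCC fraction ≤ 10% and mitochondrial fraction
  ≤ 5%; 200–6000 detected genes; all four stromal markers Pecam1/Ptprc/
  Lyve1/Col1a1 ≤ 0.1 on the log-normalized scale), a ≥ 10-cell gene filter,
  `ln(1 + count/total × 10⁴)` normalization, and OLS residualization against
  nuisance covariates (ERCC %, mito %, batch, detected genes, cell-cycle
  scores).
- **Pseudotime and state segmentation** — PCA → kNN graph → diffusion
  coordinate → principal-curve projection for a 1-D ordering t ∈ [0, 1];
  per-gene spline likelihood-ratio tests with BH correction to select
  pseudotime-dependent genes; smoothing → log₁₀(x+1) → per-gene z-score →
  truncation to [−3, 3]; Ward clustering of gene curves into four groups;
  cells segmented into the four states where the dominant cluster-average
  curve changes.
- **Signature scoring** — expression-bin-matched module scores (the
  mean-of-set minus mean-of-matched-controls convention), SASP and stemness
  programs, a cell-cycle phase caller (per-phase average scores with an
  r ≥ 0.25 gene filter; G0 iff z(G1/S) < 0 and z(G2/M) < 0), a six-pattern
  classifier for pathway dynamics along pseudotime, and paired two-group
  pathway comparison.
- **TF regulons** — per-source hypergeometric enrichment of TF target sets
  in state gene clusters with a ≥ 2-database consensus rule; TF activity
  profiles over pseudotime; a directional repressor activity score built
  from WT-vs-KO differential targets.
- **Signaling entropy** — the entropy rate of an expression-weighted random
  walk on a thresholded co-expression network, `SR = Σᵢ πᵢ Sᵢ` with
  `P_ij = A_ij x_j / (Ax)_i` and `πᵢ ∝ xᵢ(Ax)ᵢ`, normalized by
  `ln λ_max(A)`; l-Sen cells show the highest normalized entropy.
- **Limiting dilution** — single-hit Poisson model
  `P(outgrowth) = 1 − exp(−f·dose)` fitted by maximum likelihood (cloglog
  link, offset log dose), Wald 95% CI on log f reported as "1 in N", exact
  one-sided bounds at the all-negative/all-positive boundary, and a
  likelihood-ratio test between groups.

The synthetic generator (`mammaclock.simulate`) emulates the study design —
four age groups from 2 to 26 months, negative-binomial UMI counts whose
means follow six dynamic patterns over the latent axis, cell-cycle phase
structure, ERCC/mitochondrial fractions, stromal contaminants, knockout
cells shifted toward the late state, and single-hit transplant tables — so
every stage is testable against known truth without any download.

## Worked example

```python
from mammaclock.simulate import SimulationConfig, generate_aging_dataset
from mammaclock import qc, scoring, trajectory

adata, truth = generate_aging_dataset(SimulationConfig(seed=1))
filtered = qc.filter_cells_and_genes(adata)
norm = qc.normalize(filtered)

log_tpm = scoring.counts_to_log2_tpm(norm)
phases = scoring.call_cell_cycle(log_tpm, truth.phase_gene_table)
pt, genes, curves, clusters, states = trajectory.run_trajectory_stages(
    norm, cell_cycle_scores=phases.z_scores
)
print(states.boundaries)          # (0.2576, 0.5505, 0.8030)
print(dict(states.counts()))      # {1: 215, 2: 229, 3: 198, 4: 154}
```

The three printed boundaries segment the pseudotime axis into the four
states — each within 0.05 of the generator's stamped ground truth at
0.25/0.55/0.85 — and the counts are cells per state; the late-senescence
state is the smallest group, since only the oldest animals contribute many
l-Sen cells.

Limiting dilution, from a transplant table:

```python
import pandas as pd
from mammaclock.elda import fit_frequency

table = pd.DataFrame({"dose": [500], "tested": [16], "positive": [8]})
print(fit_frequency(table))       # 1 in 721.3 (95% CI 355.7-1462.7)
```

A `mammaclock` command-line interface exposes the same stages
(`simulate`, `qc`, `trajectory`, `score`, `entropy`, `elda`, `run-all`);
`run-all` writes every stage output plus a manifest of SHA-256 hashes so a
re-run with the same config is verifiably identical.

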