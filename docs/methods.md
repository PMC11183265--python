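# Methods

This note documents the models, numerical choices and limitations behind
`mammaclock`. It is written for someone who wants to know what the code
computes and why, and what passing the test suite does and does not show.

## The latent model

Cells of a mammary stem-cell-enriched population are placed on one latent
aging axis t ∈ [0, 1]. Four states partition the axis at boundaries
b = (0.25, 0.55, 0.85): a-Young [0, 0.25), q-Young [0.25, 0.55),
e-Sen [0.55, 0.85), l-Sen [0.85, 1]. State 3 is the widest interval,
mirroring its largest observed cell count in this system. The mixture of
states shifts with age; the axis itself does not encode age directly —
every age group contains all four states.

## Synthetic-data generator (`simulate`)

**Counts.** Gene g in cell c is negative-binomial with mean

    mu[g, c] = lib[c] · baseline[g] · exp(amplitude[g] · pattern_g(t_c))

and shared dispersion θ (variance μ + μ²/θ, sampled Gamma–Poisson).
Defaults: θ = 10, baseline ~ LogNormal(0, 1), per-cell library factors
lib ~ LogNormal(0, 0.35), amplitude 1.4 (≈ 4-fold swing) for the 600
pattern genes, 0 otherwise. These are ordinary magnitudes for UMI data
from a plate-based protocol.

**Age → mixture.** Four anchor mixtures (young / middle / old / geriatric)
are linearly interpolated at each configured age; defaults give a
monotonically falling state-1 share (0.55 → 0.05) and rising state-4
share (0.05 → 0.35) from 2 to 26 months, with state 2 roughly stable and
state 3 rising then saturating. Cells draw a state from their age's
mixture and a uniform t inside that state's interval.

**Pattern curves.** The six dynamic patterns are logistic ramps (monotone
patterns 1, 4, 5, 6) and Gaussian bumps (peaked patterns 2, 3):
1 declines over the whole course, 2 peaks in q-Young, 3 peaks in e-Sen,
4 switches on entering e-Sen and plateaus, 5 keeps rising through both
senescent states, 6 activates at the e-Sen/l-Sen boundary. The default
centers/widths were solved in closed form so that the noise-free, z-scored
cluster-average curves (clusters {1}, {2}, {3,4}, {5,6}) intersect exactly
at the stamped boundaries — this makes the generator's ground-truth state
labels and the curve-intersection definition of states mutually
consistent, which is a coherence requirement of the construction, not a
fit to any observed data.

**Cell cycle.** Six phases (G0, G1/S, S, G2, G2/M, M/G1) with default
mixture (0.30, 0.16, 0.15, 0.10, 0.15, 0.14). Each cycling phase owns 20
marker genes (curated phase lists in this field run 13–21 genes after
filtering) with baselines from LogNormal(1.0, 0.5) — markers are
well-expressed genes by definition — elevated e²-fold in matching cells
and e¹-fold in cells of the two adjacent phases of the circular cycle.
The adjacency bleed-through reflects that the cycle transcriptional
program is a continuum; without it, a cell in G2 would show negative
z-scores on both G1/S and G2/M and the standard quiescence rule would
misclassify cycling cells as G0 by construction.

**Technical structure.** 40 ERCC spike-in genes have constant means across
cells (fixed-volume spike-in mix) summing to ~3% of counts; 12
mitochondrial genes scale with the cell's library and contribute ~2%;
five stromal contaminant cells ignore the aging patterns and express the
four stromal markers strongly. Knockout cells, when requested, draw their
states from a late-shifted mixture (default (0.03, 0.07, 0.35, 0.55)).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: doublets, ambient RNA, batch-specific dropout,
gene–gene correlation beyond the shared pattern curves, branching or
discontinuous trajectories, and read-level artifacts. Results on this
generator demonstrate that the pipeline recovers the structure it claims
to recover when that structure is present; they do not certify behavior
under contamination modes the generator lacks.

## QC and normalization (`qc`)

The four cell criteria and the gene filter use the thresholds of the
assay this pipeline targets: per-batch top-100 barcode whitelist (a rank
filter on read counts, standing in for the upstream whitelist step), ERCC
≤ 10%, mito ≤ 5%, 200–6000 detected genes, stromal markers ≤ 0.1, genes
detected in ≥ 10 cells. Two interpretation choices: the stromal cutoff is
evaluated on the log-normalized scale (0.1 raw counts would be
meaningless for integers), and the gene filter runs after the cell
filters so detection is counted among surviving cells. Normalization is
`ln(1 + count/total × 10⁴)`.

Covariate regression is per-gene OLS against an intercept, numeric
covariates, and one-hot batch (collinear columns dropped with a warning).
The cell-cycle covariates are the phase z-scores computed on *unregressed*
data — a fixed two-pass order that breaks the circularity between phase
calling and regression. "Gene number" is regressed as the raw detected
count, not its log.

## Trajectory and states (`trajectory`)

**Pseudotime.** Genes are z-scored, PCA reduced to 10 components, a
Gaussian-kernel kNN graph (k = 15, adaptive bandwidth) built, and the
leading nontrivial eigenvector of the symmetrized diffusion operator
taken as the 1-D coordinate; a principal curve (spline fit of each PC
against the order, two projection iterations) refines it. The coordinate
is rank-uniformed, oriented so the root age group (2 months) sits early,
and min-max rescaled. This is the package's one deliberate methodological
substitution: the original analysis used a tree-based embedding, but the
trajectory in this system is linear, so a principal-curve coordinate is
an adequate, simpler stand-in.

It matters that the matrix entering pseudotime has technical covariates
*and* cell-cycle scores regressed out: the phase program is a strong
axis orthogonal to aging, and library-composition drift (strong late
programs inflate totals, deflating every other gene's normalized value)
otherwise makes hundreds of flat genes spuriously pseudotime-significant.

**Gene test.** Gaussian likelihood-ratio test of a natural cubic spline
in t (3 df, knots at quantiles) against an intercept, χ²(3), BH-corrected,
q < 0.05. Calibration is verified by simulation (null fraction at
p < 0.05 is 0.050 across seeds). Zero-variance genes get p = 1.

**Curves.** Selected genes are spline-smoothed on a 100-point grid,
log₁₀(x+1)-transformed, z-scored per gene across the grid, and clamped to
[−3, 3]. Smoothing uses a 6-df natural spline — more flexible than the
3-df basis of the gene test — because the late-activating programs turn
on over a small fraction of the axis and a 3-df fit visibly displaces
the curve crossings that define the state boundaries. Negative spline
fits are clamped to 0 before the log.

**States.** Ward/Euclidean hierarchical clustering of the curves, cut at
k = 4. Each grid point is labeled by the argmax cluster-average curve;
the label sequence is smoothed with a 5-point majority filter and runs
shorter than 3 grid points are collapsed, which suppresses micro-states
at near-tangent crossings. Exactly four dominance intervals are required
(otherwise an error suggests re-clustering); the three transition
midpoints are the boundaries, and clusters are renumbered 1→4 by
dominance order. "Intersection" is implemented as argmax change, which
coincides with pairwise curve crossings when each cluster dominates one
interval — the regime the construction guarantees.

## Scoring (`scoring`)

**Module score.** Genes are ranked by mean expression into 24
equal-frequency bins; each set gene draws 100 controls without
replacement from its own bin; controls are pooled (duplicates collapsed,
set genes excluded) and the score is mean(set) − mean(controls) per cell.
The score is shift-invariant and reproducible given the seed; the suite
checks exact agreement with an independently coded two-mean oracle.

**Phase caller.** Input is log₂(TPM+1) with equal effective gene lengths
(UMI data). Per phase, genes must correlate at Pearson r ≥ 0.25 with the
phase-average profile; the average is recomputed over survivors for two
refinement rounds (the iteration count is a choice; one round changes
little on clean lists). Phase scores are z-scored across cells; G0 iff
z(G1/S) < 0 and z(G2/M) < 0, else argmax over the five phases.

**Pattern classifier.** On range-normalized state means a₁..a₄ with
tolerance ε = 0.1, in precedence order: P6 (max in state 4, a₁..a₃ ≤ ε),
P4 (a₃, a₄ ≥ max(a₁,a₂)+3ε and |a₃−a₄| ≤ ε), P5 (a₄ > a₃ > a₂,
a₄−a₂ ≥ 3ε), P3 (max at a₃, a₄ ≤ a₃−3ε), P2 (max at a₂), P1 (max at a₁,
a₄ ≤ a₁−3ε, near-monotone decline), else unclassified. Total by
construction: every 4-tuple maps to exactly one label or None.

## TF regulons (`tfnet`)

Per source, the universe is the intersection of matrix genes with that
source's target table (sources differ in coverage; a shared universe
would penalize the smaller ones). Upper-tail hypergeometric p per
(TF, source), BH within source across TFs, and a TF is *reliable* for a
cluster when significant (q < 0.05) in ≥ 2 sources. TF activity is the
module score of the union of the TF's targets across sources.

The directional repressor score splits binding targets by WT-vs-KO
rank-sum direction (p < 0.05) and scores cells as the sign-flipped
weighted mean of the negatively regulated (KO-up, i.e. repressed)
targets. Weights are |standardized rank-sum statistic|, renormalized;
uniform weights are available (`weights="uniform"`) since the weighting
convention is not canonical. The sign flip makes the score read as
activity: silent repressed targets ⇒ high repressor activity.

## Signaling entropy (`entropy`)

Network: Pearson correlation across cells thresholded at r ≥ 0.3
(positive correlation; unweighted), restricted to the largest connected
component. In the pipeline the network is built over the
pseudotime-significant genes — the aging programs themselves — and is fit
on the reference wild-type data, then frozen before being applied to
perturbed cells. Entropy: P_ij = A_ij x_j / (Ax)_i, π_i ∝ x_i(Ax)_i
(exact stationary distribution of this reversible chain; verified
against eigen-decomposition to 1e-8), SR = Σ π_i S_i, normalized by
ln λ_max(A). Exact zeros are replaced by 10⁻³ × the smallest positive
entry, since the walk is undefined on zero-weight nodes. The normalized
rate is scale-invariant and bounded by 1.

## Limiting dilution (`elda`)

Single-hit model: P(positive well) = 1 − exp(−f·dose). The MLE of
β = log f is a binomial GLM with complementary log-log link, offset
log(dose) and slope fixed at 1, solved by damped Newton iteration on the
closed-form score (cross-checked against an independent GLM fit and a
dense grid-search oracle). Wald 95% CI on β, inverted to "1 in N
(lower–upper)" — the reporting convention of this assay; a
profile-likelihood CI is available behind `profile_ci=True`. All-negative
tables return f̂ = 0 with the exact bound −ln(0.05)/Σ(dose·wells);
all-positive tables return the analogous lower bound solved numerically.
Group comparison is a likelihood-ratio χ²(groups−1) of pooled vs
per-group frequencies, using the likelihood supremum (with a warning)
when a group is on the boundary. Simulated coverage of the Wald CI at
f = 1/500 with 4 doses × 12 wells is ~95%.

## Problem sizes

The default study conditions are 4 age groups × 200 cells, 1500 genes
(600 pattern genes), 5 contaminants; the QC acceptance check uses a
500-cell matrix; calibration uses 400 cells × 1000 null genes; coverage
uses 1000 simulated transplant experiments. These sizes were chosen so
each property is measured with adequate precision (binomial standard
errors well inside the stated tolerances) while a full suite run stays
interactive.

## Known limitations

- The 1-D pseudotime assumes a linear trajectory; branching data would
  need a different embedding and would break the four-interval
  segmentation.
- State boundaries inherit the rank-uniform scale of the inferred
  pseudotime; if the aggregate state occupancy is very unbalanced, the
  rank scale distorts distances relative to the latent axis.
- The entropy network uses positive correlations only; anti-correlated
  program pairs land in separate components and only the largest is kept.
- The phase caller's G0 rule depends on z-scores across the analyzed
  population; on a dataset of almost-all-quiescent cells the z reference
  shifts and G0 recall degrades.
- Wald CIs for limiting dilution are asymptotic; with very few wells or
  extreme doses the profile-likelihood option is preferable.
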