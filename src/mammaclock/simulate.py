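"""Synthetic aging-dataset generator with known ground truth.

Emulates the statistical structure of a chronological single-cell survey of a
mammary stem-cell-enriched population: four latent cell states ordered along
one latent aging axis in [0, 1], an age-dependent state mixture (the young
state shrinking and the late-senescence state expanding with age), gene
programs following six dynamic patterns over the axis, cell-cycle phase
structure, ERCC spike-in and mitochondrial count fractions, stromal
contaminant cells, optional knockout cells shifted toward the late state, and
limiting-dilution transplant tables drawn from a single-hit model.

Counts are negative-binomial: for gene g in cell c,

    mu[g, c] = library_size[c] * baseline[g] * exp(amplitude[g] * pattern_g(t_c))

with a shared dispersion theta (variance mu + mu^2 / theta) and log-normal
per-cell library-size factors.  ERCC spike-ins have constant means across
cells, mimicking fixed-volume spike-in mixes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse

STROMAL_MARKERS = ("Pecam1", "Ptprc", "Lyve1", "Col1a1")
PHASES = ("G0", "G1/S", "S", "G2", "G2/M", "M/G1")
CYCLING_PHASES = ("G1/S", "S", "G2", "G2/M", "M/G1")

#: Age-group anchor mixtures over the four states (young, middle, old,
#: geriatric).  State 1 declines monotonically with age, state 4 rises,
#: state 2 is roughly stable and state 3 rises then saturates.
ANCHOR_AGES = (3.0, 11.0, 18.5, 26.5)
ANCHOR_MIXTURES = (
    (0.55, 0.25, 0.15, 0.05),
    (0.35, 0.30, 0.25, 0.10),
    (0.15, 0.30, 0.40, 0.15),
    (0.05, 0.20, 0.40, 0.35),
)


@dataclass
class PatternShape:
    """Parametric curve for one dynamic pattern, mapping t in [0,1] to [0,1].

    ``kind`` is one of ``ramp_up`` / ``ramp_down`` (logistic) or ``bump``
    (Gaussian); ``center`` and ``width`` position it on the aging axis.
    """

    kind: str
    center: float
    width: float

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "ramp_up":
            return 1.0 / (1.0 + np.exp(-(t - self.center) / self.width))
        if self.kind == "ramp_down":
            return 1.0 / (1.0 + np.exp((t - self.center) / self.width))
        if self.kind == "bump":
            return np.exp(-0.5 * ((t - self.center) / self.width) ** 2)
        raise ValueError(f"unknown pattern kind {self.kind!r}")


#: Default shapes for the six dynamic patterns: 1 declines over the whole
#: course, 2 peaks in the quiescent-young interval, 3 peaks in early
#: senescence, 4 switches on at early senescence and plateaus, 5 keeps rising
#: through both senescent states, 6 activates at the e-Sen/l-Sen boundary.
DEFAULT_PATTERN_SHAPES: dict[int, PatternShape] = {
    1: PatternShape("ramp_down", 0.28, 0.08),
    2: PatternShape("bump", 0.36, 0.10),
    3: PatternShape("bump", 0.70, 0.09),
    4: PatternShape("ramp_up", 0.60, 0.04),
    5: PatternShape("ramp_up", 0.86, 0.07),
    6: PatternShape("ramp_up", 0.94, 0.035),
}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic aging dataset.

    Defaults describe four age groups of 200 cells (2, 11, 18 and 26 months)
    with mixtures interpolated between the young/middle/old/geriatric anchors,
    1500 genes of which 600 follow one of the six dynamic patterns, shared NB
    dispersion 10, ~3% ERCC and ~2% mitochondrial count fractions, and five
    stromal contaminant cells.
    """

    ages: tuple[float, ...] = (2.0, 11.0, 18.0, 26.0)
    n_cells_per_age: int = 200
    state_mixtures: dict[float, tuple[float, float, float, float]] | None = None
    n_genes: int = 1500
    pattern_counts: tuple[int, int, int, int, int, int] = (120, 80, 100, 100, 120, 80)
    pattern_shapes: dict[int, PatternShape] = field(
        default_factory=lambda: dict(DEFAULT_PATTERN_SHAPES)
    )
    amplitude: float = 1.4
    baseline_lognormal: tuple[float, float] = (0.0, 1.0)
    nb_dispersion: float = 10.0
    library_size_lognormal: tuple[float, float] = (0.0, 0.35)
    ercc_fraction: float = 0.03
    n_ercc: int = 40
    mito_fraction: float = 0.02
    n_mito: int = 12
    n_stromal_contaminants: int = 5
    phase_mixture: tuple[float, ...] = (0.30, 0.16, 0.15, 0.10, 0.15, 0.14)
    n_phase_genes: int = 20
    phase_amplitude: float = 2.0
    phase_adjacency_fraction: float = 0.5  # neighbor-phase bleed-through
    phase_gene_baseline_lognormal: tuple[float, float] = (1.0, 0.5)
    state_boundaries: tuple[float, float, float] = (0.25, 0.55, 0.85)
    n_ko_cells: int = 0
    ko_state_mixture: tuple[float, float, float, float] = (0.03, 0.07, 0.35, 0.55)
    ko_age_months: float = 4.0
    batch_size: int = 100
    reads_per_umi: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_age <= 0 or self.n_genes <= 0:
            raise ValueError("cell and gene counts must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if abs(sum(self.phase_mixture) - 1.0) > 1e-9:
            raise ValueError("phase_mixture must sum to 1")
        if len(self.phase_mixture) != len(PHASES):
            raise ValueError(f"phase_mixture needs {len(PHASES)} entries")
        b = self.state_boundaries
        if not (0 < b[0] < b[1] < b[2] < 1):
            raise ValueError("state boundaries must be increasing in (0, 1)")
        for age, mix in self.resolved_mixtures().items():
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"state mixture for age {age} must sum to 1")
        n_special = (
            sum(self.pattern_counts)
            + len(CYCLING_PHASES) * self.n_phase_genes
            + len(STROMAL_MARKERS)
            + self.n_mito
            + self.n_ercc
        )
        if n_special > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} too small for {n_special} structured genes"
            )

    def resolved_mixtures(self) -> dict[float, tuple[float, float, float, float]]:
        """State mixture per age, interpolated between anchors when unset."""
        if self.state_mixtures is not None:
            return dict(self.state_mixtures)
        anchors = np.asarray(ANCHOR_MIXTURES)
        out = {}
        for age in self.ages:
            mix = np.array(
                [np.interp(age, ANCHOR_AGES, anchors[:, s]) for s in range(4)]
            )
            mix = mix / mix.sum()
            out[age] = tuple(mix)
        return out


@dataclass
class GroundTruth:
    """Latent variables behind a generated dataset (parallel to the matrix)."""

    t_true: np.ndarray  # per cell; NaN for contaminants
    state_true: np.ndarray  # per cell in {1..4}; 0 for contaminants
    phase_true: np.ndarray  # per cell phase label
    is_contaminant: np.ndarray  # per cell bool
    pattern_true: np.ndarray  # per gene in {0..6}; 0 = no pattern
    baseline: np.ndarray  # per gene NB baseline mean
    amplitude: np.ndarray  # per gene log-scale pattern amplitude
    boundaries: tuple[float, float, float]
    gene_sets: dict[str, list[str]]
    phase_gene_table: pd.DataFrame  # columns: gene, phase

    def state_of(self, t: np.ndarray) -> np.ndarray:
        """Map latent times onto states via the configured boundaries."""
        return 1 + np.searchsorted(np.asarray(self.boundaries), np.asarray(t))


def _sample_states(rng, mixture: np.ndarray, n: int) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(mixture) / np.sum(mixture)) + 1


def _t_within_state(rng, states: np.ndarray, boundaries) -> np.ndarray:
    edges = np.concatenate([[0.0], boundaries, [1.0]])
    lo = edges[states - 1]
    hi = edges[states]
    return rng.uniform(lo, hi)


def _nb_sample(rng, mu: np.ndarray, theta: float) -> np.ndarray:
    """Gamma–Poisson draw with mean mu and variance mu + mu^2/theta."""
    lam = rng.gamma(shape=theta, scale=np.maximum(mu, 1e-300) / theta)
    return rng.poisson(lam)


def generate_aging_dataset(config: SimulationConfig) -> tuple[ad.AnnData, GroundTruth]:
    """Generate a UMI count matrix (cells x genes) with ground truth.

    Returns an :class:`anndata.AnnData` with raw counts in ``X``, cell
    metadata (``age_months``, ``batch``, ``genotype``, ``treatment``,
    ``total_reads``) in ``obs`` and gene flags (``is_ercc``, ``is_mito``,
    ``is_stromal_marker``) in ``var``, plus the :class:`GroundTruth`.
    Identical configs (same seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    mixtures = config.resolved_mixtures()

    per_state_total = np.zeros(4)
    for mix in mixtures.values():
        per_state_total += np.asarray(mix) * config.n_cells_per_age
    for s in range(4):
        if per_state_total[s] < 1.0:
            warnings.warn(
                f"state {s + 1} has near-zero expected cells at every age; "
                "downstream state recovery will be unreliable",
                stacklevel=2,
            )

    # ---- cells -----------------------------------------------------------
    ages_col, states, genotypes = [], [], []
    for age in config.ages:
        st = _sample_states(rng, np.asarray(mixtures[age]), config.n_cells_per_age)
        states.append(st)
        ages_col.extend([age] * config.n_cells_per_age)
        genotypes.extend(["WT"] * config.n_cells_per_age)
    if config.n_ko_cells > 0:
        st = _sample_states(rng, np.asarray(config.ko_state_mixture), config.n_ko_cells)
        states.append(st)
        ages_col.extend([config.ko_age_months] * config.n_ko_cells)
        genotypes.extend(["KO"] * config.n_ko_cells)
    states = np.concatenate(states)
    n_real = states.size
    t_true = _t_within_state(rng, states, np.asarray(config.state_boundaries))
    phases = rng.choice(PHASES, size=n_real, p=np.asarray(config.phase_mixture))

    n_cont = config.n_stromal_contaminants
    n_cells = n_real + n_cont
    is_cont = np.zeros(n_cells, dtype=bool)
    is_cont[n_real:] = True
    t_all = np.concatenate([t_true, np.full(n_cont, np.nan)])
    state_all = np.concatenate([states, np.zeros(n_cont, dtype=int)])
    phase_all = np.concatenate([phases, np.array(["G0"] * n_cont)])
    age_all = np.concatenate(
        [np.asarray(ages_col), np.full(n_cont, config.ages[0], dtype=float)]
    )
    geno_all = np.concatenate([np.asarray(genotypes), np.array(["stromal"] * n_cont)])

    # ---- genes -----------------------------------------------------------
    names: list[str] = []
    pattern_true: list[int] = []
    phase_of_gene: list[str] = []
    for p, cnt in enumerate(config.pattern_counts, start=1):
        for i in range(cnt):
            names.append(f"P{p}g{i:03d}")
            pattern_true.append(p)
            phase_of_gene.append("")
    for ph in CYCLING_PHASES:
        tag = ph.replace("/", "")
        for i in range(config.n_phase_genes):
            names.append(f"Cc{tag}g{i:02d}")
            pattern_true.append(0)
            phase_of_gene.append(ph)
    for m in STROMAL_MARKERS:
        names.append(m)
        pattern_true.append(0)
        phase_of_gene.append("")
    for i in range(config.n_mito):
        names.append(f"mt-G{i:02d}")
        pattern_true.append(0)
        phase_of_gene.append("")
    for i in range(config.n_ercc):
        names.append(f"ERCC-{i:05d}")
        pattern_true.append(0)
        phase_of_gene.append("")
    n_named = len(names)
    for i in range(config.n_genes - n_named):
        names.append(f"Null{i:04d}")
        pattern_true.append(0)
        phase_of_gene.append("")
    pattern_true = np.asarray(pattern_true)
    phase_of_gene = np.asarray(phase_of_gene, dtype=object)
    is_ercc = np.char.startswith(np.asarray(names, dtype=str), "ERCC-")
    is_mito = np.char.startswith(np.asarray(names, dtype=str), "mt-")
    is_marker = np.isin(np.asarray(names), STROMAL_MARKERS)
    is_bio = ~(is_ercc | is_mito)

    mu0, sig0 = config.baseline_lognormal
    baseline = rng.lognormal(mu0, sig0, size=config.n_genes)
    baseline[is_marker] = 0.002  # near-silent in epithelial cells
    # cycle markers are expressed genes by definition; give them a solid floor
    is_phase_gene = phase_of_gene != ""
    baseline[is_phase_gene] = rng.lognormal(
        *config.phase_gene_baseline_lognormal, size=int(is_phase_gene.sum())
    )
    amplitude = np.where(pattern_true > 0, config.amplitude, 0.0)

    lib = rng.lognormal(*config.library_size_lognormal, size=n_cells)

    # ---- means -----------------------------------------------------------
    mu = np.empty((config.n_genes, n_cells))
    t_filled = np.where(np.isnan(t_all), 0.5, t_all)
    curve = np.ones((config.n_genes, n_cells))
    for p, shape in config.pattern_shapes.items():
        sel = pattern_true == p
        if sel.any():
            curve[sel] = shape(t_filled)[None, :]
    mu[:] = baseline[:, None] * np.exp(amplitude[:, None] * np.where(
        pattern_true[:, None] > 0, curve, 0.0
    ))
    # phase programs: elevated in cells of the matching phase, with partial
    # bleed-through into the two adjacent phases of the (circular) cycle —
    # the cycle transcriptional program is a continuum, not disjoint blocks
    n_ph = len(CYCLING_PHASES)
    for gi, ph in enumerate(CYCLING_PHASES):
        g = phase_of_gene == ph
        for ci, ph_cell in enumerate(CYCLING_PHASES):
            c = phase_all == ph_cell
            if ci == gi:
                bump_amp = config.phase_amplitude
            elif (ci - gi) % n_ph in (1, n_ph - 1):
                bump_amp = config.phase_amplitude * config.phase_adjacency_fraction
            else:
                continue
            mu[np.ix_(g, c)] *= np.exp(bump_amp)
    # contaminants ignore aging patterns and express the stromal markers
    if n_cont:
        cont = is_cont
        mu[np.ix_(is_bio, cont)] = baseline[is_bio, None]
        mu[np.ix_(is_marker, cont)] = 20.0
    mu *= lib[None, :]

    # mitochondrial and spike-in blocks scaled to the target count fractions
    bio_tot = mu[is_bio].sum(axis=0)
    rest = 1.0 - config.ercc_fraction - config.mito_fraction
    if config.n_mito:
        w = rng.dirichlet(np.full(config.n_mito, 5.0))
        mu[is_mito] = w[:, None] * bio_tot[None, :] * (config.mito_fraction / rest)
        bio_tot = mu[is_bio].sum(axis=0)
    if config.n_ercc:
        w = rng.dirichlet(np.full(config.n_ercc, 5.0))
        mu[is_ercc] = (
            w[:, None] * bio_tot.mean() * (config.ercc_fraction / rest)
        ) * np.ones((1, n_cells))

    counts = _nb_sample(rng, mu, config.nb_dispersion)

    # ---- metadata --------------------------------------------------------
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]
    batch = []
    counter: dict[float, int] = {}
    for a in age_all:
        k = counter.get(a, 0)
        batch.append(f"age{a:g}_b{k // config.batch_size}")
        counter[a] = k + 1
    total_reads = rng.poisson(counts.sum(axis=0) * config.reads_per_umi)

    obs = pd.DataFrame(
        {
            "age_months": age_all,
            "batch": batch,
            "genotype": geno_all,
            "treatment": "none",
            "total_reads": total_reads,
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    var = pd.DataFrame(
        {
            "is_ercc": is_ercc,
            "is_mito": is_mito,
            "is_stromal_marker": is_marker,
        },
        index=pd.Index(names, name="gene"),
    )
    adata = ad.AnnData(
        X=sparse.csr_matrix(counts.T.astype(np.int64)), obs=obs, var=var
    )

    p4 = [n for n, p in zip(names, pattern_true) if p == 4]
    p5 = [n for n, p in zip(names, pattern_true) if p == 5]
    gene_sets = {
        "SASP": p4[:25] + p5[:15],  # senescence-linked secretory program
        "stemness": p5[40:70],
        "bcl11b_targets": p5[:60] + p4[50:70],
    }
    phase_table = pd.DataFrame(
        {
            "gene": [n for n, ph in zip(names, phase_of_gene) if ph],
            "phase": [ph for ph in phase_of_gene if ph],
        }
    )
    truth = GroundTruth(
        t_true=t_all,
        state_true=state_all,
        phase_true=phase_all,
        is_contaminant=is_cont,
        pattern_true=pattern_true,
        baseline=baseline,
        amplitude=amplitude,
        boundaries=config.state_boundaries,
        gene_sets=gene_sets,
        phase_gene_table=phase_table,
    )
    return adata, truth


def plant_qc_violations(
    adata: ad.AnnData, seed: int = 0, n_per_rule: int = 1
) -> pd.DataFrame:
    """Modify cells in place so each QC rule has planted violators.

    Distinct cells are given, in order: excess ERCC fraction, excess
    mitochondrial fraction, too few detected genes, too many detected genes
    (when the matrix is gene-rich enough), and stromal-marker expression.
    Returns a table (barcode, rule) of the planted violations.
    """
    rng = np.random.default_rng(seed)
    X = adata.X.toarray() if sparse.issparse(adata.X) else np.asarray(adata.X).copy()
    n_cells = X.shape[0]
    rules = ["ercc", "mito", "low_genes", "high_genes", "stromal"]
    need = n_per_rule * len(rules)
    chosen = rng.choice(n_cells, size=need, replace=False)
    records = []
    i = 0
    for rule in rules:
        for _ in range(n_per_rule):
            c = chosen[i]
            i += 1
            if rule == "ercc":
                mask = adata.var["is_ercc"].to_numpy()
                X[c, mask] += int(np.ceil(X[c].sum())) // max(mask.sum(), 1) + 5
            elif rule == "mito":
                mask = adata.var["is_mito"].to_numpy()
                X[c, mask] += int(np.ceil(X[c].sum())) // max(mask.sum(), 1) + 5
            elif rule == "low_genes":
                keep = rng.choice(X.shape[1], size=50, replace=False)
                row = np.zeros(X.shape[1])
                row[keep] = np.maximum(X[c, keep], 1)
                X[c] = row
            elif rule == "high_genes":
                X[c] = np.maximum(X[c], 1)  # detected in every gene
            elif rule == "stromal":
                mask = adata.var["is_stromal_marker"].to_numpy()
                X[c, mask] += 25
            records.append({"barcode": adata.obs_names[c], "rule": rule})
    adata.X = sparse.csr_matrix(X.astype(np.int64))
    return pd.DataFrame(records)


def generate_tf_database(
    n_tfs: int,
    targets_per_tf: int,
    n_sources: int,
    universe: list[str],
    planted_tf: str,
    planted_cluster: list[str],
    planted_cluster_overlap: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Random TF->target database with one TF enriched in a planted cluster.

    The planted TF draws ``planted_cluster_overlap`` of its targets from
    ``planted_cluster`` in at least two sources; every other target set is
    uniform over the universe.  Returns a tidy table (tf, target, source).
    """
    if planted_cluster_overlap > targets_per_tf:
        raise ValueError("planted overlap cannot exceed targets_per_tf")
    if planted_cluster_overlap > len(planted_cluster):
        raise ValueError("planted overlap exceeds cluster size")
    if n_sources < 2:
        raise ValueError("need at least two sources for a consensus database")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    cluster = list(planted_cluster)
    off_cluster = [g for g in universe if g not in set(cluster)]
    sources = [f"source{s}" for s in range(n_sources)]
    tf_names = [planted_tf] + [f"TF{i:03d}" for i in range(n_tfs - 1)]
    rows = []
    for src_i, src in enumerate(sources):
        for tf in tf_names:
            if tf == planted_tf and src_i < 2:
                hit = list(rng.choice(cluster, size=planted_cluster_overlap, replace=False))
                n_rest = targets_per_tf - planted_cluster_overlap
                rest = (
                    list(rng.choice(off_cluster, size=n_rest, replace=False))
                    if n_rest
                    else []
                )
                targets = hit + rest
            else:
                targets = list(rng.choice(universe, size=targets_per_tf, replace=False))
            rows.extend({"tf": tf, "target": g, "source": src} for g in targets)
    return pd.DataFrame(rows)


def generate_ld_assay(
    true_frequency: float,
    doses: list[int],
    replicates: int,
    n_groups: int = 1,
    seed: int = 0,
    group_frequencies: list[float] | None = None,
) -> pd.DataFrame:
    """Limiting-dilution outcome table under the single-hit Poisson model.

    Each well receives ``dose`` cells and turns positive independently with
    probability ``1 - exp(-f * dose)``.  Returns a tidy table with columns
    (group, dose, tested, positive).
    """
    if not all(d > 0 for d in doses):
        raise ValueError("doses must be positive")
    freqs = group_frequencies if group_frequencies is not None else [true_frequency] * n_groups
    if any(not (0 <= f <= 1) for f in freqs):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for gi, f in enumerate(freqs):
        for d in doses:
            p = 1.0 - np.exp(-f * d)
            pos = int(rng.binomial(replicates, p))
            rows.append(
                {"group": f"group{gi}", "dose": d, "tested": replicates, "positive": pos}
            )
    return pd.DataFrame(rows)
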