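"""End-to-end pipeline orchestration with a reproducibility manifest.

Stages run in a fixed order (simulate -> qc -> normalize -> trajectory ->
states -> scores -> tf -> entropy); every stage writes its outputs into a
run directory and a manifest JSON records seeds, stage parameters and
SHA-256 hashes of every file, so two runs with the same config are
hash-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import entropy as entropy_mod
from . import io as mio
from . import qc as qc_mod
from . import scoring, simulate, tfnet, trajectory

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Serializable configuration for a full run."""

    out_dir: str = "runs/run0"
    seed: int = 0
    input_prefix: str | None = None  # read counts instead of simulating
    simulate: bool = True
    n_cells_per_age: int = 200
    n_genes: int = 1500
    root_age_months: float = 2.0
    scale_factor: int = 10_000
    q_cutoff: float = 0.05
    grid_size: int = 100
    k_clusters: int = 4
    score_bins: int = 24
    score_controls: int = 100
    entropy_r_min: float = 0.3
    run_entropy: bool = True
    qc: dict = field(default_factory=dict)  # QCThresholds overrides

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config), "stages": {}, "files": {}}
    stage = "simulate"
    try:
        if config.simulate or config.input_prefix is None:
            sim_cfg = simulate.SimulationConfig(
                n_cells_per_age=config.n_cells_per_age,
                n_genes=config.n_genes,
                seed=config.seed,
            )
            adata, truth = simulate.generate_aging_dataset(sim_cfg)
            mio.write_count_matrix(adata, out / "counts")
            mio.write_gmt(truth.gene_sets, out / "gene_sets.gmt")
            truth.phase_gene_table.to_csv(out / "phase_genes.tsv", sep="\t", index=False)
            manifest["stages"]["simulate"] = {"n_cells": adata.n_obs, "n_genes": adata.n_vars}
        else:
            adata = mio.read_count_matrix(config.input_prefix)
            truth = None
            manifest["stages"]["simulate"] = "skipped (input provided)"

        stage = "qc"
        thresholds = qc_mod.QCThresholds(**config.qc)
        filtered = qc_mod.filter_cells_and_genes(adata, thresholds)
        manifest["stages"]["qc"] = filtered.uns["qc_report"]

        stage = "normalize"
        norm = qc_mod.normalize(filtered, scale_factor=config.scale_factor)

        stage = "trajectory"
        cc_scores = None
        if truth is not None:
            lt = scoring.counts_to_log2_tpm(norm)
            cc_scores = scoring.call_cell_cycle(lt, truth.phase_gene_table).z_scores
        pt, gene_table, curves, clusters, states = trajectory.run_trajectory_stages(
            norm,
            root_age_months=config.root_age_months,
            q_cutoff=config.q_cutoff,
            grid_size=config.grid_size,
            k=config.k_clusters,
            cell_cycle_scores=cc_scores,
        )
        genes = list(gene_table.index[gene_table["selected"]])
        manifest["stages"]["trajectory"] = {"n_significant_genes": len(genes)}

        stage = "states"
        traj_df = pd.DataFrame(
            {"pseudotime": pt.t, "state": states.states}, index=pt.t.index
        )
        traj_df.to_csv(out / "pseudotime.tsv", sep="\t")
        curves.values.to_csv(out / "smoothed_curves.tsv", sep="\t")
        clusters.to_csv(out / "gene_clusters.tsv", sep="\t")
        with open(out / "state_boundaries.json", "w") as fh:
            json.dump({"boundaries": list(states.boundaries),
                       "counts": {int(k): int(v) for k, v in states.counts().items()}}, fh)
        manifest["stages"]["states"] = {
            "boundaries": list(states.boundaries),
            "counts": {int(k): int(v) for k, v in states.counts().items()},
        }

        stage = "scores"
        if truth is not None:
            sets = truth.gene_sets
        else:
            sets = {}
        score_rows = {}
        for name, genes_set in sets.items():
            res = scoring.module_score(
                norm, genes_set, set_name=name, n_bins=config.score_bins,
                n_controls=config.score_controls, seed=config.seed,
            )
            score_rows[name] = res.scores
        if score_rows:
            pd.DataFrame(score_rows).to_csv(out / "module_scores.tsv", sep="\t")
        manifest["stages"]["scores"] = {"sets": sorted(score_rows)}

        stage = "tf"
        if truth is not None:
            cluster4 = list(clusters.index[clusters == states.cluster_order[3]])
            db = simulate.generate_tf_database(
                n_tfs=30, targets_per_tf=30, n_sources=3,
                universe=list(norm.var_names),
                planted_tf="TFplanted", planted_cluster=cluster4 or list(norm.var_names[:50]),
                planted_cluster_overlap=min(20, max(1, len(cluster4))),
                seed=config.seed,
            )
            enr = tfnet.enrich_tfs(cluster4, db, list(norm.var_names))
            enr.to_csv(out / "tf_enrichment.csv", index=False)
            manifest["stages"]["tf"] = {
                "n_reliable": int(enr[enr["reliable"]]["tf"].nunique()) if not enr.empty else 0
            }
        else:
            manifest["stages"]["tf"] = "skipped (no gene clusters labeled)"

        stage = "entropy"
        if config.run_entropy:
            # network over the aging programs: pseudotime-significant genes
            net_genes = genes if genes else list(norm.var_names)
            net = entropy_mod.build_network(norm[:, net_genes], r_min=config.entropy_r_min)
            prof = entropy_mod.entropy_profile(norm, net)
            prof.to_csv(out / "entropy.tsv", sep="\t")
            manifest["stages"]["entropy"] = {
                "n_network_genes": len(net.genes),
                "median_normalized_SR": float(prof["normalized_SR"].median()),
            }
        else:
            manifest["stages"]["entropy"] = "skipped"
    except Exception as err:  # noqa: BLE001 - rethrown with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "manifest.json":
            manifest["files"][f.name] = _sha256(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
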