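"""Plain-text I/O: matrix-market counts with TSV sidecars, GMT gene sets,
TF-target tables, phase-gene lists and limiting-dilution tables."""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


def write_count_matrix(adata: ad.AnnData, prefix: str | Path) -> None:
    """Write counts as <prefix>.mtx (genes x cells) + genes.tsv / cells.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    X = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(np.asarray(adata.X))
    spio.mmwrite(str(prefix) + ".mtx", X.T.tocoo())
    adata.var.to_csv(str(prefix) + ".genes.tsv", sep="\t")
    adata.obs.to_csv(str(prefix) + ".cells.tsv", sep="\t")


def read_count_matrix(prefix: str | Path) -> ad.AnnData:
    """Read a matrix written by :func:`write_count_matrix`."""
    prefix = str(prefix)
    X = sparse.csr_matrix(spio.mmread(prefix + ".mtx")).T
    var = pd.read_csv(prefix + ".genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(prefix + ".cells.tsv", sep="\t", index_col=0)
    if var.index.duplicated().any() or obs.index.duplicated().any():
        raise ValueError("duplicate gene names or barcodes in sidecar tables")
    for col in ("is_ercc", "is_mito", "is_stromal_marker"):
        if col in var:
            var[col] = var[col].astype(bool)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    if X.shape != (len(obs), len(var)):
        raise ValueError("matrix dimensions inconsistent with metadata")
    return ad.AnnData(X=X, obs=obs, var=var)


def write_gmt(sets: dict[str, list[str]], path: str | Path, note: str = "mammaclock") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, note, *genes]) + "\n")


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    if not any(sets.values()):
        raise ValueError(f"no non-empty gene sets in {path}")
    return sets


def read_tf_database(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"tf", "target", "source"}
    if not req.issubset(df.columns):
        raise ValueError(f"TF database needs columns {sorted(req)}")
    return df


def read_phase_genes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "phase"}.issubset(df.columns):
        raise ValueError("phase gene table needs columns (gene, phase)")
    return df


def read_ld_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    req = {"group", "dose", "tested", "positive"}
    if not req.issubset(df.columns):
        raise ValueError(f"limiting-dilution table needs columns {sorted(req)}")
    return df
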