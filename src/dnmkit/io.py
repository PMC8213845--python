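"""Readers and writers for the tabular formats the pipeline consumes.

All tables are plain TSV with a header row. Gene sets travel as GMT
(``set_id <tab> category <tab> gene1 <tab> gene2 ...``), single-cell
matrices as matrix-market plus a cell-label TSV.
"""

from __future__ import annotations

import os
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Columns of a mutation-record table. ``cadd``, allele frequencies and
#: ``vaf`` may be empty (missing); everything else is required.
RECORD_COLUMNS = [
    "proband_id",
    "group",
    "gene",
    "consequence",
    "variant_type",
    "cadd",
    "at_interface",
    "af_gnomad_nonneuro",
    "af_tommo",
    "vaf",
    "ref",
    "alt",
    "context_5p",
    "context_3p",
]

#: Columns of a per-gene mutational-model table.
GENE_MODEL_COLUMNS = [
    "gene",
    "cds_length",
    "mu_syn",
    "mu_mis",
    "mu_lof",
    "frac_cpg",
    "pli",
    "set_memberships",
]


def read_records(path: str | os.PathLike) -> pd.DataFrame:
    """Read a mutation-record TSV (one row per DNM call)."""
    df = pd.read_csv(path, sep="\t", dtype={"proband_id": str, "gene": str})
    if "at_interface" in df.columns:
        df["at_interface"] = df["at_interface"].astype(bool)
    return df


def write_records(records: pd.DataFrame, path: str | os.PathLike) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_gene_model(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-gene model table (rates, pLI, CDS length, set memberships)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    if "set_memberships" in df.columns:
        df["set_memberships"] = df["set_memberships"].fillna("")
    return df


def write_gene_model(model: pd.DataFrame, path: str | os.PathLike) -> None:
    model.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | os.PathLike) -> dict[str, dict]:
    """Read a GMT gene-set file.

    Returns a mapping ``set_id -> {"category": str, "genes": frozenset}``.
    The second GMT column (conventionally a description/URL) carries the
    set's category tag.
    """
    sets: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            set_id, category, genes = parts[0], parts[1], parts[2:]
            sets[set_id] = {"category": category, "genes": frozenset(g for g in genes if g)}
    return sets


def write_gmt(collection: Mapping[str, Mapping], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for set_id, entry in collection.items():
            genes = sorted(entry["genes"])
            fh.write("\t".join([set_id, str(entry.get("category", ""))] + genes) + "\n")


def read_cell_matrix(
    matrix_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> ad.AnnData:
    """Load a cells x genes count matrix plus per-cell labels.

    ``matrix_path`` is matrix-market (cells x genes) or a dense TSV with
    cell ids as the index and gene symbols as columns. ``labels_path`` is a
    TSV with at least ``cell_id`` and ``cluster`` columns; any additional
    QC columns (``detected_genes``, ``total_reads``, ``mito_fraction``) are
    carried into ``.obs``.
    """
    labels = pd.read_csv(labels_path, sep="\t", dtype={"cell_id": str, "cluster": str})
    labels = labels.set_index("cell_id")
    path = os.fspath(matrix_path)
    if path.endswith(".mtx"):
        x = scipy.io.mmread(path).tocsr()
        adata = ad.AnnData(X=x)
        adata.obs_names = labels.index.astype(str)
        adata.var_names = [f"G{i:06d}" for i in range(x.shape[1])]
    else:
        dense = pd.read_csv(path, sep="\t", index_col=0)
        adata = ad.AnnData(X=dense.to_numpy(), obs=pd.DataFrame(index=dense.index.astype(str)))
        adata.var_names = dense.columns.astype(str)
    for col in labels.columns:
        adata.obs[col] = labels[col].reindex(adata.obs_names).to_numpy()
    return adata


def write_cell_matrix(
    adata: ad.AnnData,
    matrix_path: str | os.PathLike,
    labels_path: str | os.PathLike,
) -> None:
    x = adata.X
    if not scipy.sparse.issparse(x):
        x = scipy.sparse.csr_matrix(np.asarray(x))
    scipy.io.mmwrite(os.fspath(matrix_path), x)
    labels = adata.obs.copy()
    labels.index.name = "cell_id"
    labels.reset_index().to_csv(labels_path, sep="\t", index=False)
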