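"""Gene-set activity in single cells via rank-recovery AUC scoring.

Each cell's genes are ranked by descending expression (ties shuffled with a
seeded generator); the recovery curve accumulates gene-set members along
the first ``max_rank`` ranks, and its area — normalised by
``max_rank * |set|`` — scores the cell's set activity in [0, 1]. Capping at
``max_rank`` makes the score insensitive to how many genes a cell happens
to express beyond its top ranks. The top fraction of cells by score is
then tested for over-representation in each cluster with a one-tailed
binomial test against the selection fraction.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse
from scipy import stats

from .geneset import fdr_adjust


def _dense(x) -> np.ndarray:
    if scipy.sparse.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)


def cell_qc(
    adata: ad.AnnData,
    min_genes: int = 1000,
    max_genes: int = 10000,
    max_reads: float = 1_500_000,
    max_mito: float = 0.02,
) -> ad.AnnData:
    """Drop low-quality cells, likely doublets and likely dying cells.

    Cells are removed if they have fewer than ``min_genes`` detected genes
    (strict <), more than ``max_genes`` detected genes or ``max_reads``
    total reads (doublet proxies), or a mitochondrial read fraction above
    ``max_mito``. QC metrics are taken from ``.obs`` when present,
    otherwise computed from the count matrix (``mito_fraction`` defaults to
    0 if absent).
    """
    x = adata.X
    obs = adata.obs
    detected = (
        obs["detected_genes"].to_numpy(dtype=float)
        if "detected_genes" in obs
        else np.asarray((x > 0).sum(axis=1)).ravel()
    )
    total = (
        obs["total_reads"].to_numpy(dtype=float)
        if "total_reads" in obs
        else np.asarray(x.sum(axis=1)).ravel()
    )
    mito = (
        obs["mito_fraction"].to_numpy(dtype=float)
        if "mito_fraction" in obs
        else np.zeros(adata.n_obs)
    )
    keep = (detected >= min_genes) & (detected <= max_genes)
    keep &= total <= max_reads
    keep &= mito <= max_mito
    return adata[keep].copy()


def auc_score(
    cell_expression: Sequence[float],
    gene_set_mask: Sequence[bool],
    max_rank: int,
    seed: int = 0,
) -> float:
    """Rank-recovery AUC of one cell for one gene set. See :func:`score_cells`."""
    expr = np.asarray(cell_expression, dtype=float)[None, :]
    mask = np.asarray(gene_set_mask, dtype=bool)
    return float(_score_matrix(expr, mask, max_rank, np.random.default_rng(seed))[0])


def _score_matrix(
    x: np.ndarray, set_mask: np.ndarray, max_rank: int, rng: np.random.Generator
) -> np.ndarray:
    n_cells, n_genes = x.shape
    if not (0 < max_rank <= n_genes):
        raise ValueError("max_rank must be in [1, n_genes]")
    n_set = int(set_mask.sum())
    if n_set == 0:
        raise ValueError("gene set is empty (no members in the matrix)")
    # Integer counts: adding U(0, 0.5) jitter randomises the order within
    # tied values without ever reordering distinct counts.
    jitter = rng.random(x.shape) * 0.5
    order = np.argsort(-(x + jitter), axis=1, kind="stable")
    # rank (0-based) of every gene in every cell
    ranks = np.empty_like(order)
    rows = np.arange(n_cells)[:, None]
    ranks[rows, order] = np.arange(n_genes)[None, :]
    set_ranks = ranks[:, set_mask]
    # a member at 0-based rank r contributes (max_rank - r) unit steps of area
    contrib = np.clip(max_rank - set_ranks, 0, None)
    return contrib.sum(axis=1) / (max_rank * n_set)


def score_cells(
    adata: ad.AnnData,
    gene_set: Iterable[str],
    max_rank: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """AUC activity score of a gene set for every cell.

    Set members absent from ``adata.var_names`` are ignored. Returns a
    Series of scores in [0, 1] indexed by cell id. Tie shuffling is seeded
    once for the whole scoring run.
    """
    genes = set(gene_set)
    mask = np.asarray(adata.var_names.isin(genes))
    x = _dense(adata.X).astype(float)
    scores = _score_matrix(x, mask, max_rank, np.random.default_rng(seed))
    return pd.Series(scores, index=adata.obs_names, name="auc")


def top_fraction_cells(scores: pd.Series, fraction: float = 0.05) -> list[str]:
    """Ids of the ``ceil(fraction * n)`` highest-scoring cells.

    Ties at the selection boundary break by cell-id order.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * len(scores))
    ranked = scores.to_frame("auc").assign(cell=scores.index.astype(str))
    ranked = ranked.sort_values(["auc", "cell"], ascending=[False, True])
    return list(ranked.index[:k])


def cluster_binomial_test(
    top_cells: Iterable[str],
    cluster_labels: pd.Series,
    expected_fraction: float = 0.05,
    n_tests: int | None = None,
) -> pd.DataFrame:
    """Per-cluster over-representation of top-scoring cells.

    For each cluster, the number of its cells in ``top_cells`` is compared
    with ``Binomial(cluster_size, expected_fraction)`` by a one-tailed
    (upper) binomial test; Bonferroni correction uses ``n_tests`` (default:
    the number of clusters).
    """
    labels = cluster_labels.astype(str)
    top = set(map(str, top_cells))
    clusters = pd.unique(labels)
    m = n_tests if n_tests is not None else len(clusters)
    rows = []
    for c in clusters:
        members = labels.index[labels == c]
        size = len(members)
        k = sum(1 for cell in members if str(cell) in top)
        p = float(stats.binom.sf(k - 1, size, expected_fraction))
        rows.append(
            {
                "cluster": c,
                "n_cells": size,
                "n_top": k,
                "fraction_top": k / size if size else np.nan,
                "p_uncorrected": p,
                "p_corrected": min(1.0, p * m),
            }
        )
    return pd.DataFrame(rows).set_index("cluster")


def cluster_signature(
    adata: ad.AnnData,
    target_cluster: str,
    comparison_clusters: Sequence[str],
    fdr_cutoff: float = 0.05,
    scale_factor: float = 10_000.0,
    cluster_key: str = "cluster",
) -> list[str]:
    """Genes significantly up-regulated in one cluster versus others.

    Counts are normalised per cell to ``scale_factor`` total and
    log1p-transformed; each gene is tested with a one-sided rank-sum test
    (target > comparison) and Benjamini-Hochberg corrected. Genes with
    ``q < fdr_cutoff`` are returned.
    """
    target_cluster = str(target_cluster)
    comparison = [str(c) for c in comparison_clusters]
    if target_cluster in comparison:
        raise ValueError("target cluster must not be among the comparison clusters")
    labels = adata.obs[cluster_key].astype(str)
    t_mask = (labels == target_cluster).to_numpy()
    c_mask = labels.isin(comparison).to_numpy()
    if t_mask.sum() < 2 or c_mask.sum() < 2:
        raise ValueError("both groups need at least 2 cells")

    x = _dense(adata.X).astype(float)
    totals = x.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = np.log1p(x / totals * scale_factor)

    t, c = norm[t_mask], norm[c_mask]
    # genes with zero variance overall carry no signal; p = 1
    pooled = np.vstack([t, c])
    varying = np.ptp(pooled, axis=0) > 0
    p = np.ones(x.shape[1])
    if varying.any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # all-tie columns yield sd=0 warnings
            res = stats.mannwhitneyu(
                t[:, varying], c[:, varying], alternative="greater",
                method="asymptotic", axis=0,
            )
        p[varying] = np.nan_to_num(res.pvalue, nan=1.0)
    q = fdr_adjust(np.clip(p, 1e-300, 1.0))
    selected = (q < fdr_cutoff) & (t.mean(axis=0) > c.mean(axis=0))
    return list(np.asarray(adata.var_names)[selected])


def hypergeom_overlap(
    set_a: Iterable[str],
    set_b: Iterable[str],
    background: Iterable[str],
) -> tuple[int, float]:
    """Upper-tail hypergeometric P for the overlap of two sets on a background.

    Members outside the background are dropped with a warning. Returns
    ``(overlap_size, p_value)``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    a, b = set(set_a), set(set_b)
    dropped = (a | b) - bg
    if dropped:
        warnings.warn(
            f"{len(dropped)} gene(s) outside the background were excluded",
            stacklevel=2,
        )
    a &= bg
    b &= bg
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(bg), len(a), len(b)))
    return k, p
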