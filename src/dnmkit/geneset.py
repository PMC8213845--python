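"""Gene-set enrichment by weighted random placement of observed mutations.

The engine keeps the observed number of mutations of each functional class
fixed and, in each permutation, re-places every mutation into a gene with
probability proportional to that gene's mutational-model rate for the
mutation's class (LoF rates for LoF mutations, damaging-missense rates for
damaging ones, and so on). Per-gene rates already encode gene length and
local sequence context, so placement at the gene level reproduces the
marginal gene-hit distribution of a site-level placement. Enrichment of a
gene set is the upper tail of the permuted set-hit counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import classify_records

DEFAULT_F_DAMAGING = 0.45
DEFAULT_SIZE_WINDOW = (30, 1500)


@dataclass
class EnrichmentResult:
    set_id: str
    observed_hits: int
    expected_hits: float
    p_uncorrected: float
    n_permutations: int
    q_fdr: float | None = None


def class_weights(gene_model: pd.DataFrame, f_damaging: float = DEFAULT_F_DAMAGING) -> dict:
    """Per-gene placement weights for each functional class.

    Damaging and non-damaging missense split the missense rate by
    ``f_damaging``; LoF and synonymous use their model rates directly.
    """
    mis = gene_model["mu_mis"].to_numpy(dtype=float)
    return {
        "LoF": gene_model["mu_lof"].to_numpy(dtype=float),
        "damaging": f_damaging * mis,
        "non_damaging_missense": (1.0 - f_damaging) * mis,
        "synonymous": gene_model["mu_syn"].to_numpy(dtype=float),
    }


def _classes(records: pd.DataFrame) -> pd.Series:
    if "functional_class" in records.columns:
        return records["functional_class"]
    return classify_records(records)


def place_mutations(
    records: pd.DataFrame,
    gene_model: pd.DataFrame,
    seed: int = 0,
    f_damaging: float = DEFAULT_F_DAMAGING,
) -> pd.Series:
    """One permuted gene assignment for the observed mutations.

    Every mutation is independently reassigned to a gene with probability
    proportional to the gene's rate for the mutation's class; class counts
    are conserved by construction. Returns a Series of gene symbols aligned
    to ``records``.
    """
    rng = np.random.default_rng(seed)
    weights = class_weights(gene_model, f_damaging)
    genes = gene_model["gene"].to_numpy()
    classes = _classes(records)
    out = pd.Series(index=records.index, dtype=object, name="gene")
    for cls, group in classes.groupby(classes):
        if cls == "other":
            raise ValueError("non-exonic ('other') records cannot be placed")
        w = weights[cls]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"all-zero placement weights for class {cls!r}")
        idx = rng.choice(len(genes), size=len(group), p=w / total)
        out.loc[group.index] = genes[idx]
    return out


def enrichment_test(
    records: pd.DataFrame,
    set_genes: Iterable[str],
    gene_model: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    f_damaging: float = DEFAULT_F_DAMAGING,
    set_id: str = "",
) -> EnrichmentResult:
    """Permutation enrichment of a gene set among the observed mutations.

    ``observed_hits`` counts mutations whose gene belongs to the set. Under
    the placement null each mutation of class ``c`` lands in the set
    independently with probability equal to the set's share of the class-``c``
    placement weight, so the per-permutation set-hit count is sampled as a
    sum of per-class binomials — identical in distribution to materialising
    full placements, and what :func:`place_mutations` would yield. The
    P-value is ``(b + 1) / (n_perm + 1)`` with ``b`` the number of
    permutations reaching at least the observed hit count.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    gene_set = set(set_genes)
    classes = _classes(records)
    if (classes == "other").any():
        raise ValueError("classify and drop non-exonic records before enrichment")
    weights = class_weights(gene_model, f_damaging)
    in_set = gene_model["gene"].isin(gene_set).to_numpy()

    observed = int(records["gene"].isin(gene_set).sum())
    rng = np.random.default_rng(seed)
    perm_hits = np.zeros(n_perm, dtype=np.int64)
    for cls, group in classes.groupby(classes):
        w = weights[cls]
        total = w.sum()
        if total <= 0:
            raise ValueError(f"all-zero placement weights for class {cls!r}")
        p_set = float(w[in_set].sum() / total)
        perm_hits += rng.binomial(len(group), p_set, size=n_perm)
    b = int(np.count_nonzero(perm_hits >= observed))
    return EnrichmentResult(
        set_id=set_id,
        observed_hits=observed,
        expected_hits=float(perm_hits.mean()),
        p_uncorrected=(b + 1) / (n_perm + 1),
        n_permutations=int(n_perm),
    )


def enrich_collection(
    records: pd.DataFrame,
    collection: Mapping[str, Mapping],
    gene_model: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    f_damaging: float = DEFAULT_F_DAMAGING,
    size_window: tuple[int, int] | None = DEFAULT_SIZE_WINDOW,
) -> pd.DataFrame:
    """Run :func:`enrichment_test` over a GMT collection with per-category FDR.

    Sets are first harmonised to the model's background genes; sets whose
    harmonised size falls outside ``size_window`` (default [30, 1500] genes)
    are excluded before testing, so the FDR denominator only counts tested
    terms of the same category.
    """
    background = set(gene_model["gene"])
    rows = []
    for i, (set_id, entry) in enumerate(collection.items()):
        members = set(entry["genes"]) & background
        if size_window is not None and not (size_window[0] <= len(members) <= size_window[1]):
            continue
        res = enrichment_test(
            records, members, gene_model, n_perm=n_perm, seed=seed + i,
            f_damaging=f_damaging, set_id=set_id,
        )
        rows.append(
            {
                "set_id": set_id,
                "category": entry.get("category", ""),
                "n_genes": len(members),
                "observed_hits": res.observed_hits,
                "expected_hits": res.expected_hits,
                "p_uncorrected": res.p_uncorrected,
                "n_permutations": res.n_permutations,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_fdr"] = fdr_adjust(out["p_uncorrected"], out["category"])
    return out


def fdr_adjust(p_values: Sequence[float], categories: Sequence | None = None) -> np.ndarray:
    """Benjamini-Hochberg q-values, adjusted within each category independently."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    if categories is None:
        return stats.false_discovery_control(p)
    cats = np.asarray(categories)
    q = np.empty_like(p)
    for c in pd.unique(cats):
        mask = cats == c
        q[mask] = stats.false_discovery_control(p[mask])
    return q


def build_topk_sets(
    expression: pd.DataFrame,
    fraction: float = 0.02,
    category: str = "tissue",
) -> dict[str, dict]:
    """Top-expression gene sets, one per tissue/condition column.

    For each column of ``expression`` (genes in the index), the
    ``ceil(fraction * n_genes)`` highest-expression genes form the set;
    ties at the cutoff break by gene-symbol order.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * len(expression))
    collection: dict[str, dict] = {}
    for col in expression.columns:
        values = pd.to_numeric(expression[col], errors="coerce")
        if values.isna().any():
            raise ValueError(f"non-numeric expression values in column {col!r}")
        ranked = values.to_frame("x").assign(gene=values.index.astype(str))
        ranked = ranked.sort_values(["x", "gene"], ascending=[False, True])
        collection[str(col)] = {
            "category": category,
            "genes": frozenset(ranked["gene"].iloc[:k]),
        }
    return collection


def ranksum_compare(
    p_values_a: Sequence[float],
    p_values_b: Sequence[float],
    alternative: str = "less",
) -> float:
    """Exact Wilcoxon rank-sum comparison of two groups of enrichment P-values.

    Default ``alternative='less'`` asks whether group A's P-values are
    stochastically smaller, i.e. A is the more-enriched group. With ties
    across the pooled sample the exact null distribution is unavailable and
    the mid-rank normal approximation is used instead (a warning notes the
    fallback).
    """
    a = np.asarray(p_values_a, dtype=float)
    b = np.asarray(p_values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "asymptotic" if has_ties else "exact"
    if has_ties:
        warnings.warn(
            "ties across groups: falling back to the mid-rank normal "
            "approximation of the rank-sum test",
            stacklevel=2,
        )
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.pvalue)


def overlap_coefficient(set_a: Iterable, set_b: Iterable) -> float:
    """Szymkiewicz-Simpson overlap coefficient ``|A & B| / min(|A|, |B|)``."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("both sets must be non-empty")
    return len(a & b) / min(len(a), len(b))
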