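"""Expected-count arithmetic under a per-gene mutational model.

Given per-gene, per-generation mutation probabilities (mu) for synonymous,
missense and LoF changes, the expected DNM count in a gene over a cohort of
``N`` trios is ``lambda = 2 * N * mu`` (two transmitted haplotypes per
trio; the diploid factor is exposed for sensitivity checks). Recurrently
hit genes are assessed with a one-tailed Poisson test against lambda, gene
sets with a one-tailed binomial test against the set's share of the total
deleterious rate, and gene-level recurrence with a weighted-placement
simulation.

The "deleterious" rate of a gene is ``mu_lof + f_damaging * mu_mis`` where
``f_damaging`` is the observed fraction of missense DNMs that are damaging
(CADD > 15) in controls; in-frame indels are excluded because the
mutational model provides no rate for them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

DIPLOID_FACTOR = 2.0


def damaging_missense_rate(mu_mis: float, f_damaging: float):
    """Per-gene damaging-missense rate: ``mu_mis * f_damaging``.

    ``f_damaging`` is the proportion of damaging missense DNMs over all
    missense DNMs (estimated in controls); must lie in [0, 1].
    """
    f = np.asarray(f_damaging, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("f_damaging must be in [0, 1]")
    out = np.asarray(mu_mis, dtype=float) * f
    return float(out) if out.ndim == 0 else out


def deleterious_rate(gene_model: pd.DataFrame, f_damaging: float) -> pd.Series:
    """Per-gene deleterious rate ``mu_lof + f_damaging * mu_mis`` (no inframe)."""
    return gene_model["mu_lof"] + damaging_missense_rate(
        gene_model["mu_mis"].to_numpy(), f_damaging
    )


def expected_count(mu: float, n_trios: int, diploid_factor: float = DIPLOID_FACTOR) -> float:
    """Expected DNM count ``lambda = diploid_factor * n_trios * mu``."""
    if n_trios < 0:
        raise ValueError("n_trios must be >= 0")
    return diploid_factor * n_trios * mu


def poisson_recurrence_test(observed: int, lam: float) -> float:
    """Upper-tail Poisson P-value, ``P(X >= observed)`` for ``X ~ Poisson(lam)``."""
    if observed < 0:
        raise ValueError("observed must be >= 0")
    if lam <= 0:
        raise ValueError("lambda must be > 0")
    return float(stats.poisson.sf(observed - 1, lam))


def exomewide_threshold(n_genes: int) -> float:
    """Exome-wide significance threshold ``0.05 / n_genes``."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return 0.05 / n_genes


def dd_expected_proportion(
    gene_model: pd.DataFrame,
    dd_set,
    f_damaging: float,
) -> float:
    """Expected share of deleterious DNMs falling in a gene set.

    The ratio of the summed deleterious rates of ``dd_set`` (e.g. the known
    developmental-disorder genes) to the sum over all genes in the model.
    """
    if len(gene_model) == 0:
        raise ValueError("gene model is empty")
    dd = set(dd_set)
    missing = dd - set(gene_model["gene"])
    if missing:
        raise ValueError(f"gene set members absent from the model: {sorted(missing)[:5]}")
    rates = deleterious_rate(gene_model, f_damaging)
    total = float(rates.sum())
    if total == 0:
        raise ValueError("total deleterious rate is zero")
    in_set = gene_model["gene"].isin(dd).to_numpy()
    return float(rates.to_numpy()[in_set].sum() / total)


def binomial_set_test(k: int, n: int, p_expected: float) -> float:
    """One-tailed binomial P-value ``P(X >= k)`` for ``X ~ Binomial(n, p_expected)``."""
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    if not (0 < p_expected < 1):
        raise ValueError("p_expected must be in (0, 1)")
    return float(stats.binom.sf(k - 1, n, p_expected))


def recurrence_simulation(
    n_mutations: int,
    gene_weights,
    n_reps: int = 1_000_000,
    seed: int = 0,
    _chunk: int = 20_000,
) -> float:
    """Probability that dropping ``n_mutations`` into the exome hits a gene twice.

    Each replicate places the mutations independently into genes with
    probability proportional to ``gene_weights`` (per-gene deleterious
    rates); the returned P-value is the fraction of replicates in which at
    least one gene receives two or more mutations.
    """
    w = np.asarray(gene_weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("gene_weights must be non-negative and not all zero")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if n_mutations < 2:
        return 0.0
    p = w / w.sum()
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_reps:
        m = min(_chunk, n_reps - done)
        genes = rng.choice(len(p), size=(m, n_mutations), p=p)
        genes.sort(axis=1)
        collision = (np.diff(genes, axis=1) == 0).any(axis=1)
        hits += int(collision.sum())
        done += m
    return hits / n_reps
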