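"""Case-control comparison of per-individual DNM rates.

The comparison runs in four steps: Poisson outlier QC on each group's
per-individual total counts, synonymous-rate calibration of the case side,
a one-tailed label-permutation test per functional class, and Bonferroni
correction over the family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CalibrationError


@dataclass
class RateTestResult:
    """Outcome of one one-tailed permutation rate comparison."""

    case_rate: float
    control_rate: float
    calibration_factor: float
    statistic: float
    p_uncorrected: float
    n_permutations: int
    p_corrected: float | None = None


def poisson_outlier_qc(counts: pd.Series | np.ndarray, alpha: float = 0.05) -> list:
    """Iteratively drop individuals whose total DNM count is a Poisson outlier.

    Starting from the individual with the maximum count, the count ``x`` is
    tested against ``dpois(x, u) * n < alpha`` where ``u`` is the mean count
    over the currently retained individuals (the candidate included) and
    ``n`` is their number; one individual is removed per iteration and
    ``u`` is recomputed. Returns the retained individual ids (the positional
    index if ``counts`` has none).

    The ``n`` multiplier plays the role of a Bonferroni-style correction for
    scanning the whole group for its most extreme member.
    """
    s = pd.Series(counts).astype(float)
    retained = s.copy()
    while len(retained) > 1:
        u = retained.mean()
        idx = retained.idxmax()
        x = retained.loc[idx]
        if stats.poisson.pmf(x, u) * len(retained) < alpha:
            retained = retained.drop(idx)
        else:
            break
    return list(retained.index)


def calibrate_rates(
    case_syn_counts: pd.Series | np.ndarray,
    control_syn_counts: pd.Series | np.ndarray,
) -> float:
    """Synonymous-rate calibration factor applied multiplicatively to case rates.

    ``factor = control synonymous rate / case synonymous rate``, both rates
    computed per individual and including population-observed variants.
    Synonymous mutations are assumed neutral, so any rate difference between
    the groups reflects pipeline or cohort artefacts rather than biology.
    """
    case = np.asarray(case_syn_counts, dtype=float)
    control = np.asarray(control_syn_counts, dtype=float)
    if case.sum() == 0:
        raise CalibrationError(
            "case synonymous count is zero: the synonymous calibration factor "
            "control_rate/case_rate is undefined"
        )
    return float((control.sum() / len(control)) / (case.sum() / len(case)))


def permutation_rate_test(
    case_counts: pd.Series | np.ndarray,
    control_counts: pd.Series | np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    calibration_factor: float = 1.0,
    _chunk: int = 2000,
) -> RateTestResult:
    """One-tailed permutation test for a higher calibrated case rate.

    The statistic is ``calibration_factor * mean(case) - mean(control)``;
    the null is built by randomly permuting group labels over the pooled
    individuals (the calibration factor stays attached to whichever
    individuals are labelled "case" in a permutation). The one-tailed
    P-value uses the pseudocount estimator ``(b + 1) / (n_perm + 1)`` with
    ``b`` the number of permutations whose statistic is >= the observed one.
    """
    case = np.asarray(case_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if len(case) == 0 or len(control) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    n1, n2 = len(case), len(control)
    pooled = np.concatenate([case, control])
    observed = calibration_factor * case.mean() - control.mean()

    rng = np.random.default_rng(seed)
    total = pooled.sum()
    b = 0
    done = 0
    while done < n_perm:
        m = min(_chunk, n_perm - done)
        # random permutations via argsort of uniform keys
        order = np.argsort(rng.random((m, n1 + n2)), axis=1)
        perm_case_sum = np.take(pooled, order[:, :n1]).sum(axis=1)
        stat = calibration_factor * perm_case_sum / n1 - (total - perm_case_sum) / n2
        b += int(np.count_nonzero(stat >= observed))
        done += m
    p = (b + 1) / (n_perm + 1)
    return RateTestResult(
        case_rate=float(case.mean()),
        control_rate=float(control.mean()),
        calibration_factor=float(calibration_factor),
        statistic=float(observed),
        p_uncorrected=float(p),
        n_permutations=int(n_perm),
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected P-value, ``min(1, p * m)``."""
    if not (0 < p <= 1):
        raise ValueError("p must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, p * m)


def rate_test_table(
    counts: pd.DataFrame,
    counts_constrained: pd.DataFrame | None = None,
    calibration_factor: float = 1.0,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run the permutation rate test for every class (and constrained-gene
    variant if given) and Bonferroni-correct over the family.

    ``counts`` is a per-individual count table from
    :func:`dnmkit.annotation.per_individual_counts` (``group`` column plus
    one column per functional class). Returns one row per test.
    """
    from .annotation import FUNCTIONAL_CLASSES

    blocks = [("all", counts)]
    if counts_constrained is not None:
        blocks.append(("constrained", counts_constrained))
    rows = []
    for gi, (gene_filter, table) in enumerate(blocks):
        case = table[table["group"] == "case"]
        control = table[table["group"] == "control"]
        for ci, cls in enumerate(FUNCTIONAL_CLASSES):
            res = permutation_rate_test(
                case[cls],
                control[cls],
                n_perm=n_perm,
                seed=seed + 1000 * gi + ci,
                calibration_factor=calibration_factor,
            )
            rows.append(
                {
                    "class": cls,
                    "gene_filter": gene_filter,
                    "case_rate": res.case_rate,
                    "control_rate": res.control_rate,
                    "calibration_factor": res.calibration_factor,
                    "statistic": res.statistic,
                    "p_uncorrected": res.p_uncorrected,
                    "n_permutations": res.n_permutations,
                }
            )
    out = pd.DataFrame(rows)
    m = len(out)
    out["n_tests"] = m
    out["p_corrected"] = [bonferroni(p, m) for p in out["p_uncorrected"]]
    return out
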