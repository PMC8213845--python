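"""Postzygotic (mosaic) variant filtering, deep-sequencing validation calls,
and substitution-spectrum bookkeeping.

Postzygotic de novo mutations (pzDNMs) arise after fertilisation and show
sub-heterozygous variant allele fractions (VAFs). Candidates from a
somatic caller are filtered on proband VAF, read support, parental
evidence, strand balance, caller fidelity (TLOD) and copy-number regions;
survivors are re-sequenced to high depth (target amplicon sequencing, TAS)
and classified by their deep VAF. Substitution spectra over seven
pyrimidine-strand categories let germline and postzygotic calls be
compared for mutational-process similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FilterError

SPECTRUM_CATEGORIES = [
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T(CpG)", "C>T(non-CpG)",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_PZ_FILTER_FIELDS = [
    "vaf_exome",
    "alt_reads_proband",
    "alt_reads_father",
    "alt_reads_mother",
    "depth_father",
    "depth_mother",
    "strand_support",
    "tlod",
    "in_cnv_region",
]

TAS_VAF_LOWER = 0.01   # inclusive
TAS_VAF_UPPER = 0.475  # exclusive for pzDNM, inclusive for likely_gDNM


@dataclass
class SpectrumComparison:
    fisher_p: float
    pearson_r: float
    method: str  # "exact" (full enumeration) or "monte_carlo"


def pz_candidate_filter(
    records: pd.DataFrame,
    max_vaf: float = 0.35,
    min_alt_proband: int = 5,
    max_alt_parent: int = 1,
    min_depth_parent: int = 10,
    min_tlod: float = 5.0,
) -> pd.DataFrame:
    """Filter somatic-caller candidates down to plausible postzygotic calls.

    A record is retained iff proband VAF < ``max_vaf`` (strict), proband
    alt reads >= ``min_alt_proband``, the variant is supported on both
    strands, each parent shows <= ``max_alt_parent`` alt reads at depth
    >= ``min_depth_parent``, TLOD >= ``min_tlod``, and the site is outside
    called CNV regions.
    """
    for field in _PZ_FILTER_FIELDS:
        if field not in records.columns:
            raise FilterError(f"required field {field!r} missing from records")
        if records[field].isna().any():
            raise FilterError(f"field {field!r} has missing values")
    keep = (
        (records["vaf_exome"] < max_vaf)
        & (records["alt_reads_proband"] >= min_alt_proband)
        & records["strand_support"].astype(bool)
        & (records["alt_reads_father"] <= max_alt_parent)
        & (records["alt_reads_mother"] <= max_alt_parent)
        & (records["depth_father"] >= min_depth_parent)
        & (records["depth_mother"] >= min_depth_parent)
        & (records["tlod"] >= min_tlod)
        & ~records["in_cnv_region"].astype(bool)
    )
    return records.loc[keep]


def tas_classify(tas_alt: int, tas_depth: int) -> tuple[str, float]:
    """Classify a deep-sequencing validation result by its VAF.

    ``pzDNM`` for VAF in [1%, 47.5%), ``likely_gDNM`` for VAF >= 47.5%,
    ``fail`` below 1%. Also returns the two-tailed binomial P-value of the
    alt count against the heterozygous-germline expectation of rate 0.5 —
    a small value rejects the germline-heterozygote hypothesis.
    """
    if tas_depth <= 0:
        raise ValueError("tas_depth must be > 0")
    if not (0 <= tas_alt <= tas_depth):
        raise ValueError("tas_alt must be in [0, tas_depth]")
    vaf = tas_alt / tas_depth
    if vaf < TAS_VAF_LOWER:
        label = "fail"
    elif vaf < TAS_VAF_UPPER:
        label = "pzDNM"
    else:
        label = "likely_gDNM"
    p = stats.binomtest(tas_alt, tas_depth, 0.5, alternative="two-sided").pvalue
    return label, float(p)


def classify_tas_table(records: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`tas_classify` to the ``tas_alt``/``tas_depth`` columns."""
    labels, pvals = [], []
    for alt, depth in zip(records["tas_alt"], records["tas_depth"]):
        label, p = tas_classify(int(alt), int(depth))
        labels.append(label)
        pvals.append(p)
    out = records.copy()
    out["tas_label"] = labels
    out["tas_p_vs_half"] = pvals
    return out


def _normalise_substitution(ref: str, alt: str, c5: str, c3: str) -> tuple[str, str, str]:
    """Fold a substitution onto the pyrimidine/A reference strand.

    Returns (ref, alt, 3'-base) after complementing G/T references; the
    reported 3' base is the one flanking the (possibly complemented) C.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref in ("G", "T"):
        return _COMPLEMENT[ref], _COMPLEMENT[alt], _COMPLEMENT[c5.upper()]
    return ref, alt, c3.upper()


def substitution_spectrum(records: pd.DataFrame) -> pd.Series:
    """Count SNVs in the seven substitution categories.

    Purine references are complemented onto the pyrimidine/A strand
    (G>A counts as C>T, T>G as A>C, ...); C>T splits by CpG context, i.e.
    whether the base 3' of the (strand-normalised) C is a G. Records need
    ``ref``, ``alt``, ``context_5p`` and ``context_3p`` columns; non-SNV
    rows are skipped with a warning.
    """
    counts = pd.Series(0, index=SPECTRUM_CATEGORIES, name="count")
    skipped = 0
    for ref, alt, c5, c3 in zip(
        records["ref"], records["alt"], records["context_5p"], records["context_3p"]
    ):
        ref, alt = str(ref), str(alt)
        if len(ref) != 1 or len(alt) != 1 or ref not in _COMPLEMENT or alt not in _COMPLEMENT:
            skipped += 1
            continue
        nref, nalt, three_prime = _normalise_substitution(ref, alt, str(c5), str(c3))
        if nref == "C" and nalt == "T":
            key = "C>T(CpG)" if three_prime == "G" else "C>T(non-CpG)"
        else:
            key = f"{nref}>{nalt}"
        counts[key] += 1
    if skipped:
        warnings.warn(f"skipped {skipped} non-SNV record(s)", stacklevel=2)
    return counts


def _enumerate_tables(col_totals: np.ndarray, n1: int):
    """All row-1 vectors of 2xK tables with the given margins (small tables)."""
    ranges = [range(min(c, n1) + 1) for c in col_totals]
    for row in product(*ranges):
        if sum(row) == n1:
            yield row


def spectrum_compare(
    spec_a: pd.Series,
    spec_b: pd.Series,
    n_resamples: int = 1_000_000,
    seed: int = 0,
    max_exact_tables: int = 200_000,
) -> SpectrumComparison:
    """Compare two substitution spectra (2 x 7 table).

    Fisher-style exact test conditioning on the margins: the null
    distribution of the first row is multivariate hypergeometric, and the
    P-value sums the probabilities of all tables no more probable than the
    observed one. Full enumeration is used when the table space is small;
    otherwise a seeded Monte-Carlo version with ``n_resamples`` sampled
    tables (the ``method`` field of the result says which ran). The
    spectra's similarity is additionally summarised by the Pearson
    correlation of their proportion vectors.
    """
    a = np.asarray(spec_a, dtype=np.int64)
    b = np.asarray(spec_b, dtype=np.int64)
    if a.sum() == 0 or b.sum() == 0:
        raise ValueError("both spectra must have a positive total")
    if a.shape != b.shape:
        raise ValueError("spectra must have the same number of categories")

    cols = a + b
    n1 = int(a.sum())
    dist = stats.multivariate_hypergeom(cols, n1)
    p_obs = dist.pmf(a)
    tol = p_obs * (1 + 1e-9)

    n_tables = 1
    for c in cols:
        n_tables *= min(int(c), n1) + 1
        if n_tables > max_exact_tables:
            break
    if n_tables <= max_exact_tables:
        p = 0.0
        for row in _enumerate_tables(cols, n1):
            pr = dist.pmf(np.asarray(row))
            if pr <= tol:
                p += pr
        method = "exact"
        p = min(1.0, float(p))
    else:
        rng = np.random.default_rng(seed)
        sampled = dist.rvs(size=n_resamples, random_state=rng)
        pr = dist.pmf(sampled)
        p = (int(np.count_nonzero(pr <= tol)) + 1) / (n_resamples + 1)
        method = "monte_carlo"

    pa = a / a.sum()
    pb = b / b.sum()
    r = float(stats.pearsonr(pa, pb).statistic)
    return SpectrumComparison(fisher_p=float(p), pearson_r=r, method=method)
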