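"""Functional classification, population filtering and aggregation of DNM calls.

Exonic de novo calls are stratified into four functional classes:

* ``LoF`` — nonsense, frameshift indel, canonical splice site;
* ``damaging`` — missense with CADD > 15, missense at a protein-protein
  interaction interface, stop-lost, start-lost, in-frame indel;
* ``non_damaging_missense`` — missense with CADD <= 15;
* ``synonymous``.

Non-exonic consequences map to ``other`` and are dropped before any
counting. Calls observed in the general population (gnomAD non-neuro or
ToMMo allele frequency > 0) are removed by :func:`filter_population`;
multiple calls in the same gene of the same proband collapse to the one
with the severest class.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ClassificationError, FilterError

LOF_CONSEQUENCES = frozenset({"nonsense", "frameshift", "canonical_splice"})
DAMAGING_NON_MISSENSE = frozenset({"stop_lost", "start_lost", "inframe_indel"})
EXONIC_CONSEQUENCES = (
    LOF_CONSEQUENCES | DAMAGING_NON_MISSENSE | {"missense", "synonymous"}
)

#: The four functional classes, in decreasing severity. ``other`` (non-exonic)
#: sorts last and is excluded from counts.
FUNCTIONAL_CLASSES = ["LoF", "damaging", "non_damaging_missense", "synonymous"]
_SEVERITY = {c: i for i, c in enumerate(FUNCTIONAL_CLASSES + ["other"])}

CADD_DAMAGING_THRESHOLD = 15.0


def classify_mutation(record: Mapping) -> str:
    """Return the functional class of a single mutation record.

    ``record`` needs ``consequence`` and, for missense calls that are not
    flagged ``at_interface``, a ``cadd`` score (the damaging cutoff is a
    strict ``> 15``).
    """
    consequence = record["consequence"]
    if consequence in LOF_CONSEQUENCES:
        return "LoF"
    if consequence in DAMAGING_NON_MISSENSE:
        return "damaging"
    if consequence == "synonymous":
        return "synonymous"
    if consequence == "missense":
        if record.get("at_interface", False):
            return "damaging"
        cadd = record.get("cadd")
        if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)):
            raise ClassificationError(
                "missense record with missing CADD score and at_interface=False"
            )
        return "damaging" if cadd > CADD_DAMAGING_THRESHOLD else "non_damaging_missense"
    return "other"


def classify_records(records: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`classify_mutation` over a record table.

    Returns a Series named ``functional_class`` aligned to ``records``.
    """
    consequence = records["consequence"]
    cadd = pd.to_numeric(records.get("cadd", pd.Series(np.nan, index=records.index)))
    at_if = records.get("at_interface", pd.Series(False, index=records.index)).fillna(False)

    out = pd.Series("other", index=records.index, name="functional_class")
    out[consequence.isin(LOF_CONSEQUENCES)] = "LoF"
    out[consequence.isin(DAMAGING_NON_MISSENSE)] = "damaging"
    out[consequence == "synonymous"] = "synonymous"

    mis = consequence == "missense"
    bad = mis & cadd.isna() & ~at_if.astype(bool)
    if bad.any():
        raise ClassificationError(
            f"{int(bad.sum())} missense record(s) with missing CADD score and "
            "at_interface=False"
        )
    out[mis & (at_if.astype(bool) | (cadd > CADD_DAMAGING_THRESHOLD))] = "damaging"
    out[mis & ~at_if.astype(bool) & (cadd <= CADD_DAMAGING_THRESHOLD)] = "non_damaging_missense"
    return out


def filter_population(records: pd.DataFrame) -> pd.DataFrame:
    """Drop records observed in the general population.

    A record is observed if either population allele frequency
    (``af_gnomad_nonneuro`` or ``af_tommo``) is > 0. A missing frequency
    means the variant is absent from that database, so it is retained.
    """
    af_g = pd.to_numeric(
        records.get("af_gnomad_nonneuro", pd.Series(np.nan, index=records.index))
    ).fillna(0.0)
    af_t = pd.to_numeric(
        records.get("af_tommo", pd.Series(np.nan, index=records.index))
    ).fillna(0.0)
    return records.loc[(af_g <= 0) & (af_t <= 0)]


def apply_candidate_filters(
    records: pd.DataFrame,
    thresholds: Mapping[str, tuple[float, float]],
) -> pd.DataFrame:
    """Keep records whose caller scores clear their per-type cutoffs.

    ``thresholds`` maps a score column name (e.g. a de novo classifier
    score) to a ``(snv_cutoff, indel_cutoff)`` pair; a record is retained
    iff every named score is >= the cutoff for its ``variant_type``. An
    empty mapping is the identity.
    """
    if not thresholds:
        return records
    keep = pd.Series(True, index=records.index)
    vt = records["variant_type"]
    for score_name, (snv_cut, indel_cut) in thresholds.items():
        if score_name not in records.columns:
            raise FilterError(f"score column {score_name!r} missing from records")
        scores = pd.to_numeric(records[score_name])
        if scores.isna().any():
            raise FilterError(
                f"score {score_name!r} missing on {int(scores.isna().sum())} record(s)"
            )
        cut = np.where(vt == "indel", indel_cut, snv_cut)
        keep &= scores.to_numpy() >= cut
    return records.loc[keep]


def dedupe_per_gene_individual(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse multiple hits of one gene in one proband to the severest call.

    Severity order is LoF > damaging > non_damaging_missense > synonymous;
    ties within a class keep the first record in input order. Row order of
    the survivors follows the input.
    """
    if records.empty:
        return records
    classes = classify_records(records)
    severity = classes.map(_SEVERITY)
    order = np.argsort(severity.to_numpy(), kind="stable")
    ranked = records.iloc[order]
    kept = ranked[~ranked.duplicated(subset=["proband_id", "gene"], keep="first")]
    return kept.sort_index()


def per_individual_counts(
    records: pd.DataFrame,
    roster: pd.DataFrame,
    genes: Iterable[str] | None = None,
    constrained_only: bool = False,
    gene_model: pd.DataFrame | None = None,
    pli_cutoff: float = 0.90,
) -> pd.DataFrame:
    """Count DNMs per individual per functional class.

    Parameters
    ----------
    records : DataFrame
        Mutation records; classified on the fly if no ``functional_class``
        column is present. ``other`` (non-exonic) records are dropped.
    roster : DataFrame
        Cohort roster with ``individual_id`` and ``group`` columns; every
        individual appears in the output even with zero counts.
    genes : iterable of str, optional
        Restrict counting to these genes.
    constrained_only : bool
        Restrict counting to constrained genes (pLI > ``pli_cutoff`` in
        ``gene_model``).

    Returns
    -------
    DataFrame indexed by individual with a ``group`` column and one integer
    column per functional class.
    """
    roster = roster.copy()
    roster["individual_id"] = roster["individual_id"].astype(str)
    known = set(roster["individual_id"])
    unknown = set(records["proband_id"].astype(str)) - known
    if unknown:
        raise ValueError(
            f"record proband(s) absent from roster: {sorted(unknown)[:5]}"
        )

    df = records.copy()
    if "functional_class" not in df.columns:
        df["functional_class"] = classify_records(df)
    df = df[df["functional_class"] != "other"]

    if constrained_only:
        if gene_model is None:
            raise ValueError("constrained_only requires a gene_model")
        constrained = set(gene_model.loc[gene_model["pli"] > pli_cutoff, "gene"])
        df = df[df["gene"].isin(constrained)]
    if genes is not None:
        df = df[df["gene"].isin(set(genes))]

    table = (
        df.groupby(["proband_id", "functional_class"], observed=True)
        .size()
        .unstack(fill_value=0)
    )
    out = pd.DataFrame(0, index=roster["individual_id"], columns=FUNCTIONAL_CLASSES)
    for c in FUNCTIONAL_CLASSES:
        if c in table.columns:
            out[c] = table[c].reindex(out.index).fillna(0).astype(int)
    out.insert(0, "group", roster.set_index("individual_id")["group"])
    out.index.name = "individual_id"
    return out


def mean_rate(counts: pd.DataFrame, classes: Sequence[str] | None = None) -> float:
    """Per-individual mean DNM count over the given classes (default: all four)."""
    cls = list(classes) if classes is not None else FUNCTIONAL_CLASSES
    return float(counts[cls].to_numpy().sum() / len(counts))
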