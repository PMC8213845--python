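"""Synthetic gene models, trio cohorts, postzygotic tables and single-cell
matrices with the statistical structure the downstream stages assume.

The generator emulates a trio-sequencing study of de novo mutations:

* a per-gene mutational model whose rates scale with CDS length and local
  context, normalised so the exome-wide DNM rate is ~1.1 per trio;
* case/control trio cohorts with Poisson per-class counts and multinomial
  gene assignment, optionally enriched for LoF/damaging mutations in a
  designated risk-gene set on the case side;
* postzygotic candidates with sub-heterozygous VAFs, exome and deep
  (amplicon) read counts;
* clustered single-cell count matrices in which one cluster over-expresses
  a signature gene set.

All randomness in a call flows from a single integer seed through one
generator, so identical seeds give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy.special import expit

# Substitution-category probabilities on the pyrimidine/A strand; C>T is
# split into CpG / non-CpG per record using the gene's CpG opportunity.
_BASE_SPECTRUM = {
    "A>C": 0.10,
    "A>G": 0.22,
    "A>T": 0.09,
    "C>A": 0.09,
    "C>G": 0.10,
    "C>T": 0.40,
}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class GeneModelParams:
    """Tunable shape of the synthetic per-gene mutational model.

    ``target_per_trio_rate`` is the exome-wide expected DNM count per trio
    (sum over genes of ``2 * (mu_syn + mu_mis + mu_lof)``); the class
    shares split that total. ``pli_frac`` controls the fraction of genes
    that come out constrained (pLI > 0.9); constrained status is made more
    likely for high-rate (long) genes, mirroring the real correlation
    between gene length and LoF intolerance. The risk set is drawn from
    constrained genes with probability proportional to their LoF rate, the
    DD-like set from all genes weighted by deleterious rate.
    """

    target_per_trio_rate: float = 1.1
    share_syn: float = 0.29
    share_mis: float = 0.62
    share_lof: float = 0.09
    pli_frac: float = 0.18
    pli_rate_slope: float = 1.5
    cds_log_mean: float = 7.3   # exp(7.3) ~ 1480 bp
    cds_log_sigma: float = 0.9
    rate_noise_sigma: float = 0.6
    risk_fraction: float = 0.05
    dd_fraction: float = 0.016
    f_damaging: float = 0.45


@dataclass
class SimulationConfig:
    """Cohort layout and injected signal for :func:`simulate_trios`."""

    n_case_trios: int
    n_control_trios: int
    risk_set: str = "risk"
    enrichment_factor: float = 1.0
    frac_population_observed: float = 0.39
    f_damaging: float = 0.45
    seed: int = 0

    def __post_init__(self):
        if self.n_case_trios < 1 or self.n_control_trios < 1:
            raise ValueError("both cohorts must have at least one trio")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if not (0 <= self.frac_population_observed <= 1):
            raise ValueError("frac_population_observed must be in [0, 1]")
        if not (0 <= self.f_damaging <= 1):
            raise ValueError("f_damaging must be in [0, 1]")


def make_gene_model(
    n_genes: int,
    seed: int = 0,
    params: GeneModelParams | None = None,
) -> pd.DataFrame:
    """Generate a per-gene mutational-model table.

    Rates are proportional to CDS length times a lognormal context factor
    and normalised so the exome-wide per-trio DNM rate equals
    ``params.target_per_trio_rate`` exactly.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    p = params or GeneModelParams()
    rng = np.random.default_rng(seed)

    cds = np.maximum(
        150, rng.lognormal(p.cds_log_mean, p.cds_log_sigma, n_genes)
    ).astype(int)
    rel = cds * rng.lognormal(0.0, p.rate_noise_sigma, n_genes)
    mu_total = rel / rel.sum() * (p.target_per_trio_rate / 2.0)

    shares = np.array([p.share_syn, p.share_mis, p.share_lof])
    shares = shares / shares.sum()
    # mild per-gene jitter of the class split
    split = rng.dirichlet(shares * 50, n_genes)
    mu = mu_total[:, None] * split

    frac_cpg = rng.beta(2, 8, n_genes)

    # constrained status correlated with rate: logistic in standardised
    # log-rate, intercept solved so the mean matches pli_frac
    z = np.log(mu_total)
    z = (z - z.mean()) / z.std()
    lo, hi = -20.0, 20.0
    for _ in range(80):
        a = (lo + hi) / 2
        if expit(a + p.pli_rate_slope * z).mean() > p.pli_frac:
            hi = a
        else:
            lo = a
    p_constrained = expit(a + p.pli_rate_slope * z)
    constrained = rng.random(n_genes) < p_constrained
    pli = np.where(
        constrained,
        rng.uniform(0.9001, 1.0, n_genes),
        rng.uniform(0.0, 0.90, n_genes),
    )

    memberships = [[] for _ in range(n_genes)]
    cons_idx = np.flatnonzero(constrained)
    n_risk = min(max(1, round(p.risk_fraction * n_genes)), len(cons_idx))
    if len(cons_idx) == 0:
        cons_idx = np.argsort(mu[:, 2])[-max(1, n_genes // 10):]
        n_risk = min(n_risk or 1, len(cons_idx))
    w_lof = mu[cons_idx, 2]
    risk_idx = rng.choice(cons_idx, size=n_risk, replace=False, p=w_lof / w_lof.sum())
    for i in risk_idx:
        memberships[i].append("risk")

    n_dd = max(1, round(p.dd_fraction * n_genes))
    w_del = mu[:, 2] + p.f_damaging * mu[:, 1]
    dd_idx = rng.choice(n_genes, size=n_dd, replace=False, p=w_del / w_del.sum())
    for i in dd_idx:
        memberships[i].append("dd")

    return pd.DataFrame(
        {
            "gene": [f"G{i:05d}" for i in range(n_genes)],
            "cds_length": cds,
            "mu_syn": mu[:, 0],
            "mu_mis": mu[:, 1],
            "mu_lof": mu[:, 2],
            "frac_cpg": frac_cpg,
            "pli": pli,
            "set_memberships": [",".join(m) for m in memberships],
        }
    )


def gene_sets_from_model(gene_model: pd.DataFrame) -> dict[str, frozenset]:
    """Extract the named gene sets encoded in ``set_memberships``."""
    sets: dict[str, set] = {}
    for gene, mem in zip(gene_model["gene"], gene_model["set_memberships"]):
        for set_id in str(mem).split(","):
            if set_id:
                sets.setdefault(set_id, set()).add(gene)
    return {k: frozenset(v) for k, v in sets.items()}


def _draw_substitutions(rng: np.random.Generator, frac_cpg: np.ndarray):
    """ref/alt/5'/3' context for SNVs, CpG share of C>T given per record."""
    n = len(frac_cpg)
    cats = list(_BASE_SPECTRUM)
    probs = np.array(list(_BASE_SPECTRUM.values()))
    choice = rng.choice(len(cats), size=n, p=probs)
    ref = np.empty(n, dtype="<U1")
    alt = np.empty(n, dtype="<U1")
    c5 = rng.choice(_BASES, size=n)
    c3 = np.empty(n, dtype="<U1")
    for i in range(n):
        cat = cats[choice[i]]
        r, a = cat.split(">")
        ref[i], alt[i] = r, a
        if cat == "C>T":
            c3[i] = "G" if rng.random() < frac_cpg[i] else rng.choice(["A", "C", "T"])
        elif r == "C":
            c3[i] = rng.choice(["A", "C", "T"])  # keep non-C>T off CpG ambiguity
        else:
            c3[i] = rng.choice(_BASES)
    # random strand: complement ref/alt and swap-complement the flanks
    flip = rng.random(n) < 0.5
    for i in np.flatnonzero(flip):
        ref[i], alt[i] = _COMPLEMENT[ref[i]], _COMPLEMENT[alt[i]]
        c5[i], c3[i] = _COMPLEMENT[c3[i]], _COMPLEMENT[c5[i]]
    return ref, alt, c5, c3


def simulate_trios(gene_model: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Simulate one case/control trio cohort of germline DNM records.

    Per-trio counts of each functional class are Poisson with mean
    ``2 * sum(class rate)``; on the case side the LoF and damaging-missense
    rates of risk-set genes are multiplied by ``config.enrichment_factor``.
    Genes are assigned multinomially with the per-gene class rates as
    weights. Each record carries a consequence, CADD score, population
    allele frequencies (a ``frac_population_observed`` share is flagged as
    seen in gnomAD/ToMMo), VAF, substitution and flanking context.
    """
    sets = gene_sets_from_model(gene_model)
    if config.risk_set not in sets:
        raise ValueError(f"unknown set identifier {config.risk_set!r}")
    risk = gene_model["gene"].isin(sets[config.risk_set]).to_numpy()

    rng = np.random.default_rng(config.seed)
    f = config.f_damaging
    mu_lof = gene_model["mu_lof"].to_numpy()
    mu_mis = gene_model["mu_mis"].to_numpy()
    mu_syn = gene_model["mu_syn"].to_numpy()
    base_w = {
        "lof": mu_lof,
        "dmis": f * mu_mis,
        "ndmis": (1 - f) * mu_mis,
        "syn": mu_syn,
    }
    frames = []
    for group, n_trios in (("case", config.n_case_trios), ("control", config.n_control_trios)):
        ids = [f"{group}_{i:05d}" for i in range(n_trios)]
        for cls, w in base_w.items():
            counts = rng.poisson(2.0 * w.sum(), size=n_trios)
            total = int(counts.sum())
            if total:
                gene_idx = rng.choice(len(w), size=total, p=w / w.sum())
                probands = np.repeat(ids, counts)
                frames.append(
                    _records_for_class(
                        rng, group, probands, gene_idx, cls, gene_model, config
                    )
                )
            # excess case mutations from the injected risk-set enrichment:
            # these model ultra-rare pathogenic DNMs and are therefore never
            # flagged as population-observed (the flag marks the recurrent
            # fraction of background mutations)
            if group == "case" and cls in ("lof", "dmis") and config.enrichment_factor > 1:
                w_risk = w * risk
                lam_extra = 2.0 * (config.enrichment_factor - 1.0) * w_risk.sum()
                extra = rng.poisson(lam_extra, size=n_trios)
                total = int(extra.sum())
                if total:
                    gene_idx = rng.choice(len(w), size=total, p=w_risk / w_risk.sum())
                    probands = np.repeat(ids, extra)
                    frames.append(
                        _records_for_class(
                            rng, group, probands, gene_idx, cls, gene_model, config,
                            force_unobserved=True,
                        )
                    )
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def _records_for_class(rng, group, probands, gene_idx, cls, gene_model, config,
                       force_unobserved=False):
    n = len(probands)
    genes = gene_model["gene"].to_numpy()[gene_idx]
    frac_cpg = gene_model["frac_cpg"].to_numpy()[gene_idx]
    ref, alt, c5, c3 = _draw_substitutions(rng, frac_cpg)
    ref = ref.astype(object)
    alt = alt.astype(object)
    variant_type = np.full(n, "snv", dtype=object)
    cadd = np.full(n, np.nan)

    if cls == "lof":
        consequence = rng.choice(
            ["nonsense", "frameshift", "canonical_splice"], size=n, p=[0.5, 0.35, 0.15]
        )
        snv = consequence != "frameshift"
        cadd[snv] = rng.uniform(20, 45, snv.sum())
    elif cls == "dmis":
        consequence = rng.choice(["missense", "inframe_indel"], size=n, p=[0.94, 0.06])
        snv = consequence == "missense"
        cadd[snv] = rng.uniform(16, 40, snv.sum())
    elif cls == "ndmis":
        consequence = np.full(n, "missense", dtype=object)
        snv = np.full(n, True)
        cadd[:] = rng.uniform(0.5, 15.0, n)
    else:
        consequence = np.full(n, "synonymous", dtype=object)
        snv = np.full(n, True)
        cadd[:] = rng.uniform(0, 10, n)

    indel = ~snv
    variant_type[indel] = "indel"
    # indel alleles: simple one-base-anchor insertions/deletions
    for i in np.flatnonzero(indel):
        if consequence[i] == "frameshift":
            ref[i], alt[i] = "A", "AT"
        else:
            ref[i], alt[i] = "ATTG", "A"

    observed = rng.random(n) < (0.0 if force_unobserved else config.frac_population_observed)
    af_g = np.zeros(n)
    af_t = np.zeros(n)
    in_gnomad = observed & (rng.random(n) < 0.8)
    in_tommo = observed & ((rng.random(n) < 0.5) | ~in_gnomad)
    af_g[in_gnomad] = 10 ** rng.uniform(-6, -3, in_gnomad.sum())
    af_t[in_tommo] = 10 ** rng.uniform(-6, -3, in_tommo.sum())

    score = np.where(
        variant_type == "indel", rng.uniform(0.95, 1.0, n), rng.uniform(0.90, 1.0, n)
    )
    return pd.DataFrame(
        {
            "proband_id": probands,
            "group": group,
            "gene": genes,
            "consequence": consequence,
            "variant_type": variant_type,
            "cadd": cadd,
            "at_interface": False,
            "af_gnomad_nonneuro": af_g,
            "af_tommo": af_t,
            "vaf": rng.beta(40, 40, n),
            "ref": ref,
            "alt": alt,
            "context_5p": c5,
            "context_3p": c3,
            "dnmfilter_score": score,
            "population_observed": observed,
            "sim_class": cls,
        }
    )


def simulate_pz(
    gene_model: pd.DataFrame,
    n_trios: int,
    n_pz: int,
    vaf_params: tuple[float, float] = (2.0, 8.0),
    depth: int = 120,
    seed: int = 0,
    tas_depth: int = 12000,
    frac_population_observed: float = 0.2,
) -> pd.DataFrame:
    """Simulate postzygotic candidate records with exome and deep read counts.

    VAFs are Beta(``vaf_params``) truncated to (0, 0.5); alt read counts
    are binomial at the exome depth and again at the deep amplicon depth.
    Substitutions come from the same seven-category spectrum as germline
    records.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    a, b = vaf_params
    if a <= 0 or b <= 0:
        raise ValueError("Beta parameters must be > 0")
    rng = np.random.default_rng(seed)

    vaf = np.empty(n_pz)
    filled = 0
    while filled < n_pz:
        draw = rng.beta(a, b, 2 * (n_pz - filled) + 8)
        draw = draw[(draw > 0) & (draw < 0.5)][: n_pz - filled]
        vaf[filled:filled + len(draw)] = draw
        filled += len(draw)

    w = (gene_model["mu_lof"] + 0.45 * gene_model["mu_mis"]).to_numpy()
    gene_idx = rng.choice(len(w), size=n_pz, p=w / w.sum())
    genes = gene_model["gene"].to_numpy()[gene_idx]
    frac_cpg = gene_model["frac_cpg"].to_numpy()[gene_idx]
    ref, alt, c5, c3 = _draw_substitutions(rng, frac_cpg)

    alt_reads = rng.binomial(depth, vaf)
    depth_f = np.maximum(1, rng.poisson(depth, n_pz))
    depth_m = np.maximum(1, rng.poisson(depth, n_pz))
    consequence = rng.choice(
        ["missense", "nonsense", "synonymous"], size=n_pz, p=[0.7, 0.2, 0.1]
    )
    cadd = np.where(
        consequence == "missense",
        rng.uniform(16, 40, n_pz),
        np.where(consequence == "nonsense", rng.uniform(25, 45, n_pz), rng.uniform(0, 10, n_pz)),
    )
    observed = rng.random(n_pz) < frac_population_observed
    af_g = np.where(observed, 10 ** rng.uniform(-6, -3, n_pz), 0.0)

    return pd.DataFrame(
        {
            "proband_id": [f"case_{i:05d}" for i in rng.integers(0, n_trios, n_pz)],
            "gene": genes,
            "consequence": consequence,
            "variant_type": "snv",
            "cadd": cadd,
            "vaf_exome": alt_reads / depth,
            "alt_reads_proband": alt_reads,
            "alt_reads_father": rng.binomial(depth_f, 5e-4),
            "alt_reads_mother": rng.binomial(depth_m, 5e-4),
            "depth_father": depth_f,
            "depth_mother": depth_m,
            "strand_support": rng.random(n_pz) < 0.98,
            "tlod": rng.gamma(3.0, 6.0, n_pz),
            "in_cnv_region": rng.random(n_pz) < 0.02,
            "tas_alt": rng.binomial(tas_depth, vaf),
            "tas_depth": tas_depth,
            "af_gnomad_nonneuro": af_g,
            "af_tommo": 0.0,
            "ref": ref,
            "alt": alt,
            "context_5p": c5,
            "context_3p": c3,
            "true_vaf": vaf,
        }
    )


def simulate_sc(
    n_cells: int,
    n_genes: int,
    cluster_props,
    signature_set,
    upregulation: float = 1.0,
    seed: int = 0,
    target_cluster: int = 0,
    markers_per_cluster: int = 20,
    marker_fold: float = 4.0,
    base_log_mean: float = -1.2,
    base_log_sigma: float = 1.2,
    dispersion: float = 2.0,
) -> ad.AnnData:
    """Simulate a clustered single-cell count matrix.

    Counts are gamma-Poisson (negative binomial) around per-gene base
    means shared across clusters; each cluster additionally up-regulates a
    private block of marker genes (giving the clustering its structure),
    and the ``target_cluster`` multiplies the signature genes' means by
    ``upregulation``. Signature genes never overlap marker genes, so with
    ``upregulation=1`` no cluster is systematically enriched for signature
    activity. Per-cell QC metrics (detected genes, total reads, simulated
    mitochondrial fraction) are emitted in ``.obs``.

    ``signature_set`` is either an integer (that many signature genes are
    drawn at random outside the marker blocks) or an explicit list of gene
    indices. Returns an :class:`anndata.AnnData` with cluster labels in
    ``obs["cluster"]`` and the signature gene names in
    ``uns["signature_genes"]``.
    """
    props = np.asarray(cluster_props, dtype=float)
    if abs(props.sum() - 1.0) > 1e-8:
        raise ValueError("cluster proportions must sum to 1")
    k = len(props)
    if not (0 <= target_cluster < k):
        raise ValueError("target_cluster out of range")
    rng = np.random.default_rng(seed)

    n_marker = markers_per_cluster * k
    if n_marker >= n_genes:
        raise ValueError("n_genes too small for the requested marker blocks")
    marker_gene = np.arange(n_marker)
    marker_cluster = np.repeat(np.arange(k), markers_per_cluster)

    if np.isscalar(signature_set):
        n_sig = int(signature_set)
        if n_sig < 1:
            raise ValueError("signature set must be non-empty")
        if n_sig > n_genes - n_marker:
            raise ValueError("signature set larger than available non-marker genes")
        sig_idx = rng.choice(np.arange(n_marker, n_genes), size=n_sig, replace=False)
    else:
        sig_idx = np.asarray(list(signature_set), dtype=int)
        if len(sig_idx) == 0:
            raise ValueError("signature set must be non-empty")

    base = rng.lognormal(base_log_mean, base_log_sigma, n_genes)
    mean = np.tile(base, (k, 1))
    mean[marker_cluster, marker_gene] *= marker_fold
    mean[target_cluster, sig_idx] *= upregulation

    labels = rng.choice(k, size=n_cells, p=props)
    lib = rng.lognormal(0.0, 0.3, n_cells)
    lam = mean[labels] * lib[:, None]
    shape = dispersion
    counts = rng.poisson(rng.gamma(shape, lam / shape))

    var_names = [f"G{i:05d}" for i in range(n_genes)]
    obs = pd.DataFrame(
        {
            "cluster": pd.Categorical([f"c{c}" for c in labels]),
            "detected_genes": (counts > 0).sum(axis=1),
            "total_reads": counts.sum(axis=1),
            "mito_fraction": rng.beta(1.5, 150, n_cells),
        },
        index=[f"cell_{i:05d}" for i in range(n_cells)],
    )
    adata = ad.AnnData(X=counts.astype(np.int64), obs=obs)
    adata.var_names = var_names
    adata.uns["signature_genes"] = [var_names[i] for i in sig_idx]
    adata.uns["target_cluster"] = f"c{target_cluster}"
    return adata
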