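# Methods

## Statistical model

### Functional classes and filtering

Exonic DNM calls are partitioned into four classes — LoF (nonsense,
frameshift, canonical splice), damaging (missense with CADD > 15, strict
inequality; missense at a protein–protein interface; stop-lost,
start-lost, in-frame indel), non-damaging missense (CADD ≤ 15) and
synonymous. Non-exonic consequences map to `other` and never enter counts.
A missense record with neither a CADD score nor an interface flag is a
hard error rather than a silent default, since its class is genuinely
undefined.

Population filtering removes any record with a positive allele frequency
in either reference database (gnomAD non-neuro, ToMMo); a *missing*
frequency means the variant was not observed there and the record is
retained — absence from the databases is exactly the retention condition.
Caller-score filtering keeps a record iff every named score is ≥ its
per-variant-type cutoff (keep-if-≥, so an SNV exactly at 0.90 survives a
0.90 cutoff). Within one proband and gene, multiple calls collapse to the
severest class; ties inside a class keep the first record in input order
(the severity order is defined across classes only, so any within-class
rule is a convention — input order makes the operation deterministic and
stable).

### Rate comparison

Per-individual counts are compared by a one-tailed permutation test on

    T = c · mean(case) − mean(control),

where the calibration factor `c = (control synonymous rate)/(case
synonymous rate)` (population-observed variants included) absorbs
cohort-level artefacts under the assumption that synonymous DNMs are
neutral. Calibration multiplies the case-side statistic rather than
reweighting individuals — the simplest reading of "adjusting" a rate, and
exact at the group level. Group labels are permuted uniformly; the P-value
is the pseudocount estimator `(b + 1)/(n_perm + 1)` with `b` the number of
permutations whose statistic is at least the observed one. The estimator
never returns zero and is the standard Monte-Carlo choice; with ties it is
(slightly) conservative, which the calibration test in the suite
quantifies. Bonferroni correction is `min(1, m·p)` over the family of
class × gene-filter tests.

Outlier QC before testing: within each group, iterate from the individual
with the maximum total count and remove it while
`dpois(x_max, mean of retained) · n_retained < 0.05`, recomputing the mean
after each removal. `n` is the number of individuals in the group — a
Bonferroni-style multiplier for having scanned the group for its extreme
member; one individual is removed per iteration.

### Per-gene mutational model

Per-gene, per-generation mutation probabilities μ (synonymous, missense,
LoF) are inputs, not derived here. The expected count of class-*c*
mutations in gene *g* over *N* trios is `λ = 2·N·μ_gc`: the rates are per
transmitted haplotype and each trio contributes two. The factor is exposed
(`diploid_factor`) because published rate tables differ in whether it is
already folded in. The deleterious rate of a gene is
`μ_LoF + f_damaging · μ_mis`, where `f_damaging` is the fraction of
missense DNMs that are damaging (CADD > 15) estimated in controls;
in-frame indels are excluded because the rate model does not cover them.

Recurrence in a single gene: one-tailed Poisson `P(X ≥ k | λ)`, against an
exome-wide threshold `0.05/n_genes` over genes with available rates.
Gene-set burden: one-tailed binomial of the observed hit count against the
set's share of the summed deleterious rate. Gene-level recurrence in a
cohort-wide candidate list: `n` mutations are placed into genes with
probability proportional to the deleterious rates, and the P-value is the
fraction of replicates in which any gene is hit twice. Placement at the
gene level (rather than per site) is exact for every statistic used here,
because only the per-gene hit distribution matters and the rate table
already integrates site-level context.

### Placement-based gene-set enrichment

The enrichment engine keeps the observed class counts fixed and re-places
each mutation into a gene with class-specific rate weights. Because the
placements are independent, the null set-hit count is a sum of per-class
binomials with success probability equal to the set's weight share; the
implementation samples those binomials directly instead of materialising
every placement, which is distribution-identical (verified against
exhaustive enumeration in the test suite) and orders of magnitude faster
at 10⁵–10⁶ permutations. `place_mutations` still produces genuine
per-gene placements for callers that need them. P-values use the same
`(b+1)/(n_perm+1)` estimator; expected hits are the permutation mean.

Sets are harmonised to the model's background genes; sets with fewer than
30 or more than 1500 members are excluded by default (too little power /
too little specificity), and Benjamini–Hochberg FDR runs within each set
category (e.g. each GO namespace) independently. Top-expression sets take
the `ceil(fraction·G)` highest-expression genes per tissue with ties at
the cutoff broken by gene symbol. Groups of sets (e.g. brain vs non-brain
tissues) are compared by the exact Wilcoxon rank-sum test on their
uncorrected enrichment P-values, one-tailed by default (the question is
whether one group is *more* enriched); with cross-group ties the exact
distribution does not exist and the mid-rank normal approximation is used
with a warning.

### Single-cell gene-set activity

Cells failing QC are dropped: < 1000 detected genes (strict), > 10,000
detected genes or > 1.5 M reads (doublet proxies), > 2% mitochondrial
reads. Each cell's genes are ranked by descending expression with
seeded shuffling of ties (counts are integers, so ties are common); the
activity score is the area under the set-recovery curve over the first
`max_rank` ranks, normalised by `max_rank · |set|` so it lies in [0, 1].
Only the top ranks enter, which makes the score robust to differences in
per-cell library complexity; it is rank-based, hence invariant to monotone
transformations of expression. The default `max_rank` of 1000 matches the
QC floor of 1000 detected genes.

The `ceil(fraction·n)` top-scoring cells (default 5%; ceiling because the
count is fractional and no rounding rule is canonical; boundary ties break
by cell id) are tested per cluster: one-tailed binomial of the cluster's
top-cell count against `Binomial(cluster size, fraction)`, Bonferroni over
the number of clusters (overridable). Cluster signatures are genes
up-regulated in a target cluster versus comparison clusters by one-sided
rank-sum tests on counts-per-10,000 log1p-normalised expression with BH
FDR < 0.05 — an emulation of standard single-cell marker detection, not a
re-implementation of any specific tool. Clustering itself is *not*
performed here; cluster labels are input, as they come from standard
toolchains. Set overlaps are one-tailed hypergeometric on an explicit
background; members outside the background are dropped with a warning.

### Postzygotic variants

Candidate filters (all must hold): proband VAF < 0.35 (strict — a true
heterozygote fluctuates around 0.5), ≥ 5 supporting reads, both strands,
≤ 1 alt read in each parent at ≥ 10× depth, caller fidelity TLOD ≥ 5, and
not in a called CNV region. The filter is monotone: relaxing any threshold
can only grow the retained set. Deep-sequencing classification uses the
amplicon VAF: `pzDNM` in [0.01, 0.475) (lower bound inclusive), `likely
gDNM` at ≥ 0.475, `fail` below 1%. The accompanying binomial test of the
alt count against rate 0.5 is two-tailed: the point is to reject the
germline-heterozygote hypothesis in either direction.

Substitution spectra use seven categories on the pyrimidine/A strand;
G and T references are complemented (G>A → C>T etc.), and C>T splits by
whether the base 3′ of the strand-normalised C is G (CpG). Records
therefore carry both flanking bases (`context_5p`, `context_3p`): a purine
reference needs its 5′ neighbour to recover the CpG status of the
complementary strand, and carrying both makes the spectrum exactly
invariant under reverse-complementing the input. Spectra are compared by
a conditional exact test on the 2×7 table (the null distribution of one
row given both margins is multivariate hypergeometric; the P-value sums
the probabilities of tables no more probable than the observed one) and
by the Pearson correlation of the proportion vectors. The table space is
enumerated exhaustively when it has ≤ 2×10⁵ candidate row vectors —
this path reproduces the reference r×c exact test to ~1e-9 — and
otherwise sampled with 10⁶ seeded Monte-Carlo tables, with the mode
recorded in the result.

## Synthetic-data generator

The generator produces data with the structure the analyses assume, at
sizes chosen to mirror a trio-sequencing study of a psychiatric phenotype.

**Gene model.** CDS lengths are lognormal (median ≈ 1.5 kb); per-gene
total rates are proportional to length times a lognormal context factor
and normalised so the exome-wide per-trio rate is exactly 1.1 — the scale
observed in trio studies. The split into synonymous/missense/LoF uses
shares 0.29/0.62/0.09 with mild Dirichlet jitter. A fraction `pli_frac`
(default 0.18, the genome-wide share of pLI > 0.9 genes) is constrained,
with constraint probability increasing in log-rate — in real data
LoF-intolerant genes are systematically long and high-μ, and this
correlation is what gives constrained-gene analyses their power. The risk
set (default 5% of genes) is drawn from constrained genes weighted by LoF
rate, emulating the observation that risk genes are large constrained
genes; a DD-like set (1.6% of genes, matching 299/19,182) is drawn
rate-weighted from all genes.

**Trio cohorts.** Per-trio class counts are Poisson(2·Σμ_class), genes
multinomial with per-gene class rates as weights. Case enrichment is
injected as an *additional* Poisson stream of LoF/damaging-missense
mutations restricted to risk-set genes with rate
`2·(factor−1)·Σ_risk μ`, so risk-set classes total `factor ×` the control
expectation. Baseline mutations are flagged population-observed with
probability 0.39 (the fraction observed in the study cohort this emulates);
the injected excess is never flagged — it models ultra-rare pathogenic
DNMs, which are by construction absent from population databases. This is
what lets downstream stages recover injected enrichment after their own
population filtering, as the analyses do on real data. Damaging missense
is a fraction `f_damaging = 0.45` of missense. CADD scores are drawn
consistently with the class (damaging missense strictly > 15), VAFs are
tight Beta around 0.5, and substitutions follow a seven-category germline
spectrum with the gene's CpG opportunity.

**Postzygotic tables.** VAF ~ Beta(2, 8) truncated to (0, 0.5); alt reads
binomial at exome depth (default 120×) and at deep amplicon depth
(default 12,000×, the scale of targeted validation sequencing); parental
alt reads binomial at a 5×10⁻⁴ error rate; a small share of records fails
strand support, TLOD or CNV criteria so the filters have work to do.

**Single-cell matrices.** Counts are gamma-Poisson (negative binomial,
dispersion 2) around per-gene lognormal base means shared across clusters;
each cluster up-regulates a private marker block (giving cluster structure)
and the designated cluster multiplies the signature genes by the
`upregulation` factor. Signature and marker genes never overlap, so with
`upregulation = 1` no cluster is systematically enriched for signature
activity — the null the per-cluster binomial test should not reject.
Library size varies lognormally per cell; QC metrics are emitted per cell
with a simulated mitochondrial fraction.

What the generator does **not** emulate: read-level errors and alignment
artefacts, pedigree errors, indel-specific rate models, batch effects in
either cohort, doublets or ambient RNA in the single-cell data, or
between-cluster differences in library size. Passing tests on this data
therefore validate the statistical machinery — calibration, power against
an injected effect of known size, estimator correctness — not robustness
to those real-data pathologies.

**Seeding.** Every generator call takes one integer seed and drives all
of its randomness from a single `numpy` generator, so outputs are
byte-identical across runs; analysis functions with stochastic components
(permutation tests, tie shuffling, Monte-Carlo exact tests) are seeded the
same way.

## Problem sizes used in the checks

The test suite validates the stochastic machinery at sizes chosen to give
tight Monte-Carlo error at interactive runtimes: type-I calibration over
1000 null cohorts of 50 + 50 trios at 399 permutations; power against a
3× LoF risk-set enrichment over 30 replicate cohorts of 250 + 1500 trios
on a 6,000-gene model; single-cell detection over 20–40 replicates of
600 cells × 1,500 genes in 8 clusters with a 40-gene signature scored at
`max_rank = 100` (the 1000-gene default scaled to the smaller gene space);
collision probabilities at 10⁵ replicates against the analytic value for
26 mutations over 19,182 genes.

## Known limitations

* The permutation rate test is conservative under heavy ties (discrete
  counts, small groups); its measured type-I error sits slightly below the
  nominal level.
* The 2×7 exact test falls back to Monte-Carlo for large tables; at 10⁶
  tables the P-value has a relative error of order 1/√(10⁶·p).
* The signature-derivation step is a generic rank-sum emulation of marker
  detection and will not numerically reproduce any particular single-cell
  framework's differential-expression output.
* Gene-level placement cannot express *within*-gene clustering of
  mutations; statistics that depend on site-level positions are out of
  scope.
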