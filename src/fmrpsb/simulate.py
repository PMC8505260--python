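"""Synthetic data generators with planted, recoverable effects.

Every input the pipeline consumes can be generated here: a gene annotation
table, CLIP-style binding statistics, GWAS summary statistics with
compound-symmetric LD, a rare-variant case-control cohort, per-gene de
novo counts, CNV tables and an overlapping ontology. A single latent
"target" gene set plays the role of the true FMRP-target/risk set: binding
p-values rank it highly and each variant-type generator plants its
configured effect size in it, so each analysis stage can be checked for
null calibration (effect = 0 / odds ratio = 1) and parameter recovery.

All generators are pure functions of :class:`SimConfig`: the same seed
reproduces the same data. Default sizes follow the study design the
pipeline emulates (400-gene sets, 3,444 trios, 4,079/5,712 exomes,
17,565/24,830 CNV subjects); every count scales down for quick runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .records import (
    BindingRecord,
    CnvRecord,
    Direction,
    GeneRecord,
    RareVariantRecord,
    SnpRecord,
    TermAnnotation,
)

__all__ = [
    "SimConfig",
    "SimData",
    "gen_genome",
    "pick_target_set",
    "gen_binding",
    "gen_gwas",
    "gen_gene_stats",
    "gen_rare_cohort",
    "gen_trios",
    "gen_cnvs",
    "gen_ontology",
    "simulate_all",
]


@dataclass
class SimConfig:
    """Serialisable knobs of the synthetic study.

    Effect-size fields are the values each pipeline stage should recover:
    ``planted_beta_common`` is the competitive-test regression coefficient
    (gene Z-score shift), ``planted_or_rare`` and ``planted_or_cnv`` are
    odds ratios (per set variant / per overlapped set gene), and
    ``planted_rr_dnm`` is the de novo rate ratio inside the target set.
    """

    seed: int = 0
    # genome
    n_genes: int = 5000
    n_chroms: int = 22
    mean_gene_length: int = 20_000
    brain_expressed_frac: float = 0.7
    mu_ns_per_exome: float = 1.0  # exome-wide per-haploid NS rate, spread over genes
    # targets
    target_fraction: float = 0.08
    # binding
    binding_noise: float = 0.15  # Beta(a, 1) shape for target p-values; smaller = cleaner
    n_replicates: int = 2
    mean_peaks: float = 2.0
    replicate_dropout: float = 0.05
    # GWAS
    snp_mean: float = 8.0
    ld_rho: float = 0.3
    low_maf_fraction: float = 0.05
    planted_beta_common: float = 0.3
    # rare variants
    n_cases: int = 4079
    n_controls: int = 5712
    planted_or_rare: float = 1.5
    ns_singletons_per_sample: float = 1.0
    lof_fraction: float = 0.12
    syn_singletons_per_sample: float = 0.45
    n_filter_probe_records: int = 40
    # de novo
    n_trios: int = 3444
    planted_rr_dnm: float = 2.0
    # CNVs
    n_cnv_cases: int = 17_565
    n_cnv_controls: int = 24_830
    planted_or_cnv: float = 1.3
    cnv_median_length: int = 150_000
    cnv_length_sigma: float = 0.6
    # ontology
    n_terms: int = 60
    term_size_median: int = 40
    term_size_sigma: float = 0.6
    term_overlap_fraction: float = 0.3
    enriched_term_fraction: float = 0.25
    enrichment_odds: float = 6.0
    iea_fraction: float = 0.2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimData:
    """Everything one synthetic study produces, plus the planted truth."""

    config: SimConfig
    genes: list[GeneRecord]
    target_set: set[str]
    binding: list[BindingRecord]
    snps: list[SnpRecord]
    ld: dict[str, np.ndarray]
    rare_variants: list[RareVariantRecord]
    sample_covariates: "object"  # pandas DataFrame
    dnm_counts: dict[str, tuple[int, int]]
    cnvs: list[CnvRecord]
    terms: list[TermAnnotation]
    truth: dict = field(default_factory=dict)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def gen_genome(cfg: SimConfig) -> list[GeneRecord]:
    """Genes on synthetic chromosomes with log-normal lengths.

    Mutation rates are proportional to gene length and normalised so the
    per-haploid exome-wide NS rate equals ``mu_ns_per_exome``; the LoF and
    synonymous classes are fixed fractions of NS (LoF is a sub-class of
    NS, so mu_lof < mu_ns).
    """
    rng = _rng(cfg, 1)
    if cfg.n_genes == 0:
        return []
    lengths = np.maximum(
        rng.lognormal(np.log(cfg.mean_gene_length), 0.8, cfg.n_genes).astype(int), 200
    )
    chroms = rng.integers(1, cfg.n_chroms + 1, cfg.n_genes)
    strands = rng.choice(["+", "-"], cfg.n_genes)
    expressed = rng.random(cfg.n_genes) < cfg.brain_expressed_frac
    mu_ns = lengths / lengths.sum() * cfg.mu_ns_per_exome
    genes = []
    pos = {c: 1_000_000 for c in range(1, cfg.n_chroms + 1)}
    order = np.argsort(chroms, kind="stable")
    for i in order:
        c = int(chroms[i])
        start = pos[c] + int(rng.integers(5_000, 120_000))
        end = start + int(lengths[i]) - 1
        pos[c] = end
        genes.append(
            GeneRecord(
                gene_id=f"G{i:05d}",
                chrom=str(c),
                start=start,
                end=end,
                strand=str(strands[i]),
                brain_expressed=bool(expressed[i]),
                mu_lof=float(0.12 * mu_ns[i]),
                mu_ns=float(mu_ns[i]),
                mu_syn=float(0.45 * mu_ns[i]),
            )
        )
    genes.sort(key=lambda g: g.gene_id)
    return genes


def pick_target_set(cfg: SimConfig, genes: list[GeneRecord]) -> set[str]:
    """Draw the latent target/risk set (a ``target_fraction`` of genes)."""
    rng = _rng(cfg, 2)
    k = int(round(cfg.target_fraction * len(genes)))
    ids = [g.gene_id for g in genes]
    return set(rng.choice(ids, size=k, replace=False))


def gen_binding(
    cfg: SimConfig, genes: list[GeneRecord], target_set: set[str]
) -> list[BindingRecord]:
    """Peak-level binding p-values across replicates, targets ranking high.

    True targets draw peak p-values from Beta(binding_noise, 1) (small
    values), non-targets from Uniform(0, 1). Each gene appears in each
    replicate with probability 1 - replicate_dropout, with a Poisson
    number of peaks, exercising the collapse rules.
    """
    rng = _rng(cfg, 3)
    records = []
    for g in genes:
        is_target = g.gene_id in target_set
        for rep in range(1, cfg.n_replicates + 1):
            if rng.random() < cfg.replicate_dropout:
                continue
            n_peaks = 1 + rng.poisson(max(cfg.mean_peaks - 1.0, 0.0))
            for _ in range(n_peaks):
                p = rng.beta(cfg.binding_noise, 1.0) if is_target else rng.random()
                records.append(
                    BindingRecord(
                        gene_id=g.gene_id,
                        stat=float(np.clip(p, 1e-300, 1.0)),
                        direction=Direction.LOWER_IS_BETTER,
                        replicate_id=f"rep{rep}",
                        source="synthetic_clip",
                    )
                )
    return records


def _calibrate_snp_shift(
    beta: float, m: int, rho: float, rng: np.random.Generator, n_draws: int = 2000
) -> float:
    """SNP z-score mean shift delta with E[gene Z(delta) - gene Z(0)] = beta.

    The probit gene Z is a nonlinear function of the SNP z-scores, so the
    required delta is found by bisection on a Monte-Carlo estimate of the
    mean gene Z, with common random numbers across candidate deltas. The
    gene Z is evaluated with the same scaled-chi-square combination the
    analysis uses, vectorised over draws via its closed-form parameters
    for compound-symmetric LD.
    """
    from .common_variant import _neg2logp_cov

    L = np.linalg.cholesky(_cs_matrix(m, rho))
    base = rng.standard_normal((n_draws, m)) @ L.T
    mean_T = 2.0 * m
    var_T = 4.0 * m + 2.0 * (m * (m - 1) / 2.0) * float(_neg2logp_cov(rho))
    c = var_T / (2.0 * mean_T)
    f = 2.0 * mean_T**2 / var_T

    def mean_z(delta: float) -> float:
        p = np.clip(2.0 * stats.norm.sf(np.abs(base + delta)), 1e-300, 1.0)
        T = (-2.0 * np.log(p)).sum(axis=1)
        gene_p = np.clip(stats.chi2.sf(T / c, f), 1e-300, 1.0)
        return float(np.mean(stats.norm.isf(gene_p)))

    z0 = mean_z(0.0)
    lo, hi = 0.0, 0.2
    while mean_z(hi) - z0 < beta:
        hi *= 2.0
        if hi > 50:
            raise RuntimeError("shift calibration failed to bracket")
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        if mean_z(mid) - z0 < beta:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _cs_matrix(m: int, rho: float) -> np.ndarray:
    R = np.full((m, m), rho)
    np.fill_diagonal(R, 1.0)
    return R


def gen_gwas(
    cfg: SimConfig, genes: list[GeneRecord], risk_set: set[str]
) -> tuple[list[SnpRecord], dict[str, np.ndarray]]:
    """GWAS summary statistics with compound-symmetric within-gene LD.

    Per gene, SNP z-scores are multivariate normal with correlation
    ``ld_rho``; risk-set genes receive a common mean shift calibrated (per
    SNP count) so the expected gene-Z elevation equals
    ``planted_beta_common``. P-values are two-sided; a small fraction of
    SNPs get MAF < 0.01 to exercise the frequency filter.
    """
    rng = _rng(cfg, 4)
    shift_cache: dict[int, float] = {}
    snps: list[SnpRecord] = []
    ld: dict[str, np.ndarray] = {}
    crng = np.random.default_rng([cfg.seed, 40])  # calibration stream
    for g in genes:
        m = 1 + rng.poisson(max(cfg.snp_mean - 1.0, 0.0))
        m = min(m, 40)
        R = _cs_matrix(m, cfg.ld_rho)
        ld[g.gene_id] = R
        delta = 0.0
        if g.gene_id in risk_set and cfg.planted_beta_common != 0.0:
            if m not in shift_cache:
                shift_cache[m] = _calibrate_snp_shift(
                    cfg.planted_beta_common, m, cfg.ld_rho, crng
                )
            delta = shift_cache[m]
        L = np.linalg.cholesky(R)
        z = L @ rng.standard_normal(m) + delta
        p = 2.0 * stats.norm.sf(np.abs(z))
        positions = np.sort(rng.integers(g.start, g.end + 1, size=m))
        for j in range(m):
            low = rng.random() < cfg.low_maf_fraction
            maf = float(rng.uniform(0.001, 0.01)) if low else float(rng.uniform(0.01, 0.5))
            snps.append(
                SnpRecord(
                    snp_id=f"{g.gene_id}_snp{j}",
                    chrom=g.chrom,
                    pos=int(positions[j]),
                    pvalue=float(np.clip(p[j], 1e-300, 1.0)),
                    maf=maf,
                )
            )
    return snps, ld


def gen_gene_stats(
    cfg: SimConfig, genes: list[GeneRecord], risk_set: set[str], stream: int = 5
):
    """Gene-level Z scores planted directly: z ~ N(beta * 1[risk], 1).

    The direct route for calibration and recovery studies of the
    competitive test, bypassing the SNP layer (where the same shift is
    induced via calibrated noncentrality).
    """
    from .records import GeneLevelStat

    rng = _rng(cfg, stream)
    out = []
    for g in genes:
        mu = cfg.planted_beta_common if g.gene_id in risk_set else 0.0
        z = float(rng.standard_normal() + mu)
        out.append(
            GeneLevelStat(
                gene_id=g.gene_id,
                n_snps=1,
                gene_p=float(stats.norm.sf(z)),
                z=z,
                covariates=(float(np.log(g.length)), 0.0, 0.0),
            )
        )
    return out


_LOF_SUBTYPES = ("nonsense", "essential_splice", "frameshift")


def gen_rare_cohort(
    cfg: SimConfig, genes: list[GeneRecord], risk_set: set[str]
) -> tuple[list[RareVariantRecord], "object"]:
    """Case-control ultra-rare singleton cohort with a planted burden OR.

    Per sample, class counts are Poisson with per-gene rates proportional
    to mutation rate; inside the risk set, case rates are multiplied by
    ``planted_or_rare`` (for Poisson-distributed exposures the prospective
    logistic coefficient of the set count is exactly ln OR). Generated
    variants are singletons by construction (cohort count 1, reference
    count 0); ``n_filter_probe_records`` extra non-singleton records are
    appended to exercise the ultra-rare filter. Returns the variant list
    and a sample covariate DataFrame (status, pc1..pc10, platform, sex,
    synonymous_burden).
    """
    import pandas as pd

    rng = _rng(cfg, 6)
    n = cfg.n_cases + cfg.n_controls
    status = np.concatenate([np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)])
    sample_ids = [f"S{i:06d}" for i in range(n)]

    gene_ids = np.array([g.gene_id for g in genes])
    mu = np.array([g.mu_ns for g in genes])
    w = mu / mu.sum()
    in_set = np.isin(gene_ids, list(risk_set))
    p_set = float(w[in_set].sum())

    lam_ns = cfg.ns_singletons_per_sample
    lam_lof = lam_ns * cfg.lof_fraction
    lam_mis = lam_ns - lam_lof
    or_r = cfg.planted_or_rare

    variants: list[RareVariantRecord] = []
    syn_burden = rng.poisson(cfg.syn_singletons_per_sample, size=n)
    mult = np.where(status == 1, or_r, 1.0)

    def emit(rate_per_sample: np.ndarray, inside: bool, kinds: tuple[str, ...]) -> None:
        counts = rng.poisson(rate_per_sample)
        total = int(counts.sum())
        if total == 0:
            return
        pool = gene_ids[in_set] if inside else gene_ids[~in_set]
        pw = w[in_set] if inside else w[~in_set]
        chosen = rng.choice(pool, size=total, p=pw / pw.sum())
        cons = rng.choice(kinds, size=total)
        owners = np.repeat(np.arange(n), counts)
        variants.extend(
            RareVariantRecord(sample_ids[i], str(g), str(c), 1, 0)
            for i, g, c in zip(owners, chosen, cons)
        )

    emit(lam_lof * p_set * mult, True, _LOF_SUBTYPES)
    emit(np.full(n, lam_lof * (1.0 - p_set)), False, _LOF_SUBTYPES)
    emit(lam_mis * p_set * mult, True, ("missense", "inframe_indel"))
    emit(np.full(n, lam_mis * (1.0 - p_set)), False, ("missense", "inframe_indel"))
    owners = np.repeat(np.arange(n), syn_burden)
    pool, pw = gene_ids[~in_set], w[~in_set]
    if owners.size:
        chosen = rng.choice(pool, size=owners.size, p=pw / pw.sum())
        variants.extend(
            RareVariantRecord(sample_ids[i], str(g), "synonymous", 1, 0)
            for i, g in zip(owners, chosen)
        )

    # records that must be removed by the ultra-rare filter
    for j in range(cfg.n_filter_probe_records):
        sid = sample_ids[int(rng.integers(0, n))]
        gene = str(rng.choice(gene_ids))
        ac = int(rng.integers(2, 6)) if j % 2 == 0 else 1
        ext = 0 if j % 2 == 0 else int(rng.integers(1, 4))
        variants.append(RareVariantRecord(sid, gene, "missense", ac, ext))

    cov = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "status": status,
            **{f"pc{k}": rng.standard_normal(n) for k in range(1, 11)},
            "platform": rng.choice(["platA", "platB"], n),
            "sex": rng.choice(["M", "F"], n),
            "synonymous_burden": syn_burden,
        }
    )
    return variants, cov


def gen_trios(
    cfg: SimConfig, genes: list[GeneRecord], risk_set: set[str]
) -> dict[str, tuple[int, int]]:
    """Per-gene de novo counts: n_lof and n_ns (NS includes LoF).

    Counts are Poisson(2 * n_trios * mu * RR) with RR = planted_rr_dnm
    inside the risk set and 1 elsewhere, drawn per class (LoF, then the
    missense/inframe remainder) so that n_lof <= n_ns by construction.
    """
    rng = _rng(cfg, 7)
    out = {}
    for g in genes:
        rr = cfg.planted_rr_dnm if g.gene_id in risk_set else 1.0
        n_lof = int(rng.poisson(2.0 * cfg.n_trios * g.mu_lof * rr))
        n_mis = int(rng.poisson(2.0 * cfg.n_trios * (g.mu_ns - g.mu_lof) * rr))
        out[g.gene_id] = (n_lof, n_lof + n_mis)
    return out


def gen_cnvs(
    cfg: SimConfig, genes: list[GeneRecord], risk_set: set[str]
) -> list[CnvRecord]:
    """CNV table with case status tilted by overlapped risk-set genes.

    CNV lengths are log-normal straddling the 100 kb filter and probe
    counts straddle 15. Status is assigned from a logistic model whose
    risk-gene coefficient is ln(planted_or_cnv) (plus small size and study
    effects), with the intercept calibrated so the expected case count is
    ``n_cnv_cases``; the regression in :mod:`fmrpsb.cnv` should therefore
    recover ln(planted_or_cnv).
    """
    from .cnv import _overlap_index

    rng = _rng(cfg, 8)
    n = cfg.n_cnv_cases + cfg.n_cnv_controls
    lengths = rng.lognormal(np.log(cfg.cnv_median_length), cfg.cnv_length_sigma, n).astype(int)
    probes = rng.poisson(lengths / 10_000.0).astype(int)
    chrom_extent: dict[str, int] = {}
    for g in genes:
        chrom_extent[g.chrom] = max(chrom_extent.get(g.chrom, 2_000_000), g.end + 200_000)
    chroms = rng.choice(sorted(chrom_extent), n)
    starts = np.array(
        [rng.integers(1, max(chrom_extent[c] - lengths[i], 2)) for i, c in enumerate(chroms)]
    )
    types = rng.choice(["deletion", "duplication"], n)
    studies = rng.choice(["study1", "study2", "study3"], n)
    chips = np.where(
        studies == "study1", "chipA", rng.choice(["chipA", "chipB"], n)
    )

    probe_cnvs = [
        CnvRecord(f"C{i:06d}", 0, str(chroms[i]), int(starts[i]), int(starts[i] + lengths[i] - 1),
                  str(types[i]), int(probes[i]), str(studies[i]), str(chips[i]))
        for i in range(n)
    ]
    idx = _overlap_index(probe_cnvs, genes)
    member = np.array([g.gene_id in risk_set for g in genes])
    n_set = np.array([int(member[gi].sum()) for gi in idx], dtype=float)

    eta = np.log(cfg.planted_or_cnv) * n_set
    eta += 0.2 * (lengths / 1e6)
    eta += np.select([studies == "study2", studies == "study3"], [0.1, -0.1], 0.0)
    target_frac = cfg.n_cnv_cases / n

    def mean_case(alpha: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))))

    lo, hi = -20.0, 20.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if mean_case(mid) < target_frac:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    status = (rng.random(n) < 1.0 / (1.0 + np.exp(-(alpha + eta)))).astype(int)

    return [
        CnvRecord(c.sample_id, int(status[i]), c.chrom, c.start, c.end, c.cnv_type,
                  c.n_probes, c.study, c.chip)
        for i, c in enumerate(probe_cnvs)
    ]


def gen_ontology(
    cfg: SimConfig, genes: list[GeneRecord], target_set: set[str]
) -> list[TermAnnotation]:
    """Overlapping GO/MP-style terms, a fraction enriched for targets.

    Term sizes are log-normal (clipped at 10); a ``term_overlap_fraction``
    of each term's genes is drawn from a shared hub pool to create
    inter-term overlap; enriched terms sample target genes with weight
    ``enrichment_odds``. Evidence codes are EXP with an IEA admixture.
    """
    rng = _rng(cfg, 9)
    gene_ids = np.array([g.gene_id for g in genes])
    is_target = np.isin(gene_ids, list(target_set))
    hub = rng.choice(gene_ids, size=max(10, len(gene_ids) // 8), replace=False)
    terms = []
    for t in range(cfg.n_terms):
        ontology = "GO" if t % 2 == 0 else "MP"
        size = max(10, int(rng.lognormal(np.log(cfg.term_size_median), cfg.term_size_sigma)))
        size = min(size, len(gene_ids))
        enriched = rng.random() < cfg.enriched_term_fraction
        w = np.where(is_target, cfg.enrichment_odds, 1.0) if enriched else np.ones(len(gene_ids))
        n_hub = int(round(cfg.term_overlap_fraction * size))
        chosen: set[str] = set()
        if n_hub:
            hub_mask = np.isin(gene_ids, hub)
            hub_genes, hw = gene_ids[hub_mask], w[hub_mask]
            chosen |= set(
                rng.choice(hub_genes, size=min(n_hub, hub_genes.size), replace=False, p=hw / hw.sum())
            )
        rest_pool = gene_ids[~np.isin(gene_ids, list(chosen))]
        rw = w[~np.isin(gene_ids, list(chosen))]
        k = size - len(chosen)
        if k > 0:
            chosen |= set(rng.choice(rest_pool, size=k, replace=False, p=rw / rw.sum()))
        evid = {
            g: ({"IEA"} if rng.random() < cfg.iea_fraction else {"EXP"}) for g in chosen
        }
        terms.append(
            TermAnnotation(
                term_id=f"{ontology}:{t:07d}", ontology=ontology,
                gene_ids=chosen, evidence_by_gene=evid,
            )
        )
    return terms


def simulate_all(cfg: SimConfig) -> SimData:
    """Generate every pipeline input from one config (one latent target set)."""
    genes = gen_genome(cfg)
    target_set = pick_target_set(cfg, genes)
    binding = gen_binding(cfg, genes, target_set)
    snps, ld = gen_gwas(cfg, genes, target_set)
    rare, cov = gen_rare_cohort(cfg, genes, target_set)
    dnm = gen_trios(cfg, genes, target_set)
    cnvs = gen_cnvs(cfg, genes, target_set)
    terms = gen_ontology(cfg, genes, target_set)
    truth = {
        "target_set_size": len(target_set),
        "planted_beta_common": cfg.planted_beta_common,
        "planted_or_rare": cfg.planted_or_rare,
        "planted_rr_dnm": cfg.planted_rr_dnm,
        "planted_or_cnv": cfg.planted_or_cnv,
    }
    return SimData(
        config=cfg, genes=genes, target_set=target_set, binding=binding,
        snps=snps, ld=ld, rare_variants=rare, sample_covariates=cov,
        dnm_counts=dnm, cnvs=cnvs, terms=terms, truth=truth,
    )
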