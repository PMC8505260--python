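"""End-to-end orchestration: bins x variant classes, partition and per-term runs.

``run_bins`` reproduces the binning analysis (competitive GWAS test, rare
LoF/NS burden, de novo rate ratios and CNV empirical p per
binding-confidence bin, Bonferroni-corrected within each family of bins).
``run_partition`` performs the pathway refinement and tests the three-way
split of targets against the functional superset (m = 3). ``run_per_term``
tests each refined term's target / non-target fractions and compares each
target fraction with the full target set (conditional test for common
variants, beta z-test for rare burden, two-sample rate ratio for de novo).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, cnv, denovo, pathways, rare_burden
from .common_variant import (
    compare_betas,
    competitive_set_test,
    conditional_set_test,
    assign_snps_to_genes,
    filter_maf,
    gene_statistic,
)
from .records import GeneLevelStat, GeneRecord, SnpRecord
from .simulate import SimConfig, SimData, simulate_all

__all__ = [
    "gene_stats_from_snps",
    "run_bins",
    "run_partition",
    "run_per_term",
    "run_all",
    "RunManifest",
]


def gene_stats_from_snps(
    snps: list[SnpRecord],
    genes: list[GeneRecord],
    ld_by_origin: dict[str, np.ndarray] | None = None,
    snp_origin: dict[str, str] | None = None,
    up_kb: float = 35.0,
    down_kb: float = 10.0,
    min_maf: float = 0.01,
) -> list[GeneLevelStat]:
    """MAF-filter, window-assign and combine SNP p-values per gene.

    Correlations are taken from ``ld_by_origin`` for SNP pairs sharing an
    origin gene and zero across origins (block structure); with no LD
    information an identity matrix is used.
    """
    kept = filter_maf(snps, min_maf)
    by_id = {s.snp_id: s for s in kept}
    assigned = assign_snps_to_genes(kept, genes, up_kb, down_kb)
    out = []
    for g in genes:
        ids = assigned.get(g.gene_id, [])
        if not ids:
            continue
        p = np.array([by_id[i].pvalue for i in ids])
        m = len(ids)
        R = np.eye(m)
        if ld_by_origin is not None and snp_origin is not None:
            for a in range(m):
                oa = snp_origin.get(ids[a])
                if oa is None or oa not in ld_by_origin:
                    continue
                block = ld_by_origin[oa]
                if block.shape[0] < 2:
                    continue
                # generator LD is compound-symmetric within the origin gene
                rho = block[0, 1]
                for b in range(a + 1, m):
                    if snp_origin.get(ids[b]) == oa:
                        R[a, b] = R[b, a] = rho
        out.append(gene_statistic(g.gene_id, p, R, gene_length=g.length))
    return out


def _covariate_matrix(stats_list: list[GeneLevelStat], background: set[str]) -> np.ndarray:
    scored = {s.gene_id: s for s in stats_list}
    bg = sorted(g for g in background if g in scored)
    return np.array([scored[g].covariates for g in bg], dtype=float)


def run_bins(
    data: SimData,
    bin_size: int = 400,
    tail_policy: str = "drop_tail",
    n_perm_cnv: int = 1000,
    seed: int = 0,
    include_cnv: bool = True,
) -> pd.DataFrame:
    """One row per (bin, variant class): effect, p, Bonferroni-adjusted p."""
    collapsed = binding.collapse_to_gene(data.binding)
    bins = binding.rank_and_bin(collapsed, bin_size, tail_policy)
    m = len(bins)

    snp_origin = {s.snp_id: s.snp_id.rsplit("_snp", 1)[0] for s in data.snps}
    stats_list = gene_stats_from_snps(data.snps, data.genes, data.ld, snp_origin)
    background = {s.gene_id for s in stats_list}
    covs = _covariate_matrix(stats_list, background)

    variants = rare_burden.filter_ultra_rare(data.rare_variants)
    rates_lof = {g.gene_id: g.mu_lof for g in data.genes}
    rates_ns = {g.gene_id: g.mu_ns for g in data.genes}
    all_gene_ids = {g.gene_id for g in data.genes}
    cnvs = cnv.filter_cnvs(data.cnvs)
    rng = np.random.default_rng(seed)

    rows = []
    for b in bins:
        name = b.name
        gset = b.gene_ids & background
        r = competitive_set_test(stats_list, gset, background, covs, name, bonferroni_m=m)
        rows.append((name, b.bin_index, "common", len(gset), r.beta, r.se, r.p_one_sided, r.p_adjusted))
        for klass in ("LoF", "NS"):
            br = rare_burden.set_burden_test(
                variants, data.sample_covariates, b.gene_ids, klass, name, bonferroni_m=m
            )
            rows.append((name, b.bin_index, f"rare_{klass}", len(b.gene_ids), br.beta, br.se, br.p, br.p_adjusted))
        for klass, rates, col in (("LoF", rates_lof, 0), ("NS", rates_ns, 1)):
            obs_in = sum(data.dnm_counts.get(g, (0, 0))[col] for g in b.gene_ids)
            rest = all_gene_ids - b.gene_ids
            obs_out = sum(data.dnm_counts.get(g, (0, 0))[col] for g in rest)
            e_in = denovo.expected_count(b.gene_ids, rates, data.config.n_trios)
            e_out = denovo.expected_count(rest, rates, data.config.n_trios)
            rr = denovo.rate_ratio_test(obs_in, e_in, obs_out, e_out, name, bonferroni_m=m)
            rows.append((name, b.bin_index, f"denovo_{klass}", len(b.gene_ids), rr.rate_ratio, np.nan, rr.p, rr.p_adjusted))
        if include_cnv and cnvs:
            cr = cnv.empirical_p(cnvs, data.genes, b.gene_ids, n_perm_cnv, rng, name)
            p_adj = min(1.0, m * cr.p_empirical)
            rows.append((name, b.bin_index, "cnv", len(b.gene_ids), cr.beta, np.nan, cr.p_empirical, p_adj))
    return pd.DataFrame(
        rows, columns=["set", "bin", "variant_class", "n_genes", "effect", "se", "p", "p_adj"]
    )


def _refine(data: SimData) -> tuple[list, set[str], set[str]]:
    """Shared pathway stage: returns (refined terms, targets, universe)."""
    universe = {g.gene_id for g in data.genes if g.brain_expressed}
    targets = data.target_set & universe
    filtered = pathways.filter_annotations(data.terms, universe)
    survivors = []
    for ontology in ("GO", "MP"):
        terms_o = [t for t in filtered if t.ontology == ontology]
        if not terms_o:
            continue
        results = [
            pathways.fisher_overrep(t.gene_ids, targets, universe, t.term_id) for t in terms_o
        ]
        picked = pathways.bonferroni_select(results, m=len(terms_o))
        ids = {r.term_id for r in picked}
        survivors.extend(t for t in terms_o if t.term_id in ids)
    refined = pathways.refine_terms(survivors, targets, universe) if survivors else []
    return refined, targets, universe


def run_partition(
    data: SimData,
    n_perm_cnv: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, list]:
    """Three-way partition tests (terms-only / overlap / targets-only), m = 3.

    Common-variant tests use a brain-expressed background so association
    attributable to brain expression alone is controlled; rare and de novo
    tests compare against brain-expressed genes outside the tested block.
    """
    refined, targets, universe = _refine(data)
    if not refined:
        return pd.DataFrame(), []
    part = pathways.build_partition(refined, targets, universe)
    blocks = {
        "terms_only": part.terms_only,
        "overlap": part.overlap,
        "targets_only": part.targets_only,
    }
    m = 3

    snp_origin = {s.snp_id: s.snp_id.rsplit("_snp", 1)[0] for s in data.snps}
    stats_list = gene_stats_from_snps(data.snps, data.genes, data.ld, snp_origin)
    background = {s.gene_id for s in stats_list} & universe
    covs = _covariate_matrix(stats_list, background)
    variants = rare_burden.filter_ultra_rare(data.rare_variants)
    rates = {"LoF": {g.gene_id: g.mu_lof for g in data.genes},
             "NS": {g.gene_id: g.mu_ns for g in data.genes}}

    rows = []
    for name, gset in blocks.items():
        if not gset:
            rows.append((name, 0, "common", np.nan, np.nan, 1.0, 1.0, "empty"))
            continue
        r = competitive_set_test(stats_list, gset & background, background, covs, name, bonferroni_m=m)
        rows.append((name, len(gset), "common", r.beta, r.se, r.p_one_sided, r.p_adjusted, ""))
        for klass in ("LoF", "NS"):
            br = rare_burden.set_burden_test(
                variants, data.sample_covariates, gset, klass, name, bonferroni_m=m
            )
            rows.append((name, len(gset), f"rare_{klass}", br.beta, br.se, br.p, br.p_adjusted, ""))
            col = 0 if klass == "LoF" else 1
            rest = universe - gset
            obs_in = sum(data.dnm_counts.get(g, (0, 0))[col] for g in gset)
            obs_out = sum(data.dnm_counts.get(g, (0, 0))[col] for g in rest)
            e_in = denovo.expected_count(gset, rates[klass], data.config.n_trios)
            e_out = denovo.expected_count(rest, rates[klass], data.config.n_trios)
            rr = denovo.rate_ratio_test(obs_in, e_in, obs_out, e_out, name, bonferroni_m=m)
            rows.append((name, len(gset), f"denovo_{klass}", rr.rate_ratio, np.nan, rr.p, rr.p_adjusted, ""))
    df = pd.DataFrame(
        rows, columns=["block", "n_genes", "variant_class", "effect", "se", "p", "p_adj", "flags"]
    )
    return df, refined


def run_per_term(data: SimData, refined: list | None = None) -> pd.DataFrame:
    """Per refined term: target/non-target association and subset-vs-whole tests."""
    if refined is None:
        refined, targets, universe = _refine(data)
    else:
        universe = {g.gene_id for g in data.genes if g.brain_expressed}
        targets = data.target_set & universe
    if not refined:
        return pd.DataFrame()
    pairs = pathways.per_term_partition_tests(refined, targets)
    m = len(refined)

    snp_origin = {s.snp_id: s.snp_id.rsplit("_snp", 1)[0] for s in data.snps}
    stats_list = gene_stats_from_snps(data.snps, data.genes, data.ld, snp_origin)
    background = {s.gene_id for s in stats_list}
    covs = _covariate_matrix(stats_list, background)
    variants = rare_burden.filter_ultra_rare(data.rare_variants)
    rates_lof = {g.gene_id: g.mu_lof for g in data.genes}

    rows = []
    for term_id, in_t, out_t in pairs:
        for label, gset in (("targets", in_t), ("non_targets", out_t)):
            if not gset:
                rows.append((term_id, label, 0, np.nan, np.nan, 1.0, 1.0, np.nan, np.nan, "empty"))
                continue
            r = competitive_set_test(
                stats_list, gset & background, background, covs,
                f"{term_id}_{label}", bonferroni_m=m,
            )
            extra = (np.nan, np.nan)
            flags = ",".join(r.flags)
            if label == "targets":
                # does the term's target fraction beat targets as a whole?
                cond = conditional_set_test(
                    stats_list, gset & background, [targets & background],
                    background, covs, f"{term_id}_cond", bonferroni_m=m,
                )
                br_sub = rare_burden.set_burden_test(
                    variants, data.sample_covariates, gset, "LoF", term_id, bonferroni_m=m
                )
                br_rest = rare_burden.set_burden_test(
                    variants, data.sample_covariates, targets - gset, "LoF", term_id, bonferroni_m=m
                )
                if (
                    np.isfinite(br_sub.beta) and np.isfinite(br_rest.beta)
                    and br_sub.se > 0 and br_rest.se > 0
                ):
                    _, p_beta = compare_betas(br_sub.beta, br_sub.se, br_rest.beta, br_rest.se)
                else:
                    p_beta = np.nan
                col = 0
                obs_in = sum(data.dnm_counts.get(g, (0, 0))[col] for g in gset)
                rest = targets - gset
                obs_out = sum(data.dnm_counts.get(g, (0, 0))[col] for g in rest)
                e_in = denovo.expected_count(gset, rates_lof, data.config.n_trios)
                e_out = denovo.expected_count(rest, rates_lof, data.config.n_trios)
                if e_in > 0 and e_out > 0:
                    rr = denovo.rate_ratio_test(obs_in, e_in, obs_out, e_out, term_id)
                    extra = (cond.p_one_sided, rr.p)
                else:
                    extra = (cond.p_one_sided, np.nan)
                rows.append(
                    (term_id, label, len(gset), r.beta, r.se, r.p_one_sided, r.p_adjusted,
                     extra[0], p_beta, flags)
                )
            else:
                rows.append(
                    (term_id, label, len(gset), r.beta, r.se, r.p_one_sided, r.p_adjusted,
                     np.nan, np.nan, flags)
                )
    return pd.DataFrame(
        rows,
        columns=["term", "fraction", "n_genes", "beta", "se", "p", "p_adj",
                 "p_conditional_on_targets", "p_beta_vs_other_targets", "flags"],
    )


@dataclasses.dataclass
class RunManifest:
    """Reproducibility record: config, seeds and output checksums."""

    config: dict
    seed: int
    outputs: dict[str, str]
    version: str = "0.1.0"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    cfg: SimConfig,
    out_dir: str | Path,
    bin_size: int = 400,
    tail_policy: str = "drop_tail",
    n_perm_cnv: int = 200,
    include_cnv: bool = True,
) -> RunManifest:
    """Simulate, run every stage and write TSV outputs plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = simulate_all(cfg)
    bins_df = run_bins(
        data, bin_size, tail_policy, n_perm_cnv, seed=cfg.seed, include_cnv=include_cnv
    )
    part_df, refined = run_partition(data)
    term_df = run_per_term(data, refined)
    outputs = {}
    for name, df in (("bins", bins_df), ("partition", part_df), ("per_term", term_df)):
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        outputs[name] = _sha256(p)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed, outputs=outputs)
    manifest.write(out / "manifest.json")
    return manifest
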