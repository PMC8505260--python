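"""CNV gene-set association with a permutation empirical null.

CNV calls are filtered to >= 100 kb and >= 15 probes, then case-control
status is regressed (logistic) on the number of set genes each CNV
overlaps, with CNV size, total genes per CNV, study and chip as
covariates; the set coefficient is tested one-sided. Because large CNVs
hit many genes at once, the model p-value is inflation-prone, so an
empirical p-value is computed against random gene sets of the same size
drawn from brain-expressed genes: the fraction of random sets whose model
p is as small or smaller (add-one rule, so the floor is 1/(n_perm+1)).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from ._glm import fit_logistic
from .records import CnvRecord, CnvSetResult, GeneRecord

logger = logging.getLogger(__name__)

__all__ = [
    "filter_cnvs",
    "overlap_counts",
    "cnv_set_test",
    "empirical_p",
    "stratify_by_type",
]

MIN_LENGTH_BP = 100_000
MIN_PROBES = 15


def filter_cnvs(
    cnvs: list[CnvRecord],
    min_length_bp: int = MIN_LENGTH_BP,
    min_probes: int = MIN_PROBES,
) -> list[CnvRecord]:
    """Keep CNVs of at least ``min_length_bp`` covered by >= ``min_probes``."""
    return [c for c in cnvs if c.length_bp >= min_length_bp and c.n_probes >= min_probes]


def stratify_by_type(cnvs: list[CnvRecord], cnv_type: str) -> list[CnvRecord]:
    """Subset CNVs by type ("deletion" or "duplication")."""
    if cnv_type not in ("deletion", "duplication"):
        raise ValueError("cnv_type must be 'deletion' or 'duplication'")
    sub = [c for c in cnvs if c.cnv_type == cnv_type]
    if not sub:
        logger.warning("no CNVs of type %s", cnv_type)
    return sub


def overlap_counts(
    cnvs: list[CnvRecord],
    genes: list[GeneRecord],
    set_genes: set[str],
) -> list[tuple[int, int]]:
    """Per CNV, count overlapped set genes and overlapped genes in total.

    A gene is overlapped when its interval shares at least one base with
    the CNV on the same chromosome (1-based inclusive coordinates).
    """
    idx = _overlap_index(cnvs, genes)
    member = np.array([g.gene_id in set_genes for g in genes], dtype=bool)
    out = []
    for gi in idx:
        out.append((int(member[gi].sum()), int(gi.size)))
    return out


def _overlap_index(cnvs: list[CnvRecord], genes: list[GeneRecord]) -> list[np.ndarray]:
    """For each CNV, indices (into ``genes``) of genes it overlaps."""
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        ids = np.array([i for i, g in enumerate(genes) if g.chrom == chrom])
        starts = np.array([genes[i].start for i in ids])
        ends = np.array([genes[i].end for i in ids])
        by_chrom[chrom] = (ids, starts, ends)
    out = []
    empty = np.array([], dtype=int)
    for c in cnvs:
        if c.chrom not in by_chrom:
            out.append(empty)
            continue
        ids, starts, ends = by_chrom[c.chrom]
        hit = (starts <= c.end) & (ends >= c.start)
        out.append(ids[hit])
    return out


def _design(cnvs: list[CnvRecord], n_total: np.ndarray) -> np.ndarray:
    """Covariate block: intercept, CNV size (Mb), genes/CNV, study & chip dummies."""
    n = len(cnvs)
    length_mb = np.array([c.length_bp for c in cnvs], dtype=float) / 1e6
    cols = [np.ones(n), length_mb, n_total.astype(float)]
    for attr in ("study", "chip"):
        levels = sorted({getattr(c, attr) for c in cnvs})
        for lev in levels[1:]:
            cols.append(np.array([1.0 if getattr(c, attr) == lev else 0.0 for c in cnvs]))
    return np.column_stack(cols)


def _fit_one_sided(y: np.ndarray, X: np.ndarray, focal_col: int) -> tuple[float, float]:
    """Logistic fit; (beta, one-sided p) for the focal column (NaN, 1 if dropped)."""
    fit = fit_logistic(y, X, firth=False)
    b, se = fit.beta[focal_col], fit.se[focal_col]
    if np.isnan(b) or not np.isfinite(se) or se == 0:
        return float("nan"), 1.0
    return float(b), float(stats.norm.sf(b / se))


def cnv_set_test(
    cnvs: list[CnvRecord],
    counts: list[tuple[int, int]],
    set_name: str = "set",
) -> tuple[float, float]:
    """Logistic regression of CNV status on set-gene overlap count.

    ``counts`` is the output of :func:`overlap_counts` for these CNVs.
    Returns ``(beta, one-sided p)``; a constant overlap count is perfectly
    collinear with the intercept, yielding ``(nan, 1.0)``.
    """
    if len(counts) != len(cnvs):
        raise ValueError("counts must align with cnvs")
    y = np.array([c.status for c in cnvs], dtype=float)
    n_set = np.array([c[0] for c in counts], dtype=float)
    n_total = np.array([c[1] for c in counts], dtype=float)
    if n_set.max(initial=0.0) == n_set.min(initial=0.0):
        logger.warning("set-overlap count constant across CNVs: degenerate for %s", set_name)
        return float("nan"), 1.0
    Xcov = _design(cnvs, n_total)
    X = np.column_stack([Xcov[:, :1], n_set, Xcov[:, 1:]])
    return _fit_one_sided(y, X, focal_col=1)


def empirical_p(
    cnvs: list[CnvRecord],
    genes: list[GeneRecord],
    set_genes: set[str],
    n_perm: int,
    seed: int | np.random.Generator,
    set_name: str = "set",
) -> CnvSetResult:
    """CNV set association with an empirical p from size-matched random sets.

    Draws ``n_perm`` uniform random gene sets of size ``|set_genes|`` from
    the brain-expressed genes and re-runs the logistic model for each;
    p_empirical = (1 + #{draws with p_model <= observed}) / (n_perm + 1).
    Degenerate draws (constant overlap) count as non-exceeding and are
    tallied. A seed (or Generator) is mandatory for reproducibility.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    universe = [g.gene_id for g in genes if g.brain_expressed]
    if not set(universe) & set_genes:
        raise ValueError("set shares no genes with the brain-expressed universe")
    k = len(set_genes)
    if k > len(universe):
        raise ValueError("set larger than the brain-expressed universe")

    idx = _overlap_index(cnvs, genes)
    gene_ids = [g.gene_id for g in genes]
    n_total = np.array([gi.size for gi in idx], dtype=float)
    y = np.array([c.status for c in cnvs], dtype=float)
    Xcov = _design(cnvs, n_total)
    # CSR-style incidence for fast per-set overlap counting
    flat = np.concatenate(idx) if idx else np.array([], dtype=int)
    offsets = np.cumsum([0] + [gi.size for gi in idx])

    def set_counts(member: np.ndarray) -> np.ndarray:
        if flat.size == 0:
            return np.zeros(len(cnvs))
        csum = np.concatenate([[0], np.cumsum(member[flat])])
        return (csum[offsets[1:]] - csum[offsets[:-1]]).astype(float)

    def run(member: np.ndarray) -> tuple[float, float]:
        n_set = set_counts(member)
        if n_set.max(initial=0.0) == n_set.min(initial=0.0):
            return float("nan"), 1.0
        X = np.column_stack([Xcov[:, :1], n_set, Xcov[:, 1:]])
        return _fit_one_sided(y, X, focal_col=1)

    member_obs = np.array([gid in set_genes for gid in gene_ids], dtype=bool)
    beta_obs, p_obs = run(member_obs)

    universe_idx = np.array([i for i, g in enumerate(genes) if g.brain_expressed])
    n_exceed = 0
    n_degenerate = 0
    for _ in range(n_perm):
        draw = rng.choice(universe_idx, size=k, replace=False)
        member = np.zeros(len(genes), dtype=bool)
        member[draw] = True
        beta_perm, p_perm = run(member)
        if np.isnan(beta_perm):
            n_degenerate += 1
            continue
        if p_perm <= p_obs:
            n_exceed += 1
    p_emp = (1 + n_exceed) / (n_perm + 1)
    flags = ("degenerate_observed",) if np.isnan(beta_obs) else ()
    if n_degenerate:
        logger.info("%d degenerate permutation draws counted as non-exceeding", n_degenerate)
    return CnvSetResult(
        set_name, beta_obs, p_obs, p_emp, n_perm, n_degenerate, flags
    )
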