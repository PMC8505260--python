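"""Ontology-term overrepresentation, greedy refinement and partitioning.

Target-gene overrepresentation in GO / Mammalian Phenotype terms is
assessed with one-sided Fisher's exact tests against the expressed-gene
universe, after removing low-provenance evidence codes (NAS, IEA, RCA)
and terms with fewer than 10 member genes. Bonferroni-surviving terms are
then refined: the term with the highest odds ratio is accepted, its genes
are removed from every remaining term, the rest are re-tested, and terms
whose unadjusted p rises above the drop threshold are discarded; this
repeats until all terms are accepted or dropped. The accepted terms'
union forms a functional superset whose intersection with the target set
yields the three-way partition (terms-only / overlap / targets-only) used
by the association modules.
"""

from __future__ import annotations

import logging

from scipy import stats

from .records import OverrepResult, Partition, TermAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "filter_annotations",
    "fisher_overrep",
    "bonferroni_select",
    "refine_terms",
    "build_partition",
    "per_term_partition_tests",
    "DEFAULT_EXCLUDED_CODES",
]

DEFAULT_EXCLUDED_CODES = frozenset({"NAS", "IEA", "RCA"})


def filter_annotations(
    terms: list[TermAnnotation],
    universe: set[str],
    excluded_codes: frozenset[str] = DEFAULT_EXCLUDED_CODES,
    min_size: int = 10,
) -> list[TermAnnotation]:
    """Apply evidence-code, expression-universe and term-size filters.

    A gene stays in a term only if it has at least one evidence code
    outside ``excluded_codes`` (genes with no recorded evidence are kept:
    absence of a code is not an excluded code) and is in the expressed
    ``universe``; terms left with fewer than ``min_size`` genes are dropped.
    """
    out = []
    for t in terms:
        kept = set()
        for g in t.gene_ids:
            codes = t.evidence_by_gene.get(g)
            if codes is not None and codes and codes <= excluded_codes:
                continue
            if g in universe:
                kept.add(g)
        if len(kept) >= min_size:
            out.append(
                TermAnnotation(
                    term_id=t.term_id,
                    ontology=t.ontology,
                    gene_ids=kept,
                    evidence_by_gene={g: set(t.evidence_by_gene.get(g, set())) for g in kept},
                )
            )
    return out


def fisher_overrep(
    term_genes: set[str],
    target_genes: set[str],
    universe: set[str],
    term_id: str = "term",
) -> OverrepResult:
    """One-sided Fisher's exact test of target enrichment in a term.

    The 2x2 table over the universe is (a, b; c, d) with a = targets in
    the term and b = non-targets in the term; the contrast group is all
    remaining universe genes. p is the hypergeometric upper tail
    P(X >= a); the odds ratio is the sample (a*d)/(b*c), with a +0.5
    Haldane correction applied to every cell iff any cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    if not term_genes <= universe or not target_genes <= universe:
        raise ValueError("term and target genes must lie within the universe")
    a = len(term_genes & target_genes)
    b = len(term_genes) - a
    c = len(target_genes) - a
    d = len(universe) - a - b - c
    # upper tail of Hypergeometric(N=|universe|, K=|targets|, n=|term|)
    p = float(stats.hypergeom.sf(a - 1, len(universe), a + c, a + b))
    haldane = min(a, b, c, d) == 0
    if haldane:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return OverrepResult(
        term_id=term_id, a=a, b=b, c=c, d=d, odds_ratio=float(odds),
        p=min(p, 1.0), haldane=haldane,
    )


def bonferroni_select(
    results: list[OverrepResult], m: int, alpha: float = 0.01
) -> list[OverrepResult]:
    """Terms surviving Bonferroni control: m * p strictly below alpha.

    ``m`` is the family size for the ontology (at least the number of
    tested terms); p_adjusted is stored as min(1, m * p).
    """
    if m < len(results):
        raise ValueError("Bonferroni m must be >= number of tested terms")
    out = []
    for r in results:
        r.p_adjusted = min(1.0, m * r.p)
        if m * r.p < alpha:
            out.append(r)
    return out


def refine_terms(
    surviving: list[TermAnnotation],
    target_genes: set[str],
    universe: set[str],
    drop_alpha: float = 0.01,
) -> list[TermAnnotation]:
    """Greedy refinement of overlapping overrepresented terms.

    Iteratively: (1) re-test every remaining term on its genes minus the
    cumulative removal set R and pick the one with the highest current
    odds ratio (ties broken by smaller p, then term id); accept it and add
    its current genes to R; (2) drop any remaining term whose re-test p
    exceeds ``drop_alpha``. Accepted terms are frozen — removal applies
    only to subsequent re-tests of the others. Returns accepted terms with
    their original (unreduced) gene sets.
    """
    remaining = {t.term_id: t for t in surviving}
    originals = dict(remaining)
    removed: set[str] = set()
    accepted: list[str] = []

    while remaining:
        tested = {}
        for tid, t in remaining.items():
            genes = t.gene_ids - removed
            tested[tid] = fisher_overrep(genes, target_genes, universe, term_id=tid)
        # drop terms no longer significant on current genes
        drop = [tid for tid, r in tested.items() if r.p > drop_alpha]
        for tid in drop:
            del remaining[tid]
        if not remaining:
            break
        best = min(
            remaining,
            key=lambda tid: (-tested[tid].odds_ratio, tested[tid].p, tid),
        )
        accepted.append(best)
        removed |= remaining[best].gene_ids
        del remaining[best]
    return [originals[tid] for tid in accepted]


def build_partition(
    refined_terms: list[TermAnnotation],
    target_genes: set[str],
    brain_expressed: set[str],
) -> Partition:
    """Split targets against the refined-term superset, within expression.

    The superset is the union of refined-term genes restricted to
    brain-expressed genes; targets are likewise restricted. Blocks:
    overlap (targets in the superset), terms_only (superset genes not
    targeted), targets_only (expressed targets outside every term).
    """
    if not refined_terms:
        raise ValueError("no refined terms to build a partition from")
    superset: set[str] = set()
    for t in refined_terms:
        superset |= t.gene_ids
    superset &= brain_expressed
    targets = target_genes & brain_expressed
    overlap = superset & targets
    if not overlap:
        logger.warning("targets share no genes with the functional superset")
    return Partition(
        overlap=overlap,
        terms_only=superset - targets,
        targets_only=targets - superset,
    )


def per_term_partition_tests(
    refined_terms: list[TermAnnotation],
    target_genes: set[str],
) -> list[tuple[str, set[str], set[str]]]:
    """Per refined term, the (targets-in-term, non-targets-in-term) pair.

    Downstream association tests run each pair against the full
    protein-coding background with Bonferroni m = number of refined terms;
    a term composed entirely of targets yields an empty non-target set,
    which is emitted as-is (the association module flags it).
    """
    out = []
    for t in refined_terms:
        in_t = t.gene_ids & target_genes
        out_t = t.gene_ids - target_genes
        if not out_t:
            logger.warning("term %s has no non-target genes", t.term_id)
        out.append((t.term_id, in_t, out_t))
    return out
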