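"""Ranking and binning of genes by CLIP binding confidence.

CLIP experiments report binding evidence at peak level, per replicate or
isoform. This module collapses those records to one confidence statistic
per gene (intersection semantics across replicates/isoforms), maps gene
identifiers through a homolog table requiring a unique protein-coding
target, and partitions the ranked genes into fixed-size bins for
downstream gene-set association.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict

from .records import BindingRecord, Direction, GeneBin, HomologPair

logger = logging.getLogger(__name__)

__all__ = ["collapse_to_gene", "map_homologs", "rank_and_bin"]


def _best(stats: list[float], direction: Direction) -> float:
    return min(stats) if direction == Direction.LOWER_IS_BETTER else max(stats)


def _check_single_source_direction(records: list[BindingRecord]) -> tuple[str, Direction]:
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise ValueError(f"records span multiple sources: {sorted(sources)}")
    directions = {r.direction for r in records}
    if len(directions) > 1:
        raise ValueError("mixed ranking directions within one source")
    return (sources.pop() if sources else ""), directions.pop()


def collapse_to_gene(
    records: list[BindingRecord],
    rule: str = "min_stat_across_replicates",
) -> list[BindingRecord]:
    """Collapse peak/replicate-level binding records to one record per gene.

    Both rules first take the best peak statistic per (gene, replicate)
    group, then combine across groups by taking the best of the per-group
    bests. Only genes observed in *every* group are kept (the intersection
    of replicates/isoforms).

    Parameters
    ----------
    records
        Peak- or gene-level binding records from a single source, all with
        the same ranking direction.
    rule
        ``"min_stat_across_replicates"`` or ``"best_peak_then_min_across_groups"``.
        The two rules share the reduce structure; the second name documents
        the peak-score-then-p-value convention of isoform-level data.

    Returns
    -------
    list of BindingRecord, one per gene present in all groups, carrying the
    collapsed statistic. Empty intersection yields an empty list with a
    warning.
    """
    if rule not in ("min_stat_across_replicates", "best_peak_then_min_across_groups"):
        raise ValueError(f"unknown collapse rule: {rule!r}")
    if not records:
        return []
    source, direction = _check_single_source_direction(records)

    by_gene_rep: dict[str, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    for r in records:
        by_gene_rep[r.gene_id][r.replicate_id].append(r.stat)

    all_groups = {r.replicate_id for r in records}
    out = []
    for gene in sorted(by_gene_rep):
        groups = by_gene_rep[gene]
        if set(groups) != all_groups:
            continue  # intersection semantics: must appear in every group
        per_group_best = [_best(stats, direction) for stats in groups.values()]
        out.append(
            BindingRecord(
                gene_id=gene,
                stat=_best(per_group_best, direction),
                direction=direction,
                replicate_id="collapsed",
                source=source,
            )
        )
    if not out:
        warnings.warn("collapse_to_gene: empty replicate intersection", stacklevel=2)
    return out


def map_homologs(
    records: list[BindingRecord],
    pairs: list[HomologPair],
) -> tuple[list[BindingRecord], int]:
    """Rename genes through a homolog table, keeping unique coding mappings.

    A gene is mapped only when it has exactly one protein-coding homolog;
    genes with zero or several candidate targets are excluded and counted.
    When two source genes map to the same target, the record with the
    better confidence statistic is retained and a collision is logged.

    Returns ``(mapped_records, n_excluded)`` where ``n_excluded`` counts
    input genes without a unique protein-coding homolog (collision losers
    are not part of this count; they mapped, but lost the target).
    """
    targets: dict[str, set[str]] = defaultdict(set)
    for p in pairs:
        if p.is_protein_coding:
            targets[p.source_gene_id].add(p.target_gene_id)

    n_excluded = 0
    mapped: dict[str, BindingRecord] = {}
    for r in records:
        cand = targets.get(r.gene_id, set())
        if len(cand) != 1:
            n_excluded += 1
            continue
        target = next(iter(cand))
        new = BindingRecord(target, r.stat, r.direction, r.replicate_id, r.source)
        prev = mapped.get(target)
        if prev is None:
            mapped[target] = new
        else:
            logger.warning("homolog collision on target %s", target)
            better = (
                new if _best([new.stat, prev.stat], new.direction) == new.stat else prev
            )
            mapped[target] = better
    return list(mapped.values()), n_excluded


def rank_and_bin(
    records: list[BindingRecord],
    bin_size: int,
    tail_policy: str = "drop_tail",
    source: str | None = None,
) -> list[GeneBin]:
    """Rank genes best-first by binding confidence and cut into bins.

    Ranking follows each record's direction (ascending for p-values,
    descending for scores); ties break lexicographically on gene id so the
    binning is a pure function of the record set. Under ``drop_tail`` a
    final partial block is discarded; under ``keep_tail`` it becomes a
    smaller final bin.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if tail_policy not in ("drop_tail", "keep_tail"):
        raise ValueError(f"unknown tail_policy: {tail_policy!r}")
    if not records:
        return []
    src, direction = _check_single_source_direction(records)
    if source is None:
        source = src
    if len({r.gene_id for r in records}) != len(records):
        raise ValueError("rank_and_bin requires one record per gene")

    sign = 1.0 if direction == Direction.LOWER_IS_BETTER else -1.0
    ranked = sorted(records, key=lambda r: (sign * r.stat, r.gene_id))

    if len(ranked) < bin_size:
        warnings.warn(
            f"fewer genes ({len(ranked)}) than bin_size ({bin_size})", stacklevel=2
        )
    bins: list[GeneBin] = []
    for i in range(0, len(ranked), bin_size):
        block = ranked[i : i + bin_size]
        if len(block) < bin_size and tail_policy == "drop_tail":
            break
        bins.append(
            GeneBin(bin_index=i // bin_size + 1, gene_ids={r.gene_id for r in block}, source=source)
        )
    return bins
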