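"""Readers and writers for the pipeline's tabular interchange formats.

GMT gene-set files, TSV tables for binding statistics, homolog pairs,
GWAS summary statistics, gene coordinates, rare-variant and CNV tables,
and GAF-like ontology annotations. All tabular work goes through pandas.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .records import (
    BindingRecord,
    CnvRecord,
    Direction,
    GeneBin,
    GeneRecord,
    HomologPair,
    RareVariantRecord,
    SnpRecord,
    TermAnnotation,
)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_binding_tsv",
    "read_homologs_tsv",
    "read_sumstats",
    "read_genes_tsv",
    "write_genes_tsv",
    "read_variants_tsv",
    "read_cnvs_tsv",
    "read_annotations_tsv",
    "write_bin_manifest",
]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: one set per line, name TAB description TAB genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)]) for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def bins_to_sets(bins: list[GeneBin]) -> dict[str, set[str]]:
    return {b.name: set(b.gene_ids) for b in bins}


def write_bin_manifest(bins: list[GeneBin], ranked_ids: list[str], path: str | Path) -> None:
    """TSV of gene_id, rank (1 = best) and bin index (0 = dropped tail)."""
    bin_of = {}
    for b in bins:
        for g in b.gene_ids:
            bin_of[g] = b.bin_index
    df = pd.DataFrame(
        {
            "gene_id": ranked_ids,
            "rank": range(1, len(ranked_ids) + 1),
            "bin": [bin_of.get(g, 0) for g in ranked_ids],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_binding_tsv(path: str | Path, source: str = "", direction: str = "lower_is_better") -> list[BindingRecord]:
    """Columns: gene_id, stat, replicate_id."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "replicate_id": str})
    return [
        BindingRecord(r.gene_id, float(r.stat), Direction(direction), str(r.replicate_id), source)
        for r in df.itertuples()
    ]


def read_homologs_tsv(path: str | Path) -> list[HomologPair]:
    """Columns: source_id, target_id, biotype (protein_coding or other)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        HomologPair(r.source_id, r.target_id, r.biotype == "protein_coding")
        for r in df.itertuples()
    ]


def read_sumstats(path: str | Path) -> list[SnpRecord]:
    """Whitespace/TSV summary statistics with columns SNP, CHR, BP, P, MAF."""
    df = pd.read_csv(path, sep=None, engine="python", dtype={"SNP": str, "CHR": str})
    return [
        SnpRecord(r.SNP, str(r.CHR), int(r.BP), float(r.P), float(getattr(r, "MAF", 0.5)))
        for r in df.itertuples()
    ]


_GENE_COLS = [
    "gene_id", "chrom", "start", "end", "strand",
    "brain_expressed", "mu_lof", "mu_ns", "mu_syn",
]


def read_genes_tsv(path: str | Path) -> list[GeneRecord]:
    """BED-like gene table (1-based inclusive start/end; documented columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [
        GeneRecord(
            r.gene_id, str(r.chrom), int(r.start), int(r.end), str(r.strand),
            bool(r.brain_expressed), float(r.mu_lof), float(r.mu_ns), float(r.mu_syn),
        )
        for r in df.itertuples()
    ]


def write_genes_tsv(genes: list[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [[getattr(g, c) for c in _GENE_COLS] for g in genes], columns=_GENE_COLS
    ).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path: str | Path) -> list[RareVariantRecord]:
    """Columns: sample_id, gene_id, consequence, ac_cohort, ac_external."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "gene_id": str})
    return [
        RareVariantRecord(
            r.sample_id, r.gene_id, str(r.consequence), int(r.ac_cohort), int(r.ac_external)
        )
        for r in df.itertuples()
    ]


def read_cnvs_tsv(path: str | Path) -> list[CnvRecord]:
    """Columns: sample, status, chr, start, end, type, probes, study, chip."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chr": str})
    return [
        CnvRecord(
            r.sample, int(r.status), str(r.chr), int(r.start), int(r.end),
            str(r.type), int(r.probes), str(r.study), str(r.chip),
        )
        for r in df.itertuples()
    ]


def read_annotations_tsv(path: str | Path) -> list[TermAnnotation]:
    """GAF-like TSV with columns gene_id, term_id, ontology, evidence."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    terms: dict[str, TermAnnotation] = {}
    for r in df.itertuples():
        t = terms.setdefault(
            r.term_id, TermAnnotation(term_id=r.term_id, ontology=r.ontology)
        )
        t.gene_ids.add(r.gene_id)
        t.evidence_by_gene.setdefault(r.gene_id, set()).add(r.evidence)
    return list(terms.values())
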