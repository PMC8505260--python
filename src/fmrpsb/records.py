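"""Shared domain records for the gene-set association pipeline.

These dataclasses are the in-memory currency passed between modules:
genomic gene annotations, CLIP binding statistics, GWAS SNP records,
rare-variant and CNV tables, and result rows. Tabular I/O converts
between these and pandas DataFrames (see :mod:`fmrpsb.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class Direction(str, Enum):
    """Ranking direction of a binding-confidence statistic."""

    LOWER_IS_BETTER = "lower_is_better"   # p-value-like
    HIGHER_IS_BETTER = "higher_is_better"  # score-like


@dataclass(frozen=True)
class BindingRecord:
    """One binding-confidence observation for a gene.

    ``stat`` may be a binding-confidence p-value (lower is better) or a
    CLIP/PARalyzer peak score (higher is better); ``direction`` says which.
    ``replicate_id`` labels the replicate or isoform the observation came
    from, and ``source`` tags the originating dataset.
    """

    gene_id: str
    stat: float
    direction: Direction = Direction.LOWER_IS_BETTER
    replicate_id: str = ""
    source: str = ""


@dataclass(frozen=True)
class HomologPair:
    """A cross-species homolog mapping (source id -> target id)."""

    source_gene_id: str
    target_gene_id: str
    is_protein_coding: bool = True


@dataclass
class GeneBin:
    """A block of genes from a confidence ranking; index 1 = top confidence."""

    bin_index: int
    gene_ids: set[str]
    source: str = ""

    @property
    def name(self) -> str:
        return f"{self.source}_bin{self.bin_index}" if self.source else f"bin{self.bin_index}"


@dataclass(frozen=True)
class GeneRecord:
    """Gene annotation: coordinates, strand, expression flag, mutation rates.

    ``mu_lof``, ``mu_ns`` and ``mu_syn`` are per-generation, per-haploid
    de novo mutation rates for the loss-of-function, nonsynonymous and
    synonymous consequence classes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    brain_expressed: bool = True
    mu_lof: float = 0.0
    mu_ns: float = 0.0
    mu_syn: float = 0.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpRecord:
    """A GWAS summary-statistic row."""

    snp_id: str
    chrom: str
    pos: int
    pvalue: float
    maf: float = 0.5


@dataclass
class GeneLevelStat:
    """Gene-wide association statistic combined from SNP p-values.

    ``z`` is the probit transform of the gene p-value (larger = more
    associated). ``covariates`` carries the regression covariates used by
    the competitive test: log gene length, log SNP count and an LD proxy
    (mean inter-SNP r^2).
    """

    gene_id: str
    n_snps: int
    gene_p: float
    z: float
    covariates: tuple[float, ...] = ()


@dataclass
class SetTestResult:
    """Result of a competitive gene-set association test."""

    set_name: str
    n_genes_tested: int
    beta: float
    se: float
    p_one_sided: float
    p_adjusted: float = 1.0
    bonferroni_m: int = 1
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class RareVariantRecord:
    """One rare coding variant carried by one sample."""

    sample_id: str
    gene_id: str
    consequence: str
    cohort_allele_count: int = 1
    external_ref_allele_count: int = 0


@dataclass
class BurdenResult:
    """Firth logistic burden test result for one set and variant class."""

    set_name: str
    variant_class: str
    beta: float
    se: float
    p: float
    p_adjusted: float = 1.0
    bonferroni_m: int = 1
    flags: tuple[str, ...] = ()


@dataclass
class RateRatioResult:
    """De novo enrichment result (one- or two-sample Poisson)."""

    set_name: str
    observed: int
    expected: float
    rate_ratio: float
    p: float
    p_adjusted: float = 1.0
    bonferroni_m: int = 1
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class CnvRecord:
    """One copy-number variant call in one sample."""

    sample_id: str
    status: int
    chrom: str
    start: int
    end: int
    cnv_type: str = "deletion"
    n_probes: int = 0
    study: str = "study1"
    chip: str = "chip1"

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass
class CnvSetResult:
    """CNV gene-set association with a permutation empirical p-value."""

    set_name: str
    beta: float
    p_model: float
    p_empirical: float
    n_permutations: int
    n_degenerate_perms: int = 0
    flags: tuple[str, ...] = ()


@dataclass
class TermAnnotation:
    """An ontology term with member genes and per-gene evidence codes."""

    term_id: str
    ontology: str
    gene_ids: set[str] = field(default_factory=set)
    evidence_by_gene: dict[str, set[str]] = field(default_factory=dict)


@dataclass
class OverrepResult:
    """Fisher overrepresentation of targets in one ontology term.

    The 2x2 table is (a, b; c, d) = (target & term, nontarget & term;
    target \\ term, nontarget \\ term) over the expressed-gene universe.
    """

    term_id: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    p_adjusted: float = 1.0
    survived_refinement: bool = False
    haldane: bool = False


@dataclass
class Partition:
    """Three-way split of targets vs the functional-term superset."""

    overlap: set[str]
    terms_only: set[str]
    targets_only: set[str]
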