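"""Ultra-rare coding-variant burden tests with Firth logistic regression.

The analysis restricts to ultra-rare singletons: variants seen exactly
once across all sequenced case-control samples and absent from an
external reference cohort. Loss-of-function (LoF) covers nonsense,
essential splice site and frameshift consequences; nonsynonymous (NS)
covers LoF plus missense and inframe indels. Per sample, the number of
class-qualifying variants falling in the gene set is the burden
predictor; case-control status is regressed on it with Firth's
penalised-likelihood logistic regression (finite estimates under
separation, which sparse rare-variant counts readily produce), adjusting
for ancestry PCs, exome-wide synonymous burden, platform and sex.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._glm import fit_logistic
from .records import BurdenResult, RareVariantRecord

__all__ = [
    "filter_ultra_rare",
    "classify",
    "firth_logistic",
    "set_burden_test",
    "build_covariate_design",
    "synonymous_burden",
    "LOF_CONSEQUENCES",
    "NS_CONSEQUENCES",
]

LOF_CONSEQUENCES = frozenset({"nonsense", "essential_splice", "frameshift"})
NS_CONSEQUENCES = LOF_CONSEQUENCES | {"missense", "inframe_indel"}
_KNOWN = NS_CONSEQUENCES | {"synonymous", "other"}


def filter_ultra_rare(variants: list[RareVariantRecord]) -> list[RareVariantRecord]:
    """Keep variants observed once in the cohort and never in the reference.

    ``cohort_allele_count`` must be computed over the full case-control
    data before filtering.
    """
    return [
        v
        for v in variants
        if v.cohort_allele_count == 1 and v.external_ref_allele_count == 0
    ]


def classify(variants: list[RareVariantRecord]) -> dict[RareVariantRecord, dict[str, bool]]:
    """Flag each variant as LoF and/or NS from its consequence annotation.

    LoF implies NS; synonymous and unrecognised consequences are in
    neither class (unknown strings are treated as "other").
    """
    import warnings

    out = {}
    for v in variants:
        cons = v.consequence if v.consequence in _KNOWN else "other"
        if v.consequence not in _KNOWN:
            warnings.warn(f"unknown consequence {v.consequence!r} treated as other", stacklevel=2)
        is_lof = cons in LOF_CONSEQUENCES
        out[v] = {"is_LoF": is_lof, "is_NS": cons in NS_CONSEQUENCES}
    return out


def synonymous_burden(variants: list[RareVariantRecord]) -> dict[str, int]:
    """Exome-wide ultra-rare synonymous singleton count per sample.

    The covariate used by the burden model when a covariate table does not
    already carry one; apply :func:`filter_ultra_rare` first.
    """
    out: dict[str, int] = {}
    for v in variants:
        if v.consequence == "synonymous":
            out[v.sample_id] = out.get(v.sample_id, 0) + 1
    return out


def firth_logistic(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Firth penalised-likelihood logistic regression.

    Maximises the likelihood plus the Jeffreys penalty 0.5 log det I(beta)
    by Newton iteration with the hat-diagonal score adjustment. Returns
    ``(betas, ses, p_values)`` (Wald, two-sided); entries for columns
    dropped as collinear are NaN. Raises no error on separation — that is
    the point of the penalty.
    """
    fit = fit_logistic(y, X, firth=True)
    return fit.beta, fit.se, fit.p


def build_covariate_design(covariates: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Expand a sample covariate table into a numeric design block.

    Expects columns pc1..pc10 (any subset of pc*), synonymous_burden, and
    categorical platform / sex which are dummy-coded (first level dropped).
    Rows must be one per sample, ordered as the caller's sample order.
    """
    num_cols = [c for c in covariates.columns if c.startswith("pc")]
    if "synonymous_burden" in covariates.columns:
        num_cols.append("synonymous_burden")
    blocks = [covariates[num_cols].to_numpy(dtype=float)] if num_cols else []
    names = list(num_cols)
    for cat in ("platform", "sex"):
        if cat in covariates.columns:
            dummies = pd.get_dummies(covariates[cat], prefix=cat, drop_first=True)
            blocks.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    X = np.hstack(blocks) if blocks else np.empty((len(covariates), 0))
    return X, names


def set_burden_test(
    variants: list[RareVariantRecord],
    covariates: pd.DataFrame,
    set_genes: set[str],
    variant_class: str = "LoF",
    set_name: str = "set",
    bonferroni_m: int = 1,
    carrier_indicator: bool = False,
) -> BurdenResult:
    """Gene-set burden of ultra-rare variants via Firth logistic regression.

    ``variants`` must already be ultra-rare filtered. The predictor is the
    per-sample count of class-qualifying variants in set genes (or a 0/1
    carrier indicator with ``carrier_indicator=True``); status is regressed
    on the predictor plus the covariate design. Requires covariate columns
    ``sample_id`` and ``status``.
    """
    if variant_class not in ("LoF", "NS"):
        raise ValueError("variant_class must be 'LoF' or 'NS'")
    qual = LOF_CONSEQUENCES if variant_class == "LoF" else NS_CONSEQUENCES

    counts: dict[str, int] = {}
    for v in variants:
        if v.gene_id in set_genes and v.consequence in qual:
            counts[v.sample_id] = counts.get(v.sample_id, 0) + 1

    cov = covariates.reset_index(drop=True)
    y = cov["status"].to_numpy(dtype=float)
    x = cov["sample_id"].map(counts).fillna(0).to_numpy(dtype=float)
    if carrier_indicator:
        x = (x > 0).astype(float)
    if x.sum() == 0:
        return BurdenResult(
            set_name, variant_class, np.nan, np.nan, 1.0, 1.0, bonferroni_m,
            ("no_qualifying_variants",),
        )

    Xcov, _ = build_covariate_design(cov.drop(columns=["sample_id", "status"], errors="ignore"))
    X = np.column_stack([np.ones(len(cov)), x, Xcov])
    betas, ses, ps = firth_logistic(y, X)
    flags: tuple[str, ...] = ()
    if np.isnan(betas[1]):
        flags = ("focal_dropped",)
        return BurdenResult(set_name, variant_class, np.nan, np.nan, 1.0, 1.0, bonferroni_m, flags)
    p = float(ps[1])
    return BurdenResult(
        set_name, variant_class, float(betas[1]), float(ses[1]), p,
        min(1.0, bonferroni_m * p), bonferroni_m, flags,
    )
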