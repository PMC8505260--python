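"""De novo mutation enrichment from per-gene mutation rates.

Expected de novo counts in a gene set follow the mutation-rate framework:
E = 2 * n_trios * sum of per-gene per-haploid rates (the factor 2 covers
the two transmitted haploid genomes per trio). Enrichment within a set is
tested against that expectation with an exact one-sided Poisson test, and
against a background set with the exact two-sample Poisson rate-ratio
test, i.e. the conditional binomial: given n = o1 + o2 events, o1 is
Binomial(n, e1 / (e1 + e2)) under equal rates.
"""

from __future__ import annotations

import logging

from scipy import stats

from .records import RateRatioResult

logger = logging.getLogger(__name__)

__all__ = ["expected_count", "poisson_test", "rate_ratio_test"]


def expected_count(genes: set[str], rates: dict[str, float], n_trios: int) -> float:
    """Expected de novo count: 2 * n_trios * sum of per-gene haploid rates.

    Genes missing from the rate table are excluded (logged), mirroring the
    usual treatment of genes outside the mutation-rate model.
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    missing = [g for g in genes if g not in rates]
    if missing:
        logger.warning("%d genes lack a mutation rate and are excluded", len(missing))
    total = sum(rates[g] for g in genes if g in rates)
    if total < 0:
        raise ValueError("mutation rates must be non-negative")
    return 2.0 * n_trios * total


def poisson_test(observed: int, expected: float) -> float:
    """One-sided upper-tail exact Poisson p-value: P(X >= observed)."""
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if expected <= 0:
        if observed > 0:
            logger.warning("expected = 0 with observed > 0: degenerate p = 0")
            return 0.0
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def rate_ratio_test(
    o1: int,
    e1: float,
    o2: int,
    e2: float,
    set_name: str = "set",
    two_sided: bool = False,
    bonferroni_m: int = 1,
) -> RateRatioResult:
    """Exact two-sample Poisson rate-ratio test (conditional binomial).

    Compares the observed/expected rate in sample 1 (the gene set) to
    sample 2 (the background, which for subset-vs-remainder comparisons
    must exclude the subset's genes). One-sided enrichment p by default:
    P(Binomial(o1 + o2, e1/(e1+e2)) >= o1); two-sided doubles the smaller
    tail (capped at 1).
    """
    if e1 <= 0 or e2 <= 0:
        raise ValueError("expected counts must be positive")
    if o1 < 0 or o2 < 0:
        raise ValueError("observed counts must be non-negative")
    n = o1 + o2
    flags: tuple[str, ...] = ()
    if n == 0:
        return RateRatioResult(
            set_name, o1, e1, float("nan"), 1.0, 1.0, bonferroni_m, ("no_events",)
        )
    q = e1 / (e1 + e2)
    upper = float(stats.binom.sf(o1 - 1, n, q))
    if two_sided:
        lower = float(stats.binom.cdf(o1, n, q))
        p = min(1.0, 2.0 * min(upper, lower))
    else:
        p = upper
    r2 = o2 / e2
    if r2 == 0:
        rr = float("inf")
        flags = flags + ("background_rate_zero",)
    else:
        rr = (o1 / e1) / r2
    return RateRatioResult(
        set_name, o1, e1, rr, p, min(1.0, bonferroni_m * p), bonferroni_m, flags
    )
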