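"""Gene statistics from SNP p-values and the competitive set test."""

import numpy as np
import pytest
from scipy import stats

from fmrpsb.common_variant import (
    assign_snps_to_genes,
    compare_betas,
    competitive_set_test,
    conditional_set_test,
    filter_maf,
    gene_statistic,
)
from fmrpsb.records import GeneLevelStat, GeneRecord, SnpRecord


def snp(sid, pos, chrom="1", p=0.5, maf=0.2):
    return SnpRecord(sid, chrom, pos, p, maf)


class TestAssignment:
    def test_plus_strand_window_boundaries(self):
        gene = GeneRecord("g", "1", 1_000_000, 1_010_000, "+")
        snps = [
            snp("in_up", 966_000),       # within 35 kb upstream (boundary region)
            snp("at_up_edge", 965_000),  # exactly start - 35000
            snp("beyond_up", 964_999),
            snp("at_down_edge", 1_020_000),  # exactly end + 10000
            snp("beyond_down", 1_020_001),
        ]
        out = assign_snps_to_genes(snps, [gene])
        assert set(out["g"]) == {"in_up", "at_up_edge", "at_down_edge"}

    def test_minus_strand_mirrors_window(self):
        gene = GeneRecord("g", "1", 1_000_000, 1_010_000, "-")
        snps = [snp("up35_right", 1_045_000), snp("down10_left", 990_000), snp("far_left", 964_999)]
        out = assign_snps_to_genes(snps, [gene])
        assert set(out["g"]) == {"up35_right", "down10_left"}

    def test_chromosome_mismatch_excluded(self):
        gene = GeneRecord("g", "2", 100, 200)
        assert assign_snps_to_genes([snp("s", 150, chrom="1")], [gene])["g"] == []

    def test_negative_window_rejected(self):
        with pytest.raises(ValueError):
            assign_snps_to_genes([], [], up_kb=-1)

    def test_matches_bruteforce_interval_scan(self, rng):
        genes = [
            GeneRecord(f"g{i}", str(rng.integers(1, 3)), int(s), int(s) + int(rng.integers(1000, 50000)),
                       strand=str(rng.choice(["+", "-"])))
            for i, s in enumerate(rng.integers(50_000, 2_000_000, size=5))
        ]
        snps = [
            snp(f"s{j}", int(rng.integers(1, 2_100_000)), chrom=str(rng.integers(1, 3)))
            for j in range(100)
        ]
        out = assign_snps_to_genes(snps, genes)
        for g in genes:
            if g.strand == "+":
                lo, hi = g.start - 35_000, g.end + 10_000
            else:
                lo, hi = g.start - 10_000, g.end + 35_000
            expected = {s.snp_id for s in snps if s.chrom == g.chrom and lo <= s.pos <= hi}
            assert set(out[g.gene_id]) == expected

    def test_maf_filter(self):
        snps = [snp("a", 1, maf=0.01), snp("b", 2, maf=0.009), snp("c", 3, maf=0.4)]
        assert {s.snp_id for s in filter_maf(snps)} == {"a", "c"}


class TestGeneStatistic:
    def test_single_snp_reduces_to_snp_p(self):
        g = gene_statistic("g", np.array([0.05]))
        assert g.gene_p == pytest.approx(0.05, rel=1e-9)
        assert g.z == pytest.approx(1.6449, abs=1e-4)

    def test_identity_ld_is_chi2_2m(self):
        p = np.linspace(0.05, 0.9, 10)
        g = gene_statistic("g", p, np.eye(10))
        T = float((-2 * np.log(p)).sum())
        assert g.gene_p == pytest.approx(stats.chi2.sf(T, 20), rel=1e-10)
        assert g.n_snps == 10

    def test_correlated_null_matches_simulation(self, rng):
        """Moment-matched tail vs an empirical tail from correlated draws.

        The scaled-chi-square approximation is accurate to about a percent
        in absolute tail probability in the significance range and to a few
        percent in the bulk of the distribution.
        """
        m, rho = 5, 0.5
        R = np.full((m, m), rho)
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        z = rng.standard_normal((200_000, m)) @ L.T
        T_sim = (-2 * np.log(2 * stats.norm.sf(np.abs(z)))).sum(axis=1)
        for target, tol in ((0.5, 0.03), (0.1, 0.01), (0.05, 0.01), (0.01, 0.01)):
            t = np.quantile(T_sim, 1 - target)
            # recover the p-value vector giving statistic t (equal p per SNP)
            p_each = np.exp(-t / (2 * m))
            g = gene_statistic("g", np.full(m, p_each), R)
            assert g.gene_p == pytest.approx(target, abs=tol)

    def test_zero_pvalue_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            g = gene_statistic("g", np.array([0.0, 0.5]))
        assert np.isfinite(g.z)

    def test_non_psd_ld_projected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.warns(UserWarning, match="PSD"):
            g = gene_statistic("g", np.array([0.2, 0.3, 0.4]), bad)
        assert 0 < g.gene_p <= 1


def make_stats(z, genes=None):
    genes = genes or [f"g{i:03d}" for i in range(len(z))]
    return [
        GeneLevelStat(g, 1, float(stats.norm.sf(zi)), float(zi)) for g, zi in zip(genes, z)
    ]


class TestCompetitiveTest:
    def test_all_equal_z_degenerate(self):
        sl = make_stats(np.ones(30))
        r = competitive_set_test(sl, {"g000", "g001"}, {s.gene_id for s in sl})
        assert r.beta == pytest.approx(0.0, abs=1e-12)
        assert r.p_one_sided == pytest.approx(1.0)
        assert "degenerate_zero_variance" in r.flags

    def test_toy_matches_closed_form_ols(self, rng):
        """20 genes, one covariate: beta/se/p equal the textbook OLS values."""
        z = rng.standard_normal(20)
        cov = rng.standard_normal((20, 1))
        sl = make_stats(z)
        bg = sorted(s.gene_id for s in sl)
        gset = set(bg[:6])
        X = np.column_stack([np.ones(20), [1.0 if g in gset else 0.0 for g in bg], cov])
        y = np.array([dict(zip(bg, z))[g] for g in bg])
        bh = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ bh
        s2 = resid @ resid / (20 - 3)
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p = stats.t.sf(bh[1] / se, 17)
        r = competitive_set_test(sl, gset, set(bg), cov)
        assert r.beta == pytest.approx(bh[1], rel=1e-9)
        assert r.se == pytest.approx(se, rel=1e-9)
        assert r.p_one_sided == pytest.approx(p, rel=1e-9)

    def test_monotone_in_set_shift(self, rng):
        z = rng.standard_normal(200)
        bg = [f"g{i:03d}" for i in range(200)]
        gset = set(bg[:40])
        betas = []
        for shift in (0.0, 0.3, 0.8):
            z2 = z.copy()
            z2[:40] += shift
            betas.append(competitive_set_test(make_stats(z2, bg), gset, set(bg)).beta)
        assert betas[0] < betas[1] < betas[2]

    def test_planted_shift_recovered(self, rng):
        """Mean estimated coefficient near the planted 0.3 over replicates."""
        reps, n, k, shift = 80, 1000, 100, 0.3
        bg = [f"g{i:04d}" for i in range(n)]
        gset = set(bg[:k])
        est = []
        for _ in range(reps):
            z = rng.standard_normal(n)
            z[:k] += shift
            est.append(competitive_set_test(make_stats(z, bg), gset, set(bg)).beta)
        mean, se = np.mean(est), np.std(est, ddof=1) / np.sqrt(reps)
        assert abs(mean - shift) < 2 * se + 1e-9

    def test_set_must_be_subset_of_background(self):
        sl = make_stats(np.zeros(5))
        with pytest.raises(ValueError):
            competitive_set_test(sl, {"zzz"}, {s.gene_id for s in sl})


class TestConditionalTest:
    def test_self_conditioning_flagged(self):
        sl = make_stats(np.arange(10.0))
        bg = {s.gene_id for s in sl}
        gset = set(sorted(bg)[:3])
        r = conditional_set_test(sl, gset, [gset], bg)
        assert "collinear_focal" in r.flags

    def test_nested_toy_matches_two_indicator_ols(self, rng):
        z = rng.standard_normal(30)
        bg = [f"g{i:03d}" for i in range(30)]
        focal = set(bg[:5])
        condition = set(bg[:12])  # focal strictly inside condition
        X = np.column_stack(
            [np.ones(30),
             [1.0 if g in focal else 0.0 for g in bg],
             [1.0 if g in condition else 0.0 for g in bg]]
        )
        bh = np.linalg.solve(X.T @ X, X.T @ z)
        resid = z - X @ bh
        se = np.sqrt(resid @ resid / 27 * np.linalg.inv(X.T @ X)[1, 1])
        r = conditional_set_test(make_stats(z, bg), focal, [condition], set(bg))
        assert r.beta == pytest.approx(bh[1], rel=1e-9)
        assert r.se == pytest.approx(se, rel=1e-9)

    def test_disjoint_uncorrelated_condition_leaves_beta(self, rng):
        reps = 60
        bg = [f"g{i:04d}" for i in range(800)]
        focal, cond = set(bg[:80]), set(bg[400:480])
        diffs = []
        for _ in range(reps):
            z = rng.standard_normal(800)
            z[:80] += 0.3
            sl = make_stats(z, bg)
            un = competitive_set_test(sl, focal, set(bg))
            co = conditional_set_test(sl, focal, [cond], set(bg))
            diffs.append(co.beta - un.beta)
        assert abs(np.mean(diffs)) < 2 * np.std(diffs, ddof=1) / np.sqrt(reps) + 1e-9


class TestCompareBetas:
    def test_equal_betas(self):
        z, p = compare_betas(0.4, 0.1, 0.4, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_known_value(self):
        z, p = compare_betas(0.3, 0.1, 0.1, 0.1)
        assert z == pytest.approx(np.sqrt(2), rel=1e-9)
        assert p == pytest.approx(0.15730, abs=1e-4)

    def test_antisymmetry(self):
        z1, p1 = compare_betas(0.5, 0.2, -0.1, 0.3)
        z2, p2 = compare_betas(-0.1, 0.3, 0.5, 0.2)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            compare_betas(0.1, 0.0, 0.2, 0.1)
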