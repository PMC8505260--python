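"""Overrepresentation testing, greedy term refinement and partitioning."""

import itertools
import math

import pytest
from scipy import stats

from fmrpsb.pathways import (
    bonferroni_select,
    build_partition,
    filter_annotations,
    fisher_overrep,
    per_term_partition_tests,
    refine_terms,
)
from fmrpsb.records import OverrepResult, TermAnnotation


def term(tid, genes, ontology="GO", evidence=None):
    ev = evidence or {g: {"EXP"} for g in genes}
    return TermAnnotation(tid, ontology, set(genes), ev)


class TestFilterAnnotations:
    def test_iea_only_genes_shrink_term_below_threshold(self):
        genes = [f"g{i}" for i in range(12)]
        ev = {g: {"EXP"} for g in genes}
        for g in genes[:3]:
            ev[g] = {"IEA"}
        t = term("T", genes, evidence=ev)
        assert filter_annotations([t], universe=set(genes)) == []

    def test_ten_exp_genes_retained(self):
        genes = [f"g{i}" for i in range(10)]
        out = filter_annotations([term("T", genes)], universe=set(genes))
        assert len(out) == 1 and out[0].gene_ids == set(genes)

    def test_mixed_evidence_keeps_gene(self):
        genes = [f"g{i}" for i in range(10)]
        ev = {g: {"IEA", "EXP"} for g in genes}  # IEA plus a valid code
        out = filter_annotations([term("T", genes, evidence=ev)], universe=set(genes))
        assert len(out) == 1

    def test_universe_restriction(self):
        genes = [f"g{i}" for i in range(15)]
        out = filter_annotations([term("T", genes)], universe=set(genes[:9]))
        assert out == []  # 9 expressed genes < 10

    def test_matches_bruteforce_filter(self, rng):
        universe = {f"g{i}" for i in range(40)}
        terms = []
        for t in range(15):
            genes = set(rng.choice(sorted(universe | {"x1", "x2"}), size=int(rng.integers(5, 25)),
                                   replace=False))
            ev = {g: {str(rng.choice(["EXP", "IEA", "NAS", "IDA"]))} for g in genes}
            terms.append(term(f"T{t}", genes, evidence=ev))
        out = {t.term_id: t.gene_ids for t in filter_annotations(terms, universe)}
        for t in terms:
            kept = {
                g for g in t.gene_ids
                if g in universe and not (t.evidence_by_gene[g] <= {"NAS", "IEA", "RCA"})
            }
            if len(kept) >= 10:
                assert out[t.term_id] == kept
            else:
                assert t.term_id not in out


class TestFisherOverrep:
    def test_worked_table(self):
        universe = {f"u{i}" for i in range(100)}
        targets = set(sorted(universe)[:20])
        term_genes = set(sorted(targets)[:6]) | set(sorted(universe - targets)[:4])
        r = fisher_overrep(term_genes, targets, universe)
        assert (r.a, r.b, r.c, r.d) == (6, 4, 14, 76)
        assert r.odds_ratio == pytest.approx((6 * 76) / (4 * 14))
        assert r.p == pytest.approx(float(stats.hypergeom.sf(5, 100, 20, 10)), rel=1e-12)

    def test_or_one_when_fractions_match(self):
        universe = {f"u{i}" for i in range(100)}
        targets = set(sorted(universe)[:50])
        term_genes = set(sorted(targets)[:5]) | set(sorted(universe - targets)[:5])
        r = fisher_overrep(term_genes, targets, universe)
        assert r.odds_ratio == pytest.approx(1.0)

    def test_all_target_term_haldane_flagged(self):
        universe = {f"u{i}" for i in range(30)}
        targets = set(sorted(universe)[:10])
        term_genes = set(sorted(targets)[:5])
        r = fisher_overrep(term_genes, targets, universe)
        assert r.haldane and r.b == 0
        assert r.p == pytest.approx(float(stats.hypergeom.sf(4, 30, 10, 5)), rel=1e-12)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_overrep(set(), set(), set())

    def test_matches_enumeration_oracle_small_universes(self):
        """Hypergeometric tail by direct combinatorial enumeration."""
        for N, K, n in itertools.product((8, 12, 20), (2, 5, 8), (3, 6, 8)):
            if K > N or n > N:
                continue
            universe = {f"u{i}" for i in range(N)}
            targets = set(sorted(universe)[:K])
            for a in range(0, min(K, n) + 1):
                b = n - a
                if b > N - K:
                    continue
                term_genes = set(sorted(targets)[:a]) | set(sorted(universe - targets)[:b])
                r = fisher_overrep(term_genes, targets, universe)
                tail = sum(
                    math.comb(K, x) * math.comb(N - K, n - x)
                    for x in range(a, min(K, n) + 1)
                ) / math.comb(N, n)
                assert r.p == pytest.approx(tail, rel=1e-10)


class TestBonferroniSelect:
    def test_strict_threshold_boundary(self):
        r = OverrepResult("T", 1, 1, 1, 1, 1.0, p=0.01 / 20)
        assert bonferroni_select([r], m=20) == []  # m*p == alpha, not < alpha
        assert r.p_adjusted == pytest.approx(0.01)

    def test_zero_p_survives(self):
        r = OverrepResult("T", 1, 1, 1, 1, 1.0, p=0.0)
        assert bonferroni_select([r], m=1000) == [r]

    def test_matches_threshold_scan(self, rng):
        results = [
            OverrepResult(f"T{i}", 1, 1, 1, 1, 1.0, p=float(p))
            for i, p in enumerate(rng.random(20) * 0.02)
        ]
        out = bonferroni_select(results, m=20)
        expected = [r for r in results if 20 * r.p < 0.01]
        assert out == expected

    def test_m_smaller_than_family_rejected(self):
        rs = [OverrepResult(f"T{i}", 1, 1, 1, 1, 1.0, p=0.5) for i in range(5)]
        with pytest.raises(ValueError):
            bonferroni_select(rs, m=3)


def toy_refinement_setup():
    targets = {f"t{i}" for i in range(40)}
    universe = targets | {f"n{i}" for i in range(160)}
    terms = [
        term("A", {f"t{i}" for i in range(12)} | {f"n{i}" for i in range(4)}),
        term("B", {f"t{i}" for i in range(12)} | {f"n{i}" for i in range(4)}),
        term("C", {f"t{i}" for i in range(20, 30)} | {f"n{i}" for i in range(10, 20)}),
        term("D", {f"t{i}" for i in range(6)} | {f"t{i}" for i in range(12, 16)}
             | {f"n{i}" for i in range(10)}),
        term("E", {f"t{i}" for i in range(30, 35)} | {f"n{i}" for i in range(20, 35)}),
        term("F", {f"t{i}" for i in range(6, 12)} | {f"t{i}" for i in range(16, 20)}
             | {f"n{i}" for i in range(40, 46)}),
    ]
    return terms, targets, universe


class TestRefinement:
    def test_duplicate_terms_keep_exactly_one(self):
        targets = {f"t{i}" for i in range(15)}
        universe = targets | {f"n{i}" for i in range(85)}
        genes = {f"t{i}" for i in range(10)} | {"n0", "n1"}
        out = refine_terms([term("dup1", genes), term("dup2", genes)], targets, universe)
        assert [t.term_id for t in out] == ["dup1"]  # tie broken by term id

    def test_disjoint_enriched_terms_both_survive(self):
        targets = {f"t{i}" for i in range(30)}
        universe = targets | {f"n{i}" for i in range(170)}
        t1 = term("T1", {f"t{i}" for i in range(10)} | {"n0", "n1"})
        t2 = term("T2", {f"t{i}" for i in range(15, 25)} | {"n5", "n6"})
        out = refine_terms([t1, t2], targets, universe)
        assert {t.term_id for t in out} == {"T1", "T2"}

    def test_six_term_worked_example(self):
        """Hand-traced greedy loop: A beats its duplicate B; D and F lose
        their borrowed overlap with A and drop; C is independent; E was
        never significant."""
        terms, targets, universe = toy_refinement_setup()
        out = refine_terms(terms, targets, universe)
        assert [t.term_id for t in out] == ["A", "C"]

    def test_six_term_example_matches_independent_loop(self):
        """Step-by-step oracle with explicit state, written against scipy."""
        terms, targets, universe = toy_refinement_setup()

        def oracle(term_list):
            remaining = {t.term_id: set(t.gene_ids) for t in term_list}
            removed, accepted = set(), []
            while remaining:
                scored = {}
                for tid, genes in remaining.items():
                    g = genes - removed
                    a = len(g & targets)
                    b = len(g) - a
                    c = len(targets) - a
                    d = len(universe) - a - b - c
                    p = float(stats.hypergeom.sf(a - 1, len(universe), a + c, a + b))
                    if min(a, b, c, d) == 0:
                        orr = (a + 0.5) * (d + 0.5) / ((b + 0.5) * (c + 0.5))
                    else:
                        orr = a * d / (b * c)
                    scored[tid] = (orr, p)
                for tid in [t for t, (_, p) in scored.items() if p > 0.01]:
                    del remaining[tid]
                if not remaining:
                    break
                best = min(remaining, key=lambda t: (-scored[t][0], scored[t][1], t))
                accepted.append(best)
                removed |= remaining.pop(best)
            return accepted

        assert [t.term_id for t in refine_terms(terms, targets, universe)] == oracle(terms)

    def test_deterministic_under_input_permutation(self, rng):
        terms, targets, universe = toy_refinement_setup()
        reference = [t.term_id for t in refine_terms(terms, targets, universe)]
        for _ in range(5):
            shuffled = list(terms)
            rng.shuffle(shuffled)
            assert [t.term_id for t in refine_terms(shuffled, targets, universe)] == reference

    def test_terminates_within_term_count(self):
        terms, targets, universe = toy_refinement_setup()
        out = refine_terms(terms, targets, universe)
        assert len(out) <= len(terms)


class TestPartition:
    def test_blocks_from_set_algebra(self, rng):
        expressed = {f"g{i}" for i in range(80)}
        targets = set(rng.choice(sorted(expressed), 25, replace=False)) | {"off_universe"}
        t1 = term("T1", set(rng.choice(sorted(expressed), 30, replace=False)))
        t2 = term("T2", set(rng.choice(sorted(expressed), 20, replace=False)))
        part = build_partition([t1, t2], targets, expressed)
        superset = (t1.gene_ids | t2.gene_ids) & expressed
        tg = targets & expressed
        assert part.overlap == superset & tg
        assert part.terms_only == superset - tg
        assert part.targets_only == tg - superset
        blocks = [part.overlap, part.terms_only, part.targets_only]
        for x, y in itertools.combinations(blocks, 2):
            assert not (x & y)
        assert part.overlap | part.targets_only == tg

    def test_disjoint_targets_give_empty_overlap(self):
        expressed = {f"g{i}" for i in range(30)}
        part = build_partition([term("T", set(sorted(expressed)[:12]))],
                               set(sorted(expressed)[20:25]), expressed)
        assert part.overlap == set()

    def test_all_targets_inside_one_term(self):
        expressed = {f"g{i}" for i in range(30)}
        targets = set(sorted(expressed)[:5])
        part = build_partition([term("T", set(sorted(expressed)[:15]))], targets, expressed)
        assert part.targets_only == set()

    def test_no_refined_terms_rejected(self):
        with pytest.raises(ValueError):
            build_partition([], {"a"}, {"a"})


class TestPerTermPairs:
    def test_pair_sizes(self):
        targets = {f"t{i}" for i in range(40)}
        genes = {f"t{i}" for i in range(25)} | {f"n{i}" for i in range(91)}
        pairs = per_term_partition_tests([term("ca_transport", genes)], targets)
        (tid, in_t, out_t), = pairs
        assert (len(in_t), len(out_t)) == (25, 91)

    def test_all_target_term_has_empty_nontarget_side(self):
        targets = {f"t{i}" for i in range(20)}
        pairs = per_term_partition_tests([term("T", set(sorted(targets)[:10]))], targets)
        assert pairs[0][2] == set()

    def test_random_toy_matches_set_algebra(self, rng):
        targets = {f"g{i}" for i in range(0, 60, 2)}
        terms = [term(f"T{k}", set(rng.choice([f"g{i}" for i in range(60)], 20, replace=False)))
                 for k in range(6)]
        for tid, in_t, out_t in per_term_partition_tests(terms, targets):
            src = next(t for t in terms if t.term_id == tid)
            assert in_t == src.gene_ids & targets
            assert out_t == src.gene_ids - targets
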