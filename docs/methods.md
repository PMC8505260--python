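# Methods

This note records the statistical models implemented in `fmrpsb`, the
defaults and the reasoning behind the open design choices, and what the
synthetic-data generators do and do not emulate.

## Ranking and binning (`fmrpsb.binding`)

Peak- or replicate-level binding statistics are collapsed to one value per
gene in two reduce steps — best peak within a (gene, replicate/isoform)
group, then best of the per-group bests — keeping only genes observed in
*every* group (intersection semantics). Both p-value-like ("lower is
better") and score-like ("higher is better") statistics are supported via
an explicit direction; negating a score and flipping the direction is a
no-op by construction.

Homolog mapping keeps a gene only when it has exactly one protein-coding
candidate in the pair table. When two source genes map onto the same
target, the record with the better statistic wins and a collision is
logged — the alternative (dropping both) would silently shrink the
ranking; either is defensible, and the choice is deterministic.

Ranking ties are broken lexicographically by gene id so binning is a pure
function of the record set (input order never matters). The tail policy is
per dataset: `drop_tail` reproduces designs that analyse only the top
⌊N/s⌋·s genes; `keep_tail` emits the final partial bin. Default bin size
is 400 genes, the size at which set-association tests retain power while
the ranking is still finely resolved.

## Gene-wide statistics and competitive tests (`fmrpsb.common_variant`)

SNPs pass a MAF ≥ 0.01 filter and are assigned to genes within a
strand-aware window, 35 kb upstream and 10 kb downstream of the gene body
(1-based inclusive boundaries). Strandedness is a config switch
(`strand_aware=False` gives the fixed start−35 kb / end+10 kb window) to
probe sensitivity, since window conventions differ between tools.

The gene statistic is T = Σᵢ −2 ln pᵢ. Under the null with correlated
SNPs, E[T] = 2m and Var[T] = 4m + 2 Σᵢ<ⱼ cov(−2 ln pᵢ, −2 ln pⱼ); T is
approximated as c·χ²_f by matching both moments (Brown's method), with
c = Var/2E and f = 2E²/Var. For *two-sided* p-values of bivariate-normal
Z-scores the pairwise covariance is an even function of the correlation ρ;
it is evaluated from a degree-10 polynomial in ρ² fitted to adaptive
quadrature of the exact double integral (max fit error < 4 × 10⁻⁴ across
ρ ∈ [0, 1]; the leading coefficient 3.910 differs from the one-sided
literature value 3.263 because squaring the Z halves the effective
information in the sign). Accuracy of the resulting tail, checked against
large simulations at m = 5, ρ = 0.5: within ~0.005 absolute for p in the
0.01–0.1 range, ~0.02 in the distribution bulk — adequate for gene-level
ranking and set testing, and exact in the two reduction cases (m = 1
returns the SNP p-value; identity LD gives the χ²₂ₘ tail). P-values of 0
are clamped to 1e-300; non-PSD LD matrices are eigenvalue-projected with a
warning.

The competitive test regresses gene Z = Φ⁻¹(1 − p_gene) on a
set-membership indicator over the full scored background, with covariates
log gene length, log SNP count, and mean inter-SNP r² as an LD proxy, and
reports the upper-tail t probability of the indicator coefficient. This is
a documented substitute for MAGMA's internals: the contract tested here is
calibration (type-I error at nominal level) and unbiased recovery of a
planted mean shift, not bit-equality with any particular release.
Conditional analysis adds one indicator column per conditioning set; a
focal set identical to a conditioning set is flagged as collinear rather
than estimated. Effect comparisons between *non-overlapping* sets use
z = (β₁−β₂)/√(se₁²+se₂²), two-sided by default (one-sided by flag); the
independence assumption is the caller's responsibility.

## Rare-variant burden (`fmrpsb.rare_burden`)

Ultra-rare singletons are variants with cohort allele count exactly 1 and
external-reference allele count 0; the cohort count must be computed over
the full case-control data before filtering. LoF = {nonsense, essential
splice, frameshift}; NS = LoF ∪ {missense, inframe indel}; consequence
strings are input annotations (no transcript-model recomputation), and
unknown strings fall to "other" with a warning.

The burden predictor is the per-sample count of class-qualifying variants
in the set (a 0/1 carrier indicator is available by flag; the count is the
default because it uses the full exposure gradient). Status is regressed
on the predictor plus the covariate design (PCs, exome-wide synonymous
singleton burden, dummy-coded platform and sex) by Firth
penalised-likelihood logistic regression: the Jeffreys penalty
½ log det I(β) keeps estimates finite under the complete separation that
sparse singleton counts readily produce. Newton iteration uses the
standard hat-diagonal score adjustment, step-halving on the penalised
likelihood, and converges when the largest adjusted-score component falls
below 1e-6 (at most 100 iterations); standard errors come from the
penalised information and p-values are two-sided Wald. Wald was chosen
over penalised-likelihood-ratio for symmetry with the reported
coefficients and the between-set z-tests on them.

A practical caveat established during validation: Wald p-values are
conservative when the set has only a handful of carriers (rejection rate
~0.003 at nominal 0.05 with ~8 carriers) and calibrate well from a few
dozen carriers upward (~0.05 at ≈46+). The calibration and recovery suites
therefore run cohorts of 1,600 cases / 2,200 controls — a scaled version
of the ~4,000/5,700 design the generator defaults mirror — where set
carrier counts are comfortably in the calibrated regime.

## De novo enrichment (`fmrpsb.denovo`)

Expected counts are E = 2 · N_trios · Σ_g μ_g with per-haploid per-gene
rates μ; the factor 2 covers the two transmitted haplotypes per trio.
Genes without a rate are excluded and logged. The one-sample test is the
exact Poisson upper tail P(X ≥ observed). The two-sample rate-ratio test
is the exact conditional binomial — given n = o₁+o₂ events,
o₁ ~ Bin(n, e₁/(e₁+e₂)) under equal rates — one-sided for enrichment by
default, two-sided by doubling the smaller tail. For subset-vs-remainder
comparisons the remainder must exclude the subset's genes (the pipeline
does this). NS counts include LoF events, mirroring the variant-class
definition; a strict missense-only class is derivable from the two
columns.

## CNV association (`fmrpsb.cnv`)

CNVs below 100 kb or 15 probes are removed (boundaries inclusive). The
regression unit is the CNV: status ~ overlapped-set-gene count + CNV size
(Mb) + total genes per CNV + study and chip dummies, plain logistic with
a one-sided Wald p on the set coefficient. Gene overlap means ≥ 1 shared
base on the same chromosome. Because large CNVs hit many genes, the model
p is anti-conservative in aggregate, so significance is judged against an
empirical null: `n_perm` random gene sets of exactly the tested set's
size, drawn uniformly from brain-expressed genes, each re-fitted;
p_emp = (1 + #{p_perm ≤ p_obs}) / (n_perm + 1). The add-one rule keeps
p_emp ≥ 1/(n_perm+1) and ties count against the tested set; degenerate
draws (constant overlap count) count as non-exceeding and are tallied.
Default n_perm is 1,000; a seed is mandatory. Deletion/duplication strata
are plain filters ahead of the same machinery.

## Pathway refinement (`fmrpsb.pathways`)

Annotations lose gene-term memberships whose *only* evidence codes are in
{NAS, IEA, RCA}, are intersected with the expressed-gene universe, and
terms under 10 genes are dropped. Overrepresentation of targets in a term
is the one-sided hypergeometric tail over the universe; the odds ratio is
the sample (a·d)/(b·c) with a Haldane +0.5 on every cell iff some cell is
zero (flagged). Bonferroni selection is strict (m·p < α, α = 0.01) with m
the per-ontology family size.

Refinement loop: re-test every remaining term on its genes minus the
cumulative removal set; drop terms whose unadjusted re-test p exceeds
0.01; accept the highest-odds-ratio survivor (ties: smaller p, then term
id) and add its genes to the removal set; repeat until no terms remain.
Accepted terms are frozen — they are never retroactively dropped; removal
only affects later re-tests of other terms. The greedy criterion uses the
Haldane-corrected sample OR. The initial selection uses adjusted p; the
drop step uses raw p — both per the stated thresholds. The output is
deterministic and invariant to input order.

The accepted terms' union, restricted to brain-expressed genes, forms the
functional superset; targets are partitioned into overlap / targets-only,
with the superset remainder as terms-only. Partition blocks are tested
against a brain-expressed background with Bonferroni m = 3, so association
attributable to brain expression alone is controlled. Per-term analysis
emits (term ∩ targets, term \ targets) pairs with m = number of refined
terms, plus subset-vs-whole comparisons (conditional competitive test for
common variants, beta z-test for burden, two-sample rate ratio for de
novo).

## Synthetic data (`fmrpsb.simulate`)

One latent target set (default 8% of genes, giving 400-gene sets at the
default 5,000-gene genome) plays the role of the true binding-target/risk
set in every generator:

- **Genome** — log-normal gene lengths (median 20 kb, σ = 0.8) on 22
  chromosomes; mutation rates proportional to length, normalised to an
  exome-wide per-haploid NS rate of 1.0 (LoF = 0.12 × NS, synonymous =
  0.45 × NS, the approximate proportions of coding mutation-rate models);
  brain expression Bernoulli(0.7).
- **Binding** — targets draw peak p-values from Beta(0.15, 1),
  non-targets from U(0,1); two replicates, Poisson peak counts, 5%
  replicate dropout, exercising the collapse rules.
- **GWAS** — per-gene SNP counts 1+Poisson(7) (capped at 40), z-scores
  multivariate normal with compound-symmetric correlation ρ = 0.3,
  two-sided p-values; risk genes get a per-SNP-count mean shift calibrated
  by bisection (common random numbers, 2,000 draws) so the *gene-Z*
  elevation equals the planted competitive β (default 0.3). A direct
  generator (`gen_gene_stats`) plants the shift on gene Z itself and is
  what the calibration/recovery suites use. 5% of SNPs get MAF < 0.01 to
  exercise the frequency filter.
- **Rare cohort** — default 4,079 cases / 5,712 controls; per-sample class
  counts Poisson with per-gene rates ∝ mutation rate (exome-wide NS
  singleton rate 1.0/sample, synonymous 0.45), case rates inside the
  target set multiplied by the planted OR (for Poisson exposures the
  prospective logistic coefficient is exactly ln OR, so recovery is
  well-defined); 10 standard-normal PCs, two platforms, sex; 40
  deliberately non-singleton records probe the ultra-rare filter.
- **Trios** — per-gene counts Poisson(2·N·μ·RR), RR planted inside the
  target set; LoF drawn first, NS = LoF + missense remainder so
  n_lof ≤ n_ns always. Default 3,444 trios.
- **CNVs** — default 17,565 / 24,830 subjects, one CNV each; log-normal
  lengths (median 150 kb) and probe counts straddling the filters; status
  assigned from a logistic model whose set-overlap coefficient is exactly
  ln(planted OR) (plus small size and study effects), intercept calibrated
  to the configured case fraction — so the analysis regression estimates
  a known truth.
- **Ontology** — 60 terms (half GO, half MP), log-normal sizes (median
  40), 30% of each term drawn from a shared hub pool to create overlap,
  25% of terms enriched for targets at odds 6, 20% IEA evidence admixture.

Every generator is a pure function of the config (identical seed ⇒
identical output). What the generators do *not* emulate: realistic LD and
recombination structure (compound symmetry within genes, independence
between genes), haplotype or sequence-level detail, population
stratification actually correlated with risk, CNV length–gene-density
correlation beyond placement, and ontology term hierarchy (the DAG).
Passing tests therefore demonstrate correctness and calibration of the
statistical machinery under the stated generative assumptions, not
performance on real cohort artefacts.

## Numerical choices

- p-value floor 1e-300 throughout log transforms.
- OLS collinearity: QR-based rank screen; exactly collinear columns are
  dropped (never the focal indicator — that case is flagged instead).
  Residual variance below machine precision relative to ‖y‖² is flagged
  degenerate with p = 1.
- Logistic/Firth: pivoted-QR collinearity screen; Cholesky solves with a
  1e-8 ridge fallback; weights clipped at 1e-12.
- Bonferroni: p_adj = min(1, m·p), with m recorded per row — per family as
  applied (per bins-within-class, 3 partition blocks, refined-term count),
  never globally.
- Empirical p: add-one rule; ties count against the tested set.

## Problem sizes used by the test and acceptance suites

Chosen so the full suite runs in a few minutes on one core while every
check retains its statistical meaning: competitive calibration 2,000
replicates (5,000 genes, 400-gene sets); Firth calibration 2,000 replicate
cohorts of 1,600/2,200; rate-ratio calibration 2,000 draws; CNV empirical
calibration 500 outer replicates at n_perm = 199; recoveries 150–400
replicates at the scales above (de novo at the full 3,444 trios with a
400-gene set). The exact-test oracles (hypergeometric enumeration,
conditional-binomial Monte Carlo at 10⁶ draws, the separated 2×2, the
identity-LD reduction) are deterministic.

## Known limitations

- The gene statistic's scaled-chi-square null is an approximation; its
  documented accuracy (above) bounds the fidelity of gene p-values under
  strong LD, and cross-gene LD is ignored (block-diagonal assumption).
- Wald burden p-values are conservative in the very-sparse-carrier regime;
  penalised-likelihood-ratio tests would calibrate deeper into sparsity
  but are not implemented.
- The CNV permutation null conditions on the observed CNV table; it does
  not model locus-specific recurrence.
- The refinement procedure is greedy; it guarantees a deterministic,
  self-consistent set of surviving terms, not a global optimum over term
  subsets.
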