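# Methods

This note documents the models and procedures implemented in `dnmcross`,
the defaults they ship with, and the choices made where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Burden and contribution (`dnmcross.burden`)

DNM tables integrated across publications differ in detection rate, so all
burden comparisons are normalised by each cohort's synonymous DNM count —
synonymous variants are assumed phenotype-neutral and to share the
cohort's detection characteristics. For each case cohort and class
c ∈ {LoF, Dmis, Pfun, Tmis} the 2×2 table (case c, case synonymous;
control c, control synonymous) yields:

* a two-tailed Fisher exact p (convention: sum of hypergeometric
  probabilities ≤ that of the observed table, the convention of standard
  exact-test implementations; `scipy.stats.fisher_exact` supplies it and
  the test suite checks it against exhaustive enumeration for all margins
  ≤ 20);
* the sample cross-product odds ratio with a Wald CI on log OR.
  With any zero cell the Haldane–Anscombe 0.5 correction is applied and
  flagged; two zero cells in a row leave the OR undefined (NaN, flagged).
  Note that some published tables print the conditional-MLE odds ratio
  (R's `fisher.test`) instead; for well-filled tables the two agree to ~2
  decimals but they are not identical estimators;
* BH adjustment within each cohort across its four classes (m = 4).
  This family structure is what reproduces published adjusted p columns;
  it is configurable in the sense that callers can re-adjust over any
  family they prefer.

The ascertainment differential f = 1 − (c/d)/(a/b) is reported as-is (it
may be negative when a class is depleted in cases), but is clipped at zero
inside the patient-contribution product f·a/N, since a contribution cannot
be negative; clipping is logged.

## TADA-Denovo (`dnmcross.tada`)

The gene-level model: under the null a gene's class-c count is
Poisson(λ₀ = 2Nμ_c); in a risk gene the rate is multiplied by
γ ~ Gamma(shape = γ̄β, rate = β). The closed-form log Bayes factor (the
gamma-Poisson marginal over the Poisson null) is computed entirely in log
space via `gammaln` and is finite for counts up to 10⁶. Per-class evidence
multiplies. The log-BF increment from x to x+1 is
log((x + γ̄β)/(β + λ₀)), so the BF is strictly increasing in the count
whenever x + γ̄β > β + λ₀ — for DNM-scale rates (λ₀ ≪ 1) that is every
count from zero.

Bayesian FDR: genes are sorted by decreasing BF; q is the running mean of
the posterior null probabilities P₀ = (1−π)/((1−π)+π·BF). Ties in BF are
broken by gene id for reproducibility and all tied genes receive the q of
the last tied position (the most conservative value of the block).

Defaults (all configurable, echoed into CLI output headers): π = 0.05,
γ̄_LoF = 20, γ̄_Dmis = 4.7, β = 1 — the values long used in the TADA
literature. Two class modes are supported: the two-class TADA convention
{LoF, Dmis} and a single aggregate {Pfun}; the aggregate is the default.
The Pfun prior mean relative risk defaults to 10.6, the
mutation-count-weighted mean of the LoF and Dmis defaults using the
control-cohort class proportions (411 LoF : 662 Dmis).

Candidate genes are the union of q < 0.05 calls from the per-disorder and
the pooled ("combined") strategies, tiered by best q at 1e-4 / 1e-3 /
1e-2 / 0.05. The disorder-bias test for shared candidates is the exact
conditional Poisson comparison: given the total count, the count in one
disorder is Binomial with success probability equal to its trio share;
one-sided p = P(X ≥ x); BH across all gene × disorder tests at 0.05.

## Permutation overlap (`dnmcross.overlap`)

The null reassigns each disorder's observed number of class-c DNMs to
genes with probability proportional to supplied per-gene class weights,
with replacement (a gene may absorb several mutations; it counts once in
the distinct-gene set). This resampling choice — rather than permuting a
fixed multiset of per-gene multiplicities — matches the multiset nature of
DNM hits and is documented as the package's reading of mutability-weighted
permutation; gene-length/trinucleotide weight derivation is outside scope
(weights are inputs; the simulator's mutation rates serve in testing).

Weighted sampling uses Walker alias tables (Vose construction), giving
O(1) draws per mutation; 100,000 permutations (the published default) on a
~18,000-gene universe is minutes of work, and a `--fast` 10,000-permutation
mode exists for exploration. Empirical p uses the +1 correction
(p = (1 + #{perm ≥ obs})/(n_perm + 1)), so p is never exactly zero and the
test is one-sided for enrichment; depletion shows only through O/E < 1.
Per-pair nulls draw seeds from one spawned `SeedSequence`, so a run is
reproducible and independent of pair ordering.

Because the overlap statistic is integer-valued, the +1-corrected p is
sub-uniform (conservative) by construction; its null distribution only
approaches continuous uniformity when the overlap spread is large. The
calibration tests therefore use DNM multisets of ~1,100 hits on a
3,000-gene universe — the scale of real per-disorder functional-DNM sets —
where the null SD of the overlap is ~12.

## Network and expression statistics (`dnmcross.network`)

Coexpression edges are Pearson |R| > 0.8 (strict) between gene rows;
constant rows are excluded with a warning, and at least three samples are
required. PPI edges keep combined score > 400 — strict, following the
"higher than" convention; a flag switches to ≥ for STRING-style
inclusive filtering. Symmetric duplicates collapse keeping the maximum
score; self-edges are dropped with a warning.

The merged network is an undirected multigraph with edge keys
"coexpression"/"ppi"; annotated genes without edges remain as degree-0
nodes so connected fractions are computed over the full candidate set.
Degree-vs-pleiotropy uses Spearman rank correlation with mid-rank ties and
the large-sample p; all-tied inputs are returned as flagged NaN rather
than an arbitrary number.

Module enrichment is a per-module Fisher 2×2 within a stated background
(in-set × in-module), BH across modules. Exact tests are conservative at
these table sizes: under a random-set null the rejection rate at p < 0.05
sits at or below the nominal level, and the calibration tests assert
exactly that (at most nominal, not degenerate), not a symmetric 5% band.

The shared-disorder trend test is a plain logistic regression of the
binary gene property on the shared-disorder count treated as a numeric
score, with a likelihood-ratio p — a monotone-trend reading of ordered
regression on an ordinal predictor, chosen because the full
ordered-logistic specification (which variable is the ordinal response) is
ambiguous in this setting. Under perfect separation the MLE diverges: the
result is flagged and the p-value falls back to the Cochran–Armitage score
test, which is defined regardless of separation and asymptotically
equivalent to the LR test under the null.

## Synthetic cohorts (`dnmcross.simulate`)

The generator is the exact generative counterpart of the analysis models,
so downstream calibration claims are testable against known truth.

* **Mutation rates.** One log-normal mutability multiplier per gene
  (σ = 1.0 default) scales all classes — long or mutable genes are so for
  every class — then class columns are rescaled so genome-wide per-trio
  rates match the configured marginals exactly (to 1e-9). Defaults
  reproduce a published 3,391-trio control cohort: 411 LoF, 2,257 missense
  (662 deleterious : 1,595 tolerated) and 932 synonymous DNMs; default
  case cohorts mirror the five published disorders at their trio counts
  (6,511 / 4,293 / 933 / 1,022 / 1,094).
* **Risk genes.** Each disorder flags ⌊π·G⌋ risk genes (π = 0.05 default).
  A fraction `shared_pool_fraction` (default 0.5) of each disorder's risk
  genes is drawn from a common pool of size max_d ⌊π_d·G⌋; the remainder
  is drawn disjointly outside the pool. Full sharing with equal π thus
  forces identical risk sets, and intermediate fractions give closed-form
  hypergeometric pairwise-overlap expectations (s₁s₂/pool for the shared
  parts). Relative risks are drawn per risk gene and class from the same
  Gamma(γ̄β, β) prior the Bayes factor integrates — simulation matches the
  model, which is what makes the FDR-calibration check meaningful.
* **Counts and records.** Class counts are Poisson(2Nμγ); counts expand
  into per-variant records with synthetic sample ids, a realistic mix of
  LoF consequence terms, and missense scores placed on the correct side of
  the Dmis threshold so classification round-trips exactly.
* **Expression and PPI.** Toy expression matrices plant K coexpression
  modules with smooth stage profiles (cosine harmonics: module 1 falls
  monotonically across stages, module 2 is U-shaped, ...) plus i.i.d.
  Gaussian noise. The harmonics are near-orthogonal by design: exactly
  mirrored profiles would be indistinguishable under an
  absolute-correlation threshold, so "contrasting" is implemented as
  orthogonal rather than negated. PPI tables connect same-module pairs
  with `p_within` and other pairs with `p_between`, scores uniform on a
  configurable range.

What the simulator does **not** emulate: sequence context (no FASTA/VCF;
counts and class labels only), inherited variants, CNVs, noncoding DNMs,
gene-length correlation with expression, cohort-specific batch effects
beyond what synonymous normalisation addresses, and real-brain
coexpression topology. Passing calibration tests therefore demonstrates
internal statistical correctness under the stated model, not robustness to
violations real data may present.

## Problem sizes used in testing

Desk-scale defaults keep the full suite fast while preserving the study's
structure: 2,000-gene universes (18,000+ supported via config), the five
published cohorts at 1/10 trio counts for the 50-seed FDR calibration, 500
null runs × 10,000 permutations for overlap calibration, and 100-run
permutation nulls for the network type-I checks.

## Known limitations

* The burden design is purely count-based with synonymous normalisation;
  no per-gene expected-count (denovolyzeR-style) burden model is included.
* TADA here is the de novo-only variant; transmitted/case-control
  components are out of scope.
* The Wald CI on log OR differs slightly from exact conditional CIs that
  some published tables print; the CI is descriptive output, not a test.
* Module labels are inputs (synthetic truth or user-supplied); WGCNA-style
  module detection itself is deliberately not re-implemented.
* Gene symbols are matched case-sensitively after whitespace trimming; no
  alias resolution.
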