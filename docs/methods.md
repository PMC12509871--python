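# Methods

## The problem

Genome-wide association scans in family-based designs test each variant
with a conditional score statistic that is robust to population
stratification, but — as in any association scan — linkage disequilibrium
(LD) spreads a causal variant's signal over its neighbours. `famfine`
couples the family-based score test with Bayesian statistical fine-mapping
so that a significant locus can be resolved into posterior inclusion
probabilities (PIPs) and signal clusters, assuming at least one causal
variant is present.

## Conditional score tests for nuclear families

For family *i* with offspring *j*, coded genotype `X_ij` and centred trait
`T_ij = Y_ij − µ`, the score statistic for one genetic factor is

    U = Σ_i Σ_j T_ij (X_ij − E[X_ij | S_i]),
    V = Σ_i T_i' Cov(X_i | S_i) T_i,        z = U / √V ,

where the moments are under the offspring-genotype distribution conditional
on the phenotypes and on the sufficient statistic `S_i` for the parental
genotypes. Conditioning removes all dependence on parental allele
frequencies, hence on population structure. Two conditioning cases are
implemented exactly:

* **Both parents genotyped** — offspring are independent Mendelian
  transmissions from the parental pair; conditional moments follow from the
  3×3×3 transmission table.
* **Missing parent(s)** — offspring are exchangeable given the (unknown)
  parents, so conditioning on the multiset of observed offspring genotypes
  leaves the uniform distribution over its distinct orderings. For *n*
  genotyped offspring with coded values `c`, each margin has mean `c̄` and
  variance `s²` (population variance of `c`), with pairwise covariance
  `−s²/(n−1)`; the row sums are fixed. A single genotyped offspring without
  genotyped parents is uninformative.

Families with exactly one genotyped parent fall back to the permutation
rule. This is valid (the conditional law given both parents is
exchangeable) but conservative: the typed parent's extra information, which
the full sufficient-statistic tables for partially typed parents would
recover, is discarded. This is a documented limitation; the two simulated
designs (trios, sibships with no parental genotypes) are handled exactly.

**Genetic factors.** Under the additive model each variant contributes one
factor (the allele2 dosage). Under recessive or dominant models each allele
defines its own coding, so every variant contributes two factors; the term
*factor* (rather than variant) is used throughout.

**Trait handling.** Binary traits use offset µ = 0 by default
(affected-only contributions, as in the classical transmission test);
quantitative traits default to µ = the offspring sample mean. Both are
overridable. Families with zero conditional variance or all-zero centred
trait contribute nothing and are not counted as informative; factors with
fewer than `min_informative` (default 10) informative families, zero total
variance, or a monomorphic coding are dropped from the panel.

**The null correlation matrix R** is the sample correlation of coded
genotypes across all genotyped offspring (pairwise-complete for
missingness), using each factor's own coding — an in-sample approximation
that ignores within-family dependence. R is regularized by flooring
eigenvalues at 1e-6 and renormalizing to a unit diagonal, so downstream
solves are well-posed.

## The locus model and Bayes factors

The z-score vector of a locus is modelled as

    Z ~ N(R β, R),

with β sparse: a configuration γ drawn from independent Bernoulli
inclusions (default probability 1/p for p factors, overridable per factor
through a prior table) and non-zero effects i.i.d. N(0, φ²). For a
configuration S this gives the closed form

    log BF(S) = −½ log det(I + φ² R_SS) + ½ z_S' (R_SS + φ⁻² I)⁻¹ z_S .

φ² defaults to the grid {0.04, 0.16, 0.64} with equal weights, mixed at the
model level; a single fixed value is supported. The grid spans effect sizes
from negligible to moderately large on the z-score scale; posterior results
for strongly significant loci are driven by the z-scores and are not
sensitive to this choice.

## Adaptive search over configurations

1. The null model and all single-factor models are evaluated exactly
   (batched linear algebra over the φ² grid).
2. **Candidate admission.** Factor *i* becomes a search candidate when the
   posterior odds of its single-factor model against the null,
   `φ_i = BF_i π_i/(1−π_i)`, exceed `10^{−λ}` — a threshold on the log
   scale; larger λ admits more factors — together with every factor whose
   squared correlation with an odds-admitted factor is at least
   `ld_admit_r2` (default 0.25). The LD clause ensures that everything the
   product approximation below would misjudge is explored exactly. The
   candidate set is a fixed function of the single-factor results, so no
   per-size recomputation is needed.
3. For sizes k = 2..K_max (default 5), every retained size-(k−1) model that
   is a subset of the candidate set (retained = within 4 log10 units of the
   current best model) is expanded by every candidate, deduplicated, and
   evaluated exactly. The level stops the search early when its total
   exact weight falls below `10^{−λ}` of the cumulative explored weight.
4. **Unexplored mass.** Every never-evaluated model M of size ≤ K_max is
   approximated by factorizing it into its candidate part D = M ∩ C and its
   noise part: the candidate part is scored by its exact explored weight
   (falling back to the product of single-factor weights for
   truncation-pruned candidate subsets, capped by the stopping rule's
   `10^{−λ}` certificate so correlated products cannot fabricate mass), and
   each noise factor multiplies in its single-factor weight. Per-size
   totals are elementary-symmetric-sum dynamic programmes in log10 space,
   run separately per φ²-grid component (the grid is mixed per model, not
   per factor) and combined with the mixture weights. For factors
   uncorrelated with all candidates this approximation is exact, because
   Bayes factors of independent blocks multiply at fixed φ².
5. PIPs sum each factor's exact explored inclusion weight and its
   approximated contributions, normalized by explored + approximated total
   mass. The procedure is fully deterministic.

The design in steps 2 and 4 is what makes the output insensitive to λ
(verified: max |ΔPIP| between λ = 1.3 and λ = 2.0 below 0.04 on
high-signal simulated loci, and machine-precision agreement with exhaustive
enumeration whenever λ makes the candidate set exhaustive). A candidate
rule based on *normalized* marginal inclusion was tried first and rejected:
a strong proxy can fall below any normalized cutoff when an even stronger
signal dominates the locus, and the plain product approximation of the
unexplored {signal, proxy} models then overestimates their weight by orders
of magnitude.

**Exhaustive enumeration** (`exhaustive_posterior`) evaluates every subset
up to size K (lexicographic order, guard at 2×10⁶ models) with the same
Bayes-factor and prior code, providing both a CAVIAR-style comparator
(K = 2) and the oracle for the adaptive search.

**Signal clusters.** Factors are agglomerated greedily in decreasing PIP
order: the highest unassigned factor with PIP ≥ `pip_floor` (default 0.01)
seeds a cluster; an unassigned factor joins only if its squared correlation
with *every* current member is ≥ `cluster_r2` (default 0.25)
(complete linkage; ties broken by panel order). The cluster PIP is the sum
of member PIPs.

## Synthetic data generator

The generator emulates a single fine-mapping locus in a family study:

* **Haplotypes** — `n_haplotypes` (default 10⁴) binary haplotypes over `p`
  (default 50) variants from a first-order Markov chain whose transition
  probabilities give adjacent-variant allele correlation `ld_rho` (default
  0.9) exactly where feasible; LD decays geometrically with distance, and
  allele frequencies (uniform on `maf_range`, default (0.05, 0.5)) co-vary
  along the locus so that near-perfect proxies (r² ≥ 0.8) occur as they do
  in real LD blocks.
* **Families** — random-mating parents, Mendelian transmission without
  within-locus recombination. Designs: `trio` (one offspring, both parents
  genotyped) and `sibpair` (two full siblings, parents masked).
* **Phenotypes** — quantitative: linear model on coded causal genotypes
  (additive dosage or recessive indicator) plus standard normal noise;
  binary: liability threshold at prevalence 0.1, with optional
  affected-offspring ascertainment. One or two causal variants; recessive
  effects restricted to variants with allele2 frequency ≥ 0.2 so
  homozygotes occur.
* **Default effect size 0.55** per causal variant: with 1000 trio families
  the analytic noncentrality `β√(n f(1−f)) / √(β² 2f(1−f) + 1)` puts the
  mean causal |z| near 7, so replicates land on both sides of the 5×10⁻⁸
  genome-wide threshold used for stratified evaluation. The
  cluster-recovery study uses 0.8 (mean |z| ≈ 9.7, clearly genome-wide).
* **Truth labels** — *Signal* = causal factor; *Proxy* = non-causal factor
  with r² ≥ 0.8 to some causal factor (measured on a reference diplotype
  sample from the pool); *Null* otherwise.

What the generator does **not** emulate: recombination within the locus,
genotyping error, missingness patterns of real pedigrees, ascertainment on
family history, multi-allelic variation, or realistic human LD beyond the
first-order Markov structure. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
performance on any particular real dataset.

## Evaluation

`evaluate_pips` joins fine-mapping output with truth labels and the
single-factor p-values: PIP distributions per Signal/Proxy/Null stratum
split by whether all causal factors reached P < 5×10⁻⁸; a decile PIP
calibration table with Clopper–Pearson intervals; and a precision–recall
curve with Signal as the positive class (average precision via
scikit-learn). Causal factors dropped from a panel count as
non-significant.

## Problem sizes used in the shipped studies

The validation suite and the reproduction script run, as the package's
standard check sizes: 2000 null replicates (500 per design × coding cell,
200 families each); 50 summary-level parity panels (p = 12, 2 causal,
moderate effects — the regime in which λ = 5 admits every factor, so the
comparison isolates algorithmic error); 40–48 full-pipeline replicates
across the eight scenario cells at the generator defaults (p = 50,
n_fam = 1000); 25 strong-signal cluster-recovery replicates.

## Numerical choices

* All model-space accumulation in log10 via stable log-sum-exp;
  subtractions guarded to return −∞ when cancellation exhausts precision.
* Bayes factors by batched Cholesky-free solves (`numpy.linalg.solve` /
  `slogdet` on stacked submatrices); `R_SS + φ⁻²I` is positive definite for
  the regularized R, with a 1e-8 ridge fallback.
* R eigenvalue floor 1e-6; duplicate factors therefore correlate at
  1 − O(10⁻⁶), not exactly 1.
* Greedy clustering ties broken by panel order; enumeration orders are
  lexicographic; identical inputs give byte-identical outputs.

## Known limitations

* One-genotyped-parent families are handled conservatively (see above).
* R from offspring genotypes ignores within-family correlation; this is an
  approximation inherited from the summary-statistic setting.
* The Bernoulli configuration prior is exchangeable given the per-factor
  probabilities; screening-based prior construction is out of scope (the
  injection hook `PriorSpec`/prior tables exists).
* Extended pedigrees, half-siblings, X-chromosome handling, phasing and
  multi-allelic variants are not supported.
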