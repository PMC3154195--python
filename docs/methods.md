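# Methods

## Model semantics

A candidate model is a set of SNP columns; it asserts that those SNPs
*jointly and exactly* are associated with the phenotype.  Structurally it
is the DAG with an edge from each model SNP into the disease node and no
other edges.  The hypothesis space attached to a size-n candidate is the
powerset of its SNPs: every subset, including the empty set (the null
model), is a competitor.  A pair model is therefore judged not only
against "no association" but against each of its loci carrying the
association alone — which is what lets the method separate genuine joint
effects from redundancy, where one locus proxies another.

The posterior is computed over this restricted space, not over all models
in the dataset.  P(Data) in the Bayes denominator is relative to the
candidate's own submodel lattice; posteriors of different candidates in a
scan are therefore each normalized in their own space and are comparable
as scores, not as a joint distribution.

## Likelihood

The likelihood of a model is the BDeu family score of the phenotype node
with the model's SNPs as parents.  The SNP nodes themselves are parentless
in every submodel, so their marginal scores are a model-independent
constant that cancels in every posterior ratio; we omit them rather than
carry a constant through log-space sums.

All scores are computed with `scipy.special.gammaln`; evidence sums use
log-sum-exp.  An empty count table scores log 1 = 0 (the empty product),
which makes likelihoods cancel exactly on a zero-row dataset — used in
tests as the degenerate case where posteriors reduce to prior shares.

The prior-equivalent sample size defaults to α = 54, a value with a
published track record of good epistasis discovery on two-locus benchmark
data; it is a configuration knob (`--alpha`), uniform over the 
r·q cells of each family.  Note one consequence of BDeu worth knowing:
with a *constant* phenotype column the likelihoods of different-sized
parent sets are *not* equal (the α/q prior spreading penalizes larger
parent-configuration spaces even when the child is constant), so
"uninformative data" in the exact-cancellation sense means zero rows, not
constant phenotype.

## Priors

The per-size model prior is πₘ = γ^(m−1) pᵐ with p the agnostic
single-SNP prior (default 10⁻⁴; 10⁻⁵ is the conservative alternative) and
γ = 0.06 the interaction factor.  This rule reduces to π₁ = p and yields
π₂ = 6×10⁻¹⁰ at p = 10⁻⁴ and 6×10⁻¹² at p = 10⁻⁵.  γ was chosen to
reproduce exactly those published 2-SNP prior values; the original
derivation behind them is not public, so the factor is an interpolating
constant, and `size_prior_overrides` accepts any alternative per-size
assignment (e.g. literature-derived priors for candidate genes).  The
null model receives 1 − Σₘ C(n,m)πₘ within a size-n candidate space, so
the prior over the lattice sums to one; a named error is raised if the
per-model priors exhaust the mass (possible only with large overrides).

## Evidence computation

Two routines compute the same 2ⁿ-term sum: the size-recursive
accumulation (initialize the accumulator with the null term
L(∅)·π∅, then for each m = 1..n visit all m-subsets by depth-first
extension) and a plain powerset iteration kept as an independent
cross-check; tests require agreement to 1e-9 in log space.  Candidates
are capped at 5 SNPs by default (`max_model_size`), both because 2ⁿ grows
and because larger joint hypotheses are not estimable at realistic sample
sizes.

Missing data: counts require fully observed parent configurations, so
each candidate is evaluated on its complete cases — individuals observed
at the phenotype and at the *union* of the candidate's SNPs, subset once
per candidate so that all submodels are scored on the same individuals
and the evidence mixture is coherent.  This is a per-model complete-case
policy, chosen over imputation for transparency; it discards information
when missingness is heavy and assumes missingness is unrelated to
phenotype and genotype.

## Baselines

The frequentist comparator is Pearson's chi-square on the joint genotype
× phenotype table (9 cells × 2 for a pair model), without continuity
correction; genotype combinations with zero total are dropped before
degrees of freedom are computed, rather than pooled.  Within one scan all
models face the same number of tests, so corrections cannot change the
ranking; Bonferroni and Šidák are exposed as explicit post-processing,
including per-size-family corrections (C(n,1), C(n,2), C(n,3) tests for
1-, 2-, 3-SNP families).

## Simulator

The generator emulates the standard two-locus pure-epistasis benchmark
design: a 3×3 penetrance table f[g1,g2] with flat marginal penetrances
under Hardy–Weinberg genotype weights, 18 unrelated HWE noise SNPs, and
retrospective 1:1 case-control sampling.  Rather than hard-coding
published penetrance tables (held in an external supplement), the package
constructs them: any candidate table is projected to pure epistasis by a
weighted two-way decomposition (keep grand mean + interaction, drop row
and column effects), then rescaled about its mean to a target broad-sense
heritability h² = Σ w (f−K)² / (K(1−K)); the variance scales
quadratically in the interaction amplitude while the prevalence K is
unchanged, so the factor is √(target/current).  Both operations raise
rather than clip if a penetrance would leave [0,1].  The default fixture
is an XOR-parity table at MAF 0.4 scaled to h² = 0.05; the hardest
published benchmark regime (h² = 0.01, MAF 0.2) is reachable the same
way.

Sampling is exact categorical draws from the Bayes-inverted genotype
distributions P(g1,g2 | case) ∝ w·f and P(g1,g2 | control) ∝ w·(1−f) —
unbiased and cheaper than prospective rejection.  Causal SNPs occupy
columns 0–1 (ids `M0P0`, `M0P1`), noise SNPs `N1..Nk` follow at MAF 0.3
by default; one seeded NumPy generator per dataset makes output fully
reproducible.  What the simulator does *not* emulate: linkage
disequilibrium between SNPs, covariates, genotyping error, population
structure, or missing genotypes.  Recovery results on this generator
therefore demonstrate the method's behaviour under clean pure epistasis,
not its robustness to real-data artefacts.

## Evaluation

ROC curves pool scores across datasets (true-model scores vs all
false-model scores) and sweep every observed score as an inclusive
threshold; the curve is the raw step function, no interpolation or convex
hull.  P-values enter with inverted orientation.  The headline discovery
number is the false-positive rate at full sensitivity — the cost of
flagging every true model.  "True model" means exact set equality with
the generating pair; supersets containing both causal loci count as
false.  Run summaries report, per sample size, how often the true model
ranked first and the mean posteriors of true, best-false and all-false
models.

The standard study conditions used by the test suite and the acceptance
script are: h² = 0.05, causal MAF 0.4, 18 noise SNPs, 1:1 sampling,
sample sizes 200/400/800/1600, 30 datasets per size, exhaustive scan of
all 1350 models up to size 3.  At these conditions the mean posterior of
the true pair rises from below 0.01 at n = 200 to ≈ 1 at n = 1600, and
flagging all true models at n = 1600 costs ~0% false positives by
posterior versus ~1% by chi-square p-value.

## Decision rule

With utilities U_TD, U_FD (≤0), U_TND, U_FND (≤0) for
true/false discovery and non-discovery, reporting maximizes expected
utility iff the posterior reaches
(U_TND − U_FD) / ((U_TD − U_FND) + (U_TND − U_FD)).
Defaults are symmetric (threshold 0.5) since no canonical utilities
exist; boundary ties report, favouring follow-up of potential
associations over missing them.

## Numerical and design choices

- Parent-configuration indexing is mixed-radix with the lowest SNP index
  most significant — score-invariant, pinned only for reproducible count
  tables.
- Ranking ties (exactly equal posteriors) break by model size then by
  SNP index tuple, so scans are byte-reproducible.
- Genotype arity is per-column (default 3); the phenotype may have more
  than two states, though binary is the exercised path.
- File formats: TSV/CSV with a named phenotype column, and the PLINK
  `.raw` additive dialect (PHENOTYPE 1/2 remapped to 0/1). Missing tokens
  `NA` / `-9`.
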