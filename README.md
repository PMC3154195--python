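# bnpp — Bayesian network posterior probabilities for disease-SNP models

`bnpp` evaluates single- and multi-locus disease-association hypotheses in
case-control genotype data by computing each model's **Bayesian Network
Posterior Probability (BNPP)**: the posterior probability that exactly that
set of SNPs, jointly, is associated with the phenotype, normalized over all
competing submodels.  It is aimed at statistical geneticists who want a
posterior probability — rather than a multiplicity-corrected p-value — for
candidate epistatic interactions, and at methodologists benchmarking
interaction-detection methods on simulated data.

## The method

A model *M* is a set of SNPs {S₁…Sₙ} drawn as parents of the disease node
*D* in a directed acyclic graph.  Its marginal likelihood is the BDeu
(Bayesian Dirichlet equivalent uniform) score of the disease node's family,

P(Data | M) = ∏ⱼ [Γ(α/q) / Γ(α/q + Nⱼ)] ∏ₖ [Γ(α/(r·q) + sⱼₖ) / Γ(α/(r·q))],

where *j* ranges over the q = 3ⁿ joint genotype configurations of the
model's SNPs, *k* over the r phenotype states, sⱼₖ are the observed counts
and α is the prior-equivalent sample size (default 54).  Every subset of
*M* — down to the empty (null) model — is a competing hypothesis; with
per-size model priors πₘ = γ^(m−1)·pᵐ (single-SNP prior p, interaction
factor γ = 0.06) and the null taking the complementary mass, Bayes' theorem
gives

BNPP(M) = P(Data | M) · π₍|M|₎ / Σ₍M′ ⊆ M₎ P(Data | M′) · π(M′).

The 2ⁿ-term evidence sum is computed exactly (models are capped at five
SNPs).  Because every submodel is weighed, a pair model cannot free-ride on
one strong single locus: the parsimonious submodel wins instead.

The package also ships the surrounding study machinery: a two-locus
**pure-epistasis simulator** (penetrance tables with provably flat marginal
penetrances, scaled to a target broad-sense heritability), an exhaustive
**scan** of all 1..k-SNP models with Pearson chi-square baselines and
Bonferroni/Šidák corrections, **ROC/recovery evaluation**, and an
expected-utility **reporting rule**.

## Worked example

Simulate 800 individuals (400 cases, 400 controls): two causal SNPs with a
purely epistatic penetrance (h² = 0.05, MAF 0.4) plus 18 noise SNPs, then
ask for the posterior of the causal pair:

```sh
$ bnpp simulate --seed 11 --n-cases 400 --n-controls 400 --out example.tsv
wrote 800 x 20 dataset to example.tsv

$ bnpp posterior --data example.tsv --model M0P0,M0P1
log evidence over 4 submodels: -540.984062
  {M0P0,M0P1}              posterior=1 log_lik=-519.7500 prior=6e-10 <- candidate
  {}                       posterior=3.31814e-07 log_lik=-555.9026 prior=1
  {M0P1}                   posterior=3.35969e-12 log_lik=-558.1929 prior=0.0001
  {M0P0}                   posterior=3.12381e-12 log_lik=-558.2657 prior=0.0001
```

Despite a prior of only 6×10⁻¹⁰ for any specific 2-SNP model, the data
raise the pair's posterior to ≈ 1: its log-likelihood beats the null by ≈ 36
nats, while each single-locus submodel scores *below* the null — the
signature of pure epistasis.  An exhaustive scan ranks the pair first among
all 210 one- and two-SNP models, with the single-SNP chi-square p-values of
the causal loci nowhere near significance:

```sh
$ bnpp scan --data example.tsv --max-size 2 --with-baseline --out scan.tsv
scanned 210 models; top: {M0P0,M0P1} posterior=1
```

`bnpp evaluate` repeats this over many simulated datasets and sample sizes
and reports recovery summaries and ROC curves; `bnpp decide` annotates a
scan with the expected-utility report/no-report decision.

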