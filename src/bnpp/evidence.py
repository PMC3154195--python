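"""Posterior probability of a disease-SNP model over its competing submodels.

A candidate model with SNP set {S_1..S_n} asserts that those SNPs *jointly*
(and only those) are associated with the disease.  Its competitors are the
2^n - 1 other subsets of the same SNPs, down to the null model in which
none is associated.  The evidence term

    P(Data) = sum over subsets M' of  P(Data | M') * pi(M')

is computed exactly — with at most 5 SNPs per model the 2^n enumeration is
cheap — and the posterior follows from Bayes' theorem:

    P(M | Data) = P(Data | M) * pi(M) / P(Data).

This posterior over the candidate's own submodel space is the BNPP
(Bayesian Network Posterior Probability).  P(Data | M') is the BDeu family
score of the disease node with M' as parents; the SNP nodes are parentless
in every submodel, so their own family scores are a shared constant that
cancels in the ratio and is omitted.

Two equivalent evidence routines are provided: the recursive accumulation
(size by size, visiting every m-subset by depth-first extension) and a
plain powerset iteration used as an independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import log
from typing import Iterable

import numpy as np
from scipy.special import logsumexp

from .datamodel import GenotypeDataset, ModelSpec, complete_cases
from .priors import PriorSpec, empty_model_prior, model_size_prior
from .scoring import PHENOTYPE, HyperparameterSpec, family_log_score, tabulate_family_counts

#: Models larger than this are refused: the 2^n submodel enumeration is
#: exact, and multi-locus hypotheses beyond five SNPs are not meaningful
#: at attainable sample sizes.
MAX_MODEL_SIZE = 5


class ModelTooLargeError(ValueError):
    pass


@dataclass(frozen=True)
class EvidenceBreakdown:
    """P(Data) over a candidate's submodel space, with per-subset terms.

    ``submodel_terms`` maps every subset (including the empty model) to a
    ``(log_likelihood, prior, log_weighted_term)`` triple; ``log_evidence``
    is the log-sum-exp of the weighted terms.
    """

    candidate: ModelSpec
    log_evidence: float
    submodel_terms: dict[ModelSpec, tuple[float, float, float]]


@dataclass
class PosteriorRecord:
    """One model's BNPP together with the quantities that produced it."""

    model: ModelSpec
    log_likelihood: float
    prior: float
    posterior: float
    rank: int | None = None


def _check_size(model: ModelSpec, max_model_size: int) -> None:
    if model.size > max_model_size:
        raise ModelTooLargeError(
            f"model has {model.size} SNPs; the exact submodel sum is capped "
            f"at {max_model_size} (override with max_model_size)"
        )


def model_log_likelihood(
    dataset: GenotypeDataset,
    model: ModelSpec,
    hyper: HyperparameterSpec,
) -> float:
    """log P(Data | model): BDeu score of the disease node given the model's SNPs.

    Computed on the complete-case subset for the model (individuals missing
    the phenotype or any model SNP are dropped).  The empty model scores
    the phenotype with no parents.
    """
    sub = complete_cases(dataset, model)
    counts = tabulate_family_counts(sub, PHENOTYPE, model)
    return family_log_score(counts, hyper)


def _subset_log_likelihoods(
    dataset: GenotypeDataset,
    model: ModelSpec,
    hyper: HyperparameterSpec,
    cache: dict[tuple[int, ...], float] | None = None,
) -> dict[ModelSpec, float]:
    """Family scores of every subset of ``model``, on shared complete cases.

    Complete-case subsetting uses the union of the candidate's SNPs once,
    so every submodel is scored on the same individuals and the evidence
    mixture is coherent.  ``cache`` (keyed by subset index tuple) is only
    consulted for datasets with no missing data, where the complete-case
    subset is the whole dataset regardless of the candidate.
    """
    usable_cache = cache if (cache is not None and not dataset.has_missing()) else None
    sub = complete_cases(dataset, model)
    out: dict[ModelSpec, float] = {}
    for subset in model.subsets():
        key = subset.snp_indices
        if usable_cache is not None and key in usable_cache:
            out[subset] = usable_cache[key]
            continue
        ll = family_log_score(tabulate_family_counts(sub, PHENOTYPE, subset), hyper)
        out[subset] = ll
        if usable_cache is not None:
            usable_cache[key] = ll
    return out


def _assemble(
    candidate: ModelSpec,
    loglikes: dict[ModelSpec, float],
    subset_order: Iterable[ModelSpec],
    priors: PriorSpec,
) -> EvidenceBreakdown:
    pi0 = empty_model_prior(priors, candidate.size)
    terms: dict[ModelSpec, tuple[float, float, float]] = {}
    for subset in subset_order:
        prior = pi0 if subset.size == 0 else model_size_prior(subset.size, priors)
        ll = loglikes[subset]
        terms[subset] = (ll, prior, ll + log(prior))
    log_ev = float(logsumexp([t[2] for t in terms.values()]))
    return EvidenceBreakdown(candidate=candidate, log_evidence=log_ev, submodel_terms=terms)


def log_evidence_recursive(
    dataset: GenotypeDataset,
    model: ModelSpec,
    priors: PriorSpec,
    hyper: HyperparameterSpec,
    max_model_size: int = MAX_MODEL_SIZE,
    _cache: dict[tuple[int, ...], float] | None = None,
) -> EvidenceBreakdown:
    """Evidence over the candidate's submodels by size-recursive accumulation.

    The accumulator starts from the null model's term L(empty) * pi_empty;
    then for each size m = 1..n every m-subset is visited by depth-first
    extension of a partial model and contributes L(M') * pi_m.
    """
    _check_size(model, max_model_size)
    loglikes = _subset_log_likelihoods(dataset, model, hyper, _cache)

    order: list[ModelSpec] = [ModelSpec()]

    def visit(partial: list[int], start: int, m: int) -> None:
        if len(partial) == m:
            order.append(ModelSpec(partial))
            return
        for i in range(start, model.size):
            partial.append(model.snp_indices[i])
            visit(partial, i + 1, m)
            partial.pop()

    for m in range(1, model.size + 1):
        visit([], 0, m)
    return _assemble(model, loglikes, order, priors)


def log_evidence_bruteforce(
    dataset: GenotypeDataset,
    model: ModelSpec,
    priors: PriorSpec,
    hyper: HyperparameterSpec,
    max_model_size: int = MAX_MODEL_SIZE,
) -> EvidenceBreakdown:
    """Evidence by explicit powerset iteration; oracle for the recursion."""
    _check_size(model, max_model_size)
    loglikes = _subset_log_likelihoods(dataset, model, hyper)
    order = [
        ModelSpec(c)
        for m in range(model.size + 1)
        for c in combinations(model.snp_indices, m)
    ]
    return _assemble(model, loglikes, order, priors)


def bnpp_posterior(
    dataset: GenotypeDataset,
    model: ModelSpec,
    priors: PriorSpec,
    hyper: HyperparameterSpec,
    max_model_size: int = MAX_MODEL_SIZE,
    _cache: dict[tuple[int, ...], float] | None = None,
) -> PosteriorRecord:
    """BNPP of one candidate model: its posterior among its own submodels."""
    if model.size < 1:
        raise ValueError("BNPP is defined for models with at least one SNP")
    breakdown = log_evidence_recursive(
        dataset, model, priors, hyper, max_model_size, _cache
    )
    ll, prior, weighted = breakdown.submodel_terms[model]
    return PosteriorRecord(
        model=model,
        log_likelihood=ll,
        prior=prior,
        posterior=float(np.exp(weighted - breakdown.log_evidence)),
    )


def submodel_posteriors(breakdown: EvidenceBreakdown) -> list[PosteriorRecord]:
    """Posterior of every submodel in a breakdown, ranked.

    Posteriors sum to one over the 2^n subsets.  Sorting is by posterior
    descending; ties go to the smaller model, then lexicographic indices —
    comparing a candidate against the simpler hypotheses that a subset of
    its loci carries the whole association.
    """
    records = [
        PosteriorRecord(
            model=subset,
            log_likelihood=ll,
            prior=prior,
            posterior=float(np.exp(weighted - breakdown.log_evidence)),
        )
        for subset, (ll, prior, weighted) in breakdown.submodel_terms.items()
    ]
    records.sort(key=lambda r: (-r.posterior, r.model.size, r.model.snp_indices))
    for i, rec in enumerate(records):
        rec.rank = i + 1
    return records
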