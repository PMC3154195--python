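"""Exhaustive posterior scan of all small SNP models, plus frequentist baselines.

A scan enumerates every 1..k-SNP model over the dataset's columns (for a
20-SNP panel at k = 3 that is 20 + 190 + 1140 = 1350 models), computes
each model's BNPP, optionally attaches a Pearson chi-square p-value on the
model's joint genotype x phenotype contingency table, and returns the
records ranked by posterior.

Multiple-testing corrections (Bonferroni, Sidak) are deliberately *not*
applied inside the scan: within one scan every model faces the same
correction, which cannot change the ranking.  They are exposed as explicit
post-processing for cross-study comparison, including the per-size-family
variant in which 1-, 2- and 3-SNP models are corrected by their own family
sizes C(n,1), C(n,2), C(n,3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .datamodel import MISSING, GenotypeDataset, ModelSpec, complete_cases
from .evidence import MAX_MODEL_SIZE, PosteriorRecord, bnpp_posterior
from .priors import PriorSpec
from .scoring import PHENOTYPE, HyperparameterSpec, tabulate_family_counts


class UndefinedTestError(ValueError):
    """The contingency table has fewer than two nonempty rows or columns."""


@dataclass
class ScanResult:
    """Ranked posterior records for every enumerated model."""

    records: list[PosteriorRecord]
    baseline_pvalues: dict[ModelSpec, float] | None
    max_size: int
    priors: PriorSpec
    hyper: HyperparameterSpec
    snp_ids: list[str] = field(default_factory=list)

    def posterior_of(self, model: ModelSpec) -> float:
        for rec in self.records:
            if rec.model == model:
                return rec.posterior
        raise KeyError(f"model {model} not in scan")

    def to_frame(self) -> pd.DataFrame:
        """Tabular view: one row per model, ranked, TSV-ready."""
        rows = []
        for rec in self.records:
            row = {
                "model_id": rec.model.label(),
                "snps": ",".join(
                    self.snp_ids[i] if self.snp_ids else str(i)
                    for i in rec.model
                ),
                "size": rec.model.size,
                "log_likelihood": rec.log_likelihood,
                "prior": rec.prior,
                "posterior": rec.posterior,
                "rank": rec.rank,
            }
            if self.baseline_pvalues is not None:
                row["pvalue"] = self.baseline_pvalues[rec.model]
            rows.append(row)
        return pd.DataFrame(rows)


def enumerate_models(n_snps: int, max_size: int) -> Iterator[ModelSpec]:
    """Every SNP subset of size 1..max_size, in (size, lexicographic) order."""
    if not 1 <= max_size <= n_snps:
        raise ValueError(f"need 1 <= max_size <= n_snps, got {max_size} > {n_snps}")
    for m in range(1, max_size + 1):
        for combo in combinations(range(n_snps), m):
            yield ModelSpec(combo)


def pearson_chisq_pvalue(dataset: GenotypeDataset, model: ModelSpec) -> float:
    """Pearson chi-square p-value for the model's joint genotype table.

    The table crosses the joint genotype combinations of the model's SNPs
    (9 cells for a SNP pair) against the phenotype classes, on the model's
    complete cases.  Genotype combinations with zero total are dropped
    before computing degrees of freedom, which are then
    (combinations - 1) x (phenotype classes - 1); no continuity correction.
    """
    if model.size < 1:
        raise ValueError("chi-square test needs at least one SNP")
    sub = complete_cases(dataset, model)
    table = tabulate_family_counts(sub, PHENOTYPE, model).counts
    table = table[table.sum(axis=1) > 0]
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise UndefinedTestError(
            "need at least 2 nonempty genotype combinations and 2 phenotype "
            f"classes; table shape after dropping empties is {table.shape}"
        )
    _, p, _, _ = chi2_contingency(table, correction=False)
    return float(p)


def bonferroni(p: float, n_tests: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * n)."""
    _check_p(p, n_tests)
    return min(1.0, p * n_tests)


def sidak(p: float, n_tests: int) -> float:
    """Sidak-corrected p-value: 1 - (1 - p)^n."""
    _check_p(p, n_tests)
    return float(-np.expm1(n_tests * np.log1p(-p))) if p < 1 else 1.0


def _check_p(p: float, n_tests: int) -> None:
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of [0,1]: {p}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")


def scan(
    dataset: GenotypeDataset,
    max_size: int,
    priors: PriorSpec,
    hyper: HyperparameterSpec,
    with_baseline: bool = False,
    max_model_size: int = MAX_MODEL_SIZE,
) -> ScanResult:
    """Compute the BNPP of every 1..max_size-SNP model over the dataset.

    Output order is deterministic: posterior descending, ties broken by
    model size then lexicographic SNP indices.  For datasets with no
    missing genotypes the subset likelihoods shared among overlapping
    candidates are computed once.
    """
    cache: dict[tuple[int, ...], float] = {}
    records: list[PosteriorRecord] = []
    pvalues: dict[ModelSpec, float] | None = {} if with_baseline else None
    for model in enumerate_models(dataset.n_snps, max_size):
        records.append(
            bnpp_posterior(dataset, model, priors, hyper, max_model_size, _cache=cache)
        )
        if pvalues is not None:
            pvalues[model] = pearson_chisq_pvalue(dataset, model)
    records.sort(key=lambda r: (-r.posterior, r.model.size, r.model.snp_indices))
    for i, rec in enumerate(records):
        rec.rank = i + 1
    return ScanResult(
        records=records,
        baseline_pvalues=pvalues,
        max_size=max_size,
        priors=priors,
        hyper=hyper,
        snp_ids=list(dataset.snp_ids),
    )
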