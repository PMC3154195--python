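"""Prior probabilities of m-SNP association models.

In an agnostic genome-wide study the prior that any one named SNP is
associated with the disease is small; surveyed estimates put it between
1e-5 and 1e-4.  Multi-locus models are rarer still.  The default rule used
here is

    pi_m = gamma^(m-1) * p^m

with p the single-SNP prior and gamma an interaction discount (default
0.06), so pi_1 = p, pi_2 = gamma * p^2 (6e-10 at p = 1e-4, 6e-12 at
p = 1e-5), and so on.  All m-SNP models share the same prior.  Explicit
per-size overrides replace the rule where an analyst has real prior
information (e.g. literature-derived priors for a known candidate gene).

The null model's prior over a candidate space of n SNPs is the complement
of the prior mass assigned to the C(n, m) models of each size, so the prior
over all 2^n submodels sums to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb


class PriorError(ValueError):
    pass


class NonpositiveNullPriorError(PriorError):
    """Per-model priors are too large: the null model would get mass <= 0."""


@dataclass(frozen=True)
class PriorSpec:
    """Agnostic per-SNP prior plus the rule deriving per-size model priors."""

    snp_prior: float = 1e-4
    interaction_factor: float = 0.06
    size_prior_overrides: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.snp_prior < 1:
            raise PriorError(f"snp_prior must be in (0,1), got {self.snp_prior}")
        if self.interaction_factor <= 0:
            raise PriorError(
                f"interaction_factor must be > 0, got {self.interaction_factor}"
            )
        for m, v in self.size_prior_overrides.items():
            if not 0 < v < 1:
                raise PriorError(f"override for size {m} must be in (0,1), got {v}")


def model_size_prior(m: int, spec: PriorSpec) -> float:
    """Prior probability of one specific m-SNP model."""
    if m < 1:
        raise PriorError(f"model size must be >= 1, got {m}")
    if m in spec.size_prior_overrides:
        return spec.size_prior_overrides[m]
    return spec.interaction_factor ** (m - 1) * spec.snp_prior**m


def empty_model_prior(spec: PriorSpec, n: int) -> float:
    """Prior of the null model within a size-n candidate's submodel space.

    Returns 1 - sum_{m=1..n} C(n, m) * pi_m; raises if the alternatives
    already exhaust the prior mass.
    """
    if n < 0:
        raise PriorError(f"candidate size must be >= 0, got {n}")
    total_alternatives = sum(
        comb(n, m) * model_size_prior(m, spec) for m in range(1, n + 1)
    )
    p0 = 1.0 - total_alternatives
    if p0 <= 0:
        raise NonpositiveNullPriorError(
            f"per-model priors leave no mass for the null model "
            f"(alternatives sum to {total_alternatives})"
        )
    return p0
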