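"""Case-control data with two-locus pure epistasis and HWE noise SNPs.

The generator emulates the classic benchmark design for epistasis
detection: two causal SNPs whose *joint* genotype determines disease risk
through a 3x3 penetrance table f[g1][g2] = P(D=1 | g1, g2), while each
SNP's *marginal* penetrance — the risk averaged over the partner's
Hardy-Weinberg genotype distribution — is flat.  Neither locus is
individually predictive; only the pair carries signal.  The remaining
SNPs are independent HWE noise, and cases/controls are sampled
retrospectively at a fixed ratio (1:1 by default).

Arbitrary penetrance tables are made purely epistatic by a weighted
two-way decomposition: under HWE weights w[g1][g2] = u[g1] * v[g2] the
table splits into grand mean + row effects + column effects + interaction,
and keeping only grand mean + interaction zeroes both marginals.  The
interaction can then be rescaled to hit a target broad-sense heritability

    h2 = sum_g w (f - K)^2 / (K (1 - K)),   K = sum_g w f  (prevalence),

so fixtures can reproduce regimes such as the hardest published two-locus
benchmarks (h2 = 0.01, minor-allele frequency 0.2).

Sampling is exact: genotype pairs for cases are drawn from
P(g1, g2 | D=1) = w f / K, for controls from w (1 - f) / (1 - K) — the
retrospective (Bayes-inverted) distributions — with no rejection step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .datamodel import GenotypeDataset

#: Tolerance on the flat-marginal (pure epistasis) certificate.
MARGINAL_TOL = 1e-9


class SimulationError(ValueError):
    pass


class ProjectionRangeError(SimulationError):
    """Removing marginal effects pushed a penetrance outside [0, 1]."""


class UnreachableHeritabilityError(SimulationError):
    """The target h2 needs penetrances outside [0, 1]."""


def hwe_frequencies(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype frequencies for 0/1/2 minor-allele copies."""
    if not 0 < maf <= 0.5:
        raise SimulationError(f"minor-allele frequency must be in (0, 0.5], got {maf}")
    p = maf
    return np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])


@dataclass(frozen=True)
class PenetranceModel:
    """A 3x3 two-locus penetrance table with its HWE genotype weights."""

    table: np.ndarray
    maf_a: float
    maf_b: float

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        if table.shape != (3, 3):
            raise SimulationError(f"penetrance table must be 3x3, got {table.shape}")
        if np.any(table < 0) or np.any(table > 1):
            raise SimulationError("penetrances must lie in [0, 1]")
        object.__setattr__(self, "table", table)
        hwe_frequencies(self.maf_a)
        hwe_frequencies(self.maf_b)

    @property
    def weights(self) -> np.ndarray:
        """Joint HWE genotype-pair frequencies w[g1, g2]; sum to 1."""
        return np.outer(hwe_frequencies(self.maf_a), hwe_frequencies(self.maf_b))

    @property
    def prevalence(self) -> float:
        """K = sum w f, the population disease probability."""
        return float(np.sum(self.weights * self.table))

    def marginal_penetrances(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-genotype disease risk of each locus, partner averaged out."""
        u = hwe_frequencies(self.maf_a)
        v = hwe_frequencies(self.maf_b)
        return self.table @ v, u @ self.table

    def is_purely_epistatic(self, tol: float = MARGINAL_TOL) -> bool:
        """True when both marginal penetrances are constant (no single-locus effect)."""
        ma, mb = self.marginal_penetrances()
        return bool(np.ptp(ma) <= tol and np.ptp(mb) <= tol)


@dataclass(frozen=True)
class SimulationConfig:
    """Sampling design: cohort sizes, noise panel, minor-allele frequencies."""

    n_cases: int = 100
    n_controls: int = 100
    n_noise_snps: int = 18
    noise_maf: float | tuple[float, ...] = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0 or self.n_cases + self.n_controls == 0:
            raise SimulationError("need a positive number of individuals")
        if self.n_noise_snps < 0:
            raise SimulationError("n_noise_snps must be >= 0")
        mafs = self.noise_mafs
        if len(mafs) != self.n_noise_snps:
            raise SimulationError(
                f"{len(mafs)} noise MAFs for {self.n_noise_snps} noise SNPs"
            )
        for m in mafs:
            hwe_frequencies(m)

    @property
    def noise_mafs(self) -> tuple[float, ...]:
        if isinstance(self.noise_maf, (int, float)):
            return (float(self.noise_maf),) * self.n_noise_snps
        return tuple(float(m) for m in self.noise_maf)


def _decompose(candidate: np.ndarray, maf_a: float, maf_b: float):
    """Weighted two-way split: grand mean, row/column margins, interaction."""
    u = hwe_frequencies(maf_a)
    v = hwe_frequencies(maf_b)
    row = candidate @ v          # marginal penetrance of locus A
    col = u @ candidate          # marginal penetrance of locus B
    mean = float(u @ candidate @ v)
    interaction = candidate - row[:, None] - col[None, :] + mean
    return mean, row, col, interaction


def project_pure_epistasis(
    candidate: np.ndarray, maf_a: float, maf_b: float
) -> PenetranceModel:
    """Strip single-locus effects from a penetrance table.

    Returns grand mean + interaction of the weighted two-way decomposition;
    both marginal penetrances of the result are exactly the prevalence.
    Raises :class:`ProjectionRangeError` if the projection leaves [0, 1].
    """
    candidate = np.asarray(candidate, dtype=float)
    if candidate.shape != (3, 3):
        raise SimulationError(f"candidate table must be 3x3, got {candidate.shape}")
    if np.any(candidate < 0) or np.any(candidate > 1):
        raise SimulationError("candidate penetrances must lie in [0, 1]")
    mean, _, _, interaction = _decompose(candidate, maf_a, maf_b)
    table = mean + interaction
    if np.any(table < 0) or np.any(table > 1):
        raise ProjectionRangeError(
            "interaction too large for the baseline penetrance: projected "
            f"table spans [{table.min():.4g}, {table.max():.4g}]"
        )
    return PenetranceModel(table=table, maf_a=maf_a, maf_b=maf_b)


def broad_sense_heritability(model: PenetranceModel) -> float:
    """Fraction of disease-liability variance explained by genotype.

    h2 = sum w (f - K)^2 / (K (1 - K)) with K the prevalence; equals 0 for
    a flat table and 1 for a deterministic 0/1 table at K = 1/2.
    """
    k = model.prevalence
    if k <= 0 or k >= 1:
        raise SimulationError(f"heritability undefined at prevalence {k}")
    w = model.weights
    return float(np.sum(w * (model.table - k) ** 2) / (k * (1 - k)))


def scale_to_heritability(model: PenetranceModel, target_h2: float) -> PenetranceModel:
    """Rescale the table's variation about its mean to hit a target h2.

    Penetrance variance scales quadratically in the interaction amplitude
    while the prevalence stays fixed, so the scale factor is
    sqrt(target / current).  Raises if the rescaled table would need
    clipping to [0, 1] (clipping would break the flat-marginal property).
    """
    if not 0 < target_h2 < 1:
        raise SimulationError(f"target h2 must be in (0, 1), got {target_h2}")
    current = broad_sense_heritability(model)
    if current < 1e-24:  # numerically flat table
        raise SimulationError("model has zero interaction; nothing to rescale")
    k = model.prevalence
    factor = float(np.sqrt(target_h2 / current))
    table = k + factor * (model.table - k)
    if np.any(table < 0) or np.any(table > 1):
        raise UnreachableHeritabilityError(
            f"h2 = {target_h2} unreachable: rescaled penetrances span "
            f"[{table.min():.4g}, {table.max():.4g}]"
        )
    return PenetranceModel(table=table, maf_a=model.maf_a, maf_b=model.maf_b)


def xor_penetrance(
    baseline: float = 0.1,
    effect: float = 0.1,
    maf_a: float = 0.5,
    maf_b: float = 0.5,
) -> PenetranceModel:
    """XOR-pattern table: risk raised when the loci's allele counts differ in parity.

    At maf 0.5/0.5 the pattern is already marginal-free; at other MAFs it is
    projected.  A convenient seed table for :func:`scale_to_heritability`.
    """
    g = np.arange(3)
    candidate = baseline + effect * ((g[:, None] + g[None, :]) % 2)
    return project_pure_epistasis(candidate, maf_a, maf_b)


def case_control_genotype_distributions(
    model: PenetranceModel,
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective genotype-pair distributions P(g1,g2|case), P(g1,g2|control)."""
    w = model.weights
    f = model.table
    case_mass = w * f
    ctrl_mass = w * (1 - f)
    return (
        case_mass / case_mass.sum() if case_mass.sum() > 0 else case_mass,
        ctrl_mass / ctrl_mass.sum() if ctrl_mass.sum() > 0 else ctrl_mass,
    )


#: Column ids for the two causal loci, placed first in the genotype matrix.
CAUSAL_IDS = ("M0P0", "M0P1")


def simulate_case_control(
    model: PenetranceModel, config: SimulationConfig
) -> GenotypeDataset:
    """Draw a case-control dataset from a penetrance model.

    The causal pair occupies columns 0 and 1 (ids "M0P0", "M0P1"); noise
    SNPs "N1".."Nk" follow, i.i.d. HWE and independent of phenotype.  Rows
    are all cases first, then all controls.  Fully reproducible from
    ``config.seed``.
    """
    if config.n_cases > 0 and np.all(model.table == 0):
        raise SimulationError("penetrance is identically 0: no cases can exist")
    if config.n_controls > 0 and np.all(model.table == 1):
        raise SimulationError("penetrance is identically 1: no controls can exist")
    case_dist, ctrl_dist = case_control_genotype_distributions(model)
    case_dist = case_dist / case_dist.sum() if config.n_cases else case_dist
    ctrl_dist = ctrl_dist / ctrl_dist.sum() if config.n_controls else ctrl_dist

    rng = np.random.default_rng(config.seed)
    n = config.n_cases + config.n_controls
    parts = []
    if config.n_cases:
        parts.append(rng.choice(9, size=config.n_cases, p=case_dist.ravel()))
    if config.n_controls:
        parts.append(rng.choice(9, size=config.n_controls, p=ctrl_dist.ravel()))
    pair_flat = np.concatenate(parts)
    geno = np.empty((n, 2 + config.n_noise_snps), dtype=np.int64)
    geno[:, 0] = pair_flat // 3
    geno[:, 1] = pair_flat % 3
    for j, maf in enumerate(config.noise_mafs):
        geno[:, 2 + j] = rng.binomial(2, maf, size=n)
    phenotype = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int64), np.zeros(config.n_controls, dtype=np.int64)]
    )
    snp_ids = list(CAUSAL_IDS) + [f"N{j + 1}" for j in range(config.n_noise_snps)]
    return GenotypeDataset(
        genotypes=geno,
        phenotype=phenotype,
        snp_ids=snp_ids,
    )


def write_metadata(
    model: PenetranceModel, config: SimulationConfig, path: str | Path
) -> Path:
    """Sidecar YAML recording the generating model alongside a dataset file."""
    path = Path(path)
    meta = {
        "penetrance_table": [[float(x) for x in row] for row in model.table],
        "maf_a": model.maf_a,
        "maf_b": model.maf_b,
        "prevalence": model.prevalence,
        "broad_sense_heritability": broad_sense_heritability(model),
        "purely_epistatic": bool(model.is_purely_epistatic()),
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_noise_snps": config.n_noise_snps,
        "noise_maf": list(config.noise_mafs),
        "seed": config.seed,
        "causal_snp_ids": list(CAUSAL_IDS),
    }
    path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return path
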