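"""Core data types for case-control genotype data and association models.

A :class:`GenotypeDataset` holds an individuals x SNPs matrix of discrete
genotypes (0/1/2 copies of the minor allele by default) together with a
binary phenotype vector (0 = control, 1 = case).  A :class:`ModelSpec` is a
set of SNP column indices naming one disease-association hypothesis: the
model in which exactly those SNPs, jointly, are parents of the disease node.

Readers and writers support plain TSV/CSV tables (header row, one phenotype
column, one column per SNP) and the PLINK ``.raw`` additive-coding dialect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel used internally for a missing genotype or phenotype.
MISSING = -1

#: Tokens recognised as missing values in text files.
MISSING_TOKENS = ("NA", "-9")


class DatasetError(ValueError):
    """Base class for genotype-table validation errors."""


class MissingPhenotypeColumnError(DatasetError):
    """The named phenotype column is absent from the file."""


class NonIntegerGenotypeError(DatasetError):
    """A genotype cell is neither an integer nor a recognised missing token."""


class GenotypeRangeError(DatasetError):
    """A genotype value is outside 0..arity-1 for its SNP."""


class DuplicateSnpIdError(DatasetError):
    """Two SNP columns share the same identifier."""


@dataclass(frozen=True)
class ModelSpec:
    """A disease-association model: a set of SNP column indices.

    The empty model (``size == 0``) is the null hypothesis that none of the
    candidate SNPs is associated with the phenotype.
    """

    snp_indices: tuple[int, ...]

    def __init__(self, snp_indices: Iterable[int] = ()):
        idx = tuple(sorted(int(i) for i in snp_indices))
        if len(set(idx)) != len(idx):
            raise ValueError(f"duplicate SNP indices in model: {idx}")
        if idx and idx[0] < 0:
            raise ValueError(f"negative SNP index in model: {idx}")
        object.__setattr__(self, "snp_indices", idx)

    @property
    def size(self) -> int:
        return len(self.snp_indices)

    def __iter__(self):
        return iter(self.snp_indices)

    def __contains__(self, i: int) -> bool:
        return i in self.snp_indices

    def subsets(self) -> "Iterable[ModelSpec]":
        """Yield every submodel (all subsets, including the empty model)."""
        from itertools import combinations

        for m in range(self.size + 1):
            for combo in combinations(self.snp_indices, m):
                yield ModelSpec(combo)

    def label(self, snp_ids: Sequence[str] | None = None) -> str:
        if not self.snp_indices:
            return "{}"
        if snp_ids is None:
            return "{" + ",".join(str(i) for i in self.snp_indices) + "}"
        return "{" + ",".join(snp_ids[i] for i in self.snp_indices) + "}"


@dataclass
class GenotypeDataset:
    """Individuals x SNPs genotype matrix plus a discrete phenotype vector."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: list[str]
    snp_arities: np.ndarray = field(default=None)  # type: ignore[assignment]
    phenotype_arity: int = 2

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise DatasetError("genotype matrix must be 2-dimensional")
        self.phenotype = np.asarray(self.phenotype, dtype=np.int64)
        if self.snp_arities is None:
            self.snp_arities = np.full(self.genotypes.shape[1], 3, dtype=np.int64)
        else:
            self.snp_arities = np.asarray(self.snp_arities, dtype=np.int64)
        self.snp_ids = list(self.snp_ids)
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def validate(self) -> None:
        n, s = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise DatasetError(
                f"phenotype length {self.phenotype.shape} != individual count {n}"
            )
        if len(self.snp_ids) != s:
            raise DatasetError(f"{len(self.snp_ids)} snp_ids for {s} genotype columns")
        if len(set(self.snp_ids)) != s:
            raise DuplicateSnpIdError("snp_ids are not unique")
        if self.snp_arities.shape != (s,):
            raise DatasetError("snp_arities length mismatch")
        for j in range(s):
            col = self.genotypes[:, j]
            obs = col[col != MISSING]
            if obs.size and (obs.min() < 0 or obs.max() >= self.snp_arities[j]):
                raise GenotypeRangeError(
                    f"SNP {self.snp_ids[j]!r} has value outside "
                    f"0..{self.snp_arities[j] - 1}"
                )
        obs_ph = self.phenotype[self.phenotype != MISSING]
        if obs_ph.size and (obs_ph.min() < 0 or obs_ph.max() >= self.phenotype_arity):
            raise GenotypeRangeError(
                f"phenotype value outside 0..{self.phenotype_arity - 1}"
            )

    def equals(self, other: "GenotypeDataset") -> bool:
        return (
            np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotype, other.phenotype)
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.snp_arities, other.snp_arities)
            and self.phenotype_arity == other.phenotype_arity
        )

    def has_missing(self) -> bool:
        return bool((self.genotypes == MISSING).any() or (self.phenotype == MISSING).any())


def complete_cases(dataset: GenotypeDataset, model: ModelSpec) -> GenotypeDataset:
    """Subset to individuals fully observed at the phenotype and the model's SNPs.

    Columns outside the model are retained unchanged (including any missing
    values they carry); only rows are dropped.  Counting the disease node's
    family requires every parent configuration to be fully observed, so each
    model is evaluated on its own complete cases.
    """
    for i in model:
        if i >= dataset.n_snps:
            raise IndexError(f"model SNP index {i} out of bounds")
    keep = dataset.phenotype != MISSING
    for i in model:
        keep &= dataset.genotypes[:, i] != MISSING
    if keep.all():
        return dataset
    return GenotypeDataset(
        genotypes=dataset.genotypes[keep],
        phenotype=dataset.phenotype[keep],
        snp_ids=dataset.snp_ids,
        snp_arities=dataset.snp_arities,
        phenotype_arity=dataset.phenotype_arity,
    )


# ---------------------------------------------------------------------------
# Text table I/O

_PLINK_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


def _parse_cell(token: str, what: str) -> int:
    token = token.strip()
    if token in MISSING_TOKENS or token == "":
        return MISSING
    try:
        return int(token)
    except ValueError:
        # PLINK .raw exports can carry float-formatted integers ("2.0")
        try:
            f = float(token)
        except ValueError:
            raise NonIntegerGenotypeError(f"non-integer {what} cell: {token!r}") from None
        if f != int(f):
            raise NonIntegerGenotypeError(f"non-integer {what} cell: {token!r}") from None
        return int(f)


def read_genotype_table(
    path: str | Path,
    format: str = "tsv",
    phenotype_column: str = "pheno",
    snp_arity: int = 3,
    phenotype_arity: int = 2,
) -> GenotypeDataset:
    """Read a delimited genotype table into a :class:`GenotypeDataset`.

    ``format`` is one of ``tsv``, ``csv`` or ``plink_raw``.  For the plain
    formats the file has a header row with one column named
    ``phenotype_column`` and one column per SNP; cells are integers or a
    missing token ("NA"/"-9").  The PLINK ``.raw`` dialect is
    whitespace-delimited with leading FID/IID/PAT/MAT/SEX/PHENOTYPE columns
    and PHENOTYPE coded 1 = control / 2 = case (remapped to 0/1).
    """
    path = Path(path)
    # duplicate detection must see the raw header; pandas silently mangles
    # repeated column names
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
    raw_header = header_line.split(
        {"tsv": "\t", "csv": ","}.get(format)  # None => any whitespace
    )
    if len(set(raw_header)) != len(raw_header):
        raise DuplicateSnpIdError("duplicate column ids in file header")
    if format == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
        for col in _PLINK_META:
            if col not in df.columns:
                raise MissingPhenotypeColumnError(
                    f"PLINK .raw file lacks required column {col!r}"
                )
        snp_cols = [c for c in df.columns if c not in _PLINK_META]
        pheno_raw = np.array(
            [_parse_cell(v, "phenotype") for v in df["PHENOTYPE"]], dtype=np.int64
        )
        # 1/2 -> 0/1; missing stays missing
        phenotype = np.where(pheno_raw == MISSING, MISSING, pheno_raw - 1)
    else:
        sep = {"tsv": "\t", "csv": ","}.get(format)
        if sep is None:
            raise ValueError(f"unknown format: {format!r}")
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        if phenotype_column not in df.columns:
            raise MissingPhenotypeColumnError(
                f"phenotype column {phenotype_column!r} not in {list(df.columns)}"
            )
        snp_cols = [c for c in df.columns if c != phenotype_column]
        phenotype = np.array(
            [_parse_cell(v, "phenotype") for v in df[phenotype_column]], dtype=np.int64
        )

    if len(set(snp_cols)) != len(snp_cols):
        raise DuplicateSnpIdError("duplicate SNP column ids in file")
    geno = np.empty((len(df), len(snp_cols)), dtype=np.int64)
    for j, c in enumerate(snp_cols):
        geno[:, j] = [_parse_cell(v, "genotype") for v in df[c]]
    return GenotypeDataset(
        genotypes=geno,
        phenotype=phenotype,
        snp_ids=snp_cols,
        snp_arities=np.full(len(snp_cols), snp_arity, dtype=np.int64),
        phenotype_arity=phenotype_arity,
    )


def write_genotype_table(
    dataset: GenotypeDataset,
    path: str | Path,
    format: str = "tsv",
    phenotype_column: str = "pheno",
) -> Path:
    """Write a dataset as a delimited text table readable by the reader."""
    path = Path(path)

    def fmt(v: int) -> str:
        return "NA" if v == MISSING else str(v)

    if format == "plink_raw":
        cols: dict[str, list[str]] = {
            "FID": [f"F{i + 1}" for i in range(dataset.n_individuals)],
            "IID": [f"I{i + 1}" for i in range(dataset.n_individuals)],
            "PAT": ["0"] * dataset.n_individuals,
            "MAT": ["0"] * dataset.n_individuals,
            "SEX": ["0"] * dataset.n_individuals,
            "PHENOTYPE": [
                "NA" if v == MISSING else str(v + 1) for v in dataset.phenotype
            ],
        }
        for j, sid in enumerate(dataset.snp_ids):
            cols[sid] = [fmt(v) for v in dataset.genotypes[:, j]]
        pd.DataFrame(cols).to_csv(path, sep=" ", index=False)
        return path

    sep = {"tsv": "\t", "csv": ","}.get(format)
    if sep is None:
        raise ValueError(f"unknown format: {format!r}")
    cols = {
        sid: [fmt(v) for v in dataset.genotypes[:, j]]
        for j, sid in enumerate(dataset.snp_ids)
    }
    cols[phenotype_column] = [fmt(v) for v in dataset.phenotype]
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)
    return path
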