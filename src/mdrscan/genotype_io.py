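"""Reading and writing case-control genotype data in the one-hot CSV layout.

Each data row describes one biallelic variant: four metadata columns
(chromosome, 1-based position, reference allele, alternate allele) followed
by one indicator triple (AA, Aa, aa) per individual. Exactly one indicator
of a triple is 1 for a called genotype; an all-zero triple is the only
accepted non-one-hot pattern and denotes a missing call. Genotype classes
are coded 0 (homozygous reference), 1 (heterozygous), 2 (homozygous
alternate) and :data:`MISSING` (-1) in memory.

Phenotypes are a single-column CSV (optional header), one status per
individual in genotype column order, encoded ``0``/``1`` or
``control``/``case``.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "MISSING",
    "VALID_ALLELES",
    "GenotypeFormatError",
    "GenotypeEncodingError",
    "PhenotypeConsistencyError",
    "VariantKey",
    "GenotypeMatrix",
    "PhenotypeVector",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
]

#: In-memory code for a missing genotype call (all-zero indicator triple).
MISSING: int = -1

VALID_ALLELES = frozenset("ACGT")

_METADATA_COLUMNS = ("chromosome", "position", "ref_allele", "alt_allele")


class GenotypeFormatError(ValueError):
    """Structurally malformed genotype or phenotype file (row width, labels)."""


class GenotypeEncodingError(ValueError):
    """Indicator triple that is neither one-hot nor all-zero, or non-{0,1}."""


class PhenotypeConsistencyError(ValueError):
    """Phenotype vector incompatible with the genotype matrix it annotates."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Identity of a biallelic variant: chromosome, 1-based position, alleles."""

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.ref_allele not in VALID_ALLELES or self.alt_allele not in VALID_ALLELES:
            raise ValueError(
                f"alleles must be single nucleotides in {sorted(VALID_ALLELES)}, "
                f"got {self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")

    def __str__(self) -> str:
        return f"{self.chromosome}:{self.position}:{self.ref_allele}>{self.alt_allele}"


@dataclass
class GenotypeMatrix:
    """Genotype class codes for ``len(variants)`` variants × ``n_individuals``.

    ``codes`` is an int8 array with entries in {0, 1, 2, MISSING}; row order
    follows ``variants``.
    """

    variants: list[VariantKey]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D (variants x individuals) array")
        if self.codes.shape[0] != len(self.variants):
            raise ValueError(
                f"{len(self.variants)} variants but {self.codes.shape[0]} code rows"
            )
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            v, i = np.argwhere(bad)[0]
            raise GenotypeEncodingError(
                f"invalid genotype code {self.codes[v, i]} at variant {v}, individual {i}"
            )
        if len(set(self.variants)) != len(self.variants):
            raise ValueError("duplicate variant keys in matrix")

    @property
    def n_variants(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def one_hot(self, dtype=np.float64) -> np.ndarray:
        """(n_variants, 3, n_individuals) indicator array; missing rows all-zero.

        This binarized representation is what the vectorized counting paths
        consume: a product of indicators over two variants is nonzero only
        for individuals called at both.
        """
        out = np.zeros((self.n_variants, 3, self.n_individuals), dtype=dtype)
        for g in range(3):
            out[:, g, :] = self.codes == g
        return out


@dataclass
class PhenotypeVector:
    """Binary case/control status per individual (1 = case, 0 = control)."""

    status: np.ndarray
    n_cases: int = field(init=False)
    n_controls: int = field(init=False)

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.ndim != 1:
            raise ValueError("status must be one-dimensional")
        if not np.isin(self.status, (0, 1)).all():
            raise GenotypeFormatError("phenotype status values must be 0/1")
        self.n_cases = int(self.status.sum())
        self.n_controls = int(len(self.status) - self.n_cases)

    @property
    def n_individuals(self) -> int:
        return len(self.status)

    def check_against(self, matrix: GenotypeMatrix) -> None:
        if self.n_individuals != matrix.n_individuals:
            raise PhenotypeConsistencyError(
                f"{self.n_individuals} phenotype labels for "
                f"{matrix.n_individuals} genotyped individuals"
            )


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _looks_like_header(fields: Sequence[str]) -> bool:
    if len(fields) < 5:
        return True
    try:
        int(fields[1])
    except ValueError:
        return True
    return False


def read_genotypes(
    path: str | Path, expected_individuals: int | None = None
) -> GenotypeMatrix:
    """Read a one-hot genotype CSV (optionally gzip-compressed).

    Parameters
    ----------
    path
        CSV with 4 metadata columns then 3 indicator columns per individual.
        A header row is detected (non-integer second field) and skipped.
    expected_individuals
        If given, the file must describe exactly this many individuals.

    Raises
    ------
    GenotypeFormatError
        Wrong row width (named by 1-based data row number) or inconsistent
        width across rows.
    GenotypeEncodingError
        An indicator that is not 0/1, or a triple with two or more 1s.
    """
    variants: list[VariantKey] = []
    rows: list[np.ndarray] = []
    n_ind: int | None = expected_individuals
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split(",")
            if lineno == 1 and _looks_like_header(fields):
                continue
            n_data = len(fields) - 4
            if n_data < 3 or n_data % 3 != 0:
                raise GenotypeFormatError(
                    f"row {lineno}: expected 4 metadata columns plus a multiple "
                    f"of 3 indicator columns, got {len(fields)} columns"
                )
            row_ind = n_data // 3
            if n_ind is None:
                n_ind = row_ind
            elif row_ind != n_ind:
                raise GenotypeFormatError(
                    f"row {lineno}: {row_ind} individuals, expected {n_ind}"
                )
            try:
                key = VariantKey(fields[0], int(fields[1]), fields[2], fields[3])
            except ValueError as exc:
                raise GenotypeFormatError(f"row {lineno}: {exc}") from exc
            try:
                ind = np.array(fields[4:], dtype=np.int64)
            except ValueError as exc:
                raise GenotypeEncodingError(
                    f"row {lineno}: non-numeric indicator value ({exc})"
                ) from exc
            if not np.isin(ind, (0, 1)).all():
                bad = ind[~np.isin(ind, (0, 1))][0]
                raise GenotypeEncodingError(
                    f"row {lineno}: indicator value {bad} is not 0 or 1"
                )
            triples = ind.reshape(n_ind, 3)
            ones = triples.sum(axis=1)
            if (ones > 1).any():
                j = int(np.argmax(ones > 1))
                raise GenotypeEncodingError(
                    f"row {lineno}: individual {j + 1} has {ones[j]} indicators set"
                )
            codes = np.where(ones == 0, MISSING, np.argmax(triples, axis=1))
            variants.append(key)
            rows.append(codes.astype(np.int8))
    if n_ind is None:
        raise GenotypeFormatError(f"{path}: no data rows and no expected_individuals")
    codes = (
        np.array(rows, dtype=np.int8)
        if rows
        else np.empty((0, n_ind), dtype=np.int8)
    )
    return GenotypeMatrix(variants=variants, codes=codes)


def write_genotypes(matrix: GenotypeMatrix, path: str | Path) -> Path:
    """Write ``matrix`` in the one-hot CSV layout (gzip if path ends in .gz).

    Emits a header row, then one row per variant with deterministic column
    order: chromosome, position, ref, alt, then (AA, Aa, aa) per individual.
    Missing calls are written as the all-zero triple.
    """
    path = Path(path)
    n = matrix.n_individuals
    header = list(_METADATA_COLUMNS) + ["AA", "Aa", "aa"] * n
    buf = io.StringIO()
    buf.write(",".join(header) + "\n")
    eye = np.eye(3, dtype=np.int64)
    zero = np.zeros(3, dtype=np.int64)
    for key, codes in zip(matrix.variants, matrix.codes):
        triples = np.concatenate(
            [eye[c] if c != MISSING else zero for c in codes]
        ) if n else np.empty(0, dtype=np.int64)
        row = [key.chromosome, str(key.position), key.ref_allele, key.alt_allele]
        row.extend(map(str, triples))
        buf.write(",".join(row) + "\n")
    with _open_text(path, "wt") as fh:
        fh.write(buf.getvalue())
    return path


_CASE_LABELS = {"1": 1, "case": 1, "0": 0, "control": 0}


def read_phenotypes(path: str | Path) -> PhenotypeVector:
    """Read a single-column phenotype CSV; labels 0/1 or control/case.

    A first line that is not a recognized label is treated as a header.
    """
    labels: list[int] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            token = line.strip().strip(",").lower()
            if not token:
                continue
            if token not in _CASE_LABELS:
                if lineno == 1:
                    continue  # header
                raise GenotypeFormatError(
                    f"row {lineno}: unknown phenotype label {line.strip()!r}"
                )
            labels.append(_CASE_LABELS[token])
    return PhenotypeVector(status=np.array(labels, dtype=np.int8))


def write_phenotypes(phenotypes: PhenotypeVector, path: str | Path) -> Path:
    path = Path(path)
    with _open_text(path, "wt") as fh:
        fh.write("status\n")
        for s in phenotypes.status:
            fh.write(f"{int(s)}\n")
    return path
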