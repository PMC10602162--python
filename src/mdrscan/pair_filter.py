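"""Exhaustive pairwise chi-square association scan.

The pair space of n variants (n(n-1)/2 combinations) is screened with a
Pearson chi-square test of each 3x3 genotype-combination table against
case/control status, and only pairs below a p-value threshold are kept for
the downstream cross-validated risk-model stage. Counting is vectorized:
genotypes are expanded to binary indicator triples and cell counts become
products of indicator matrices summed over individuals, which is how the
whole scan stays a handful of matrix operations per chunk.

The test is Pearson's statistic on the K x 2 table formed by the non-empty
genotype-combination columns (K <= 9) versus status, with K - 1 degrees of
freedom; empty combinations are structural zeros and carry no information
about association. No continuity correction and no minimum expected-count
rule are applied — this is a screening filter, not a confirmatory test —
but a warning is logged when any expected count falls below 5.

Chunked evaluation is deterministic and resumable: the retained set is
identical for any chunk size, worker count or pair ordering, and a scan
writing to disk records completed chunks so an interrupted run can resume
without recomputing or duplicating output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import islice
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from joblib import Parallel, delayed
from scipy.stats import chi2 as _chi2_dist

from .genotype_io import MISSING, GenotypeMatrix, PhenotypeVector, VariantKey

__all__ = [
    "PairTable",
    "ChiSquareResult",
    "FilterConfig",
    "UndefinedTestError",
    "DegenerateTableError",
    "count_pairs",
    "build_pair_table",
    "chi_square_pair",
    "scan_pairs",
    "scan_to_tsv",
    "bonferroni_threshold",
    "truncate_significant",
]

logger = logging.getLogger(__name__)

PAIR_TSV_COLUMNS = (
    "chrom_a", "pos_a", "ref_a", "alt_a",
    "chrom_b", "pos_b", "ref_b", "alt_b",
    "chi2", "df", "p_value",
)


class UndefinedTestError(ValueError):
    """Chi-square test undefined: one status class absent or a single column."""


class DegenerateTableError(ValueError):
    """No individual contributes to the pair table after missingness exclusion."""


@dataclass
class PairTable:
    """3x3x2 contingency counts for a variant pair.

    ``counts[ga, gb, s]`` is the number of individuals with genotype ``ga``
    at the first variant, ``gb`` at the second, and status ``s``
    (0 = control, 1 = case). Individuals missing either call are excluded,
    so the 18 cells sum to ``n_complete`` <= n_individuals.
    """

    counts: np.ndarray
    n_complete: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3, 2):
            raise ValueError(f"counts must be 3x3x2, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("negative cell count")
        if int(self.counts.sum()) != self.n_complete:
            raise ValueError(
                f"cells sum to {int(self.counts.sum())}, n_complete={self.n_complete}"
            )

    @property
    def n_cases(self) -> int:
        return int(self.counts[:, :, 1].sum())

    @property
    def n_controls(self) -> int:
        return int(self.counts[:, :, 0].sum())

    def transposed(self) -> "PairTable":
        """Table with the two variants exchanged."""
        return PairTable(self.counts.transpose(1, 0, 2).copy(), self.n_complete)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    degrees_of_freedom: int
    p_value: float


@dataclass
class FilterConfig:
    """Scan configuration; default threshold keeps pairs with p < 1e-6."""

    p_threshold: float = 1e-6
    family_alpha: float = 0.05
    chunk_size: int = 10_000
    workers: int = 1
    resume: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise ValueError(f"p_threshold must be in (0, 1], got {self.p_threshold}")
        if not 0 < self.family_alpha <= 1:
            raise ValueError(f"family_alpha must be in (0, 1], got {self.family_alpha}")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def count_pairs(n_variants: int) -> int:
    """Number of unordered variant pairs, n(n-1)/2, as an exact integer."""
    n = int(n_variants)
    if n < 0:
        raise ValueError(f"n_variants must be >= 0, got {n_variants}")
    return n * (n - 1) // 2


def bonferroni_threshold(n_tests: int, family_alpha: float = 0.05) -> float:
    """Per-test p-value threshold controlling the family-wise error rate."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not 0 < family_alpha <= 1:
        raise ValueError(f"family_alpha must be in (0, 1], got {family_alpha}")
    return family_alpha / n_tests


def truncate_significant(x: float, digits: int = 3) -> float:
    """Truncate (round toward zero) to the given number of significant digits."""
    if x == 0 or not math.isfinite(x):
        return x
    exp = math.floor(math.log10(abs(x)))
    scale = 10.0 ** (exp - digits + 1)
    return math.trunc(x / scale) * scale


def build_pair_table(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    i: int,
    j: int,
    individuals: Sequence[int] | np.ndarray | None = None,
) -> PairTable:
    """Tally the 3x3x2 table for variants ``i`` and ``j``.

    Only individuals in ``individuals`` (default: all) with non-missing
    calls at both variants contribute.
    """
    if i == j:
        raise ValueError(f"pair must consist of two distinct variants, got ({i}, {j})")
    phenotypes.check_against(matrix)
    if individuals is None:
        individuals = np.arange(matrix.n_individuals)
    idx = np.asarray(individuals, dtype=np.intp)
    if idx.size == 0:
        raise DegenerateTableError("empty individual subset")
    ga = matrix.codes[i, idx]
    gb = matrix.codes[j, idx]
    st = phenotypes.status[idx]
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        raise DegenerateTableError(
            f"no individual has complete genotypes at pair ({i}, {j})"
        )
    ga, gb, st = ga[ok], gb[ok], st[ok]
    flat = (ga.astype(np.int64) * 3 + gb) * 2 + st
    counts = np.bincount(flat, minlength=18).reshape(3, 3, 2)
    return PairTable(counts=counts, n_complete=int(ok.sum()))


def _chi2_batch(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Pearson chi-square over a batch of 9-column x 2 tables.

    Parameters are (m, 9) case and control counts. Returns (statistic, df,
    p_value, testable) arrays; non-testable entries (single non-empty
    column, or a status margin of zero) get NaN statistics.
    """
    cc = np.asarray(case_counts, dtype=np.float64)
    co = np.asarray(control_counts, dtype=np.float64)
    tot = cc + co
    n = tot.sum(axis=1)
    cases = cc.sum(axis=1)
    controls = co.sum(axis=1)
    k = (tot > 0).sum(axis=1)
    testable = (k >= 2) & (cases > 0) & (controls > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e_case = tot * (cases / n)[:, None]
        e_ctrl = tot * (controls / n)[:, None]
        nz = tot > 0
        stat = (
            np.where(nz, (cc - e_case) ** 2 / np.where(nz, e_case, 1.0), 0.0).sum(axis=1)
            + np.where(nz, (co - e_ctrl) ** 2 / np.where(nz, e_ctrl, 1.0), 0.0).sum(axis=1)
        )
    df = np.maximum(k - 1, 1)
    pval = np.full(len(stat), np.nan)
    pval[testable] = _chi2_dist.sf(stat[testable], df[testable])
    stat = np.where(testable, stat, np.nan)
    small = testable & (
        np.where(tot > 0, np.minimum(e_case, e_ctrl), np.inf).min(axis=1) < 5
    )
    if small.any():
        logger.debug("%d tables have an expected count below 5", int(small.sum()))
    return stat, df, pval, testable


def chi_square_pair(table: PairTable) -> ChiSquareResult:
    """Pearson chi-square of genotype combination versus status.

    The K non-empty genotype-combination columns form a K x 2 table tested
    with K - 1 degrees of freedom; the p-value is the upper-tail chi-square
    probability (regularized upper incomplete gamma).
    """
    cc = table.counts[:, :, 1].reshape(1, 9)
    co = table.counts[:, :, 0].reshape(1, 9)
    if table.n_cases == 0 or table.n_controls == 0:
        raise UndefinedTestError("all contributing individuals share one status")
    if int(((cc + co) > 0).sum()) < 2:
        raise UndefinedTestError("fewer than two non-empty genotype combinations")
    tot = (cc + co)[0]
    e_min = (tot[tot > 0] * min(table.n_cases, table.n_controls) / table.n_complete).min()
    if e_min < 5:
        logger.warning("expected count %.2f below 5; chi-square approximate", e_min)
    stat, df, pval, _ = _chi2_batch(cc, co)
    return ChiSquareResult(float(stat[0]), int(df[0]), float(pval[0]))


def _all_pairs(n: int) -> Iterator[tuple[int, int]]:
    for i in range(n):
        for j in range(i + 1, n):
            yield (i, j)


def _canonical(pairs: Iterable[tuple[int, int]]) -> Iterator[tuple[int, int]]:
    for i, j in pairs:
        if i == j:
            raise ValueError(f"pair ({i}, {j}) is not a pair of distinct variants")
        yield (i, j) if i < j else (j, i)


def _chunked(it: Iterator, size: int) -> Iterator[list]:
    while chunk := list(islice(it, size)):
        yield chunk


@dataclass(frozen=True)
class PairHit:
    """One retained pair: indices, keys and its chi-square result."""

    i: int
    j: int
    key_a: VariantKey
    key_b: VariantKey
    result: ChiSquareResult


def _chunk_hits(
    one_hot: np.ndarray,
    case_w: np.ndarray,
    ctrl_w: np.ndarray,
    chunk: list[tuple[int, int]],
    p_threshold: float,
) -> tuple[list[tuple[int, int, float, int, float]], int, int]:
    """Evaluate one chunk of pairs; returns (hits, n_tested, n_skipped)."""
    ii = np.fromiter((p[0] for p in chunk), dtype=np.intp, count=len(chunk))
    jj = np.fromiter((p[1] for p in chunk), dtype=np.intp, count=len(chunk))
    a = one_hot[ii]
    b = one_hot[jj]
    cc = np.einsum("man,mbn,n->mab", a, b, case_w).reshape(len(chunk), 9)
    co = np.einsum("man,mbn,n->mab", a, b, ctrl_w).reshape(len(chunk), 9)
    stat, df, pval, testable = _chi2_batch(cc, co)
    # a threshold of 1.0 keeps every testable pair (p is never > 1)
    keep = testable & ((pval < p_threshold) | (p_threshold >= 1.0))
    hits = [
        (int(ii[m]), int(jj[m]), float(stat[m]), int(df[m]), float(pval[m]))
        for m in np.flatnonzero(keep)
    ]
    return hits, int(testable.sum()), int(len(chunk) - testable.sum())


def scan_pairs(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    config: FilterConfig | None = None,
    pairs: Iterable[tuple[int, int]] | None = None,
    skip_log: list[tuple[int, int]] | None = None,
) -> Iterator[PairHit]:
    """Stream pairs whose chi-square p-value is below the threshold.

    ``pairs`` defaults to all n(n-1)/2 combinations in canonical (i < j)
    order. Non-testable pairs (one status class absent among complete
    individuals, or a single populated genotype combination) are skipped
    and optionally appended to ``skip_log``. The emitted set is invariant
    to chunk size and worker count.
    """
    config = config or FilterConfig()
    phenotypes.check_against(matrix)
    one_hot = matrix.one_hot()
    case_w = (phenotypes.status == 1).astype(np.float64)
    ctrl_w = 1.0 - case_w
    source = _canonical(pairs) if pairs is not None else _all_pairs(matrix.n_variants)
    chunks = _chunked(source, config.chunk_size)

    if config.workers == 1:
        for chunk in chunks:
            hits, n_tested, n_skip = _chunk_hits(
                one_hot, case_w, ctrl_w, chunk, config.p_threshold
            )
            if skip_log is not None and n_skip:
                skip_log.extend(_find_skips(one_hot, case_w, ctrl_w, chunk))
            for i, j, stat, df, pval in hits:
                yield PairHit(
                    i, j, matrix.variants[i], matrix.variants[j],
                    ChiSquareResult(stat, df, pval),
                )
    else:
        parallel = Parallel(n_jobs=config.workers, backend="threading")
        for batch in _chunked(chunks, config.workers * 4):
            results = parallel(
                delayed(_chunk_hits)(one_hot, case_w, ctrl_w, c, config.p_threshold)
                for c in batch
            )
            for chunk, (hits, n_tested, n_skip) in zip(batch, results):
                if skip_log is not None and n_skip:
                    skip_log.extend(_find_skips(one_hot, case_w, ctrl_w, chunk))
                for i, j, stat, df, pval in hits:
                    yield PairHit(
                        i, j, matrix.variants[i], matrix.variants[j],
                        ChiSquareResult(stat, df, pval),
                    )


def _find_skips(one_hot, case_w, ctrl_w, chunk) -> list[tuple[int, int]]:
    ii = np.fromiter((p[0] for p in chunk), dtype=np.intp, count=len(chunk))
    jj = np.fromiter((p[1] for p in chunk), dtype=np.intp, count=len(chunk))
    cc = np.einsum("man,mbn,n->mab", one_hot[ii], one_hot[jj], case_w).reshape(-1, 9)
    co = np.einsum("man,mbn,n->mab", one_hot[ii], one_hot[jj], ctrl_w).reshape(-1, 9)
    _, _, _, testable = _chi2_batch(cc, co)
    return [(int(ii[m]), int(jj[m])) for m in np.flatnonzero(~testable)]


def _hit_row(hit: PairHit) -> str:
    a, b = hit.key_a, hit.key_b
    r = hit.result
    return (
        f"{a.chromosome}\t{a.position}\t{a.ref_allele}\t{a.alt_allele}\t"
        f"{b.chromosome}\t{b.position}\t{b.ref_allele}\t{b.alt_allele}\t"
        f"{r.statistic:.6e}\t{r.degrees_of_freedom}\t{r.p_value:.6e}"
    )


def scan_to_tsv(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    out_dir: str | Path,
    config: FilterConfig | None = None,
    pairs: Iterable[tuple[int, int]] | None = None,
) -> dict:
    """Run the scan writing retained pairs to ``out_dir/pairs.tsv``.

    Completed chunks are recorded in ``out_dir/chunks.done`` together with
    the output byte offset reached, so a killed scan rerun with
    ``config.resume`` truncates any partial trailing chunk and continues;
    the final file is byte-identical to an uninterrupted run. Returns a
    summary dict (pairs tested / retained / skipped).
    """
    config = config or FilterConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tsv = out_dir / "pairs.tsv"
    done = out_dir / "chunks.done"

    completed: dict[int, int] = {}
    if config.resume and done.exists() and tsv.exists():
        for line in done.read_text().splitlines():
            cid, offset, tested, kept, skipped = line.split("\t")
            completed[int(cid)] = int(offset)
    else:
        done.unlink(missing_ok=True)
        tsv.unlink(missing_ok=True)

    phenotypes.check_against(matrix)
    one_hot = matrix.one_hot()
    case_w = (phenotypes.status == 1).astype(np.float64)
    ctrl_w = 1.0 - case_w
    source = _canonical(pairs) if pairs is not None else _all_pairs(matrix.n_variants)

    header = "\t".join(PAIR_TSV_COLUMNS) + "\n"
    if not tsv.exists():
        tsv.write_text(header)
    # truncate a trailing partial chunk
    valid_to = max(completed.values(), default=len(header.encode()))
    with open(tsv, "r+b") as fh:
        fh.truncate(valid_to)

    n_tested = n_retained = n_skipped = 0
    stats_from_log = _replay_done_counts(done) if completed else (0, 0, 0)
    n_tested, n_retained, n_skipped = stats_from_log

    with open(tsv, "a") as out, open(done, "a") as log:
        for cid, chunk in enumerate(_chunked(source, config.chunk_size)):
            if cid in completed:
                continue
            hits, tested, skipped = _chunk_hits(
                one_hot, case_w, ctrl_w, chunk, config.p_threshold
            )
            for i, j, stat, df, pval in hits:
                out.write(
                    _hit_row(
                        PairHit(
                            i, j, matrix.variants[i], matrix.variants[j],
                            ChiSquareResult(stat, df, pval),
                        )
                    )
                    + "\n"
                )
            out.flush()
            offset = out.tell()
            log.write(f"{cid}\t{offset}\t{tested}\t{len(hits)}\t{skipped}\n")
            log.flush()
            n_tested += tested
            n_retained += len(hits)
            n_skipped += skipped
    return {
        "pairs_tested": n_tested,
        "pairs_retained": n_retained,
        "pairs_skipped": n_skipped,
        "output": str(tsv),
    }


def _replay_done_counts(done: Path) -> tuple[int, int, int]:
    tested = kept = skipped = 0
    for line in done.read_text().splitlines():
        _, _, t, k, s = line.split("\t")
        tested += int(t)
        kept += int(k)
        skipped += int(s)
    return tested, kept, skipped
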