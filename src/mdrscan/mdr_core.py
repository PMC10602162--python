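"""Cross-validated Multifactor Dimensionality Reduction over variant pairs.

For each candidate pair the two-locus genotype table is collapsed into a
one-dimensional high-risk/low-risk classifier: within each cross-validation
training split, a 3x3 cell is labeled high risk when its case:control ratio
strictly exceeds the training split's overall case:control ratio T. The
classifier predicts "case" for held-out individuals falling in high-risk
cells and "control" otherwise, yielding a per-fold prediction power
(accuracy, with precision always reported alongside). A pair's consistency
is the number of folds in which it ranks inside the top fraction of pairs
by prediction power; pairs consistent in all k folds are selected.

All per-fold tallies run through the binarized one-hot representation, so
building every pair's training and testing tables is a batch of matrix
products; a per-individual loop implementation exists only in the test
suite as the independence oracle.

Determinism: the CV assignment is a seeded stratified round-robin deal, and
rankings break ties by the mean training-table chi-square statistic and
then by lexicographic variant keys, so results are invariant to pair
ordering, chunking and worker count.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from joblib import Parallel, delayed

from .genotype_io import MISSING, GenotypeMatrix, PhenotypeVector, VariantKey
from .pair_filter import PairTable, _chi2_batch

__all__ = [
    "HIGH",
    "LOW",
    "EMPTY",
    "ConfigurationError",
    "UndefinedThresholdError",
    "CVPlan",
    "RiskModel",
    "FoldScore",
    "PairResult",
    "MDRConfig",
    "make_cv_plan",
    "fit_risk_model",
    "classify",
    "score_fold",
    "run_mdr",
    "consistency_histogram",
    "write_results_tsv",
    "read_pairs_tsv",
]

# cell risk labels
HIGH: int = 1
LOW: int = 0
EMPTY: int = -1


class ConfigurationError(ValueError):
    """Infeasible analysis configuration (e.g. a status class smaller than k)."""


class UndefinedThresholdError(ValueError):
    """Training split has no controls (or no cases): T is undefined."""


@dataclass
class CVPlan:
    """Stratified k-fold assignment; ``assignment[i]`` is individual i's fold."""

    k: int
    assignment: np.ndarray
    seed: int

    def train_mask(self, fold: int) -> np.ndarray:
        return self.assignment != fold

    def test_mask(self, fold: int) -> np.ndarray:
        return self.assignment == fold


@dataclass
class RiskModel:
    """High/low-risk labeling of the 3x3 genotype-combination grid.

    ``labels[ga, gb]`` is HIGH when the training case:control ratio of the
    cell strictly exceeds ``threshold_T`` (a cell with cases but no controls
    counts as exceeding), EMPTY when no training individual fell in the
    cell, LOW otherwise.
    """

    threshold_T: float
    labels: np.ndarray


@dataclass
class FoldScore:
    """Held-out performance of one pair in one fold.

    ``usable`` is False when the fold was degenerate for this pair (no
    complete held-out individuals, or an undefined training threshold);
    degenerate folds are excluded from means and can never be "top".
    """

    accuracy: float
    precision: float
    n_test_used: int
    usable: bool = True


@dataclass
class PairResult:
    pair: tuple[VariantKey, VariantKey]
    indices: tuple[int, int]
    fold_scores: list[FoldScore]
    mean_power: float
    mean_accuracy: float
    mean_precision: float
    consistency: int
    selected: bool


@dataclass
class MDRConfig:
    """k folds, top fraction per fold, ranking metric, seed, workers."""

    k: int = 5
    top_fraction: float = 0.20
    seed: int = 0
    power_metric: str = "accuracy"
    workers: int = 1
    chunk_size: int = 4096

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigurationError(f"k must be >= 2, got {self.k}")
        if not 0 < self.top_fraction <= 1:
            raise ConfigurationError(
                f"top_fraction must be in (0, 1], got {self.top_fraction}"
            )
        if self.power_metric not in ("accuracy", "precision"):
            raise ConfigurationError(
                f"power_metric must be 'accuracy' or 'precision', got {self.power_metric!r}"
            )
        if self.workers < 1 or self.chunk_size < 1:
            raise ConfigurationError("workers and chunk_size must be >= 1")


def make_cv_plan(phenotypes: PhenotypeVector, k: int = 5, seed: int = 0) -> CVPlan:
    """Seeded stratified k-fold assignment.

    Cases and controls are shuffled independently and dealt round-robin, so
    per-class fold sizes differ by at most one and the same seed reproduces
    the same plan exactly.
    """
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    for cls, name in ((1, "cases"), (0, "controls")):
        n_cls = int((phenotypes.status == cls).sum())
        if n_cls < k:
            raise ConfigurationError(
                f"{n_cls} {name} cannot be split into {k} folds"
            )
    rng = np.random.default_rng(seed)
    assignment = np.empty(phenotypes.n_individuals, dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(phenotypes.status == cls)
        idx = rng.permutation(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return CVPlan(k=k, assignment=assignment, seed=seed)


def fit_risk_model(train_table: PairTable) -> RiskModel:
    """Label each genotype-combination cell by the MDR threshold rule.

    T is the overall case:control ratio of the individuals behind the
    training table; a cell is HIGH iff cell_cases / cell_controls > T,
    evaluated exactly in integer arithmetic
    (cell_cases * controls > cases * cell_controls).
    """
    cases, controls = train_table.n_cases, train_table.n_controls
    if controls == 0:
        raise UndefinedThresholdError("training split has no controls")
    if cases == 0:
        raise UndefinedThresholdError("training split has no cases")
    cell_cases = train_table.counts[:, :, 1]
    cell_controls = train_table.counts[:, :, 0]
    labels = np.where(
        cell_cases * controls > cases * cell_controls, HIGH, LOW
    ).astype(np.int8)
    labels[cell_cases + cell_controls == 0] = EMPTY
    return RiskModel(threshold_T=cases / controls, labels=labels)


def classify(model: RiskModel, genotype_pairs: Sequence[tuple[int, int]]) -> np.ndarray:
    """Predict status for complete genotype pairs: 1 (case) for high-risk
    cells, 0 (control) for low-risk and empty cells."""
    ga = np.asarray([g[0] for g in genotype_pairs], dtype=np.intp)
    gb = np.asarray([g[1] for g in genotype_pairs], dtype=np.intp)
    if len(ga) and (
        ga.min() < 0 or ga.max() > 2 or gb.min() < 0 or gb.max() > 2
    ):
        raise ValueError("genotype codes must be in {0, 1, 2}")
    return (model.labels[ga, gb] == HIGH).astype(np.int8)


def score_fold(
    model: RiskModel,
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    pair: tuple[int, int],
    test_individuals: Sequence[int] | np.ndarray,
) -> FoldScore:
    """Accuracy and precision of a fitted risk model on held-out individuals.

    Individuals missing either call are excluded. Precision is 0 by
    convention when no individual is predicted a case.
    """
    idx = np.asarray(test_individuals, dtype=np.intp)
    i, j = pair
    ga = matrix.codes[i, idx]
    gb = matrix.codes[j, idx]
    ok = (ga != MISSING) & (gb != MISSING)
    if not ok.any():
        return FoldScore(accuracy=0.0, precision=0.0, n_test_used=0, usable=False)
    truth = phenotypes.status[idx][ok]
    pred = classify(model, list(zip(ga[ok], gb[ok])))
    n_used = int(ok.sum())
    accuracy = float((pred == truth).mean())
    n_pred_case = int(pred.sum())
    precision = (
        float(truth[pred == 1].sum() / n_pred_case) if n_pred_case else 0.0
    )
    return FoldScore(accuracy=accuracy, precision=precision, n_test_used=n_used)


def _fold_pair_stats(
    one_hot: np.ndarray,
    status: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    ii: np.ndarray,
    jj: np.ndarray,
) -> dict[str, np.ndarray]:
    """Vectorized per-pair training fit + held-out scoring for one fold.

    Training and testing 3x3 case/control tables for every pair in the
    batch are four batched indicator matrix products; the risk labeling and
    the held-out confusion counts are then pure table arithmetic (held-out
    accuracy only needs the test table, not per-individual predictions).
    """
    case = (status == 1).astype(np.float64)
    ctrl = 1.0 - case
    a, b = one_hot[ii], one_hot[jj]
    tr_case = np.einsum("man,mbn,n->mab", a, b, case * train)
    tr_ctrl = np.einsum("man,mbn,n->mab", a, b, ctrl * train)
    te_case = np.einsum("man,mbn,n->mab", a, b, case * test)
    te_ctrl = np.einsum("man,mbn,n->mab", a, b, ctrl * test)
    tr_case_i = np.rint(tr_case).astype(np.int64)
    tr_ctrl_i = np.rint(tr_ctrl).astype(np.int64)
    cases_tr = tr_case_i.sum(axis=(1, 2))
    controls_tr = tr_ctrl_i.sum(axis=(1, 2))
    # exact integer form of cell_ratio > T
    high = tr_case_i * controls_tr[:, None, None] > cases_tr[:, None, None] * tr_ctrl_i
    n_used = (te_case + te_ctrl).sum(axis=(1, 2))
    correct = np.where(high, te_case, te_ctrl).sum(axis=(1, 2))
    pred_case = np.where(high, te_case + te_ctrl, 0.0).sum(axis=(1, 2))
    true_case = np.where(high, te_case, 0.0).sum(axis=(1, 2))
    usable = (n_used > 0) & (cases_tr > 0) & (controls_tr > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        accuracy = np.where(usable & (n_used > 0), correct / np.maximum(n_used, 1), 0.0)
        precision = np.where(pred_case > 0, true_case / np.maximum(pred_case, 1e-300), 0.0)
    precision = np.where(usable, precision, 0.0)
    chi2_stat, _, _, chi2_ok = _chi2_batch(
        tr_case_i.reshape(-1, 9), tr_ctrl_i.reshape(-1, 9)
    )
    return {
        "accuracy": accuracy,
        "precision": precision,
        "n_used": np.rint(n_used).astype(np.int64),
        "usable": usable,
        "train_chi2": np.where(chi2_ok, np.nan_to_num(chi2_stat), 0.0),
    }


def run_mdr(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    pairs: Sequence[tuple[int, int]],
    config: MDRConfig | None = None,
    cv_plan: CVPlan | None = None,
) -> list[PairResult]:
    """Evaluate pairs with k-fold MDR and select the consistent top pairs.

    In every fold, each pair's risk model is fitted on the training folds
    and scored on the held-out fold; the top ``ceil(top_fraction * n_pairs)``
    pairs by the fold's power metric form the fold's top set (ties broken by
    higher mean training-table chi-square, then lexicographic variant keys).
    Consistency counts the folds in which a pair is top; a pair is selected
    iff it is top in all k folds. Output order follows the input pair list,
    but every score, consistency value and selection flag is independent of
    pair order, chunking and worker count.
    """
    config = config or MDRConfig()
    phenotypes.check_against(matrix)
    if not pairs:
        raise ConfigurationError("pairs must be nonempty")
    canonical: list[tuple[int, int]] = []
    for i, j in pairs:
        if i == j:
            raise ConfigurationError(f"pair ({i}, {j}) is not two distinct variants")
        canonical.append((i, j) if i < j else (j, i))
    plan = cv_plan or make_cv_plan(phenotypes, k=config.k, seed=config.seed)
    if plan.k != config.k:
        raise ConfigurationError("cv_plan.k differs from config.k")
    n_pairs = len(canonical)
    one_hot = matrix.one_hot()
    status = phenotypes.status
    ii = np.fromiter((p[0] for p in canonical), dtype=np.intp, count=n_pairs)
    jj = np.fromiter((p[1] for p in canonical), dtype=np.intp, count=n_pairs)

    chunks = [
        (ii[s : s + config.chunk_size], jj[s : s + config.chunk_size])
        for s in range(0, n_pairs, config.chunk_size)
    ]
    acc = np.empty((plan.k, n_pairs))
    prec = np.empty((plan.k, n_pairs))
    n_used = np.empty((plan.k, n_pairs), dtype=np.int64)
    usable = np.empty((plan.k, n_pairs), dtype=bool)
    train_chi2 = np.empty((plan.k, n_pairs))
    parallel = (
        Parallel(n_jobs=config.workers, backend="threading")
        if config.workers > 1
        else None
    )
    for f in range(plan.k):
        train = plan.train_mask(f).astype(np.float64)
        test = plan.test_mask(f).astype(np.float64)
        if parallel is None:
            parts = [
                _fold_pair_stats(one_hot, status, train, test, ci, cj)
                for ci, cj in chunks
            ]
        else:
            parts = parallel(
                delayed(_fold_pair_stats)(one_hot, status, train, test, ci, cj)
                for ci, cj in chunks
            )
        for name, dest in (
            ("accuracy", acc), ("precision", prec), ("n_used", n_used),
            ("usable", usable), ("train_chi2", train_chi2),
        ):
            dest[f] = np.concatenate([p[name] for p in parts])

    # fold-independent tie-break keys: mean training chi2, variant key order
    mean_chi2 = train_chi2.mean(axis=0)
    key_tuples = [
        (matrix.variants[i], matrix.variants[j]) for i, j in canonical
    ]
    key_rank = np.empty(n_pairs, dtype=np.int64)
    key_rank[np.array(sorted(range(n_pairs), key=lambda m: key_tuples[m]))] = np.arange(
        n_pairs
    )

    metric = acc if config.power_metric == "accuracy" else prec
    top_n = math.ceil(config.top_fraction * n_pairs)
    in_top = np.zeros((plan.k, n_pairs), dtype=bool)
    for f in range(plan.k):
        m = np.where(usable[f], metric[f], -np.inf)
        order = np.lexsort((key_rank, -mean_chi2, -m))
        in_top[f, order[:top_n]] = True
    consistency = in_top.sum(axis=0)

    results: list[PairResult] = []
    for m in range(n_pairs):
        scores = [
            FoldScore(
                accuracy=float(acc[f, m]),
                precision=float(prec[f, m]),
                n_test_used=int(n_used[f, m]),
                usable=bool(usable[f, m]),
            )
            for f in range(plan.k)
        ]
        ok = usable[:, m]
        mean_acc = float(acc[ok, m].mean()) if ok.any() else 0.0
        mean_prec = float(prec[ok, m].mean()) if ok.any() else 0.0
        results.append(
            PairResult(
                pair=key_tuples[m],
                indices=canonical[m],
                fold_scores=scores,
                mean_power=mean_acc if config.power_metric == "accuracy" else mean_prec,
                mean_accuracy=mean_acc,
                mean_precision=mean_prec,
                consistency=int(consistency[m]),
                selected=bool(consistency[m] == plan.k),
            )
        )
    return results


def consistency_histogram(results: Iterable[PairResult]) -> dict[int, int]:
    """Count pairs by consistency value (Fig.-4/5-style grouping)."""
    return dict(Counter(r.consistency for r in results))


def write_results_tsv(results: Sequence[PairResult], path: str | Path) -> Path:
    """Write per-pair MDR results as TSV (variant identity, per-fold
    accuracies, means, consistency, selection flag)."""
    path = Path(path)
    k = len(results[0].fold_scores) if results else 0
    cols = [
        "chrom_a", "pos_a", "ref_a", "alt_a",
        "chrom_b", "pos_b", "ref_b", "alt_b",
    ]
    cols += [f"accuracy_fold{f}" for f in range(k)]
    cols += ["mean_accuracy", "mean_precision", "consistency", "selected"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            a, b = r.pair
            row = [
                a.chromosome, str(a.position), a.ref_allele, a.alt_allele,
                b.chromosome, str(b.position), b.ref_allele, b.alt_allele,
            ]
            row += [f"{s.accuracy:.6e}" for s in r.fold_scores]
            row += [
                f"{r.mean_accuracy:.6e}",
                f"{r.mean_precision:.6e}",
                str(r.consistency),
                "true" if r.selected else "false",
            ]
            fh.write("\t".join(row) + "\n")
    return path


def read_pairs_tsv(path: str | Path, matrix: GenotypeMatrix) -> list[tuple[int, int]]:
    """Resolve a retained-pairs TSV (from the chi-square scan) back to
    variant index pairs in ``matrix``; unknown keys raise KeyError."""
    lookup = {key: idx for idx, key in enumerate(matrix.variants)}
    pairs: list[tuple[int, int]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {name: pos for pos, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            ka = VariantKey(f[col["chrom_a"]], int(f[col["pos_a"]]),
                            f[col["ref_a"]], f[col["alt_a"]])
            kb = VariantKey(f[col["chrom_b"]], int(f[col["pos_b"]]),
                            f[col["ref_b"]], f[col["alt_b"]])
            pairs.append((lookup[ka], lookup[kb]))
    return pairs
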