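"""Synthetic case-control genotype datasets with known planted structure.

The generator emulates the structure of a genotyping-array case-control
cohort: biallelic variants with genotypes in Hardy-Weinberg proportions
(p^2, 2pq, q^2), a binary phenotype with a configurable case:control split,
and optional planted pairwise interactions specified as 3x3 penetrance
tables P(case | gA, gB). Because the design is retrospective (fixed numbers
of cases and controls, as in the cohort the pipeline targets), planted
genotype pairs are drawn from the status-conditional distributions obtained
by Bayes inversion of the penetrance table at the stated minor-allele
frequencies:

    P(gA, gB | case)    ∝ P(case | gA, gB) · P(gA) P(gB)
    P(gA, gB | control) ∝ (1 − P(case | gA, gB)) · P(gA) P(gB)

Null variants are sampled independently of phenotype. A truth manifest
records every planted pair so detection can be scored afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np

from .genotype_io import (
    GenotypeMatrix,
    PhenotypeVector,
    VariantKey,
    write_genotypes,
    write_phenotypes,
)
from .mdr_core import PairResult

__all__ = [
    "PenetranceModel",
    "SimConfig",
    "hwe_genotype_probs",
    "xor_penetrance",
    "null_penetrance",
    "simulate_dataset",
    "write_dataset",
    "truth_recovery_report",
]


class SimulationConfigError(ValueError):
    """Penetrance/prevalence combination leaves a status class unreachable."""


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities (AA, Aa, aa) at minor-allele
    frequency ``maf`` (alt allele = minor allele)."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf must be in (0, 0.5], got {maf}")
    p = 1.0 - maf
    return np.array([p * p, 2.0 * p * maf, maf * maf])


def xor_penetrance(high: float = 0.8, low: float = 0.2) -> np.ndarray:
    """Penetrance table with elevated risk on the odd-parity genotype cells
    (0,1), (1,0), (1,2), (2,1) — a purely epistatic pattern with no marginal
    effect at maf 0.5."""
    table = np.full((3, 3), low)
    for a, b in ((0, 1), (1, 0), (1, 2), (2, 1)):
        table[a, b] = high
    return table


def null_penetrance(p: float = 0.5) -> np.ndarray:
    """Constant penetrance table: no association by construction."""
    return np.full((3, 3), p)


@dataclass
class PenetranceModel:
    """A planted pairwise interaction: P(case | gA, gB) and the two mafs."""

    table: np.ndarray
    maf_a: float = 0.5
    maf_b: float = 0.5

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.shape != (3, 3):
            raise ValueError(f"penetrance table must be 3x3, got {self.table.shape}")
        if ((self.table < 0) | (self.table > 1)).any():
            raise ValueError("penetrance entries must lie in [0, 1]")
        hwe_genotype_probs(self.maf_a)
        hwe_genotype_probs(self.maf_b)

    def joint_prior(self) -> np.ndarray:
        """P(gA, gB) under HWE and linkage equilibrium between the two loci."""
        return np.outer(hwe_genotype_probs(self.maf_a), hwe_genotype_probs(self.maf_b))

    def prevalence(self) -> float:
        """Population P(case) implied by the table at these frequencies."""
        return float((self.joint_prior() * self.table).sum())

    def conditional(self, status: int) -> np.ndarray:
        """P(gA, gB | status) by Bayes inversion; status 1 = case."""
        pen = self.table if status == 1 else 1.0 - self.table
        w = self.joint_prior() * pen
        total = w.sum()
        if total <= 0:
            cls = "case" if status == 1 else "control"
            raise SimulationConfigError(
                f"penetrance table makes the {cls} class unreachable"
            )
        return w / total


@dataclass
class SimConfig:
    """Study conditions for one simulated dataset.

    ``null_maf_range`` is the sampling range for null-variant minor-allele
    frequencies (common-variant array regime). ``baseline_prevalence``,
    when given, rescales every planted table multiplicatively so its
    implied population prevalence matches; by default tables are taken as
    absolute P(case | genotypes).
    """

    n_cases: int = 527
    n_controls: int = 601
    n_null_variants: int = 100
    planted_models: list[PenetranceModel] = dc_field(default_factory=list)
    baseline_prevalence: float | None = None
    null_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise SimulationConfigError("need at least one case and one control")
        if self.n_null_variants < 0:
            raise SimulationConfigError("n_null_variants must be >= 0")
        lo, hi = self.null_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationConfigError(
                f"null_maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.null_maf_range}"
            )
        if self.baseline_prevalence is not None and not (
            0 < self.baseline_prevalence < 1
        ):
            raise SimulationConfigError(
                f"baseline_prevalence must be in (0, 1), got {self.baseline_prevalence}"
            )


def _calibrated(model: PenetranceModel, prevalence: float | None) -> PenetranceModel:
    if prevalence is None:
        return model
    implied = model.prevalence()
    if implied <= 0:
        raise SimulationConfigError("penetrance table has zero implied prevalence")
    scaled = model.table * (prevalence / implied)
    if scaled.max() > 1.0:
        raise SimulationConfigError(
            f"rescaling to prevalence {prevalence} pushes a penetrance above 1"
        )
    return PenetranceModel(table=scaled, maf_a=model.maf_a, maf_b=model.maf_b)


_BASES = np.array(list("ACGT"))


def _variant_keys(rng: np.random.Generator, n: int, start_pos: int) -> list[VariantKey]:
    keys = []
    for v in range(n):
        ref, alt = rng.choice(4, size=2, replace=False)
        keys.append(
            VariantKey("1", start_pos + 1000 * v, str(_BASES[ref]), str(_BASES[alt]))
        )
    return keys


def simulate_dataset(
    config: SimConfig,
) -> tuple[GenotypeMatrix, PhenotypeVector, dict[str, Any]]:
    """Draw one dataset and its truth manifest.

    Null variants come first, then each planted model contributes two
    variants; the manifest records planted indices, keys, tables and the
    implied prevalence. Identical configs produce identical datasets.
    """
    rng = np.random.default_rng(config.seed)
    n_ind = config.n_cases + config.n_controls
    status = np.concatenate(
        [np.ones(config.n_cases, dtype=np.int8), np.zeros(config.n_controls, dtype=np.int8)]
    )
    rng.shuffle(status)
    phenotypes = PhenotypeVector(status=status)

    lo, hi = config.null_maf_range
    null_mafs = rng.uniform(lo, hi, config.n_null_variants)
    rows = []
    for v in range(config.n_null_variants):
        probs = hwe_genotype_probs(float(null_mafs[v]))
        rows.append(rng.choice(3, size=n_ind, p=probs).astype(np.int8))

    planted_entries = []
    next_idx = config.n_null_variants
    for model in config.planted_models:
        cal = _calibrated(model, config.baseline_prevalence)
        case_d = cal.conditional(1).ravel()
        ctrl_d = cal.conditional(0).ravel()
        cells = np.empty(n_ind, dtype=np.int64)
        is_case = status == 1
        cells[is_case] = rng.choice(9, size=int(is_case.sum()), p=case_d)
        cells[~is_case] = rng.choice(9, size=int((~is_case).sum()), p=ctrl_d)
        rows.append((cells // 3).astype(np.int8))
        rows.append((cells % 3).astype(np.int8))
        planted_entries.append(
            {
                "indices": (next_idx, next_idx + 1),
                "penetrance": cal.table.tolist(),
                "maf_a": cal.maf_a,
                "maf_b": cal.maf_b,
                "prevalence": cal.prevalence(),
            }
        )
        next_idx += 2

    n_var = config.n_null_variants + 2 * len(config.planted_models)
    keys = _variant_keys(rng, n_var, start_pos=10_000)
    codes = (
        np.vstack(rows) if rows else np.empty((0, n_ind), dtype=np.int8)
    )
    matrix = GenotypeMatrix(variants=keys, codes=codes)
    for entry in planted_entries:
        ia, ib = entry["indices"]
        entry["key_a"] = str(keys[ia])
        entry["key_b"] = str(keys[ib])
    manifest = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "n_null_variants": config.n_null_variants,
        "null_maf_range": list(config.null_maf_range),
        "baseline_prevalence": config.baseline_prevalence,
        "planted_pairs": planted_entries,
    }
    return matrix, phenotypes, manifest


def write_dataset(
    matrix: GenotypeMatrix,
    phenotypes: PhenotypeVector,
    manifest: dict[str, Any],
    out_dir: str | Path,
) -> dict[str, str]:
    """Write genotypes.csv, phenotypes.csv and truth.json under ``out_dir``."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    g = write_genotypes(matrix, out_dir / "genotypes.csv")
    p = write_phenotypes(phenotypes, out_dir / "phenotypes.csv")
    manifest = dict(manifest)
    manifest["genotypes"] = str(g)
    manifest["phenotypes"] = str(p)
    t = out_dir / "truth.json"
    t.write_text(json.dumps(manifest, indent=2) + "\n")
    return {"genotypes": str(g), "phenotypes": str(p), "truth": str(t)}


def truth_recovery_report(
    results: Iterable[PairResult], manifest: dict[str, Any]
) -> list[dict[str, Any]]:
    """Detection status of every planted pair among MDR results.

    Joins by unordered variant-key pair; a planted pair missing from the
    results is reported with status "not scanned" rather than raising.
    """
    by_keys: dict[frozenset, PairResult] = {}
    results = list(results)
    ranked = sorted(results, key=lambda r: -r.mean_power)
    rank_of = {id(r): pos + 1 for pos, r in enumerate(ranked)}
    for r in results:
        by_keys[frozenset(str(k) for k in r.pair)] = r
    report = []
    for entry in manifest.get("planted_pairs", []):
        key = frozenset((entry["key_a"], entry["key_b"]))
        r = by_keys.get(key)
        if r is None:
            report.append(
                {"pair": sorted(key), "status": "not scanned", "detected": False}
            )
        else:
            report.append(
                {
                    "pair": sorted(key),
                    "status": "scanned",
                    "detected": bool(r.selected),
                    "consistency": r.consistency,
                    "mean_power": r.mean_power,
                    "rank_by_mean_power": rank_of[id(r)],
                }
            )
    return report
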