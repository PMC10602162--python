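# Methods

## Data model

A dataset is a genotype matrix (variants × individuals, classes coded
0 = homozygous reference AA, 1 = heterozygous Aa, 2 = homozygous alternate
aa) plus a binary phenotype vector (1 = case, 0 = control). On disk the
matrix uses a one-hot CSV layout: four metadata columns (chromosome,
1-based position, reference and alternate allele) followed by an
(AA, Aa, aa) indicator triple per individual. Exactly one indicator of a
triple is 1 for a called genotype; the all-zero triple is the only
representable non-one-hot state and is therefore defined as a missing
call. Individuals missing either variant of a pair are excluded from that
pair's tables and from its held-out classification; no imputation is
attempted. Coordinates are copied verbatim; the reader transparently
accepts gzip-compressed files.

## Stage 1: chi-square pair filter

For a pair (A, B) the 9 genotype combinations are cross-tabulated against
status. The test is Pearson's chi-square on the K×2 table of the K
non-empty combination columns, with df = K−1. Dropping structurally empty
columns (rather than fixing df = 8) is the standard Pearson treatment of
empty categories and avoids zero expected counts; it is a deliberate
choice where either convention could be defended. The p-value is the
upper-tail chi-square probability, computed through the regularized upper
incomplete gamma function (scipy's `chi2.sf`). No continuity correction
and no minimum-expected-count rule are applied — the filter is a screen,
not a confirmatory test — but a warning is logged when an expected count
falls below 5. Pairs for which the test is undefined (all contributing
individuals in one status class, or a single populated combination) are
skipped and logged, never fatal.

A threshold of 1.0 keeps every testable pair (the retained set is defined
by p < threshold; at threshold 1.0 the boundary case p = 1 is included so
"keep everything" means what it says).

Multiple-testing arithmetic: `bonferroni_threshold(n, α) = α/n`, and
`truncate_significant` reproduces printed thresholds that are truncated
(not rounded) to a fixed number of significant digits — e.g. α = 0.05 over
1,883,192 tests is 2.65509…×10⁻⁸, printed as 2.65×10⁻⁸.

### Vectorized counting

Genotypes are expanded to a (variants × 3 × individuals) binary indicator
array; a pair's cell count for (g_A, g_B, status) is the inner product of
indicator rows with a status weight vector, so a chunk of pairs is four
`einsum` calls. Missing calls are all-zero indicator columns and drop out
of the products automatically. The per-individual loop formulation exists
only in the test suite and the acceptance script as the independence
oracle; the two paths agree exactly (integer tallies) on randomized
datasets with missingness.

### Chunking, parallelism, resumability

Pairs are enumerated in canonical order (i < j) and processed in chunks.
The retained set is invariant to chunk size, worker count and pair
ordering; workers share memory (joblib threading backend — the work is
numpy-bound) and chunk results are merged in submission order, so output
is deterministic. The file-writing scan records each completed chunk with
the output byte offset reached; a rerun with `resume` truncates any
partial trailing chunk and continues, producing a file byte-identical to
an uninterrupted run.

## Stage 2: cross-validated MDR

Cross-validation is stratified: cases and controls are shuffled
independently with the run seed and dealt round-robin to k folds, so
per-class fold sizes differ by at most one. Stratification is a design
choice — an unstratified split can starve a fold of one class and make the
risk threshold unstable — and the seeded deal makes the plan reproducible.

Per fold and pair, the training table's cells are labeled **high risk**
when cell_cases/cell_controls strictly exceeds T = cases/controls of the
training split. The comparison is done in integer arithmetic
(cell_cases·controls > cases·cell_controls), which is exact, handles the
controls-free cell (cases > 0, controls = 0 ⇒ high) with no special case,
and makes the tie rule (ratio = T ⇒ low) bit-reproducible. Cells with no
training individuals are labeled empty and classify held-out individuals
as controls — conservative, since an empty cell carries no evidence of
risk. Held-out accuracy is computed from the pair's testing table (a
prediction depends only on the cell an individual falls in, so no
per-individual pass is needed); precision is the case fraction among
predicted cases, 0 by convention when no case is predicted.

Ranking uses held-out accuracy by default. The field's usage of
"prediction power" is ambiguous between accuracy and precision; accuracy
is the standard MDR criterion, so it ranks, and precision is always
computed and reported alongside, with a config switch (`power_metric`) to
rank by precision instead. The per-fold top set is the best
⌈top_fraction × n_pairs⌉ pairs; ties are broken by higher mean
training-table chi-square across folds, then lexicographic variant keys,
so "top 20%" is deterministic and order-invariant. A pair degenerate in a
fold (no usable held-out individuals, or a one-class training split) ranks
below every scored pair in that fold and is excluded from its means, so it
can never reach consistency k. Consistency is the number of folds in which
the pair is top; selection requires consistency = k (default 5 of 5).

Pairs are evaluated independently given the CV plan, so evaluation
parallelizes over pair chunks; only the final per-fold ranking is global.

## Synthetic cohorts

The generator mirrors a retrospective case-control design: the numbers of
cases and controls are fixed (defaults 527/601, a cohort-scale split),
and genotypes are drawn conditionally on status.

* **Null variants** are sampled under Hardy–Weinberg proportions
  (p², 2pq, q²) at a minor-allele frequency drawn uniformly from
  (0.05, 0.5) — the common-variant regime of a genotyping array —
  independently of phenotype.
* **Planted pairs** are specified as 3×3 penetrance tables
  P(case | g_A, g_B). Under linkage equilibrium the joint genotype prior
  is the outer product of the two HWE vectors, and Bayes inversion gives
  the conditional cell distributions from which case and control genotype
  pairs are drawn:
  P(g | case) ∝ P(case | g)·P(g), P(g | control) ∝ (1−P(case | g))·P(g).
  Population prevalence enters only as the normalizer Σ P(case | g)·P(g);
  a table is taken as absolute penetrance by default, and an optional
  `baseline_prevalence` rescales it multiplicatively to a stated
  prevalence (a configuration error if that pushes any entry out of [0,1]
  or leaves a status class unreachable).
* The stock XOR-style model places P(case) = 0.8 on the four odd-parity
  cells (0,1), (1,0), (1,2), (2,1) and 0.2 elsewhere; at maf 0.5 it has no
  marginal single-locus effect, making it a pure-interaction benchmark.

What the generator does **not** emulate: linkage disequilibrium between
variants, population stratification, genotyping error, and quantitative
phenotypes. Pipeline validation on these cohorts therefore demonstrates
correctness of the counting, testing and selection machinery and
statistical power against independent-variant noise — not robustness to
LD-induced correlation or confounding in real cohorts.

## Problem sizes and seeds

Validation runs use desk-scale conditions chosen so each stage is
exercised at meaningful sample sizes: oracle-equivalence checks on 20
random datasets of up to 50 variants × 300 individuals; null calibration
on 500 variants × 400 individuals (124,750 pairs); planted-pair recovery
on 100 replicates of 600 individuals with 49 null pairs competing against
one planted XOR pair; partition-invariance on a ~1,000-pair run. All
randomness flows from explicit seeds; identical configurations produce
byte-identical outputs.

## Known limitations

* **Small-sample behaviour of the chi-square screen.** With up to 9
  genotype-combination columns and a few hundred individuals, rare-cell
  expected counts are small and Pearson's chi-square is conservative in
  the tail: at 400 individuals the marginal rejection rate at α = 0.01 is
  ≈0.006–0.009 depending on allele frequencies. Moreover, in a full
  pairwise scan every variant participates in n−2 pairs and all pairs
  share one phenotype vector, so retained-fraction estimates across a
  dataset are strongly correlated between pairs: their seed-to-seed
  standard deviation is several times the nominal binomial standard error
  at the pair count. Calibration statements about the scan should
  therefore be read at dataset granularity, not per-pair-binomial
  granularity; the test statistic itself is calibrated (checked against
  independent well-populated tables).
* The risk-model threshold T is recomputed per training split from the
  individuals contributing to the pair's table; with heavy differential
  missingness T can vary between pairs within a fold.
* Selection controls consistency, not a family-wise error rate; the
  Bonferroni line reported alongside is a reference threshold for the
  chi-square p-values, not a significance guarantee for the MDR scores.
* Only pairwise interactions are considered; higher-order models and
  covariate adjustment are out of scope.
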