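# mdrscan

Exhaustive pairwise variant-interaction analysis for case-control cohorts:
a chi-square association pre-filter over all variant pairs followed by
cross-validated **Multifactor Dimensionality Reduction (MDR)** with
consistency-based selection, plus a synthetic data generator with planted
penetrance-table interactions so every stage can be validated end to end.

## The problem

Complex diseases such as Type 2 Diabetes are shaped by many variants acting
together; single-variant association scans miss effects that only appear in
the *joint* genotype distribution of two loci (epistasis). Testing all pairs
is the simplest interaction analysis, but for a genotyping panel of n
variants the pair space is n(n−1)/2 — about 6×10¹³ pairs at n ≈ 1.1×10⁷ —
so a practical pipeline screens pairs with a cheap association test first
and runs the more powerful classifier-based method on the survivors.

## The method

**Stage 1 — chi-square pair filter.** For each variant pair the 3×3
genotype-combination table (AA/Aa/aa × AA/Aa/aa), split into cases and
controls, is tested with Pearson's chi-square on the K×2 table formed by
the K non-empty genotype combinations versus status (df = K−1). Pairs with
p below a threshold (default 1×10⁻⁶) are retained. A Bonferroni threshold
α/n_tests for the retained family is reported for reference.

**Stage 2 — cross-validated MDR.** For each retained pair and each of k
(default 5) stratified cross-validation folds:

1. build the pair's training contingency table;
2. label each cell **high risk** if its case:control ratio strictly exceeds
   T = (training cases)/(training controls), else **low risk**;
3. classify held-out individuals — high-risk cell ⇒ case, otherwise ⇒
   control — and score accuracy and precision;
4. rank all pairs by held-out prediction power within the fold.

A pair's **consistency** is the number of folds in which it lands in the
top fraction (default 20%) of the ranking; pairs consistent in **all k
folds** are selected. Counting is vectorized throughout: genotypes are
expanded to binary indicator triples and every contingency table is a batch
of indicator matrix products, which makes million-pair scans tractable and
is verified exactly against per-individual loop oracles in the test suite.

**Synthetic cohorts.** The generator emulates a retrospective case-control
design: null variants drawn under Hardy–Weinberg proportions independently
of phenotype, and planted interactions specified as 3×3 penetrance tables
P(case | g_A, g_B) whose status-conditional genotype distributions are
obtained by Bayes inversion at the stated minor-allele frequencies. A truth
manifest records the planted pairs for recovery scoring.

## Worked example

```sh
cat > sim.yaml <<'EOF'
n_cases: 150
n_controls: 150
n_null_variants: 30
seed: 42
planted_models:
  - table: [[0.2, 0.8, 0.2], [0.8, 0.2, 0.8], [0.2, 0.8, 0.2]]
    maf_a: 0.5
    maf_b: 0.5
EOF

mdrscan simulate --config sim.yaml --out data
# wrote data/genotypes.csv, data/phenotypes.csv, data/truth.json
mdrscan filter --genotypes data/genotypes.csv --phenotypes data/phenotypes.csv \
               --p-threshold 0.01 --out scan
# tested 496 pairs, retained 9, skipped 0
mdrscan mdr --genotypes data/genotypes.csv --phenotypes data/phenotypes.csv \
            --pairs scan/pairs.tsv --k 5 --top-fraction 0.2 --seed 7 --out mdr
# evaluated 9 pairs, selected 1
mdrscan report --results mdr/results.tsv --alpha 0.05
```

The report groups pairs by consistency value with their mean held-out
accuracy and precision:

```
consistency	n_pairs	mean_accuracy	mean_precision
0	4	0.5575	0.5896
1	3	0.5856	0.6446
2	1	0.5967	0.6051
5	1	0.7967	0.8046
selected	1
bonferroni_threshold	5.55e-03	(alpha=0.05, n_tests=9)
```

The single pair at consistency 5 — top-20% predictor in every fold, hence
selected — is the planted interaction (`data/truth.json` lists it as
`1:40000:G>T` × `1:41000:A>T`): its XOR-style penetrance pattern gives it
~0.80 held-out accuracy while the 30 null variants hover near 0.56, the
chance level for a slightly imbalanced split. The Bonferroni line is
α divided by the number of pairs in the tested family.

The same pipeline is available as library calls (`simulate_dataset`,
`scan_pairs`, `run_mdr`, `truth_recovery_report`); the CLI only orchestrates
them and writes a JSON manifest per run.

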