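"""MDR: stratified CV, risk-model fitting, held-out scoring, consistency
selection; vectorized path checked against a per-individual loop oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from mdrscan import (
    MDRConfig,
    PairTable,
    PhenotypeVector,
    RiskModel,
    classify,
    consistency_histogram,
    fit_risk_model,
    make_cv_plan,
    run_mdr,
    score_fold,
)
from mdrscan.mdr_core import (
    EMPTY,
    HIGH,
    LOW,
    ConfigurationError,
    UndefinedThresholdError,
)

from conftest import make_matrix, random_dataset


# ---------------------------------------------------------------- CV plans

class TestMakeCvPlan:
    def test_even_split(self):
        p = PhenotypeVector(status=np.array([1] * 10 + [0] * 10))
        plan = make_cv_plan(p, k=5, seed=0)
        for f in range(5):
            te = plan.test_mask(f)
            assert (p.status[te] == 1).sum() == 2
            assert (p.status[te] == 0).sum() == 2

    def test_seed_determinism(self):
        p = PhenotypeVector(status=np.array([1] * 30 + [0] * 40))
        a = make_cv_plan(p, k=5, seed=7).assignment
        b = make_cv_plan(p, k=5, seed=7).assignment
        c = make_cv_plan(p, k=5, seed=8).assignment
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_cohort_sized_fold_counts(self):
        """527 cases / 601 controls over 5 folds: pigeonhole gives case
        counts in {105, 106} and control counts in {120, 121}."""
        p = PhenotypeVector(status=np.array([1] * 527 + [0] * 601))
        plan = make_cv_plan(p, k=5, seed=1)
        for f in range(5):
            te = plan.test_mask(f)
            assert int((p.status[te] == 1).sum()) in (105, 106)
            assert int((p.status[te] == 0).sum()) in (120, 121)

    def test_small_class_rejected(self):
        p = PhenotypeVector(status=np.array([1] * 3 + [0] * 50))
        with pytest.raises(ConfigurationError):
            make_cv_plan(p, k=5)

    @given(
        n_cases=st.integers(5, 60),
        n_controls=st.integers(5, 60),
        k=st.integers(2, 5),
        seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_partition_properties(self, n_cases, n_controls, k, seed):
        if min(n_cases, n_controls) < k:
            return
        p = PhenotypeVector(status=np.array([1] * n_cases + [0] * n_controls))
        plan = make_cv_plan(p, k=k, seed=seed)
        # every individual tested exactly once; folds nonempty; sizes within 1
        assert sorted(np.unique(plan.assignment)) == list(range(k))
        for cls in (0, 1):
            sizes = [
                int(((plan.assignment == f) & (p.status == cls)).sum())
                for f in range(k)
            ]
            assert max(sizes) - min(sizes) <= 1


# ----------------------------------------------------- risk model & scoring

def table_from_cells(cells):
    counts = np.zeros((3, 3, 2), dtype=np.int64)
    for (a, b), (cases, controls) in cells.items():
        counts[a, b] = [controls, cases]
    return PairTable(counts, int(counts.sum()))


class TestFitRiskModel:
    def test_threshold_rule_at_balanced_training(self):
        t = table_from_cells({
            (0, 0): (3, 1),   # ratio 3 > 1       -> high
            (0, 1): (2, 2),   # tie with T        -> low
            (1, 0): (1, 0),   # cases, no controls-> high
            (1, 1): (2, 2),
            (2, 2): (0, 3),
        })
        model = fit_risk_model(t)
        assert model.threshold_T == pytest.approx(1.0)
        assert model.labels[0, 0] == HIGH
        assert model.labels[0, 1] == LOW
        assert model.labels[1, 0] == HIGH
        assert model.labels[2, 2] == LOW
        assert model.labels[2, 0] == EMPTY

    def test_no_controls_undefined(self):
        t = table_from_cells({(0, 0): (4, 0), (1, 1): (2, 0)})
        with pytest.raises(UndefinedThresholdError):
            fit_risk_model(t)


class TestClassify:
    def test_all_high_predicts_all_cases(self):
        model = RiskModel(1.0, np.full((3, 3), HIGH, dtype=np.int8))
        assert classify(model, [(0, 0), (2, 1)]).tolist() == [1, 1]

    def test_empty_cell_predicts_control(self):
        labels = np.full((3, 3), LOW, dtype=np.int8)
        labels[2, 2] = EMPTY
        assert classify(RiskModel(1.0, labels), [(2, 2)]).tolist() == [0]

    def test_xor_lookup(self):
        labels = np.full((3, 3), LOW, dtype=np.int8)
        labels[0, 1] = labels[1, 0] = HIGH
        model = RiskModel(1.0, labels)
        assert classify(model, [(0, 1), (0, 0), (1, 0)]).tolist() == [1, 0, 1]


class TestScoreFold:
    def test_perfect_model(self):
        m = make_matrix([[0] * 5 + [2] * 5, [0] * 5 + [2] * 5])
        p = PhenotypeVector(status=np.array([1] * 5 + [0] * 5))
        labels = np.full((3, 3), LOW, dtype=np.int8)
        labels[0, 0] = HIGH
        s = score_fold(RiskModel(1.0, labels), m, p, (0, 1), range(10))
        assert (s.accuracy, s.precision, s.n_test_used) == (1.0, 1.0, 10)

    def test_all_control_prediction_has_zero_precision(self):
        m = make_matrix([[0, 0, 0, 0], [0, 0, 0, 0]])
        p = PhenotypeVector(status=np.array([1, 1, 0, 0]))
        s = score_fold(RiskModel(1.0, np.full((3, 3), LOW, dtype=np.int8)),
                       m, p, (0, 1), range(4))
        assert s.precision == 0.0
        assert s.accuracy == 0.5

    def test_mixed_confusion_arithmetic(self):
        """8 tested, 6 correct, 3 predicted case of which 2 true."""
        # cell (0,0) high: 2 cases + 1 control land there; rest in (1,1) low
        codes_a = [0, 0, 0, 1, 1, 1, 1, 1]
        codes_b = [0, 0, 0, 1, 1, 1, 1, 1]
        status = [1, 1, 0, 0, 0, 0, 0, 1]
        m = make_matrix([codes_a, codes_b])
        p = PhenotypeVector(status=np.array(status))
        labels = np.full((3, 3), LOW, dtype=np.int8)
        labels[0, 0] = HIGH
        s = score_fold(RiskModel(1.0, labels), m, p, (0, 1), range(8))
        assert s.accuracy == pytest.approx(0.75)
        assert s.precision == pytest.approx(2 / 3)
        assert s.n_test_used == 8

    def test_missing_individuals_excluded(self):
        m = make_matrix([[0, -1, 0], [0, 0, -1]])
        p = PhenotypeVector(status=np.array([1, 0, 0]))
        labels = np.full((3, 3), HIGH, dtype=np.int8)
        s = score_fold(RiskModel(1.0, labels), m, p, (0, 1), range(3))
        assert s.n_test_used == 1


# ------------------------------------------------------------------ run_mdr

def naive_mdr(matrix, phenotypes, pairs, config):
    """Per-individual loop reference: tables, scores, ranking, consistency."""
    plan = make_cv_plan(phenotypes, k=config.k, seed=config.seed)
    n_pairs = len(pairs)
    acc = np.zeros((config.k, n_pairs))
    prec = np.zeros((config.k, n_pairs))
    usable = np.zeros((config.k, n_pairs), dtype=bool)
    chi2 = np.zeros((config.k, n_pairs))
    for f in range(config.k):
        train = np.flatnonzero(plan.train_mask(f))
        test = np.flatnonzero(plan.test_mask(f))
        for m_, (i, j) in enumerate(pairs):
            counts = np.zeros((3, 3, 2), dtype=np.int64)
            for ind in train:
                ga, gb = matrix.codes[i, ind], matrix.codes[j, ind]
                if ga == -1 or gb == -1:
                    continue
                counts[ga, gb, phenotypes.status[ind]] += 1
            cases, controls = counts[:, :, 1].sum(), counts[:, :, 0].sum()
            if cases == 0 or controls == 0:
                continue
            high = counts[:, :, 1] * controls > cases * counts[:, :, 0]
            n_used = correct = pred_case = true_case = 0
            for ind in test:
                ga, gb = matrix.codes[i, ind], matrix.codes[j, ind]
                if ga == -1 or gb == -1:
                    continue
                n_used += 1
                pred = 1 if high[ga, gb] else 0
                correct += pred == phenotypes.status[ind]
                if pred == 1:
                    pred_case += 1
                    true_case += phenotypes.status[ind]
            if n_used == 0:
                continue
            usable[f, m_] = True
            acc[f, m_] = correct / n_used
            prec[f, m_] = true_case / pred_case if pred_case else 0.0
            flat = counts.reshape(9, 2)[:, ::-1]
            flat = flat[flat.sum(axis=1) > 0]
            if flat.shape[0] >= 2 and (flat.sum(axis=0) > 0).all():
                chi2[f, m_] = chi2_contingency(flat, correction=False).statistic
    mean_chi2 = chi2.mean(axis=0)
    keys = [(matrix.variants[i], matrix.variants[j]) for i, j in pairs]
    key_rank = np.empty(n_pairs, dtype=int)
    key_rank[sorted(range(n_pairs), key=lambda m_: keys[m_])] = np.arange(n_pairs)
    top_n = math.ceil(config.top_fraction * n_pairs)
    consistency = np.zeros(n_pairs, dtype=int)
    metric = acc if config.power_metric == "accuracy" else prec
    for f in range(config.k):
        mf = np.where(usable[f], metric[f], -np.inf)
        order = np.lexsort((key_rank, -mean_chi2, -mf))
        consistency[order[:top_n]] += 1
    return acc, prec, usable, consistency


class TestRunMdr:
    def test_singleton_pair_always_selected(self, rng):
        m, p = random_dataset(rng, 4, 60)
        res = run_mdr(m, p, [(0, 3)], MDRConfig(seed=2))
        assert res[0].consistency == 5 and res[0].selected

    def test_matches_loop_oracle(self, rng):
        m, p = random_dataset(rng, 10, 120, missing_rate=0.1)
        pairs = [(i, j) for i in range(10) for j in range(i + 1, 10)]
        cfg = MDRConfig(seed=11)
        res = run_mdr(m, p, pairs, cfg)
        acc, prec, usable, consistency = naive_mdr(m, p, pairs, cfg)
        for m_, r in enumerate(res):
            for f, s in enumerate(r.fold_scores):
                assert s.usable == usable[f, m_]
                if s.usable:
                    assert s.accuracy == pytest.approx(acc[f, m_], abs=1e-12)
                    assert s.precision == pytest.approx(prec[f, m_], abs=1e-12)
            assert r.consistency == consistency[m_]
            assert r.selected == (consistency[m_] == cfg.k)

    def test_pair_order_and_workers_invariance(self, rng):
        m, p = random_dataset(rng, 8, 100)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        cfg = MDRConfig(seed=5)
        base = run_mdr(m, p, pairs, cfg)
        rev = run_mdr(m, p, pairs[::-1], cfg)
        par = run_mdr(m, p, pairs, MDRConfig(seed=5, workers=4, chunk_size=3))
        by_pair = lambda rs: {
            r.indices: (tuple(s.accuracy for s in r.fold_scores),
                        r.consistency, r.selected)
            for r in rs
        }
        assert by_pair(base) == by_pair(rev) == by_pair(par)

    def test_top_fraction_monotonicity(self, rng):
        m, p = random_dataset(rng, 8, 100)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        lo = run_mdr(m, p, pairs, MDRConfig(seed=3, top_fraction=0.2))
        hi = run_mdr(m, p, pairs, MDRConfig(seed=3, top_fraction=0.5))
        for a, b in zip(lo, hi):
            assert b.consistency >= a.consistency

    def test_planted_xor_dominates_nulls(self, rng):
        from mdrscan import PenetranceModel, SimConfig, simulate_dataset, xor_penetrance

        cfg = SimConfig(n_cases=150, n_controls=150, n_null_variants=20,
                        planted_models=[PenetranceModel(xor_penetrance())], seed=9)
        matrix, phen, manifest = simulate_dataset(cfg)
        pairs = [(i, j) for i in range(22) for j in range(i + 1, 22)]
        res = run_mdr(matrix, phen, pairs, MDRConfig(seed=9))
        planted = tuple(manifest["planted_pairs"][0]["indices"])
        winner = max(res, key=lambda r: r.mean_power)
        assert winner.indices == planted
        assert winner.selected

    def test_empty_pairs_rejected(self, rng):
        m, p = random_dataset(rng, 4, 60)
        with pytest.raises(ConfigurationError):
            run_mdr(m, p, [], MDRConfig())


class TestConsistencyHistogram:
    def test_counts_partition_input(self, rng):
        m, p = random_dataset(rng, 8, 80)
        pairs = [(i, j) for i in range(8) for j in range(i + 1, 8)]
        res = run_mdr(m, p, pairs, MDRConfig(seed=1))
        hist = consistency_histogram(res)
        assert sum(hist.values()) == len(pairs)
        assert all(0 <= c <= 5 for c in hist)

    def test_explicit_example_and_empty(self):
        class R:
            def __init__(self, c):
                self.consistency = c

        assert consistency_histogram([R(5), R(5), R(2)]) == {5: 2, 2: 1}
        assert consistency_histogram([]) == {}
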