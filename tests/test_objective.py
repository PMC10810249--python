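import itertools

import numpy as np
import pytest

from gwolfsel.io_prep import ExpressionDataError, ExpressionMatrix
from gwolfsel.objective import (
    ConfusionCounts,
    FitnessEvaluator,
    SplitSpec,
    classifier_weights,
    compute_metrics,
    confusion_from_labels,
    ensemble_predict,
    fitness_from_components,
    metrics_from_labels,
    smote_arrays,
    smote_balance,
    stratified_split,
)
from gwolfsel.synthetic import SyntheticSpec, generate_dataset


def counting_metrics_oracle(y_true, y_pred):
    """Direct-counting oracle for every confusion-table metric."""
    tp = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 1)
    tn = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 0)
    fp = sum(1 for t, p in zip(y_true, y_pred) if t == 0 and p == 1)
    fn = sum(1 for t, p in zip(y_true, y_pred) if t == 1 and p == 0)
    n = tp + tn + fp + fn

    def div(a, b):
        return a / b if b else 0.0

    ac = (tp + tn) / n
    pr, re = div(tp, tp + fp), div(tp, tp + fn)
    f1 = div(2 * pr * re, pr + re)
    f2 = div(5 * pr * re, 4 * pr + re)
    mcc = div(tp * tn - fp * fn, np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    bac = 0.5 * (div(tp, tp + fn) + div(tn, tn + fp))
    return ac, pr, re, f1, f2, mcc, bac


class TestMetrics:
    def test_perfect_classifier(self):
        ms = compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert (ms.ac, ms.pr, ms.re, ms.f1, ms.f2, ms.bac) == (1, 1, 1, 1, 1, 1)
        assert ms.mcc == pytest.approx(1)

    def test_hand_worked_example(self):
        ms = compute_metrics(ConfusionCounts(tp=3, fp=1, fn=2, tn=4))
        assert ms.ac == pytest.approx(0.7)
        assert ms.pr == pytest.approx(0.75)
        assert ms.re == pytest.approx(0.6)
        assert ms.f1 == pytest.approx(0.6667, abs=5e-5)
        assert ms.f2 == pytest.approx(0.625)
        assert ms.mcc == pytest.approx(0.4082, abs=5e-5)
        assert ms.bac == pytest.approx(0.7)

    def test_exhaustive_oracle_small_n(self):
        for n in range(1, 5):
            for y in itertools.product([0, 1], repeat=n):
                for p in itertools.product([0, 1], repeat=n):
                    ms = metrics_from_labels(np.array(y), np.array(p))
                    expected = counting_metrics_oracle(y, p)
                    got = (ms.ac, ms.pr, ms.re, ms.f1, ms.f2, ms.mcc, ms.bac)
                    np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_degenerate_flags(self):
        ms = compute_metrics(ConfusionCounts(tp=0, tn=4, fp=0, fn=0))
        assert ms.pr == 0.0 and "pr" in ms.degenerate

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=1)


class TestSplit:
    def test_spec_arithmetic_100_samples(self):
        rngv = np.random.default_rng(0).normal(7, 1, (5, 100))
        m = ExpressionMatrix(
            rngv,
            [f"g{i}" for i in range(5)],
            [f"s{i}" for i in range(100)],
            labels=np.r_[np.ones(80, int), np.zeros(20, int)],
        )
        res = stratified_split(m, SplitSpec(seed=4))
        def counts(part):
            y = part.labels
            return int((y == 1).sum()), int((y == 0).sum())
        assert counts(res.train) == (48, 12)
        assert counts(res.validation) == (16, 4)
        assert counts(res.test) == (16, 4)
        # disjoint and exhaustive
        all_idx = np.concatenate([res.train_idx, res.validation_idx, res.test_idx])
        assert sorted(all_idx) == list(range(100))

    def test_seed_determinism(self, small_planted):
        m, _ = small_planted
        a = stratified_split(m, SplitSpec(seed=11))
        b = stratified_split(m, SplitSpec(seed=11))
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.test_idx, b.test_idx)

    def test_bad_fractions(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.5, 0.2, 0.2))

    def test_class_too_small(self, tiny_matrix):
        with pytest.raises(ExpressionDataError):
            stratified_split(tiny_matrix, SplitSpec())


class TestSMOTE:
    def test_balances_to_majority(self, rng):
        X = rng.normal(size=(50, 8))
        y = np.r_[np.ones(40, int), np.zeros(10, int)]
        Xb, yb = smote_arrays(X, y, rng=rng)
        assert (yb == 1).sum() == (yb == 0).sum() == 40

    def test_synthetic_points_on_minority_segments(self, rng):
        """Each synthetic point must be a convex combination of two minority
        originals with a single interpolation factor across coordinates."""
        X = rng.normal(size=(60, 6))
        y = np.r_[np.ones(50, int), np.zeros(10, int)]
        Xm = X[y == 0]
        n_checked = 0
        for _ in range(25):  # ~1000 synthetic points across repetitions
            Xb, yb = smote_arrays(X, y, rng=rng)
            for s in Xb[60:]:
                ok = False
                for a, b in itertools.combinations(range(len(Xm)), 2):
                    d = Xm[b] - Xm[a]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        u = np.where(np.abs(d) > 1e-12, (s - Xm[a]) / d, np.nan)
                    u_vals = u[np.isfinite(u)]
                    if len(u_vals) and np.allclose(u_vals, u_vals[0], atol=1e-8):
                        if -1e-9 <= u_vals[0] <= 1 + 1e-9:
                            ok = True
                            break
                assert ok, "synthetic point not on any minority segment"
                n_checked += 1
        assert n_checked >= 1000

    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(20, 4))
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        Xb, yb = smote_arrays(X, y, rng=rng)
        np.testing.assert_array_equal(Xb, X)

    def test_minority_of_one_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        y = np.array([1, 1, 1, 1, 0])
        with pytest.raises(ValueError):
            smote_arrays(X, y, rng=rng)

    def test_matrix_wrapper(self, small_planted, rng):
        m, _ = small_planted
        out = smote_balance(m, rng=rng)
        y = out.labels
        assert (y == 1).sum() == (y == 0).sum()
        # originals first, unchanged
        np.testing.assert_array_equal(out.values[:, : m.n_samples], m.values)


class TestWeightsAndVoting:
    def _ms(self, **kw):
        base = dict(ac=0.9, pr=0.9, re=0.9, f1=0.9, f2=0.9, mcc=0.8, bac=0.9)
        base.update(kw)
        from gwolfsel.objective import MetricSet
        return MetricSet(**base)

    def test_identical_sets_uniform(self):
        w = classifier_weights([self._ms()] * 4)
        np.testing.assert_allclose(w, 0.25)

    def test_normalization_arithmetic(self):
        # construct metric sets whose products are (0.4, 0.4, 0.1, 0.1)
        sets = [
            self._ms(ac=p, pr=1, re=1, f1=1, f2=1) for p in (0.4, 0.4, 0.1, 0.1)
        ]
        np.testing.assert_allclose(classifier_weights(sets), [0.4, 0.4, 0.1, 0.1])

    def test_zero_recall_zero_weight(self):
        sets = [self._ms()] * 3 + [self._ms(re=0.0)]
        w = classifier_weights(sets)
        assert w[3] == 0.0
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_uniform_fallback(self):
        sets = [self._ms(re=0.0)] * 4
        np.testing.assert_allclose(classifier_weights(sets), 0.25)

    def test_unanimous_vote(self):
        preds = np.ones((4, 3), dtype=int)
        out = ensemble_predict(preds, [0.25] * 4)
        np.testing.assert_array_equal(out, 1)

    def test_weighted_majority(self):
        preds = np.array([[1], [0], [0], [0]])
        assert ensemble_predict(preds, [0.4, 0.3, 0.2, 0.1])[0] == 0

    def test_tie_goes_positive(self):
        preds = np.array([[1], [0], [0], [1]])
        assert ensemble_predict(preds, [0.4, 0.3, 0.2, 0.1])[0] == 1

    def test_arity_mismatch(self):
        with pytest.raises(ValueError):
            ensemble_predict(np.ones((3, 2)), [0.5, 0.5])


class TestFitness:
    def test_full_mask_perfect_ensemble(self):
        assert fitness_from_components(1.0, 100, 100) == pytest.approx(0.2)

    def test_reported_best_set_value(self):
        # Avg 0.978 on 1404 of 10629 features -> fitness 0.0440
        fit = fitness_from_components(0.978, 1404, 10629)
        assert fit == pytest.approx(0.044, abs=5e-4)

    def test_symmetric_midpoint(self):
        assert fitness_from_components(0.5, 50, 100) == pytest.approx(0.5)

    def test_literal_form(self):
        assert fitness_from_components(1.0, 100, 100, literal=True) == pytest.approx(1.0)

    def test_monotone_in_nf(self):
        fits = [fitness_from_components(0.9, nf, 200) for nf in range(0, 201, 10)]
        assert np.all(np.diff(fits) > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            fitness_from_components(0.9, 10, 100, phi=1.5)
        with pytest.raises(ValueError):
            fitness_from_components(0.9, 101, 100)


@pytest.fixture(scope="module")
def evaluator(small_planted):
    m, _ = small_planted
    split = stratified_split(m, SplitSpec(seed=5))
    return FitnessEvaluator(split=split, seed=5), m


class TestFitnessEvaluator:

    def test_deterministic_and_cached(self, evaluator, rng):
        ev, m = evaluator
        mask = (rng.random(m.n_genes) < 0.3).astype(np.int8)
        a = ev.evaluate(mask)
        n_before = ev.n_evaluations
        b = ev.evaluate(mask.copy())
        assert a == b
        assert ev.n_evaluations == n_before  # cache hit

    def test_empty_mask_sentinel(self, evaluator):
        ev, m = evaluator
        fv = ev.evaluate(np.zeros(m.n_genes, dtype=np.int8))
        assert fv.fit == 1.0 and "empty_mask" in fv.flags

    def test_never_touches_test_samples(self, evaluator, small_planted):
        ev, m = evaluator
        split = stratified_split(m, SplitSpec(seed=5))
        assert ev.consulted_sample_ids.isdisjoint(split.test.sample_ids)

    def test_wrong_length_rejected(self, evaluator):
        ev, _ = evaluator
        with pytest.raises(ValueError):
            ev.evaluate(np.ones(3, dtype=np.int8))


def test_confusion_totals(rng):
    y = (rng.random(30) < 0.6).astype(int)
    p = (rng.random(30) < 0.5).astype(int)
    c = confusion_from_labels(y, p)
    assert c.total == 30
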