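"""Wrapper feature selection: transfer, fitness, metrics, protocols."""

import numpy as np
import pytest

from whaleopt import (HoldoutMaskEvaluator, KELMClassifier,
                      WhaleFeatureSelector, binarize, confusion_metrics,
                      evaluate_mask, exhaustive_best_mask, fitness,
                      generate_classification, kfold_protocol,
                      run_binary_optimizer, sigmoid_transfer)


class TestTransfer:
    def test_midpoint_and_known_value(self):
        assert sigmoid_transfer(0.0) == 0.5
        assert sigmoid_transfer(3.0) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)))

    def test_monotone_and_symmetric(self):
        xs = np.linspace(-30, 30, 101)
        ys = sigmoid_transfer(xs)
        assert np.all(np.diff(ys) > 0)
        assert np.allclose(ys + sigmoid_transfer(-xs), 1.0)

    def test_binarize_saturation_and_tie_rule(self):
        rng = np.random.default_rng(0)
        bits = binarize(np.full(50, 30.0), rng)
        assert bits.all()
        # at x=0 the transfer is exactly 0.5; r == 0.5 selects the bit

        class HalfRng:
            def random(self, n):
                return np.full(n, 0.5)

            def integers(self, n):
                return 0

        assert binarize(np.zeros(4), HalfRng()).all()

    def test_binarize_repairs_empty_mask(self):
        rng = np.random.default_rng(1)
        bits = binarize(np.full(6, -1e3), rng)
        assert bits.sum() == 1

    def test_empirical_frequency_matches_transfer(self):
        rng = np.random.default_rng(2)
        n = 100000
        x = np.ones(n)
        hits = binarize(x, rng).mean()
        p = sigmoid_transfer(1.0)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits - p) < 3 * se


class TestFitness:
    @pytest.mark.parametrize("error,k,D,expected", [
        (0.0, 0, 36, 0.0),
        (1.0, 36, 36, 1.0),
        (0.1, 18, 36, 0.104),
    ])
    def test_weighted_objective(self, error, k, D, expected):
        assert fitness(error, k, D) == pytest.approx(expected)

    def test_validation(self):
        with pytest.raises(ValueError):
            fitness(1.5, 0, 10)
        with pytest.raises(ValueError):
            fitness(0.5, 11, 10)
        with pytest.raises(ValueError):
            fitness(0.5, 0, 0)

    def test_bounded_on_unit_inputs(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            e = rng.random()
            k = rng.integers(0, 21)
            assert 0.0 <= fitness(e, int(k), 20) <= 1.0


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        m = confusion_metrics(y, y)
        for key in ("accuracy", "specificity", "precision", "recall",
                    "f_measure"):
            assert m[key] == 1.0

    def test_hand_computed_table(self):
        y_true = np.repeat([1, 0], [55, 45])
        y_pred = np.concatenate([
            np.ones(50), np.zeros(5),       # 50 TP, 5 FN
            np.ones(5), np.zeros(40)])      # 5 FP, 40 TN
        m = confusion_metrics(y_true, y_pred)
        assert m["accuracy"] == pytest.approx(0.90)
        assert m["specificity"] == pytest.approx(8 / 9)
        assert m["precision"] == pytest.approx(10 / 11)
        assert m["recall"] == pytest.approx(10 / 11)
        assert m["f_measure"] == pytest.approx(10 / 11)

    def test_all_positive_predictions(self):
        y_true = np.array([1, 1, 0, 0])
        m = confusion_metrics(y_true, np.ones(4))
        assert m["specificity"] == 0.0
        assert m["recall"] == 1.0

    def test_zero_denominator_flagged(self):
        y_true = np.array([1, 1, 0, 0])
        with pytest.warns(UserWarning, match="precision"):
            m = confusion_metrics(y_true, np.zeros(4))
        assert m["precision"] == 0.0
        assert "precision" in m["degenerate"]


@pytest.fixture(scope="module")
def planted():
    return generate_classification(n=200, D=8, k_informative=3, effect=2.5,
                                   seed=11)


class TestEvaluator:
    def test_planted_mask_separates(self, planted):
        mask = np.zeros(8, bool)
        mask[sorted(planted.planted)] = True
        err = evaluate_mask(mask, planted.X, planted.y, seed=3)
        assert err < 0.15

    def test_pure_noise_mask_is_chance_level(self):
        ds = generate_classification(n=400, D=6, k_informative=1, effect=0.0,
                                     seed=12)
        mask = np.ones(6, bool)
        err = evaluate_mask(mask, ds.X, ds.y, seed=4)
        assert 0.3 < err < 0.7

    def test_deterministic_and_cached(self, planted):
        ev = HoldoutMaskEvaluator(planted.X, planted.y, seed=5)
        mask = np.array([1, 0, 1, 1, 0, 0, 1, 0], bool)
        assert ev.error(mask) == ev.error(mask.copy())
        assert evaluate_mask(mask, planted.X, planted.y, seed=5) == \
            ev.error(mask)

    def test_matches_direct_kelm_fit(self, planted):
        """The fast masked-kernel path reproduces a plain KELM fit on the
        same inner split."""
        from sklearn.model_selection import train_test_split
        ev = HoldoutMaskEvaluator(planted.X, planted.y, seed=6)
        X_tr, X_val, y_tr, y_val = train_test_split(
            planted.X, planted.y, test_size=0.2, stratify=planted.y,
            random_state=6)
        for mask in (np.array([1, 1, 0, 0, 1, 0, 1, 0], bool),
                     np.ones(8, bool)):
            model = KELMClassifier().fit(X_tr[:, mask], y_tr)
            direct = float(np.mean(model.predict(X_val[:, mask]) != y_val))
            assert ev.error(mask) == pytest.approx(direct, abs=1e-12)

    def test_invalid_masks_rejected(self, planted):
        ev = HoldoutMaskEvaluator(planted.X, planted.y, seed=7)
        with pytest.raises(ValueError):
            ev.error(np.zeros(8, bool))
        with pytest.raises(ValueError):
            ev.error(np.ones(5, bool))


class TestBinaryOptimizer:
    def test_never_beats_exhaustive_minimum(self, planted):
        ev = HoldoutMaskEvaluator(planted.X, planted.y, seed=8)
        _, best = exhaustive_best_mask(ev, 8)
        mask, fit, curve = run_binary_optimizer(
            planted.X, planted.y, n_pop=10, n_iter=20, seed=1, evaluator=ev)
        assert fit >= best - 1e-12
        assert all(b <= a for a, b in zip(curve, curve[1:]))

    def test_reproducible_mask(self, planted):
        ev1 = HoldoutMaskEvaluator(planted.X, planted.y, seed=9)
        ev2 = HoldoutMaskEvaluator(planted.X, planted.y, seed=9)
        m1, f1, _ = run_binary_optimizer(planted.X, planted.y, n_pop=8,
                                         n_iter=12, seed=2, evaluator=ev1)
        m2, f2, _ = run_binary_optimizer(planted.X, planted.y, n_pop=8,
                                         n_iter=12, seed=2, evaluator=ev2)
        assert np.array_equal(m1, m2) and f1 == f2

    def test_bwoa_variant_and_validation(self, planted):
        mask, fit, _ = run_binary_optimizer(planted.X, planted.y,
                                            algorithm="bwoa", n_pop=8,
                                            n_iter=10, seed=3)
        assert mask.any()
        with pytest.raises(ValueError):
            run_binary_optimizer(planted.X, planted.y, algorithm="nope")
        with pytest.raises(ValueError):
            run_binary_optimizer(np.empty((0, 3)), np.empty(0))


class TestKfoldProtocol:
    def test_report_structure_and_counts(self, planted):
        res = kfold_protocol(planted.X, planted.y, k=3, repeats=2, seed=4,
                             n_pop=8, n_iter=10)
        assert len(res.per_fold) == 6 == res.n_runs
        assert res.selection_counts.sum() >= res.n_runs  # >=1 feature/run
        assert np.all(res.selection_counts <= res.n_runs)
        for rec in res.per_fold:
            assert 0.0 <= rec["accuracy"] <= 1.0
            assert rec["n_selected"] == int(np.sum(rec["mask"]))
        csv = res.to_csv()
        assert csv.count("\n") == 6 + 3  # header + folds + AVG + STD

    def test_masks_derive_from_training_partition_only(self, planted):
        """Dropping a held-out fold entirely does not change the mask the
        optimizer finds on the training partition (no leakage path)."""
        X, y = planted.X, planted.y
        from sklearn.model_selection import StratifiedKFold
        skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=4)
        tr, te = next(iter(skf.split(X, y)))
        ev1 = HoldoutMaskEvaluator(X[tr], y[tr], seed=10)
        m1, _, _ = run_binary_optimizer(X[tr], y[tr], n_pop=8, n_iter=10,
                                        seed=5, evaluator=ev1)
        X_perturbed = X.copy()
        X_perturbed[te] += 100.0  # corrupt only held-out rows
        ev2 = HoldoutMaskEvaluator(X_perturbed[tr], y[tr], seed=10)
        m2, _, _ = run_binary_optimizer(X_perturbed[tr], y[tr], n_pop=8,
                                        n_iter=10, seed=5, evaluator=ev2)
        assert np.array_equal(m1, m2)

    def test_k_reduced_when_class_too_small(self):
        ds = generate_classification(n=30, D=4, k_informative=2, effect=2.0,
                                     class_balance=0.15, seed=13)
        with pytest.warns(UserWarning, match="reducing"):
            res = kfold_protocol(ds.X, ds.y, k=10, repeats=1, seed=1,
                                 n_pop=6, n_iter=5)
        assert res.n_runs < 10


class TestSelectorEstimator:
    def test_sklearn_selector_interface(self, planted):
        sel = WhaleFeatureSelector(n_pop=8, n_iter=10, random_state=3)
        Xt = sel.fit_transform(planted.X, planted.y)
        assert Xt.shape == (200, sel.support_.sum())
        assert sel.get_support().dtype == bool
        from sklearn.base import clone
        assert clone(sel).get_params() == sel.get_params()
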