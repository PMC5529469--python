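"""Multi-kernel SVM, weight grids, and nested leave-one-out CV."""

import numpy as np
import pytest
from sklearn.svm import SVC

from hyfcnet import (
    ClassifierConfig,
    composite_kernel,
    linear_gram,
    nested_loocv,
    svm_fit_predict,
    weight_grid,
)
from hyfcnet.classification import KernelBundle, normalize_rows
from hyfcnet.errors import (
    DegenerateLabelsError,
    InsufficientDataError,
    InvalidWeightError,
    ShapeError,
)


def _random_psd(rng, n):
    x = rng.standard_normal((n, n + 2))
    return x @ x.T / (n + 2)


class TestLinearGram:
    def test_identical_unit_subjects(self):
        f = np.array([[3.0, 4.0], [3.0, 4.0]])
        g = linear_gram(f, normalize=True)
        np.testing.assert_allclose(g, 1.0)

    def test_orthogonal_subjects(self):
        f = np.array([[1.0, 0.0], [0.0, 2.0]])
        g = linear_gram(f)
        assert g[0, 1] == 0.0

    def test_matches_double_loop(self, rng):
        f = rng.standard_normal((5, 3))
        g = linear_gram(f, normalize=False)
        for a in range(5):
            for b in range(5):
                expected = sum(f[a, d] * f[b, d] for d in range(3))
                assert g[a, b] == pytest.approx(expected, abs=1e-12)

    def test_empty_features_rejected(self):
        with pytest.raises(ShapeError):
            linear_gram(np.empty((4, 0)))

    def test_normalized_rows_have_unit_norm(self, rng):
        f = rng.standard_normal((6, 4))
        np.testing.assert_allclose(np.linalg.norm(normalize_rows(f), axis=1), 1.0)


class TestCompositeKernel:
    def test_vertex_weight_returns_that_kernel(self, rng):
        grams = [_random_psd(rng, 5) for _ in range(3)]
        np.testing.assert_array_equal(
            composite_kernel(grams, (1.0, 0.0, 0.0)), grams[0]
        )

    def test_equal_grams_any_weights(self, rng):
        g = _random_psd(rng, 4)
        out = composite_kernel([g, g, g], (0.3, 0.5, 0.2))
        np.testing.assert_allclose(out, g, atol=1e-12)

    def test_psd_at_reference_weights(self, rng):
        grams = [_random_psd(rng, 6) for _ in range(3)]
        composite = composite_kernel(grams, (0.3, 0.5, 0.2))
        assert np.linalg.eigvalsh(composite).min() >= -1e-9

    def test_off_simplex_rejected(self, rng):
        grams = [_random_psd(rng, 3) for _ in range(3)]
        with pytest.raises(InvalidWeightError):
            composite_kernel(grams, (0.5, 0.5, 0.5))
        with pytest.raises(InvalidWeightError):
            composite_kernel(grams, (-0.2, 0.6, 0.6))

    def test_bundle_builds_composite_in_low_high_assoc_order(self, rng):
        grams = {"high": _random_psd(rng, 4), "low": _random_psd(rng, 4)}
        bundle = KernelBundle(grams, (0.25, 0.75))
        np.testing.assert_allclose(
            bundle.composite, 0.25 * grams["low"] + 0.75 * grams["high"]
        )


class TestWeightGrid:
    @pytest.mark.parametrize("step,count", [(0.5, 6), (1.0, 3), (0.1, 66)])
    def test_counts(self, step, count):
        grid = weight_grid(step)
        assert len(grid) == count
        assert len(set(grid)) == count
        for tau in grid:
            assert min(tau) >= 0
            assert sum(tau) == pytest.approx(1.0, abs=1e-12)

    def test_single_kernel(self):
        assert weight_grid(0.1, n_kernels=1) == [(1.0,)]


class TestSvm:
    def test_separable_toy(self):
        f = np.array([[-1.0], [-1.0], [1.0], [1.0]])
        y = np.array([-1.0, -1.0, 1.0, 1.0])
        gram = f @ f.T
        dec, pred = svm_fit_predict(gram, y, gram)
        np.testing.assert_array_equal(pred, y)
        assert np.all(np.sign(dec) == y)

    def test_symmetric_pair_midpoint(self):
        f = np.array([[0.0], [2.0]])
        y = np.array([-1.0, 1.0])
        gram = f @ f.T
        mid = np.array([[1.0]]) @ f.T
        dec, _ = svm_fit_predict(gram, y, mid)
        assert dec[0] == pytest.approx(0.0, abs=1e-8)

    def test_duplication_invariance(self, rng):
        # cleanly separated clusters: no dual variable sits at the box
        # bound, so duplicating every subject leaves the solution fixed
        y = np.array([1.0, 1.0, 1.0, 1.0, -1.0, -1.0, -1.0, -1.0])
        f = 0.3 * rng.standard_normal((8, 3))
        f[:, 0] += 3.0 * y
        test = 0.3 * rng.standard_normal((4, 3))
        dec_single, _ = svm_fit_predict(f @ f.T, y, test @ f.T)
        f2 = np.vstack([f, f])
        y2 = np.concatenate([y, y])
        dec_double, _ = svm_fit_predict(f2 @ f2.T, y2, test @ f2.T)
        np.testing.assert_allclose(dec_double, dec_single, atol=1e-5)

    def test_agrees_with_libsvm(self, rng):
        """Dual-route check: the SMO solver reproduces sklearn's SVC
        decision function on random precomputed-kernel problems."""
        for trial in range(20):
            n = int(rng.integers(6, 25))
            f = normalize_rows(rng.standard_normal((n, int(rng.integers(2, 6)))))
            y = rng.choice([-1.0, 1.0], size=n)
            if np.unique(y).size < 2:
                continue
            gram = f @ f.T
            test = normalize_rows(rng.standard_normal((3, f.shape[1])))
            dec, _ = svm_fit_predict(gram, y, test @ f.T)
            ref = SVC(kernel="precomputed", C=1.0, tol=1e-8).fit(gram, y)
            np.testing.assert_allclose(dec, ref.decision_function(test @ f.T), atol=1e-4)

    def test_single_class_fold_rejected(self, rng):
        f = rng.standard_normal((4, 2))
        with pytest.raises(DegenerateLabelsError):
            svm_fit_predict(f @ f.T, np.ones(4), f @ f.T)


def _fast_config(**kw):
    defaults = dict(tau_step=0.5, n_lambdas=4)
    defaults.update(kw)
    return ClassifierConfig(**defaults)


class TestNestedLoocv:
    def test_oracle_feature_reaches_perfect_accuracy(self, rng):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        oracle = np.where(y == 1, 1.0, -1.0)[:, None]
        feats = {
            t: np.column_stack([oracle, 0.05 * rng.standard_normal((8, 3))])
            for t in ("low", "high", "associated")
        }
        res = nested_loocv(feats, y, _fast_config())
        assert res.metrics.acc == 1.0
        assert res.metrics.auc == 1.0

    def test_vertex_tau_grid_reproduces_single_type(self, rng):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        feats = {
            "low": rng.standard_normal((8, 6)) + 0.8 * np.where(y == 1, 1, -1)[:, None],
            "high": rng.standard_normal((8, 6)),
            "associated": rng.standard_normal((8, 6)),
        }
        multi = nested_loocv(feats, y, _fast_config(), taus=[(1.0, 0.0, 0.0)])
        single = nested_loocv({"low": feats["low"]}, y, _fast_config())
        np.testing.assert_array_equal(multi.y_pred, single.y_pred)
        np.testing.assert_allclose(multi.decision_values, single.decision_values, atol=1e-12)

    def test_permutation_null_near_chance(self, rng):
        """Shuffled labels give ~50% accuracy on average."""
        accs = []
        for rep in range(12):
            y = np.array([0] * 5 + [1] * 5)
            rng.shuffle(y)
            if min(np.sum(y == 0), np.sum(y == 1)) < 3:
                continue
            feats = {"low": rng.standard_normal((10, 6))}
            res = nested_loocv(feats, y, _fast_config(n_lambdas=3))
            accs.append(res.metrics.acc)
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.5) <= max(3 * se, 0.2)

    def test_determinism(self, rng):
        y = np.array([0, 0, 0, 1, 1, 1])
        feats = {"low": rng.standard_normal((6, 5)), "high": rng.standard_normal((6, 5))}
        a = nested_loocv(feats, y, _fast_config())
        b = nested_loocv(feats, y, _fast_config())
        np.testing.assert_array_equal(a.decision_values, b.decision_values)
        assert [f.weights for f in a.folds] == [f.weights for f in b.folds]

    def test_small_cohort_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            nested_loocv({"low": rng.standard_normal((5, 3))}, np.array([0, 0, 1, 1, 1]))
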