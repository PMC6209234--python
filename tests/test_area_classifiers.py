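"""Sparse autoencoder objective/gradients/training and probabilistic SVM."""

import numpy as np
import pytest
from scipy.special import expit

from rsdiag.area_classifiers import (
    SAEHyperParams,
    SparseAutoencoder,
    grid_search_sae,
    grid_search_svm,
    membership_score,
    sae_loss,
    sae_loss_grad,
    train_area_svm,
    train_sae,
    _init_params,
    _loss_and_grad,
    _pack,
    _unpack,
)


def _model(d, h, hyper=None, seed=0):
    theta = _init_params(d, h, seed)
    w1, b1, w2, b2 = _unpack(theta, d, h)
    return SparseAutoencoder(w1, b1, w2, b2,
                             hyper or SAEHyperParams(hidden_size=h))


class TestLoss:
    def test_kl_vanishes_at_target_activation(self, rng):
        # zero encoder weights, bias at logit(rho) -> every rho_hat_j == rho
        d, h, rho = 4, 3, 0.3
        hyper = SAEHyperParams(hidden_size=h, sparsity_target=rho,
                               sparsity_weight=10.0, weight_decay=0.0)
        b1 = np.full(h, np.log(rho / (1 - rho)))
        m = SparseAutoencoder(np.zeros((h, d)), b1, np.zeros((d, h)),
                              np.zeros(d), hyper)
        x = rng.normal(size=(6, d))
        # loss equals pure reconstruction error (x_hat = 0)
        assert sae_loss(m, x) == pytest.approx(
            0.5 * np.mean(np.sum(x**2, axis=1)))

    def test_zero_everything_zero_reconstruction_term(self):
        hyper = SAEHyperParams(hidden_size=2, sparsity_weight=0.0,
                               weight_decay=0.123)
        m = SparseAutoencoder(np.zeros((2, 3)), np.zeros(2),
                              np.zeros((3, 2)), np.zeros(3), hyper)
        # rho_hat = 0.5 everywhere, beta = 0, weights zero => loss 0
        assert sae_loss(m, np.zeros((4, 3))) == pytest.approx(0.0)

    def test_nan_input_rejected(self):
        m = _model(3, 2)
        with pytest.raises(ValueError):
            sae_loss(m, np.array([[1.0, np.nan, 0.0]]))

    def test_analytic_gradient_matches_finite_differences(self, rng):
        """Central finite differences on a 5x4 toy, rel. error < 1e-5."""
        d, h = 4, 3
        hyper = SAEHyperParams(hidden_size=h, sparsity_target=0.2,
                               sparsity_weight=2.5, weight_decay=1e-4)
        x = rng.normal(size=(5, d))
        theta = _init_params(d, h, seed=2)
        _, grad = _loss_and_grad(theta, x, hyper)
        eps = 1e-6
        num = np.zeros_like(theta)
        for i in range(len(theta)):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += eps
            tm[i] -= eps
            num[i] = (_loss_and_grad(tp, x, hyper)[0]
                      - _loss_and_grad(tm, x, hyper)[0]) / (2 * eps)
        rel = np.abs(grad - num) / np.maximum(np.abs(num), 1e-8)
        assert rel.max() < 1e-5


class TestTraining:
    def test_rank_one_data_reconstructed(self, rng):
        u = rng.normal(size=(20, 1))
        v = rng.normal(size=(1, 6))
        x = u @ v
        hyper = SAEHyperParams(hidden_size=4, sparsity_weight=0.0,
                               weight_decay=0.0)
        m = train_sae(x, hyper, seed=0, max_iter=2000, tol=1e-12)
        assert m.reconstruction_error(x) < 1e-3 * np.mean(np.sum(x**2, 1))

    def test_seeded_determinism(self, rng):
        x = rng.normal(size=(15, 5))
        m1 = train_sae(x, seed=7)
        m2 = train_sae(x, seed=7)
        assert np.array_equal(m1.w_enc, m2.w_enc)
        assert np.array_equal(m1.b_dec, m2.b_dec)

    def test_loss_not_above_initialization(self, rng):
        x = rng.normal(size=(12, 6))
        m = train_sae(x, seed=1)
        assert m.final_loss <= m.loss_trace[0] + 1e-12

    def test_strong_sparsity_pins_mean_activation(self, rng):
        x = rng.normal(size=(30, 8))
        hyper = SAEHyperParams(hidden_size=4, sparsity_target=0.15,
                               sparsity_weight=200.0, weight_decay=0.0)
        m = train_sae(x, hyper, seed=0, max_iter=1000)
        rho_hat = m.encode(x).mean(axis=0)
        assert np.all(np.abs(rho_hat - 0.15) < 0.05)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            train_sae(np.ones((1, 4)))


class TestGridSearchSAE:
    def test_singleton_grid_returned(self, rng):
        x = rng.normal(size=(20, 5))
        grids = {"hidden_size": [12], "sparsity_target": [0.2],
                 "sparsity_weight": [2.0], "weight_decay": [1e-5]}
        best = grid_search_sae(x, grids, seed=0)
        assert best == SAEHyperParams(12, 0.2, 2.0, 1e-5)

    def test_selection_matches_exhaustive_evaluation(self, rng):
        """The returned combination is the argmin of held-out error."""
        import itertools

        u = rng.normal(size=(40, 2))
        v = rng.normal(size=(2, 6))
        x = u @ v + rng.normal(size=(40, 6)) * 0.05
        train, val = x[:30], x[30:]
        grids = {"hidden_size": [2, 4], "sparsity_target": [0.1, 0.5],
                 "sparsity_weight": [1.0, 20.0], "weight_decay": [1e-6]}
        best = grid_search_sae(train, grids, validation=val, seed=0,
                               max_iter=300)
        errs = {}
        for h, r, b, w in itertools.product(*grids.values()):
            hyper = SAEHyperParams(h, r, b, w)
            m = train_sae(train, hyper, seed=0, max_iter=300)
            errs[hyper] = m.reconstruction_error(val)
        assert errs[best] == min(errs.values())

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_sae(rng.normal(size=(20, 4)), {"hidden_size": []})


class TestAreaSVM:
    def _clouds(self, rng, n=30, d=3, gap=10.0):
        x = np.vstack([rng.normal(size=(n, d)),
                       rng.normal(size=(n, d)) + gap])
        y = np.array([0] * n + [1] * n)
        return x, y

    def test_separated_clouds_perfect_training_accuracy(self, rng):
        x, y = self._clouds(rng)
        svm = train_area_svm(x, y)
        assert np.mean(svm.predict(x) == y) == 1.0

    def test_contradictory_points_bounded_accuracy(self):
        x = np.array([[0.0, 0.0]] * 4)
        y = np.array([0, 1, 0, 1])
        svm = train_area_svm(x, y)
        assert np.mean(svm.predict(x) == y) <= 0.5

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_area_svm(rng.normal(size=(10, 2)), np.zeros(10))

    def test_default_hyperparameters_recorded(self, rng):
        x, y = self._clouds(rng)
        svm = train_area_svm(x, y)
        assert svm.kernel_scale == 5.0
        assert svm.box_constraint == 12.0

    def test_membership_is_sigmoid_of_decision(self, rng):
        x, y = self._clouds(rng)
        svm = train_area_svm(x, y)
        pts = rng.normal(size=(10, 3)) + 5.0
        d = svm.decision_value(pts)
        assert np.allclose(membership_score(svm, pts), expit(d))
        s = membership_score(svm, pts)
        assert np.all((s > 0) & (s < 1))
        # monotone in decision value
        order = np.argsort(d)
        assert np.all(np.diff(s[order]) >= 0)

    def test_sigmoid_landmarks(self):
        assert expit(0.0) == 0.5
        assert expit(10.0) == pytest.approx(0.99995, abs=1e-5)

    def test_label_flip_symmetry(self, rng):
        x, y = self._clouds(rng)
        pts = rng.normal(size=(20, 3)) * 4 + 5
        s = membership_score(train_area_svm(x, y), pts)
        s_flip = membership_score(train_area_svm(x, 1 - y), pts)
        assert np.allclose(s_flip, 1.0 - s, atol=5e-3)  # SVM solver tolerance


class TestGridSearchSVM:
    def test_singleton_grid(self, rng):
        x = np.vstack([rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 5])
        y = np.array([0] * 10 + [1] * 10)
        best = grid_search_svm((x, y), (x, y),
                               {"kernel_scale": [3.0], "box_constraint": [7.0]})
        assert best == (3.0, 7.0)

    def test_tie_prefers_smallest_scale_then_box(self, rng):
        x = np.vstack([rng.normal(size=(10, 2)), rng.normal(size=(10, 2)) + 50])
        y = np.array([0] * 10 + [1] * 10)
        best = grid_search_svm((x, y), (x, y),
                               {"kernel_scale": [2.0, 8.0],
                                "box_constraint": [1.0, 12.0]})
        assert best == (2.0, 1.0)  # all perfect -> lexicographic minimum

    def test_better_scale_wins(self, rng):
        # fine structure at scale ~0.5: a huge kernel scale underfits
        x = rng.normal(size=(80, 1)) * 0.5
        y = (np.sin(x[:, 0] * 8) > 0).astype(int)
        xv = rng.normal(size=(60, 1)) * 0.5
        yv = (np.sin(xv[:, 0] * 8) > 0).astype(int)
        ks, _ = grid_search_svm((x, y), (xv, yv),
                                {"kernel_scale": [0.3, 30.0],
                                 "box_constraint": [12.0]})
        assert ks == 0.3

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_svm((np.zeros((4, 1)), np.array([0, 1, 0, 1])),
                            (np.zeros((2, 1)), np.array([0, 1])),
                            {"kernel_scale": [], "box_constraint": [1.0]})
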