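"""The sparse LSTM: penalties, gradients, training and prediction contracts."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oglcsite as og
from oglcsite.srnn import (
    CLIP_EPS,
    build_model,
    classify,
    cross_entropy,
    l1_penalty,
    loss_and_grad,
    penalty_and_grad,
    predict_proba,
    regularized_loss,
    sgl_penalty,
    load_model,
    save_model,
)

from conftest import separable_dataset


def tiny_spec(**overrides):
    base = dict(
        input_dim=3, half_width=1, hidden_size=2, dense_sizes=(3,),
        reg_input="sgl", reg_hidden="l1", lam=0.1, alpha=0.5, seed=7,
    )
    base.update(overrides)
    return og.RegularizedModelSpec(**base)


class TestForward:
    def test_softmax_normalization(self):
        spec = og.RegularizedModelSpec(
            input_dim=25, half_width=10, hidden_size=8, dense_sizes=(4,)
        )
        model = build_model(spec)
        rng = np.random.default_rng(0)
        probs = model.forward(rng.uniform(size=(1, 21, 25)))
        assert probs.shape == (1, 2)
        assert probs.sum() == pytest.approx(1.0)

    def test_same_seed_identical_init(self):
        a = build_model(tiny_spec()).get_flat()
        b = build_model(tiny_spec()).get_flat()
        np.testing.assert_array_equal(a, b)

    def test_batch_shapes(self):
        model = build_model(tiny_spec())
        probs = model.forward(np.zeros((5, 3, 3)))
        assert probs.shape == (5, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0)

    def test_batch_vs_single_consistency(self):
        model = build_model(tiny_spec())
        X = np.random.default_rng(1).normal(size=(6, 3, 3))
        batch = predict_proba(model, X)
        singles = np.array([predict_proba(model, X[i : i + 1])[0] for i in range(6)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_dim_mismatch_raises(self):
        with pytest.raises(ValueError):
            build_model(tiny_spec()).forward(np.zeros((2, 3, 9)))


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy([1], [1 - CLIP_EPS]) < 1e-6

    def test_uniform_prediction_is_ln2(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2))

    def test_batch_mean(self):
        assert cross_entropy([1, 0], [0.5, 0.5]) == pytest.approx(np.log(2))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            cross_entropy([1, 0], [0.5])


class TestPenalties:
    def test_l1_hand_values(self):
        assert l1_penalty(np.array([0.5, -0.5, 0.0])) == 1.0
        assert l1_penalty(np.zeros(5)) == 0.0

    def test_sgl_hand_values(self):
        w = np.array([3.0, 4.0])
        assert sgl_penalty(w, alpha=1.0) == pytest.approx(np.sqrt(2) * 5, abs=1e-9)
        assert sgl_penalty(w, alpha=0.0) == pytest.approx(7.0, abs=1e-9)
        assert sgl_penalty(w, alpha=0.5) == pytest.approx(
            0.5 * np.sqrt(2) * 5 + 0.5 * 7, abs=1e-9
        )

    def test_overlapping_groups_rejected(self):
        with pytest.raises(ValueError):
            sgl_penalty(np.ones(4), groups=[np.array([0, 1]), np.array([1, 2])])

    @given(st.integers(0, 500))
    def test_homogeneity_and_alpha_reduction(self, draw):
        rng = np.random.default_rng(draw)
        w = rng.normal(size=rng.integers(1, 30))
        c = float(rng.normal() * 3)
        assert l1_penalty(c * w) == pytest.approx(abs(c) * l1_penalty(w))
        assert sgl_penalty(c * w, alpha=0.7) == pytest.approx(
            abs(c) * sgl_penalty(w, alpha=0.7)
        )
        assert sgl_penalty(w, alpha=0.0) == pytest.approx(l1_penalty(w))


class TestObjective:
    def test_lambda_zero_equals_cross_entropy(self):
        spec = tiny_spec(lam=0.0)
        model = build_model(spec)
        X = np.random.default_rng(2).normal(size=(4, 3, 3))
        y = np.array([0, 1, 0, 1])
        p = model.forward(X)[:, 1]
        assert regularized_loss(y, p, model, spec) == cross_entropy(y, p)

    @given(st.integers(0, 100))
    def test_decomposition_for_random_weights(self, draw):
        """objective - cross_entropy == lambda * R(W) exactly."""
        rng = np.random.default_rng(draw)
        lam = float(rng.uniform(0, 2))
        spec = tiny_spec(lam=lam)
        model = build_model(spec)
        model.set_flat(rng.normal(size=model.n_parameters))
        X = rng.normal(size=(3, 3, 3))
        y = rng.integers(0, 2, size=3)
        p = model.forward(X)[:, 1]
        penalty = penalty_and_grad(model, spec)[0]
        assert regularized_loss(y, p, model, spec) - cross_entropy(y, p) == pytest.approx(
            lam * penalty
        )

    def test_doubling_lambda_doubles_penalty_term(self):
        model = build_model(tiny_spec(lam=0.5))
        X = np.random.default_rng(3).normal(size=(4, 3, 3))
        y = np.array([1, 0, 1, 0])
        p = model.forward(X)[:, 1]
        gap1 = regularized_loss(y, p, model, tiny_spec(lam=0.5)) - cross_entropy(y, p)
        gap2 = regularized_loss(y, p, model, tiny_spec(lam=1.0)) - cross_entropy(y, p)
        assert gap2 == pytest.approx(2 * gap1)


class TestGradient:
    @pytest.mark.parametrize("reg", [("none", "none"), ("l1", "none"), ("sgl", "sgl")])
    def test_matches_finite_differences(self, reg):
        """Analytic gradient of the full objective vs central differences."""
        spec = tiny_spec(reg_input=reg[0], reg_hidden=reg[1], lam=0.05)
        model = build_model(spec)
        rng = np.random.default_rng(4)
        X = rng.normal(size=(5, 3, 3))
        y = rng.integers(0, 2, size=5)
        _, grad = loss_and_grad(model, X, y, spec)
        flat = model.get_flat()
        numeric = np.zeros_like(flat)
        h = 1e-6
        for i in range(flat.size):
            for delta, sign in ((h, 1.0), (-h, -1.0)):
                probe = flat.copy()
                probe[i] += delta
                model.set_flat(probe)
                p = model.forward(X)[:, 1]
                numeric[i] += sign * regularized_loss(y, p, model, spec)
        model.set_flat(flat)
        numeric /= 2 * h
        rel = np.abs(numeric - grad).max() / max(np.abs(numeric).max(), 1e-12)
        assert rel <= 1e-4


class TestTraining:
    def test_separable_data_reaches_perfect_training_f1(self):
        ds = separable_dataset(n=500, seed=5)
        train_ds, val_ds = og.split_train_test(ds, 0.2, 5)
        spec = og.RegularizedModelSpec(
            input_dim=len(ds.feature_names), half_width=ds.half_width,
            hidden_size=8, dense_sizes=(4,), lam=0.0, max_epochs=50,
            batch_size=32, seed=5,
        )
        fitted = og.train(build_model(spec), train_ds, val_ds, spec)
        pred = classify(predict_proba(fitted, train_ds))
        rep = og.metrics(og.confusion_counts(train_ds.y, pred))
        assert rep.f1 == 1.0
        assert fitted.stopped_epoch <= 50

    @staticmethod
    def _input_norms_after_training(lam, epochs):
        """Input-group norms at the last optimization step (validation
        selection rightly rejects a fully collapsed model, so sparsity is
        read from the end-of-training parameters)."""
        ds = separable_dataset(n=300, seed=6)
        train_ds, val_ds = og.split_train_test(ds, 0.2, 6)
        spec = og.RegularizedModelSpec(
            input_dim=len(ds.feature_names), half_width=ds.half_width,
            hidden_size=4, dense_sizes=(), reg_input="l1", lam=lam,
            max_epochs=epochs, patience=epochs, min_delta=0.0,
            batch_size=32, seed=6,
        )
        fitted = og.train(build_model(spec), train_ds, val_ds, spec)
        flat = fitted.last_parameters
        return np.array(
            [np.linalg.norm(flat[g])
             for g in fitted.model.parameter_groups().input_groups]
        )

    def test_heavy_l1_drives_input_groups_to_zero(self):
        """With a dominating penalty most input-group norms collapse."""
        norms = self._input_norms_after_training(lam=10.0, epochs=120)
        assert np.mean(norms < 1e-3) > 0.5

    def test_sparsity_nondecreasing_in_lambda(self):
        """The count of near-zero input groups grows (weakly) with lambda."""
        counts = [
            int((self._input_norms_after_training(lam, epochs=60) < 1e-3).sum())
            for lam in (0.0, 1e-4, 1e-3, 1e-2, 1e-1)
        ]
        assert counts == sorted(counts)

    def test_training_reproducible(self):
        ds = separable_dataset(n=200, seed=7)
        train_ds, val_ds = og.split_train_test(ds, 0.2, 7)
        spec = og.RegularizedModelSpec(
            input_dim=len(ds.feature_names), half_width=ds.half_width,
            hidden_size=4, dense_sizes=(4,), reg_input="sgl", lam=1e-3,
            max_epochs=10, seed=7,
        )
        a = og.train(build_model(spec), train_ds, val_ds, spec)
        b = og.train(build_model(spec), train_ds, val_ds, spec)
        assert a.training_log == b.training_log
        assert a.stopped_epoch == b.stopped_epoch
        np.testing.assert_array_equal(a.model.get_flat(), b.model.get_flat())

    def test_empty_sets_rejected(self):
        spec = tiny_spec()
        with pytest.raises(ValueError):
            og.train(build_model(spec), (np.empty((0, 3, 3)), np.empty(0)),
                     (np.zeros((1, 3, 3)), np.zeros(1)), spec)


class TestClassify:
    def test_threshold_examples(self):
        assert classify(np.array([0.6]), 0.5)[0] == 1
        assert classify(np.array([0.6]), 0.9)[0] == 0

    def test_raising_threshold_monotone(self):
        p = np.random.default_rng(8).uniform(size=200)
        counts = [classify(p, t).sum() for t in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts, reverse=True)


def test_lambda_cv_selection_returns_grid_member():
    """The CV grid search reports a mean-F1 table over the grid and picks
    its argmax (ties toward the smaller penalty)."""
    ds = separable_dataset(n=160, seed=21)
    spec = og.RegularizedModelSpec(
        input_dim=len(ds.feature_names), half_width=ds.half_width,
        hidden_size=4, dense_sizes=(), reg_input="sgl", max_epochs=5, seed=21,
    )
    best, table = og.select_lambda_cv(ds, spec, grid=(1e-4, 1e-2), k=2, seed=21)
    assert set(table) == {1e-4, 1e-2}
    assert best in table
    assert all(0.0 <= v <= 1.0 for v in table.values())


def test_checkpoint_round_trip(tmp_path, tiny_trained):
    ds, fitted = tiny_trained
    path = tmp_path / "model.npz"
    save_model(fitted, path)
    back = load_model(path)
    assert back.spec == fitted.spec
    np.testing.assert_array_equal(back.model.get_flat(), fitted.model.get_flat())
    assert back.feature_names == fitted.feature_names
    np.testing.assert_allclose(
        predict_proba(back, ds.subset(range(10))),
        predict_proba(fitted, ds.subset(range(10))),
    )
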