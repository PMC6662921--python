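import numpy as np
import pytest
from scipy import sparse

from ehrmtl.errors import ConfigurationError, DegenerateLabelsError
from ehrmtl.metrics import auprc
from ehrmtl.models import (
    DEFAULT_LAMBDA_GRID,
    HyperParams,
    TrainConfig,
    _FeedForwardNet,
    load_model,
    save_model,
    train_l1_logreg,
    train_mtnn,
    train_stnn,
)


class TestHyperParams:
    def test_canonical_grid_has_twenty_points(self):
        grid = HyperParams.grid()
        assert len(grid) == 20
        assert len(set(grid)) == 20
        assert {h.n_hidden_layers for h in grid} == {1, 2}
        assert {h.hidden_size for h in grid} == {128, 256, 512, 1024, 2048}
        assert {h.learning_rate for h in grid} == {1e-4, 5e-5}

    def test_invalid_values_rejected(self):
        with pytest.raises(ConfigurationError):
            HyperParams(0, 128, 1e-4)
        with pytest.raises(ConfigurationError):
            HyperParams(1, 128, -1.0)


class TestGradients:
    def test_backprop_matches_numerical_gradient(self):
        """Finite-difference check of the full loss gradient (incl. batch norm)."""
        rng = np.random.default_rng(0)
        net = _FeedForwardNet(6, [5, 4], n_tasks=2, rng=rng)
        X = rng.normal(size=(12, 6))
        Y = (rng.random((12, 2)) < 0.4).astype(float)
        w = np.array([1.0, 0.5])
        state = net.state()
        _, grads = net.loss_and_grads(X, Y, w)
        net.load_state(state)  # undo running-stat update

        eps = 1e-6
        params = net.parameters()
        for pi in [0, 2, 3, 8, 9]:  # W1, gamma1, beta1, W_out, b_out
            p = params[pi]
            flat_idx = [0, p.size // 2, p.size - 1]
            for fi in flat_idx:
                orig = p.flat[fi]
                p.flat[fi] = orig + eps
                lp, _ = net.loss_and_grads(X, Y, w)
                net.load_state(state)
                p = net.parameters()[pi]
                p.flat[fi] = orig - eps
                lm, _ = net.loss_and_grads(X, Y, w)
                net.load_state(state)
                p = net.parameters()[pi]
                numeric = (lp - lm) / (2 * eps)
                assert grads[pi].flat[fi] == pytest.approx(numeric, abs=1e-6, rel=1e-4)


class TestSTNN:
    def test_separable_problem_is_solved(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        assert model.val_auprc >= 0.99

    def test_deterministic_under_fixed_seed(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        a = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        b = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        assert a.val_auprc_trace == b.val_auprc_trace
        assert a.best_epoch == b.best_epoch
        assert np.array_equal(a.predict_scores(Xval), b.predict_scores(Xval))

    def test_single_class_labels_rejected(self, toy_separable, toy_hp, toy_tc):
        Xtr, _, Xval, yval = toy_separable
        with pytest.raises(DegenerateLabelsError):
            train_stnn(Xtr, np.zeros(len(Xtr)), Xval, yval, toy_hp, toy_tc)

    def test_early_stopping_reports_trace_maximum(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        assert model.val_auprc == max(model.val_auprc_trace)
        assert model.val_auprc_trace[model.best_epoch - 1] == model.val_auprc
        # restored parameters reproduce the reported best validation AUPRC
        assert auprc(yval, model.predict_scores(Xval)) == pytest.approx(
            model.val_auprc
        )

    def test_sparse_input_equivalent_to_dense(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        dense = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        sp = train_stnn(
            sparse.csr_matrix(Xtr), ytr, sparse.csr_matrix(Xval), yval, toy_hp, toy_tc
        )
        assert dense.val_auprc_trace == pytest.approx(sp.val_auprc_trace)


class TestMTNN:
    def test_duplicated_target_auxiliary_does_not_hurt(self, toy_separable, toy_hp):
        """An auxiliary task identical to the target duplicates its gradient
        signal; mean validation AUPRC over seeds must not drop materially."""
        Xtr, ytr, Xval, yval = toy_separable
        st_scores, mt_scores = [], []
        for seed in range(5):
            tc = TrainConfig(max_epochs=30, batch_size=32, seed=seed)
            st = train_stnn(Xtr, ytr, Xval, yval, toy_hp, tc)
            mt = train_mtnn(Xtr, ytr, ytr[:, None], Xval, yval, toy_hp, tc)
            st_scores.append(st.val_auprc)
            mt_scores.append(mt.val_auprc)
        assert np.mean(mt_scores) >= np.mean(st_scores) - 0.02

    def test_zero_auxiliary_tasks_rejected(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        with pytest.raises(ConfigurationError):
            train_mtnn(Xtr, ytr, np.empty((len(Xtr), 0)), Xval, yval, toy_hp, toy_tc)

    def test_head_count_is_tasks_plus_one(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        rng = np.random.default_rng(1)
        aux = (rng.random((len(Xtr), 3)) < 0.5).astype(int)
        model = train_mtnn(Xtr, ytr, aux, Xval, yval, toy_hp, toy_tc)
        assert model.n_tasks == 4
        assert model._net.W_out.shape[1] == 4

    def test_degenerate_auxiliary_dropped_with_warning(
        self, toy_separable, toy_hp, toy_tc
    ):
        Xtr, ytr, Xval, yval = toy_separable
        aux = np.zeros((len(Xtr), 1), dtype=int)
        with pytest.warns(RuntimeWarning, match="single class"):
            model = train_mtnn(Xtr, ytr, aux, Xval, yval, toy_hp, toy_tc)
        assert model.val_auprc > 0

    def test_zero_weighted_auxiliary_matches_stnn_trajectory(
        self, toy_separable, toy_hp, toy_tc
    ):
        """With the auxiliary loss weight forced to 0, the shared trunk and
        target head follow the single-task trajectory exactly."""
        Xtr, ytr, Xval, yval = toy_separable
        rng = np.random.default_rng(2)
        aux = (rng.random((len(Xtr), 1)) < 0.5).astype(int)
        st = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        mt = train_mtnn(
            Xtr, ytr, aux, Xval, yval, toy_hp, toy_tc, aux_loss_weights=[0.0]
        )
        assert mt.val_auprc_trace == pytest.approx(st.val_auprc_trace)
        assert np.allclose(
            st.predict_scores(Xval), mt.predict_scores(Xval, task_id=0)
        )

    def test_target_and_auxiliary_heads_score_differently(
        self, toy_separable, toy_hp, toy_tc
    ):
        Xtr, ytr, Xval, yval = toy_separable
        rng = np.random.default_rng(3)
        aux = (rng.random((len(Xtr), 1)) < 0.5).astype(int)
        model = train_mtnn(Xtr, ytr, aux, Xval, yval, toy_hp, toy_tc)
        assert not np.allclose(
            model.predict_scores(Xtr, task_id=0), model.predict_scores(Xtr, task_id=1)
        )


class TestPredictScores:
    def test_empty_batch(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        assert model.predict_scores(Xtr[:0]).shape == (0,)

    def test_scores_bounded(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        big = np.random.default_rng(4).normal(scale=50, size=(10_000, Xtr.shape[1]))
        s = model.predict_scores(big)
        assert s.min() >= 0.0 and s.max() <= 1.0

    def test_unknown_task_rejected(self, toy_separable, toy_hp, toy_tc):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        with pytest.raises(LookupError):
            model.predict_scores(Xval, task_id=1)


class TestCheckpointing:
    def test_round_trip_preserves_scores(self, toy_separable, toy_hp, toy_tc, tmp_path):
        Xtr, ytr, Xval, yval = toy_separable
        model = train_stnn(Xtr, ytr, Xval, yval, toy_hp, toy_tc)
        save_model(model, tmp_path / "ckpt")
        back = load_model(tmp_path / "ckpt")
        assert np.allclose(model.predict_scores(Xval), back.predict_scores(Xval))
        assert back.best_epoch == model.best_epoch
        assert back.hyperparams == model.hyperparams


class TestL1LogReg:
    def test_strong_penalty_selects_informative_feature(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(400, 20))
        y = (X[:, 7] > 0).astype(int)
        X[:, 7] += 2 * y
        model = train_l1_logreg(X[:300], y[:300], X[300:], y[300:],
                                lambda_grid=[10.0])
        coef = np.abs(model._linear.coef_.ravel())
        assert coef[7] > 0
        assert coef[7] >= coef.max() * 0.99

    def test_infinite_penalty_limit_scores_at_prevalence(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(300, 10))
        y = (rng.random(300) < 0.2).astype(int)
        model = train_l1_logreg(X, y, X, y, lambda_grid=[1e8])
        scores = model.predict_scores(X)
        assert np.ptp(scores) < 1e-6  # constant scorer
        assert model.val_auprc == pytest.approx(y.mean())

    def test_deterministic_lambda_choice(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 10))
        y = (X[:, 0] + 0.5 * rng.normal(size=300) > 0.8).astype(int)
        a = train_l1_logreg(X[:200], y[:200], X[200:], y[200:])
        b = train_l1_logreg(X[:200], y[:200], X[200:], y[200:])
        assert a.lam == b.lam
        assert len(a.lambda_trace) == len(DEFAULT_LAMBDA_GRID) == 7

    def test_degenerate_labels_rejected(self):
        X = np.zeros((50, 3))
        with pytest.raises(DegenerateLabelsError):
            train_l1_logreg(X, np.ones(50), X, np.ones(50))
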