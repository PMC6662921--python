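"""Model families: single-task nets (STNN), hard-parameter-sharing multitask
nets (MTNN), and an L1-regularized logistic-regression baseline.

The neural nets are feed-forward: input -> (linear -> batch norm -> ReLU) x L
-> one sigmoid output head per task, with a shared trunk and per-task heads in
the multitask case.  Training minimizes the (unweighted-mean) per-task binary
cross-entropy with Adam (beta1=0.9, beta2=0.99), Xavier-uniform initialization,
and per-epoch early stopping on the *target* task's validation AUPRC.  The
engine is implemented directly on NumPy/SciPy arrays; sparse feature batches
are densified per minibatch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, DegenerateLabelsError
from .metrics import auprc

__all__ = [
    "HyperParams",
    "TrainConfig",
    "FittedModel",
    "train_stnn",
    "train_mtnn",
    "train_l1_logreg",
    "predict_scores",
    "DEFAULT_LAMBDA_GRID",
]


@dataclass(frozen=True)
class HyperParams:
    """One point of the neural-net grid.

    The canonical grid — :meth:`grid` — crosses depth (1 or 2 hidden layers),
    width (128..2048) and initial learning rate (1e-4, 5e-5), giving 20
    configurations.  Other values are accepted for toy experiments.
    """

    n_hidden_layers: int = 1
    hidden_size: int = 256
    learning_rate: float = 1e-4

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 1:
            raise ConfigurationError("n_hidden_layers must be >= 1")
        if self.hidden_size < 1:
            raise ConfigurationError("hidden_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")

    DEPTHS = (1, 2)
    WIDTHS = (128, 256, 512, 1024, 2048)
    LEARNING_RATES = (1e-4, 5e-5)

    @classmethod
    def grid(cls) -> list["HyperParams"]:
        return [
            cls(d, w, lr)
            for d in cls.DEPTHS
            for w in cls.WIDTHS
            for lr in cls.LEARNING_RATES
        ]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared across the grid."""

    max_epochs: int = 6
    adam_beta1: float = 0.9
    adam_beta2: float = 0.99
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.batch_size < 2:
            raise ConfigurationError("batch_size must be >= 2 (batch norm)")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _FeedForwardNet:
    """Trunk of (linear, batch-norm, ReLU) blocks plus per-task sigmoid heads.

    Head weight columns are drawn sequentially per task so that the target
    head's initialization does not depend on how many auxiliary heads follow.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(
        self,
        n_features: int,
        hidden_sizes: Sequence[int],
        n_tasks: int,
        rng: np.random.Generator,
    ) -> None:
        self.n_tasks = n_tasks
        self.hidden_sizes = tuple(hidden_sizes)
        self.layers: list[dict[str, np.ndarray]] = []
        fan_in = n_features
        for h in self.hidden_sizes:
            limit = np.sqrt(6.0 / (fan_in + h))
            self.layers.append(
                {
                    "W": rng.uniform(-limit, limit, size=(fan_in, h)),
                    "b": np.zeros(h),
                    "gamma": np.ones(h),
                    "beta": np.zeros(h),
                    "rmean": np.zeros(h),
                    "rvar": np.ones(h),
                }
            )
            fan_in = h
        limit = np.sqrt(6.0 / (fan_in + 1))
        cols = [rng.uniform(-limit, limit, size=(fan_in, 1)) for _ in range(n_tasks)]
        self.W_out = np.concatenate(cols, axis=1)
        self.b_out = np.zeros(n_tasks)

    # -- parameter bookkeeping ---------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in self.layers:
            params.extend([layer["W"], layer["b"], layer["gamma"], layer["beta"]])
        params.extend([self.W_out, self.b_out])
        return params

    def state(self) -> list[np.ndarray]:
        out = [p.copy() for p in self.parameters()]
        for layer in self.layers:
            out.extend([layer["rmean"].copy(), layer["rvar"].copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, s in zip(params, state[: len(params)]):
            p[...] = s
        rest = state[len(params):]
        for i, layer in enumerate(self.layers):
            layer["rmean"][...] = rest[2 * i]
            layer["rvar"][...] = rest[2 * i + 1]

    # -- forward / backward -------------------------------------------------

    def loss_and_grads(
        self, X, Y: np.ndarray, task_weights: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        """Weighted-mean BCE over tasks on one minibatch and its gradients,
        updating batch-norm running statistics as a side effect."""
        B = Y.shape[0]
        A = X.toarray() if sparse.issparse(X) else np.asarray(X, dtype=float)
        caches = []
        for layer in self.layers:
            Z = A @ layer["W"] + layer["b"]
            mu = Z.mean(axis=0)
            var = Z.var(axis=0)
            xhat = (Z - mu) / np.sqrt(var + self.BN_EPS)
            H = np.maximum(layer["gamma"] * xhat + layer["beta"], 0.0)
            layer["rmean"] *= 1.0 - self.BN_MOMENTUM
            layer["rmean"] += self.BN_MOMENTUM * mu
            layer["rvar"] *= 1.0 - self.BN_MOMENTUM
            layer["rvar"] += self.BN_MOMENTUM * var
            caches.append((A, var, xhat, H))
            A = H
        logits = A @ self.W_out + self.b_out

        w = task_weights / task_weights.sum()
        # numerically stable BCE on logits
        bce = np.maximum(logits, 0.0) - logits * Y + np.log1p(np.exp(-np.abs(logits)))
        loss = float((bce.mean(axis=0) * w).sum())

        dlogits = (_sigmoid(logits) - Y) * w / B
        grads: list[np.ndarray] = []
        gW_out = A.T @ dlogits
        gb_out = dlogits.sum(axis=0)
        dA = dlogits @ self.W_out.T
        for layer, (A_in, var, xhat, H) in zip(reversed(self.layers), reversed(caches)):
            dZn = dA * (H > 0)
            dgamma = (dZn * xhat).sum(axis=0)
            dbeta = dZn.sum(axis=0)
            dxhat = dZn * layer["gamma"]
            ivar = 1.0 / np.sqrt(var + self.BN_EPS)
            dZ = (ivar / B) * (
                B * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
            )
            gW = (A_in.T @ dZ) if not sparse.issparse(A_in) else A_in.T @ dZ
            gW = np.asarray(gW)
            gb = dZ.sum(axis=0)
            dA = dZ @ layer["W"].T
            grads = [gW, gb, dgamma, dbeta] + grads
        grads = grads + [gW_out, gb_out]
        return loss, grads

    def recalibrate_norm(self, X, chunk: int = 4096) -> None:
        """Replace the batch-norm EMA statistics with exact statistics of the
        given (training) data under the current weights.

        With small minibatches the EMA window covers only a few hundred rows
        and eval-time normalization becomes a noise source; exact ("precise")
        statistics remove it.  Called once per epoch before validation.
        """
        n = X.shape[0]
        A = X
        for layer in self.layers:
            # accumulate exact first/second moments of Z = A @ W + b
            s1 = np.zeros(layer["W"].shape[1])
            s2 = np.zeros(layer["W"].shape[1])
            for start in range(0, n, chunk):
                Ab = A[start : start + chunk]
                Ab = Ab.toarray() if sparse.issparse(Ab) else np.asarray(Ab, dtype=float)
                Z = Ab @ layer["W"] + layer["b"]
                s1 += Z.sum(axis=0)
                s2 += (Z * Z).sum(axis=0)
            mu = s1 / n
            layer["rmean"][...] = mu
            layer["rvar"][...] = np.maximum(s2 / n - mu * mu, 0.0)
            # propagate activations under the recalibrated statistics
            H = np.empty((n, layer["W"].shape[1]))
            for start in range(0, n, chunk):
                Ab = A[start : start + chunk]
                Ab = Ab.toarray() if sparse.issparse(Ab) else np.asarray(Ab, dtype=float)
                Z = Ab @ layer["W"] + layer["b"]
                xhat = (Z - layer["rmean"]) / np.sqrt(layer["rvar"] + self.BN_EPS)
                H[start : start + chunk] = np.maximum(
                    layer["gamma"] * xhat + layer["beta"], 0.0
                )
            A = H

    def predict(self, X, chunk: int = 4096) -> np.ndarray:
        """Per-task probabilities using batch-norm running statistics."""
        n = X.shape[0]
        out = np.empty((n, self.n_tasks))
        for start in range(0, n, chunk):
            sl = slice(start, min(start + chunk, n))
            A = X[sl]
            A = A.toarray() if sparse.issparse(A) else np.asarray(A, dtype=float)
            for layer in self.layers:
                Z = A @ layer["W"] + layer["b"]
                xhat = (Z - layer["rmean"]) / np.sqrt(layer["rvar"] + self.BN_EPS)
                A = np.maximum(layer["gamma"] * xhat + layer["beta"], 0.0)
            out[sl] = _sigmoid(A @ self.W_out + self.b_out)
        if n == 0:
            out = out.reshape(0, self.n_tasks)
        return out


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float, beta1: float, beta2: float,
                 eps: float = 1e-8) -> None:
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class FittedModel:
    """A trained scorer for one or more tasks (task 0 is always the target)."""

    family: str  # "STNN" | "MTNN" | "LR"
    n_tasks: int
    val_auprc: float
    best_epoch: int | None = None
    val_auprc_trace: tuple[float, ...] | None = None
    hyperparams: HyperParams | None = None
    lam: float | None = None
    lambda_trace: tuple[tuple[float, float], ...] | None = None
    _net: _FeedForwardNet | None = None
    _linear: LogisticRegression | None = None

    def predict_scores(self, X, task_id: int = 0) -> np.ndarray:
        """Probability scores in [0, 1], one per row of ``X``."""
        if not (0 <= task_id < self.n_tasks):
            raise LookupError(
                f"task_id {task_id} unknown; model has {self.n_tasks} task(s)"
            )
        if X.shape[0] == 0:
            return np.empty(0)
        if self._net is not None:
            return self._net.predict(X)[:, task_id]
        assert self._linear is not None
        return self._linear.predict_proba(X)[:, 1]


def predict_scores(model: FittedModel, X, task_id: int = 0) -> np.ndarray:
    return model.predict_scores(X, task_id)


def _check_binary(y: np.ndarray, what: str) -> None:
    u = np.unique(y)
    if u.size < 2:
        raise DegenerateLabelsError(f"{what} labels contain a single class")
    if not np.all(np.isin(u, (0, 1))):
        raise ConfigurationError(f"{what} labels must be binary 0/1")


def _train_net(
    X_train,
    Y_train: np.ndarray,
    X_val,
    y_val: np.ndarray,
    hp: HyperParams,
    tc: TrainConfig,
    family: str,
    task_weights: np.ndarray,
) -> FittedModel:
    n, n_features = X_train.shape
    n_tasks = Y_train.shape[1]
    init_seed, shuffle_seed = np.random.SeedSequence(tc.seed).spawn(2)
    net = _FeedForwardNet(
        n_features, [hp.hidden_size] * hp.n_hidden_layers, n_tasks,
        np.random.default_rng(init_seed),
    )
    adam = _Adam(net.parameters(), hp.learning_rate, tc.adam_beta1, tc.adam_beta2)
    shuffle_rng = np.random.default_rng(shuffle_seed)
    Yf = Y_train.astype(float)

    best_state = net.state()
    best_auprc = -np.inf
    best_epoch = 0
    trace: list[float] = []
    params = net.parameters()
    for epoch in range(1, tc.max_epochs + 1):
        perm = shuffle_rng.permutation(n)
        for start in range(0, n, tc.batch_size):
            idx = perm[start : start + tc.batch_size]
            if idx.size < 2:  # batch norm needs >= 2 rows
                continue
            _, grads = net.loss_and_grads(X_train[idx], Yf[idx], task_weights)
            adam.step(params, grads)
        net.recalibrate_norm(X_train)
        val_scores = net.predict(X_val)[:, 0]
        epoch_auprc = auprc(y_val, val_scores)
        trace.append(epoch_auprc)
        if epoch_auprc > best_auprc:
            best_auprc = epoch_auprc
            best_epoch = epoch
            best_state = net.state()
    net.load_state(best_state)
    return FittedModel(
        family=family,
        n_tasks=n_tasks,
        val_auprc=float(best_auprc),
        best_epoch=best_epoch,
        val_auprc_trace=tuple(trace),
        hyperparams=hp,
        _net=net,
    )


def train_stnn(
    X_train, y_train, X_val, y_val, hp: HyperParams, tc: TrainConfig
) -> FittedModel:
    """Single-task net: one sigmoid head on the trunk, early-stopped on
    validation AUPRC."""
    y_train = np.asarray(y_train).ravel()
    _check_binary(y_train, "training")
    return _train_net(
        X_train, y_train[:, None], X_val, np.asarray(y_val).ravel(), hp, tc,
        family="STNN", task_weights=np.ones(1),
    )


def train_mtnn(
    X_train,
    y_train,
    aux_train: np.ndarray,
    X_val,
    y_val,
    hp: HyperParams,
    tc: TrainConfig,
    aux_loss_weights: Sequence[float] | None = None,
) -> FittedModel:
    """Multitask net: shared trunk, K+1 heads (target first).

    The loss is the weighted mean of per-task BCEs (uniform by default).
    Early stopping monitors the target head only.  An auxiliary task whose
    training labels are single-class is dropped (weight 0) with a warning.
    """
    y_train = np.asarray(y_train).ravel()
    aux_train = np.atleast_2d(np.asarray(aux_train))
    if aux_train.shape[0] != y_train.size and aux_train.shape[1] == y_train.size:
        aux_train = aux_train.T
    K = aux_train.shape[1]
    if K < 1:
        raise ConfigurationError("MTNN requires at least one auxiliary task; use STNN")
    _check_binary(y_train, "training target")
    weights = np.ones(K + 1)
    if aux_loss_weights is not None:
        if len(aux_loss_weights) != K:
            raise ConfigurationError("aux_loss_weights must have one entry per task")
        weights[1:] = np.asarray(aux_loss_weights, dtype=float)
    for k in range(K):
        if np.unique(aux_train[:, k]).size < 2:
            warnings.warn(
                f"auxiliary task {k} has a single class in training data; "
                "dropping its loss",
                RuntimeWarning,
                stacklevel=2,
            )
            weights[1 + k] = 0.0
    Y = np.column_stack([y_train, aux_train])
    return _train_net(
        X_train, Y, X_val, np.asarray(y_val).ravel(), hp, tc,
        family="MTNN", task_weights=weights,
    )


def save_model(model: FittedModel, path) -> None:
    """Checkpoint a fitted neural model: an ``.npz`` of parameter arrays plus
    a JSON sidecar (family, hyperparameters, best epoch, validation trace)."""
    import json
    from pathlib import Path

    if model._net is None:
        raise ConfigurationError("only neural models are checkpointed this way")
    path = Path(path)
    state = model._net.state()
    np.savez(path.with_suffix(".npz"), *state)
    meta = {
        "family": model.family,
        "n_tasks": model.n_tasks,
        "n_features": model._net.layers[0]["W"].shape[0],
        "hidden_sizes": list(model._net.hidden_sizes),
        "best_epoch": model.best_epoch,
        "val_auprc": model.val_auprc,
        "val_auprc_trace": list(model.val_auprc_trace or ()),
        "hyperparams": {
            "n_hidden_layers": model.hyperparams.n_hidden_layers,
            "hidden_size": model.hyperparams.hidden_size,
            "learning_rate": model.hyperparams.learning_rate,
        }
        if model.hyperparams
        else None,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def load_model(path) -> FittedModel:
    """Inverse of :func:`save_model`."""
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    net = _FeedForwardNet(
        meta["n_features"],
        meta["hidden_sizes"],
        meta["n_tasks"],
        np.random.default_rng(0),
    )
    with np.load(path.with_suffix(".npz")) as npz:
        net.load_state([npz[k] for k in npz.files])
    hp = HyperParams(**meta["hyperparams"]) if meta["hyperparams"] else None
    return FittedModel(
        family=meta["family"],
        n_tasks=meta["n_tasks"],
        val_auprc=meta["val_auprc"],
        best_epoch=meta["best_epoch"],
        val_auprc_trace=tuple(meta["val_auprc_trace"]),
        hyperparams=hp,
        _net=net,
    )


#: 7 log-spaced L1 regularization strengths (lambda = 1 / C)
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-4, 2, 7))


def train_l1_logreg(
    X_train, y_train, X_val, y_val, lambda_grid: Sequence[float] | None = None
) -> FittedModel:
    """L1-penalized logistic regression, strength selected on validation AUPRC.

    Ties favor the stronger penalty (sparser model).
    """
    y_train = np.asarray(y_train).ravel()
    _check_binary(y_train, "training")
    y_val = np.asarray(y_val).ravel()
    grid = tuple(lambda_grid) if lambda_grid is not None else DEFAULT_LAMBDA_GRID
    best = None
    trace = []
    for lam in sorted(grid, reverse=True):
        clf = LogisticRegression(
            l1_ratio=1.0, C=1.0 / lam, solver="liblinear", max_iter=500, tol=1e-5
        )
        clf.fit(X_train, y_train)
        val_auprc = auprc(y_val, clf.predict_proba(X_val)[:, 1])
        trace.append((float(lam), float(val_auprc)))
        if best is None or val_auprc > best[1]:
            best = (lam, val_auprc, clf)
    lam, val_auprc, clf = best
    return FittedModel(
        family="LR",
        n_tasks=1,
        val_auprc=float(val_auprc),
        lam=float(lam),
        lambda_trace=tuple(trace),
        _linear=clf,
    )
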