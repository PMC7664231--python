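"""Two-layer feedforward networks trained by Bayesian-regularized
Levenberg-Marquardt.

The network is ``z = W2 tanh(W1 x + b1) + b2`` with 10 hidden units by
default; the classifier applies a softmax to ``z`` at inference (it is
trained against one-hot targets under squared error, the convention of
MSE-based regularized trainers), the regressor uses the linear output
directly on standardized targets.

Training minimizes the regularized objective

    F(w) = beta * E_D + alpha * E_W,

with ``E_D`` the summed squared residuals over all scalar observations
(rows x outputs) and ``E_W`` the summed squared weights, by
Levenberg-Marquardt steps on the Gauss-Newton Hessian
``H = 2 beta J'J + 2 alpha I``.  After each accepted step the evidence
framework re-estimates the hyperparameters (MacKay):

    gamma = N_w - 2 alpha tr(H^-1)      # effective number of parameters
    alpha = gamma / (2 E_W)
    beta  = (n_obs - gamma) / (2 E_D)

so no validation split is needed; overfitting is suppressed by the
evidence-driven weight decay.  Samples are split 70/30 into training
and testing sets by a seeded uniform permutation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = [
    "FFNet",
    "TrainState",
    "DataSplit",
    "TrainConfig",
    "split",
    "forward",
    "train_bayesian_regularization",
    "predict_class",
    "predict_values",
    "BRNetClassifier",
    "BRNetRegressor",
]


# ---------------------------------------------------------------------------
# network container

@dataclass
class FFNet:
    """Weights and biases of a two-layer tanh feedforward network."""

    w1: np.ndarray  # (n_hidden, n_in)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_out, n_hidden)
    b2: np.ndarray  # (n_out,)
    out_act: str = "linear"  # "linear" | "softmax"

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, float)
        self.b1 = np.asarray(self.b1, float).ravel()
        self.w2 = np.asarray(self.w2, float)
        self.b2 = np.asarray(self.b2, float).ravel()
        nh, ni = self.w1.shape
        no = self.w2.shape[0]
        if self.b1.size != nh or self.w2.shape[1] != nh or self.b2.size != no:
            raise ValueError("inconsistent layer shapes")
        for arr in (self.w1, self.b1, self.w2, self.b2):
            if not np.isfinite(arr).all():
                raise ValueError("non-finite network parameters")
        if self.out_act not in ("linear", "softmax"):
            raise ValueError(f"unknown output activation {self.out_act!r}")

    @property
    def n_in(self) -> int:
        return self.w1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.w1.shape[0]

    @property
    def n_out(self) -> int:
        return self.w2.shape[0]

    @property
    def n_params(self) -> int:
        return self.w1.size + self.b1.size + self.w2.size + self.b2.size

    # -- flat parameter vector ------------------------------------------
    def get_flat(self) -> np.ndarray:
        return np.concatenate([self.w1.ravel(), self.b1,
                               self.w2.ravel(), self.b2])

    def set_flat(self, w: np.ndarray) -> None:
        nh, ni, no = self.n_hidden, self.n_in, self.n_out
        i = 0
        self.w1 = w[i:i + nh * ni].reshape(nh, ni); i += nh * ni
        self.b1 = w[i:i + nh].copy(); i += nh
        self.w2 = w[i:i + no * nh].reshape(no, nh); i += no * nh
        self.b2 = w[i:i + no].copy()

    @classmethod
    def init(cls, n_in: int, n_hidden: int, n_out: int,
             out_act: str = "linear", rng=None) -> "FFNet":
        """Layer-wise uniform initialization scaled by fan-in."""
        rng = np.random.default_rng(rng)
        w1 = rng.uniform(-1, 1, (n_hidden, n_in)) / np.sqrt(n_in)
        b1 = rng.uniform(-0.5, 0.5, n_hidden)
        w2 = rng.uniform(-1, 1, (n_out, n_hidden)) / np.sqrt(n_hidden)
        b2 = rng.uniform(-0.5, 0.5, n_out)
        return cls(w1=w1, b1=b1, w2=w2, b2=b2, out_act=out_act)

    def to_dict(self) -> dict:
        return {"w1": self.w1.tolist(), "b1": self.b1.tolist(),
                "w2": self.w2.tolist(), "b2": self.b2.tolist(),
                "out_act": self.out_act}

    @classmethod
    def from_dict(cls, d: dict) -> "FFNet":
        return cls(w1=np.asarray(d["w1"]), b1=np.asarray(d["b1"]),
                   w2=np.asarray(d["w2"]), b2=np.asarray(d["b2"]),
                   out_act=d["out_act"])


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def forward(net: FFNet, X: np.ndarray, linear: bool = False) -> np.ndarray:
    """Network outputs for rows of ``X``.

    ``linear=True`` returns the pre-activation outputs even for softmax
    nets (the quantity the trainer fits)."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != net.n_in:
        raise ValueError(f"X has {X.shape[1]} columns, net expects {net.n_in}")
    a1 = np.tanh(X @ net.w1.T + net.b1)
    z = a1 @ net.w2.T + net.b2
    if net.out_act == "softmax" and not linear:
        return _softmax(z)
    return z


def predict_class(net: FFNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(argmax labels, softmax scores) for a classification net."""
    scores = _softmax(forward(net, X, linear=True))
    return scores.argmax(axis=1), scores


def predict_values(net: FFNet, X: np.ndarray) -> np.ndarray:
    """Continuous outputs of a regression net."""
    return forward(net, X, linear=True)


# ---------------------------------------------------------------------------
# data split

@dataclass
class DataSplit:
    """A random 70/30 train/test index partition."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int


def split(n: int, seed: int, train_frac: float = 0.7) -> DataSplit:
    """Uniform random permutation; the first round(train_frac * n)
    indices train (134 samples -> 94 train / 40 test)."""
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.rint(train_frac * n))
    return DataSplit(train_idx=perm[:n_train], test_idx=perm[n_train:],
                     seed=seed)


# ---------------------------------------------------------------------------
# Bayesian-regularized Levenberg-Marquardt

@dataclass
class TrainState:
    """Snapshot of one accepted training epoch."""

    epoch: int
    alpha: float
    beta: float
    mu: float
    gamma: float
    sse_data: float
    sse_weights: float
    f_before: float
    f_after: float


@dataclass
class TrainConfig:
    max_epochs: int = 300
    mu0: float = 0.005
    mu_max: float = 1e10
    mu_factor: float = 10.0
    grad_tol: float = 1e-7
    bayes: bool = True       # False freezes alpha=0, beta=1 (plain LM)
    bayes_warmup: int = 5    # pure-LM epochs before evidence updates start
    alpha0: float = 0.0
    beta0: float = 1.0


def _jacobian(net: FFNet, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Jacobian d z / d params of the linear-output net, plus outputs.

    Rows are ordered sample-major (all outputs of sample 0 first),
    matching ``(T - Z).ravel()``.
    """
    n = X.shape[0]
    nh, ni, no = net.n_hidden, net.n_in, net.n_out
    a1 = np.tanh(X @ net.w1.T + net.b1)      # (n, nh)
    z = a1 @ net.w2.T + net.b2
    d = 1.0 - a1 ** 2                        # (n, nh)
    p_w1, p_b1, p_w2 = nh * ni, nh, no * nh
    J = np.zeros((n * no, net.n_params))
    off_b1 = p_w1
    off_w2 = p_w1 + p_b1
    off_b2 = off_w2 + p_w2
    for k in range(no):
        rows = slice(k, n * no, no)
        g = d * net.w2[k]                    # (n, nh)
        J[rows, :p_w1] = (g[:, :, None] * X[:, None, :]).reshape(n, p_w1)
        J[rows, off_b1:off_b1 + nh] = g
        J[rows, off_w2 + k * nh: off_w2 + (k + 1) * nh] = a1
        J[rows, off_b2 + k] = 1.0
    return J, z


def train_bayesian_regularization(
    net: FFNet, X: np.ndarray, T: np.ndarray, config: TrainConfig = None
) -> list[TrainState]:
    """Train ``net`` in place; returns the accepted-epoch trace.

    Damping ``mu`` is divided by 10 on an accepted step and multiplied
    by 10 on rejection; training stops at ``max_epochs``, when ``mu``
    exceeds ``mu_max``, or when the gradient falls below ``grad_tol``.
    One scalar observation per target value: ``n_obs = rows x outputs``.
    """
    config = config or TrainConfig()
    X = np.atleast_2d(np.asarray(X, float))
    T = np.asarray(T, float)
    if T.ndim == 1:
        T = T[:, None]
    if X.shape[0] != T.shape[0]:
        raise ValueError("X and T row counts differ")
    if T.shape[1] != net.n_out:
        raise ValueError(f"targets have {T.shape[1]} columns, net has "
                         f"{net.n_out} outputs")
    n_obs = T.size
    n_w = net.n_params
    alpha, beta = config.alpha0, config.beta0
    mu = config.mu0
    w = net.get_flat()
    trace: list[TrainState] = []

    J, z = _jacobian(net, X)
    e = (T - z).ravel()
    e_d = float(e @ e)
    e_w = float(w @ w)
    if not np.isfinite(e_d):
        raise FloatingPointError("non-finite loss at initialization")

    for epoch in range(1, config.max_epochs + 1):
        f_cur = beta * e_d + alpha * e_w
        g = -2.0 * beta * (J.T @ e) + 2.0 * alpha * w
        if np.abs(g).max() < config.grad_tol:
            break
        jtj = J.T @ J
        accepted = False
        while mu <= config.mu_max:
            h_damped = 2.0 * beta * jtj + (2.0 * alpha + mu) * np.eye(n_w)
            try:
                step = np.linalg.solve(h_damped, -g)
            except np.linalg.LinAlgError:
                mu *= config.mu_factor
                continue
            w_new = w + step
            net.set_flat(w_new)
            z_new = forward(net, X, linear=True)
            e_new = (T - z_new).ravel()
            if not np.isfinite(e_new).all():
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; the step diverged"
                )
            e_d_new = float(e_new @ e_new)
            e_w_new = float(w_new @ w_new)
            f_new = beta * e_d_new + alpha * e_w_new
            if f_new < f_cur:
                accepted = True
                mu = max(mu / config.mu_factor, 1e-20)
                w, e_d, e_w = w_new, e_d_new, e_w_new
                break
            mu *= config.mu_factor
        if not accepted:
            net.set_flat(w)
            break

        J, _ = _jacobian(net, X)
        e = (T - forward(net, X, linear=True)).ravel()
        gamma = float(n_w)
        if config.bayes and epoch > config.bayes_warmup:
            # tr(H^-1) via the eigenvalues of J'J (robust when
            # ill-conditioned: every term stays positive)
            evals = np.linalg.eigvalsh(J.T @ J)
            evals = np.clip(evals, 0.0, None)
            tr_hinv = float(np.sum(1.0 / (2.0 * beta * evals + 2.0 * alpha + 1e-300)))
            gamma = n_w - 2.0 * alpha * tr_hinv
            # at least one residual degree of freedom so the noise level
            # beta stays estimable when n_params >= n_obs
            gamma = float(np.clip(gamma, 0.0, min(n_w, n_obs - 1)))
            alpha = float(np.clip(gamma / (2.0 * e_w + 1e-300), 1e-12, 1e12))
            beta = float(np.clip((n_obs - gamma) / (2.0 * e_d + 1e-300),
                                 1e-12, 1e12))
        trace.append(TrainState(
            epoch=epoch, alpha=alpha, beta=beta, mu=mu, gamma=gamma,
            sse_data=e_d, sse_weights=e_w,
            f_before=f_cur, f_after=f_new,
        ))
        if mu > config.mu_max:
            break
    net.set_flat(w)
    return trace


# ---------------------------------------------------------------------------
# scikit-learn estimators

class BRNetClassifier(ClassifierMixin, BaseEstimator):
    """Softmax-output feedforward classifier trained by Bayesian-
    regularized Levenberg-Marquardt on one-hot targets.

    Parameters
    ----------
    n_hidden : int
        Hidden tan-sigmoid units (10 by default).
    max_epochs : int
        Levenberg-Marquardt epoch budget.
    random_state : int
        Seed for weight initialization.
    """

    def __init__(self, n_hidden: int = 10, max_epochs: int = 300,
                 random_state: int = 0):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        onehot = np.eye(len(self.classes_))[y_idx]
        self.net_ = FFNet.init(X.shape[1], self.n_hidden, len(self.classes_),
                               out_act="softmax",
                               rng=np.random.default_rng(self.random_state))
        self.trace_ = train_bayesian_regularization(
            self.net_, X, onehot, TrainConfig(max_epochs=self.max_epochs))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        return _softmax(forward(self.net_, X, linear=True))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class BRNetRegressor(RegressorMixin, BaseEstimator):
    """Linear-output feedforward regressor trained by Bayesian-
    regularized Levenberg-Marquardt.

    Targets are standardized per output column on the fitted rows and
    de-standardized at prediction.
    """

    def __init__(self, n_hidden: int = 10, max_epochs: int = 300,
                 random_state: int = 0):
        self.n_hidden = n_hidden
        self.max_epochs = max_epochs
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, multi_output=True)
        y = np.asarray(y, float)
        self._single_output = y.ndim == 1
        Y = y[:, None] if self._single_output else y
        self.y_mean_ = Y.mean(axis=0)
        sd = Y.std(axis=0)
        self.y_sd_ = np.where(sd > 0, sd, 1.0)
        T = (Y - self.y_mean_) / self.y_sd_
        self.net_ = FFNet.init(X.shape[1], self.n_hidden, T.shape[1],
                               out_act="linear",
                               rng=np.random.default_rng(self.random_state))
        self.trace_ = train_bayesian_regularization(
            self.net_, X, T, TrainConfig(max_epochs=self.max_epochs))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "net_")
        X = check_array(X)
        z = forward(self.net_, X, linear=True)
        out = z * self.y_sd_ + self.y_mean_
        return out[:, 0] if self._single_output else out


def save_net(path, net: FFNet, extra: dict = None) -> None:
    d = net.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d))


def load_net(path) -> tuple[FFNet, dict]:
    d = json.loads(Path(path).read_text())
    net = FFNet.from_dict(d)
    extra = {k: v for k, v in d.items()
             if k not in ("w1", "b1", "w2", "b2", "out_act")}
    return net, extra
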