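"""Single-hidden-layer feed-forward regression networks.

The regression surface is y = w2 . sigma(W1 x + b1) + b2 with a linear
output unit and a logistic ("logsig") or tanh ("tansig") hidden layer.
Inputs and the target are min-max scaled to [-1, 1]; scaling parameters
are fitted on the training split only and stored with the model, and all
reported errors are on the denormalized kcal/mol scale.

Training is full-batch, either Levenberg-Marquardt (damped Gauss-Newton
on the residual Jacobian; the workhorse for networks of this size) or
plain gradient descent, with early stopping on a validation split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .solvation_math import ErrorSummary, error_summary

__all__ = [
    "NetworkConfig",
    "NetworkModel",
    "TrainOutcome",
    "init_network",
    "forward",
    "train",
    "save_model",
    "load_model",
]

_TRANSFERS = ("logsig", "tansig")
_TRAINERS = ("lm", "gd")
_MODEL_SCHEMA_VERSION = 1
_MU_CAP = 1e10


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and trainer settings for one network."""

    n_hidden: int = 10
    transfer: str = "tansig"
    trainer: str = "lm"
    max_epochs: int = 1000
    val_fail_limit: int = 6
    lm_mu0: float = 1e-3
    lm_mu_inc: float = 10.0
    lm_mu_dec: float = 0.1
    gd_learning_rate: float = 0.01
    grad_tol: float = 1e-10  # per-sample gradient norm on the normalized objective
    val_min_improvement: float = 0.0
    restore_best_val: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden < 1:
            raise ValueError(f"n_hidden must be >= 1, got {self.n_hidden}")
        if self.max_epochs < 1:
            raise ValueError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.transfer not in _TRANSFERS:
            raise ValueError(f"transfer must be one of {_TRANSFERS}")
        if self.trainer not in _TRAINERS:
            raise ValueError(f"trainer must be one of {_TRAINERS}")


@dataclass
class NetworkModel:
    """Weights, biases and normalization of one trained (or initial) network."""

    feature_names: tuple[str, ...]
    W1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_hidden,)
    b2: float
    in_min: np.ndarray  # (n_inputs,)
    in_max: np.ndarray
    out_min: float
    out_max: float
    transfer: str = "tansig"

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W1.shape[1]

    @property
    def n_parameters(self) -> int:
        return self.n_hidden * self.n_inputs + 2 * self.n_hidden + 1

    def copy(self) -> "NetworkModel":
        return NetworkModel(
            feature_names=tuple(self.feature_names),
            W1=self.W1.copy(),
            b1=self.b1.copy(),
            w2=self.w2.copy(),
            b2=float(self.b2),
            in_min=self.in_min.copy(),
            in_max=self.in_max.copy(),
            out_min=float(self.out_min),
            out_max=float(self.out_max),
            transfer=self.transfer,
        )

    def fit_normalization(self, X: np.ndarray, y: np.ndarray) -> None:
        """Fit per-feature and target min-max ranges (training split only)."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.in_min = X.min(axis=0)
        self.in_max = X.max(axis=0)
        degenerate = self.in_max <= self.in_min
        if np.any(degenerate):
            # widen constant features symmetrically so scaling stays defined
            self.in_min = self.in_min - np.where(degenerate, 0.5, 0.0)
            self.in_max = self.in_max + np.where(degenerate, 0.5, 0.0)
        self.out_min = float(y.min())
        self.out_max = float(y.max())
        if self.out_max <= self.out_min:
            self.out_min -= 0.5
            self.out_max += 0.5

    def normalize_in(self, X: np.ndarray) -> np.ndarray:
        return 2.0 * (X - self.in_min) / (self.in_max - self.in_min) - 1.0

    def normalize_out(self, y: np.ndarray) -> np.ndarray:
        return 2.0 * (y - self.out_min) / (self.out_max - self.out_min) - 1.0

    def denormalize_out(self, y_norm: np.ndarray) -> np.ndarray:
        return (y_norm + 1.0) / 2.0 * (self.out_max - self.out_min) + self.out_min


@dataclass
class TrainOutcome:
    """Result of one training run; error summaries are in kcal/mol.

    ``model`` carries the weights of the best validation epoch (the
    performance model); ``final_model`` carries the last-epoch weights,
    which are what a warm-started retraining records.
    """

    model: NetworkModel
    epochs_run: int
    stop_reason: str  # max_epochs | val_early_stop | converged
    train_summary: ErrorSummary | None = None
    val_summary: ErrorSummary | None = None
    test_summary: ErrorSummary | None = None
    final_model: NetworkModel | None = None


def _transfer(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "tansig":
        return np.tanh(z)
    return 1.0 / (1.0 + np.exp(-z))  # logsig


def _transfer_deriv(h: np.ndarray, kind: str) -> np.ndarray:
    # expressed through the activation itself
    if kind == "tansig":
        return 1.0 - h * h
    return h * (1.0 - h)


def init_network(
    config: NetworkConfig, n_inputs: int, seed: int, feature_names=None
) -> NetworkModel:
    """Draw initial weights and biases uniformly in [-0.5, 0.5].

    The same seed always yields bit-identical weights.  Normalization is
    initialized to the identity map and is refitted at training time.
    """
    if n_inputs < 1:
        raise ValueError(f"n_inputs must be >= 1, got {n_inputs}")
    rng = np.random.default_rng(seed)
    if feature_names is None:
        feature_names = tuple(f"x{i}" for i in range(n_inputs))
    return NetworkModel(
        feature_names=tuple(feature_names),
        W1=rng.uniform(-0.5, 0.5, size=(config.n_hidden, n_inputs)),
        b1=rng.uniform(-0.5, 0.5, size=config.n_hidden),
        w2=rng.uniform(-0.5, 0.5, size=config.n_hidden),
        b2=float(rng.uniform(-0.5, 0.5)),
        in_min=-np.ones(n_inputs),
        in_max=np.ones(n_inputs),
        out_min=-1.0,
        out_max=1.0,
        transfer=config.transfer,
    )


def _forward_norm(model: NetworkModel, Xn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    h = _transfer(Xn @ model.W1.T + model.b1, model.transfer)
    return h @ model.w2 + model.b2, h


def forward(model: NetworkModel, X: np.ndarray, feature_names=None) -> np.ndarray:
    """Predict solvation free energies (kcal/mol) for rows of ``X``.

    When ``feature_names`` is given it must match the model's stored
    feature order.  Inputs outside the training range are allowed and
    extrapolate through the scaled network.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if feature_names is not None and tuple(feature_names) != tuple(model.feature_names):
        raise ValueError(
            f"feature mismatch: model expects {model.feature_names}, got {tuple(feature_names)}"
        )
    if X.shape[1] != model.n_inputs:
        raise ValueError(f"expected {model.n_inputs} columns, got {X.shape[1]}")
    yn, _ = _forward_norm(model, model.normalize_in(X))
    return model.denormalize_out(yn)


# ---------------------------------------------------------------------------
# parameter packing and the residual Jacobian

def _pack(model: NetworkModel) -> np.ndarray:
    return np.concatenate(
        [model.W1.ravel(), model.b1, model.w2, [model.b2]]
    )


def _unpack(model: NetworkModel, theta: np.ndarray) -> None:
    nh, ni = model.W1.shape
    model.W1 = theta[: nh * ni].reshape(nh, ni)
    model.b1 = theta[nh * ni : nh * ni + nh]
    model.w2 = theta[nh * ni + nh : nh * ni + 2 * nh]
    model.b2 = float(theta[-1])


def _residual_jacobian(
    model: NetworkModel, Xn: np.ndarray, tn: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals r = yhat_norm - t_norm and their Jacobian w.r.t. all parameters."""
    yn, h = _forward_norm(model, Xn)
    r = yn - tn
    d = _transfer_deriv(h, model.transfer) * model.w2  # (n, nh)
    n, nh = h.shape
    J = np.empty((n, model.n_parameters))
    ni = Xn.shape[1]
    # dW1[j,k] = d[:,j] * x[:,k]
    J[:, : nh * ni] = (d[:, :, None] * Xn[:, None, :]).reshape(n, nh * ni)
    J[:, nh * ni : nh * ni + nh] = d
    J[:, nh * ni + nh : nh * ni + 2 * nh] = h
    J[:, -1] = 1.0
    return r, J


def _sse(model: NetworkModel, Xn: np.ndarray, tn: np.ndarray) -> float:
    yn, _ = _forward_norm(model, Xn)
    return float(np.sum((yn - tn) ** 2))


def train(
    model: NetworkModel,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    config: NetworkConfig,
    X_test: np.ndarray | None = None,
    y_test: np.ndarray | None = None,
    refit_norms: bool = True,
) -> TrainOutcome:
    """Train a network on a train/validation pair.

    Levenberg-Marquardt solves (J'J + mu I) delta = J'r each epoch,
    accepting the step (and relaxing mu) when the training SSE drops and
    stiffening mu otherwise; gradient descent takes a fixed full-batch
    step.  Training stops at ``max_epochs``, when the validation SSE has
    risen ``val_fail_limit`` consecutive epochs, or when the gradient
    norm falls below ``grad_tol``; the returned weights are always those
    of the best validation epoch.  ``refit_norms=False`` keeps the
    model's stored normalization (used for warm-started retraining).
    """
    X_train = np.asarray(X_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if X_train.shape[0] == 0 or X_val.shape[0] == 0:
        raise ValueError("train and validation sets must be nonempty")
    model = model.copy()
    if refit_norms:
        model.fit_normalization(X_train, y_train)
    Xn_tr = model.normalize_in(X_train)
    tn_tr = model.normalize_out(y_train)
    Xn_val = model.normalize_in(X_val)
    tn_val = model.normalize_out(y_val)

    theta = _pack(model)
    # The starting point (random init or warm start) is retained unless a
    # trained epoch beats its validation SSE by the configured relative
    # margin: noise-level "improvements" must not displace an already
    # validated warm start.
    val0 = _sse(model, Xn_val, tn_val)
    best_val = val0 * (1.0 - config.val_min_improvement)
    best_theta = theta.copy()
    val_prev = val0
    val_fails = 0
    mu = config.lm_mu0
    sse_tr = _sse(model, Xn_tr, tn_tr)
    stop_reason = "max_epochs"
    epochs = 0

    for _ in range(config.max_epochs):
        r, J = _residual_jacobian(model, Xn_tr, tn_tr)
        g = J.T @ r
        gnorm = float(np.linalg.norm(g)) / Xn_tr.shape[0]
        if gnorm < config.grad_tol:
            stop_reason = "converged"
            break
        if config.trainer == "lm":
            A = J.T @ J
            accepted = False
            while mu <= _MU_CAP:
                try:
                    c = cho_factor(A + mu * np.eye(A.shape[0]), lower=True)
                    delta = cho_solve(c, g)
                except LinAlgError:
                    mu *= config.lm_mu_inc
                    continue
                trial = theta - delta
                _unpack(model, trial)
                sse_try = _sse(model, Xn_tr, tn_tr)
                if sse_try < sse_tr:
                    theta = trial
                    sse_tr = sse_try
                    mu = max(mu * config.lm_mu_dec, 1e-20)
                    accepted = True
                    break
                mu *= config.lm_mu_inc
            if not accepted:
                # damping at its cap with no downhill step: local minimum
                _unpack(model, theta)
                stop_reason = "converged"
                break
        else:  # gd
            theta = theta - config.gd_learning_rate * 2.0 * g
            _unpack(model, theta)
            sse_tr = _sse(model, Xn_tr, tn_tr)
        epochs += 1

        val_sse = _sse(model, Xn_val, tn_val)
        if val_sse < best_val:
            best_val = val_sse
            best_theta = theta.copy()
        if val_sse > val_prev:
            val_fails += 1
            if val_fails >= config.val_fail_limit:
                stop_reason = "val_early_stop"
                break
        else:
            val_fails = 0
        val_prev = val_sse

    final_model = model.copy()
    _unpack(final_model, theta)
    _unpack(model, best_theta if config.restore_best_val else theta)
    outcome = TrainOutcome(
        model=model,
        epochs_run=epochs,
        stop_reason=stop_reason,
        train_summary=error_summary(y_train, forward(model, X_train)),
        val_summary=error_summary(y_val, forward(model, X_val)),
        final_model=final_model,
    )
    if X_test is not None and y_test is not None and len(y_test):
        outcome.test_summary = error_summary(
            np.asarray(y_test, float), forward(model, np.asarray(X_test, float))
        )
    return outcome


# ---------------------------------------------------------------------------
# serialization

def model_to_dict(model: NetworkModel) -> dict:
    return {
        "schema_version": _MODEL_SCHEMA_VERSION,
        "feature_names": list(model.feature_names),
        "transfer": model.transfer,
        "n_hidden": model.n_hidden,
        "n_inputs": model.n_inputs,
        "W1": model.W1.ravel().tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2,
        "in_min": model.in_min.tolist(),
        "in_max": model.in_max.tolist(),
        "out_min": model.out_min,
        "out_max": model.out_max,
    }


def model_from_dict(d: dict) -> NetworkModel:
    if d.get("schema_version") != _MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {d.get('schema_version')!r}; "
            f"expected {_MODEL_SCHEMA_VERSION}"
        )
    nh, ni = d["n_hidden"], d["n_inputs"]
    return NetworkModel(
        feature_names=tuple(d["feature_names"]),
        W1=np.array(d["W1"], dtype=float).reshape(nh, ni),
        b1=np.array(d["b1"], dtype=float),
        w2=np.array(d["w2"], dtype=float),
        b2=float(d["b2"]),
        in_min=np.array(d["in_min"], dtype=float),
        in_max=np.array(d["in_max"], dtype=float),
        out_min=float(d["out_min"]),
        out_max=float(d["out_max"]),
        transfer=d["transfer"],
    )


def save_model(model: NetworkModel, path) -> None:
    """Write the model as JSON (weights row-major, full float precision)."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh)


def load_model(path) -> NetworkModel:
    with open(path) as fh:
        return model_from_dict(json.load(fh))
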