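"""Three-layer feed-forward network with adaptive momentum backpropagation.

One hidden layer with the hyperbolic-tangent-sigmoid (tansig) activation
and a linear (purelin) output unit, trained full-batch on the
least-mean-squares criterion by gradient descent with momentum and an
adaptive learning rate: the rate grows by a fixed factor after an epoch
that lowered the loss, and an epoch that raises the loss past a tolerance
ratio is rejected, the momentum buffer cleared, and the rate cut.  The
learning rate 0.01 and momentum 0.4 follow the study configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .config import InvalidConfigError


def tansig(n):
    """Hyperbolic tangent sigmoid: -1 + 2/(1 + exp(-2n)), i.e. tanh(n)."""
    return np.tanh(n)


def purelin(n):
    """Linear (identity) activation."""
    return n


@dataclass
class TrainConfig:
    learning_rate: float = 0.01
    momentum: float = 0.4
    max_epochs: int = 5000
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    error_ratio_limit: float = 1.04
    init_scale: float = 0.5
    seed: int = 0
    early_stop_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InvalidConfigError("learning_rate must be positive")
        if not (0.0 <= self.momentum < 1.0):
            raise InvalidConfigError("momentum must lie in [0, 1)")
        # factors of exactly 1 turn the schedule off (plain gradient descent)
        if self.lr_increase < 1.0:
            raise InvalidConfigError("lr_increase must be >= 1")
        if not (0.0 < self.lr_decrease <= 1.0):
            raise InvalidConfigError("lr_decrease must lie in (0, 1]")


@dataclass
class AnnModel:
    """Weights and biases of the 3-layer network."""

    w_hidden: np.ndarray  # (n_hidden, n_inputs)
    b_hidden: np.ndarray  # (n_hidden,)
    w_out: np.ndarray     # (n_hidden,)
    b_out: float
    n_hidden: int

    def copy(self) -> "AnnModel":
        return AnnModel(self.w_hidden.copy(), self.b_hidden.copy(),
                        self.w_out.copy(), float(self.b_out), self.n_hidden)


@dataclass
class TrainTrace:
    mse: list = field(default_factory=list)
    learning_rate: list = field(default_factory=list)

    @property
    def epochs_run(self) -> int:
        return len(self.mse)


def init_ann(n_inputs: int, n_hidden: int, cfg: TrainConfig) -> AnnModel:
    """Seeded uniform(-init_scale, init_scale) weights, zero biases."""
    if n_inputs < 1 or n_hidden < 1:
        raise InvalidConfigError("n_inputs and n_hidden must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    w_h = rng.uniform(-cfg.init_scale, cfg.init_scale, size=(n_hidden, n_inputs))
    w_o = rng.uniform(-cfg.init_scale, cfg.init_scale, size=n_hidden)
    return AnnModel(w_h, np.zeros(n_hidden), w_o, 0.0, n_hidden)


def forward(m: AnnModel, X: np.ndarray) -> np.ndarray:
    """Network scores: purelin(w_out . tansig(W_h x + b_h) + b_out)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != m.w_hidden.shape[1]:
        raise ValueError("input width does not match the network")
    H = tansig(X @ m.w_hidden.T + m.b_hidden)
    return purelin(H @ m.w_out + m.b_out)


def _loss_and_grads(m: AnnModel, X: np.ndarray, y: np.ndarray):
    """LMS loss L = mean((score - y)^2)/2 and its analytic gradients."""
    n = X.shape[0]
    H = tansig(X @ m.w_hidden.T + m.b_hidden)      # (n, h)
    score = H @ m.w_out + m.b_out
    err = score - y
    loss = float(err @ err) / (2.0 * n)
    d_score = err / n                               # dL/dscore
    g_wo = H.T @ d_score
    g_bo = float(d_score.sum())
    d_H = np.outer(d_score, m.w_out) * (1.0 - H * H)
    g_wh = d_H.T @ X
    g_bh = d_H.sum(axis=0)
    return loss, (g_wh, g_bh, g_wo, g_bo)


def train(m: AnnModel, X: np.ndarray, y: np.ndarray,
          cfg: TrainConfig) -> tuple[AnnModel, TrainTrace]:
    """Full-batch adaptive gradient descent with momentum on the LMS loss.

    Update: dw_t = momentum * dw_{t-1} - lr_t * grad.  After each epoch the
    new loss is compared with the previous one: if it exceeds
    ``error_ratio_limit`` times the previous loss the step is rejected, the
    momentum buffer zeroed, and the rate decreased; otherwise the step is
    accepted and, when the loss fell, the rate increased.  Stops at
    ``max_epochs`` or when the accepted-loss change drops below
    ``early_stop_tol``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise ValueError("X/y row mismatch")
    m = m.copy()
    lr = cfg.learning_rate
    vel = [np.zeros_like(m.w_hidden), np.zeros_like(m.b_hidden),
           np.zeros_like(m.w_out), 0.0]
    trace = TrainTrace()
    prev_loss, _ = _loss_and_grads(m, X, y)
    for _ in range(cfg.max_epochs):
        loss, grads = _loss_and_grads(m, X, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss after {trace.epochs_run} epochs")
        steps = [cfg.momentum * v - lr * g for v, g in zip(vel, grads)]
        cand = m.copy()
        cand.w_hidden += steps[0]
        cand.b_hidden += steps[1]
        cand.w_out += steps[2]
        cand.b_out += steps[3]
        new_loss, _ = _loss_and_grads(cand, X, y)
        if new_loss > cfg.error_ratio_limit * loss:
            # reject: keep weights, clear momentum, cool the rate
            vel = [np.zeros_like(m.w_hidden), np.zeros_like(m.b_hidden),
                   np.zeros_like(m.w_out), 0.0]
            lr *= cfg.lr_decrease
            trace.mse.append(loss)
            trace.learning_rate.append(lr)
            prev_loss = loss
            continue
        m, vel = cand, steps
        if new_loss < loss:
            lr *= cfg.lr_increase
        trace.mse.append(new_loss)
        trace.learning_rate.append(lr)
        if abs(prev_loss - new_loss) < cfg.early_stop_tol:
            break
        prev_loss = new_loss
    return m, trace


def predict_class(m: AnnModel, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Class 1 iff the network score is >= threshold."""
    return (forward(m, X) >= threshold).astype(int)


def error_rate(pred: np.ndarray, truth: np.ndarray) -> float:
    """Misclassification fraction."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size == 0:
        raise ValueError("pred and truth must be nonempty and equal length")
    return float(np.mean(pred != truth))


def save_model(m: AnnModel, cfg: TrainConfig, trace: TrainTrace, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "w_hidden": m.w_hidden.tolist(), "b_hidden": m.b_hidden.tolist(),
            "w_out": m.w_out.tolist(), "b_out": m.b_out, "n_hidden": m.n_hidden,
            "config": asdict(cfg),
            "trace": {"mse": trace.mse, "learning_rate": trace.learning_rate},
        }, fh)


def load_model(path) -> tuple[AnnModel, TrainConfig, TrainTrace]:
    with open(path) as fh:
        d = json.load(fh)
    m = AnnModel(np.array(d["w_hidden"]), np.array(d["b_hidden"]),
                 np.array(d["w_out"]), float(d["b_out"]), int(d["n_hidden"]))
    cfg = TrainConfig(**d["config"])
    tr = TrainTrace(d["trace"]["mse"], d["trace"]["learning_rate"])
    return m, cfg, tr
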