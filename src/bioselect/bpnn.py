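"""Backpropagation network with momentum and a variable learning rate.

A three-layer net: n inputs, H = 2n + 1 sigmoid hidden units, one linear
output trained against 0/1 targets by full-batch gradient descent on squared
error.  The learning rate adapts per epoch: an epoch whose MSE rises beyond a
tolerance of the previous MSE is reverted (and the rate shrunk); an epoch
that lowers the MSE is accepted and the rate grown.  Momentum accumulates a
velocity term that is reset whenever an epoch is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_X_y, check_array, check_is_fitted

__all__ = ["BPNNConfig", "hidden_node_count", "BackpropClassifier"]


@dataclass(frozen=True)
class BPNNConfig:
    """Training settings; the defaults are the standard adaptive-rate choices."""

    init_weight_low: float = -0.5
    init_weight_high: float = 0.5
    initial_lr: float = 0.5
    momentum: float = 0.9
    lr_increase: float = 1.05
    lr_decrease: float = 0.7
    error_increase_tolerance: float = 1.04
    max_epochs: int = 1000
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self):
        if not self.lr_increase > 1 > self.lr_decrease > 0:
            raise ValueError("need lr_increase > 1 > lr_decrease > 0")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


def hidden_node_count(n_inputs: int) -> int:
    """Hidden width rule H = 2n + 1 for n input nodes."""
    if n_inputs < 1:
        raise ValueError("need at least one input node")
    return 2 * n_inputs + 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class BackpropClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier: sigmoid hidden layer, linear output, 0.5 threshold.

    Parameters follow the adaptive-learning-rate construction: ``momentum``
    scales the retained velocity, ``lr_increase``/``lr_decrease`` rescale the
    learning rate after improving/worsening epochs, and an epoch whose MSE
    exceeds ``error_increase_tolerance`` times the previous MSE is undone.
    ``hidden=None`` uses the 2n + 1 rule.
    """

    def __init__(self, hidden: int | None = None, initial_lr: float = 0.5,
                 momentum: float = 0.9, lr_increase: float = 1.05,
                 lr_decrease: float = 0.7, error_increase_tolerance: float = 1.04,
                 max_epochs: int = 1000, convergence_tol: float = 1e-6,
                 init_weight_low: float = -0.5, init_weight_high: float = 0.5,
                 random_state: int = 0):
        self.hidden = hidden
        self.initial_lr = initial_lr
        self.momentum = momentum
        self.lr_increase = lr_increase
        self.lr_decrease = lr_decrease
        self.error_increase_tolerance = error_increase_tolerance
        self.max_epochs = max_epochs
        self.convergence_tol = convergence_tol
        self.init_weight_low = init_weight_low
        self.init_weight_high = init_weight_high
        self.random_state = random_state

    @classmethod
    def from_config(cls, config: BPNNConfig, hidden: int | None = None):
        return cls(hidden=hidden, initial_lr=config.initial_lr,
                   momentum=config.momentum, lr_increase=config.lr_increase,
                   lr_decrease=config.lr_decrease,
                   error_increase_tolerance=config.error_increase_tolerance,
                   max_epochs=config.max_epochs,
                   convergence_tol=config.convergence_tol,
                   init_weight_low=config.init_weight_low,
                   init_weight_high=config.init_weight_high,
                   random_state=config.seed)

    # -- forward / loss / gradients ---------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Hidden activations and raw linear output scores."""
        hidden = _sigmoid(X @ self.W1_ + self.b1_)
        scores = hidden @ self.w2_ + self.b2_
        return hidden, scores

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        _, scores = self._forward(np.asarray(X, dtype=float))
        return float(np.mean((scores - np.asarray(y, dtype=float)) ** 2))

    def gradients(self, X: np.ndarray, y: np.ndarray) -> dict[str, np.ndarray]:
        """Analytic batch gradients of the MSE w.r.t. every weight and bias."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        hidden, scores = self._forward(X)
        m = X.shape[0]
        d_out = 2.0 * (scores - y) / m          # dE/d(score)
        d_hidden = np.outer(d_out, self.w2_) * hidden * (1.0 - hidden)
        return {
            "W1": X.T @ d_hidden,
            "b1": d_hidden.sum(axis=0),
            "w2": hidden.T @ d_out,
            "b2": np.array(d_out.sum()),
        }

    def _train_epoch(self, X, y) -> bool:
        """One batch gradient step with momentum, accept/revert, and lr update."""
        grads = self.gradients(X, y)
        old = {"W1": self.W1_.copy(), "b1": self.b1_.copy(),
               "w2": self.w2_.copy(), "b2": self.b2_}
        for key in self._velocity:
            self._velocity[key] = (self.momentum * self._velocity[key]
                                   - self.learning_rate_ * grads[key])
        self.W1_ = self.W1_ + self._velocity["W1"]
        self.b1_ = self.b1_ + self._velocity["b1"]
        self.w2_ = self.w2_ + self._velocity["w2"]
        self.b2_ = float(self.b2_ + self._velocity["b2"])
        new_mse = self.loss(X, y)
        if not np.isfinite(new_mse):
            raise FloatingPointError("non-finite training error; state dumped in error_history_")
        prev = self.error_history_[-1]
        if new_mse > self.error_increase_tolerance * prev:
            # reject: undo the step, shrink the rate, drop accumulated velocity
            self.W1_, self.b1_, self.w2_ = old["W1"], old["b1"], old["w2"]
            self.b2_ = float(old["b2"])
            self.learning_rate_ *= self.lr_decrease
            self._velocity = {k: np.zeros_like(v) for k, v in self._velocity.items()}
            self.error_history_.append(prev)
            self.lr_history_.append(self.learning_rate_)
            return False
        if new_mse < prev:
            self.learning_rate_ *= self.lr_increase
        self.error_history_.append(new_mse)
        self.lr_history_.append(self.learning_rate_)
        return True

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y):
        X, y = check_X_y(X, y)
        self.classes_ = np.unique(y)
        if self.classes_.shape[0] != 2:
            raise ValueError("binary targets required")
        y01 = (y == self.classes_[1]).astype(float)
        n = X.shape[1]
        if n < 1:
            raise ValueError("need at least one input feature")
        H = self.hidden if self.hidden is not None else hidden_node_count(n)
        rng = np.random.default_rng(self.random_state)
        lo, hi = self.init_weight_low, self.init_weight_high
        self.W1_ = rng.uniform(lo, hi, size=(n, H))
        self.b1_ = rng.uniform(lo, hi, size=H)
        self.w2_ = rng.uniform(lo, hi, size=H)
        self.b2_ = float(rng.uniform(lo, hi))
        self._velocity = {"W1": np.zeros((n, H)), "b1": np.zeros(H),
                          "w2": np.zeros(H), "b2": np.zeros(())}
        self.learning_rate_ = float(self.initial_lr)
        self.error_history_ = [self.loss(X, y01)]
        self.lr_history_ = [self.learning_rate_]
        self.n_features_in_ = n
        self.n_hidden_ = H
        for epoch in range(self.max_epochs):
            before = self.error_history_[-1]
            accepted = self._train_epoch(X, y01)
            # a rejected (reverted) epoch leaves the error unchanged and must
            # not count as convergence
            if accepted and abs(self.error_history_[-1] - before) < self.convergence_tol:
                break
        self.n_iter_ = len(self.error_history_) - 1
        return self

    def decision_function(self, X):
        check_is_fitted(self, "W1_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature-count mismatch with the fitted network")
        _, scores = self._forward(X)
        return scores

    def predict(self, X):
        scores = self.decision_function(X)
        return self.classes_[(scores >= 0.5).astype(int)]
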