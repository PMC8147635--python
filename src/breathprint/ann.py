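"""Feed-forward tanh network trained with resilient backpropagation.

The classifier maps a 19-element breathprint through two hidden layers
(17 and 7 units by default) to a single tanh output in (-1, 1); targets
are -1 (control) and +1 (case).  Training uses sign-based per-weight step
adaptation (iRprop- by default: steps grow x1.2 on gradient-sign
agreement, shrink x0.5 on a flip, and the flipped gradient is zeroed),
full-batch, with the stopping/restart protocol:

* stop when the mean squared error reaches ``minimal_error``, or
* at ``max_epoch`` epochs, or
* after ``max_same_error`` consecutive epochs with unchanged error
  (absolute tolerance 1e-12), or
* after ``max_error_inc`` consecutive epochs of increasing error;

on any stop short of ``minimal_error`` the weights are re-initialized and
training restarts, up to ``max_retries`` times, keeping the best run.

``learn_rate`` is the initial rprop step size.  Classic rprop has neither
a learning rate nor a momentum term, so the ``alpha`` parameter is given a
configurable role: ``"momentum"`` (default) smooths the gradient,
g <- grad + alpha * g_prev, before its sign is taken; ``"decay"`` adds an
L2 penalty alpha/2 * ||w||^2 to the loss; ``"none"`` ignores it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

STEP_GROW = 1.2
STEP_SHRINK = 0.5
STEP_MIN = 1e-8
STEP_MAX = 0.05
SAME_ERROR_TOL = 1e-12

_ALPHA_ROLES = ("momentum", "decay", "none")
_VARIANTS = ("irprop-", "rprop-")


@dataclass
class TrainingConfig:
    """Rprop training parameter block."""

    max_epoch: int = 5000
    max_retries: int = 25
    max_same_error: int = 30
    max_error_inc: int = 15
    minimal_error: float = 0.0005
    learn_rate: float = 0.0010
    alpha: float = 0.0500
    topology: tuple[int, ...] = (17, 7)
    alpha_role: str = "momentum"
    variant: str = "irprop-"
    step_min: float = STEP_MIN
    step_max: float = STEP_MAX
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("max_epoch", "max_retries", "max_same_error", "max_error_inc"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.minimal_error <= 0:
            raise ValueError("minimal_error must be > 0")
        if any(h < 1 for h in self.topology):
            raise ValueError("hidden layer sizes must be >= 1")
        if self.alpha_role not in _ALPHA_ROLES:
            raise ValueError(f"alpha_role must be one of {_ALPHA_ROLES}")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")


# ---------------------------------------------------------------------------
# functional core (weights as flat lists of arrays)


def init_weights(layer_sizes: list[int], rng: np.random.Generator):
    """Uniform(-0.5, 0.5) weights and biases, scaled by 1/sqrt(fan-in)."""
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(n_in, n_out)) / np.sqrt(n_in))
        biases.append(rng.uniform(-0.5, 0.5, size=n_out))
    return weights, biases


def forward(weights, biases, X: np.ndarray) -> np.ndarray:
    """Forward pass; returns the (n,) tanh output."""
    a = X
    for w, b in zip(weights, biases):
        a = np.tanh(a @ w + b)
    return a[:, 0]


def loss_and_gradients(weights, biases, X: np.ndarray, t: np.ndarray, decay: float = 0.0):
    """Mean-squared-error loss and its gradients by backpropagation.

    ``decay`` adds alpha/2 * sum(w^2) (weights and biases) to the loss.
    Returns (loss, grad_weights, grad_biases); the reported loss includes
    the penalty, while the plain data MSE is available via :func:`mse`.
    """
    n = X.shape[0]
    activations = [X]
    a = X
    for w, b in zip(weights, biases):
        a = np.tanh(a @ w + b)
        activations.append(a)
    out = activations[-1][:, 0]
    err = out - t
    loss = float(np.mean(err**2))

    delta = (2.0 / n) * err[:, None] * (1.0 - activations[-1] ** 2)
    grad_w, grad_b = [], []
    for layer in range(len(weights) - 1, -1, -1):
        grad_w.insert(0, activations[layer].T @ delta)
        grad_b.insert(0, delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ weights[layer].T) * (1.0 - activations[layer] ** 2)
    if decay > 0.0:
        loss += 0.5 * decay * (
            sum(float(np.sum(w**2)) for w in weights)
            + sum(float(np.sum(b**2)) for b in biases)
        )
        grad_w = [g + decay * w for g, w in zip(grad_w, weights)]
        grad_b = [g + decay * b for g, b in zip(grad_b, biases)]
    return loss, grad_w, grad_b


def mse(weights, biases, X: np.ndarray, t: np.ndarray) -> float:
    out = forward(weights, biases, X)
    return float(np.mean((out - t) ** 2))


def _rprop_attempt(X, t, layer_sizes, cfg: TrainingConfig, rng):
    """One training run from fresh weights; returns (weights, biases,
    final data MSE, error trace, stop reason)."""
    weights, biases = init_weights(layer_sizes, rng)
    params = weights + biases
    steps = [np.full_like(p, cfg.learn_rate) for p in params]
    prev_grad = [np.zeros_like(p) for p in params]
    momentum = [np.zeros_like(p) for p in params]
    decay = cfg.alpha if cfg.alpha_role == "decay" else 0.0

    trace = []
    prev_err = np.inf
    same_run = inc_run = 0
    stop = "max_epoch"
    for epoch in range(cfg.max_epoch):
        loss, gw, gb = loss_and_gradients(weights, biases, X, t, decay=decay)
        data_err = loss if decay == 0.0 else mse(weights, biases, X, t)
        trace.append(data_err)

        if data_err <= cfg.minimal_error:
            stop = "minimal_error"
            break
        if epoch > 0:
            if abs(data_err - prev_err) <= SAME_ERROR_TOL:
                same_run += 1
            else:
                same_run = 0
            if data_err > prev_err:
                inc_run += 1
            else:
                inc_run = 0
            if same_run >= cfg.max_same_error:
                stop = "same_error"
                break
            if inc_run >= cfg.max_error_inc:
                stop = "error_increase"
                break
        prev_err = data_err

        grads = gw + gb
        for i, (p, g) in enumerate(zip(params, grads)):
            if cfg.alpha_role == "momentum":
                momentum[i] = g + cfg.alpha * momentum[i]
                g = momentum[i]
            sign_prod = g * prev_grad[i]
            grew = sign_prod > 0.0
            shrunk = sign_prod < 0.0
            steps[i][grew] = np.minimum(steps[i][grew] * STEP_GROW, cfg.step_max)
            steps[i][shrunk] = np.maximum(steps[i][shrunk] * STEP_SHRINK, cfg.step_min)
            if cfg.variant == "irprop-":
                g = np.where(shrunk, 0.0, g)
            p -= np.sign(g) * steps[i]
            prev_grad[i] = g
    final = mse(weights, biases, X, t)
    return weights, biases, final, trace, stop


def rprop_train(X, t, cfg: TrainingConfig):
    """Full protocol: train with restarts, keep the best attempt.

    ``t`` must contain both -1 and +1 targets.  Returns a dict with
    weights, biases, final_error, trace of the kept attempt, stop reason,
    and the number of attempts used.
    """
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if not (np.any(t > 0) and np.any(t < 0)):
        raise ValueError("degenerate labels: need both classes to train")
    layer_sizes = [X.shape[1], *cfg.topology, 1]
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    best = None
    attempts = 0
    for _ in range(cfg.max_retries):
        attempts += 1
        weights, biases, final, trace, stop = _rprop_attempt(X, t, layer_sizes, cfg, rng)
        if best is None or final < best["final_error"]:
            best = {
                "weights": weights,
                "biases": biases,
                "final_error": final,
                "trace": trace,
                "stop_reason": stop,
            }
        if best["final_error"] <= cfg.minimal_error:
            break
    best["n_attempts"] = attempts
    return best


# ---------------------------------------------------------------------------
# scikit-learn estimator


class RpropNetClassifier(ClassifierMixin, BaseEstimator):
    """19 -> 17 -> 7 -> 1 tanh network with resilient backpropagation.

    ``decision_function`` returns the raw network output in (-1, 1);
    ``predict`` thresholds it at ``decision_threshold`` (strictly greater
    counts as the positive class).

    Attributes (after fit): ``classes_``, ``weights_``, ``biases_``,
    ``final_error_``, ``loss_curve_``, ``n_attempts_``, ``stop_reason_``.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (17, 7),
        max_epoch: int = 5000,
        max_retries: int = 25,
        max_same_error: int = 30,
        max_error_inc: int = 15,
        minimal_error: float = 0.0005,
        learn_rate: float = 0.0010,
        alpha: float = 0.0500,
        alpha_role: str = "momentum",
        variant: str = "irprop-",
        decision_threshold: float = 0.0,
        random_state: int | None = None,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_epoch = max_epoch
        self.max_retries = max_retries
        self.max_same_error = max_same_error
        self.max_error_inc = max_error_inc
        self.minimal_error = minimal_error
        self.learn_rate = learn_rate
        self.alpha = alpha
        self.alpha_role = alpha_role
        self.variant = variant
        self.decision_threshold = decision_threshold
        self.random_state = random_state

    def _config(self) -> TrainingConfig:
        return TrainingConfig(
            max_epoch=self.max_epoch,
            max_retries=self.max_retries,
            max_same_error=self.max_same_error,
            max_error_inc=self.max_error_inc,
            minimal_error=self.minimal_error,
            learn_rate=self.learn_rate,
            alpha=self.alpha,
            topology=tuple(self.hidden_layer_sizes),
            alpha_role=self.alpha_role,
            variant=self.variant,
            seed=0 if self.random_state is None else int(self.random_state),
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, n_features)")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"need exactly 2 classes, got {len(self.classes_)}"
            )
        t = np.where(y == self.classes_[1], 1.0, -1.0)
        result = rprop_train(X, t, self._config())
        self.weights_ = result["weights"]
        self.biases_ = result["biases"]
        self.final_error_ = result["final_error"]
        self.loss_curve_ = result["trace"]
        self.n_attempts_ = result["n_attempts"]
        self.stop_reason_ = result["stop_reason"]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        return forward(self.weights_, self.biases_, X)

    def predict(self, X) -> np.ndarray:
        values = self.decision_function(X)
        return self.classes_[(values > self.decision_threshold).astype(int)]

    @property
    def n_parameters_(self) -> int:
        check_is_fitted(self, "weights_")
        return sum(w.size for w in self.weights_) + sum(b.size for b in self.biases_)


def n_parameters(layer_sizes: list[int]) -> int:
    """Weight + bias count of a fully connected net (e.g. 474 for 19-17-7-1)."""
    return sum(
        n_in * n_out + n_out for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:])
    )


def model_to_json_dict(clf: RpropNetClassifier) -> dict:
    """Serializable snapshot of a fitted model."""
    check_is_fitted(clf, "weights_")
    return {
        "layer_sizes": [clf.n_features_in_, *clf.hidden_layer_sizes, 1],
        "weights": [w.tolist() for w in clf.weights_],
        "biases": [b.tolist() for b in clf.biases_],
        "classes": [str(c) for c in clf.classes_],
        "final_error": clf.final_error_,
        "config": clf.get_params(),
    }


def model_from_json_dict(payload: dict) -> RpropNetClassifier:
    clf = RpropNetClassifier(**payload["config"])
    clf.weights_ = [np.asarray(w, dtype=float) for w in payload["weights"]]
    clf.biases_ = [np.asarray(b, dtype=float) for b in payload["biases"]]
    clf.classes_ = np.asarray(payload["classes"])
    clf.final_error_ = payload["final_error"]
    clf.n_features_in_ = payload["layer_sizes"][0]
    clf.loss_curve_ = []
    clf.n_attempts_ = 0
    clf.stop_reason_ = "loaded"
    return clf


def numerical_gradient(weights, biases, X, t, decay: float = 0.0, eps: float = 1e-6):
    """Central finite-difference gradient of the loss (oracle for tests)."""
    def loss_of(params_w, params_b):
        l, _, _ = loss_and_gradients(params_w, params_b, X, t, decay=decay)
        return l

    grads_w = []
    for li, w in enumerate(weights):
        g = np.zeros_like(w)
        for idx in np.ndindex(*w.shape):
            wp = [a.copy() for a in weights]
            wm = [a.copy() for a in weights]
            wp[li][idx] += eps
            wm[li][idx] -= eps
            g[idx] = (loss_of(wp, biases) - loss_of(wm, biases)) / (2 * eps)
        grads_w.append(g)
    grads_b = []
    for li, b in enumerate(biases):
        g = np.zeros_like(b)
        for idx in np.ndindex(*b.shape):
            bp = [a.copy() for a in biases]
            bm = [a.copy() for a in biases]
            bp[li][idx] += eps
            bm[li][idx] -= eps
            g[idx] = (loss_of(weights, bp) - loss_of(weights, bm)) / (2 * eps)
        grads_b.append(g)
    return grads_w, grads_b
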