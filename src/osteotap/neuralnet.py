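"""From-scratch feed-forward sigmoid network with back-propagation.

Every neuron applies the logistic sigmoid a = 1/(1 + e^{-u}) to its
weighted input sum, so the single output neuron yields a score strictly
inside (0, 1); the teacher encoding is 0 for osteoporotic (OP) and 1
for healthy (OK).  Training minimises the half sum-of-squares error
energy E = ½ Σ (o − t)² by plain gradient descent, either online
(one example per update) or in block mode (one update per full pass).

Three checkpoint criteria are evaluated on the validation set after
each epoch: (1) a new minimum of r = FPR/TPR, armed only once r has
fallen below the configured ratio threshold; (2) a new maximum of
IR-level accuracy; (3) the training error dropping below its stop
threshold, which also ends the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default output-ambiguity threshold used when scoring checkpoints
DEFAULT_TAU = 0.4


@dataclass
class NetworkModel:
    layer_sizes: list[int]
    weights: list[np.ndarray]  # weights[l] has shape (n_out, n_in)
    biases: list[np.ndarray]
    seed: int | None = None

    def copy(self) -> "NetworkModel":
        return NetworkModel(layer_sizes=list(self.layer_sizes),
                            weights=[w.copy() for w in self.weights],
                            biases=[b.copy() for b in self.biases],
                            seed=self.seed)


@dataclass
class TrainingConfig:
    learning_rate: float = 0.01
    mode: str = "online"  # "online" | "block"
    max_epochs: int = 5000
    seed: int = 0
    stop_error: float = 0.25  # stop when E_train drops below this
    checkpoint_ratio: float = 0.7  # arms the r-minimum criterion
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.mode not in ("online", "block"):
            raise ValueError("mode must be 'online' or 'block'")


@dataclass
class Checkpoint:
    epoch: int
    criterion: str  # "min_ratio" | "max_accuracy" | "train_error"
    model: NetworkModel
    value: float


@dataclass
class TrainingHistory:
    train_error: list[float] = field(default_factory=list)
    val_error: list[float] = field(default_factory=list)
    checkpoints: dict[str, Checkpoint] = field(default_factory=dict)

    @property
    def epochs_run(self) -> int:
        return len(self.train_error)


def default_architecture(n_inputs: int, n_train: int) -> list[int]:
    """120-hidden single layer; a second 40-neuron layer for larger sets."""
    if n_train > 100:
        return [n_inputs, 120, 40, 1]
    return [n_inputs, 120, 1]


def initialize(layer_sizes: list[int], seed: int) -> NetworkModel:
    """Uniform weights in ±0.5/sqrt(fan-in), zero biases; reproducible per seed."""
    if not layer_sizes or len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    if layer_sizes[-1] != 1:
        raise ValueError("output layer must have exactly one neuron")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        scale = 0.5 / np.sqrt(n_in)
        weights.append(rng.uniform(-scale, scale, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetworkModel(layer_sizes=list(layer_sizes), weights=weights,
                        biases=biases, seed=seed)


def sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u, dtype=float)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    eu = np.exp(u[~pos])
    out[~pos] = eu / (1.0 + eu)
    return out


def forward(net: NetworkModel, x: np.ndarray):
    """Network output(s) in (0,1) plus the per-layer activations.

    Accepts a single vector (d,) or a batch (n, d); the output is a
    scalar or an (n,) array accordingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != net.layer_sizes[0]:
        raise ValueError(f"input size {a.shape[1]} != input layer {net.layer_sizes[0]}")
    activations = [a]
    for w, b in zip(net.weights, net.biases):
        a = sigmoid(a @ w.T + b)
        activations.append(a)
    out = a[:, 0]
    if single:
        return float(out[0]), [act[0] for act in activations]
    return out, activations


def predict(net: NetworkModel, X: np.ndarray) -> np.ndarray:
    return forward(net, np.atleast_2d(X))[0]


def error_energy(outputs: np.ndarray, teachers: np.ndarray) -> float:
    """Half the summed squared output-teacher deviations."""
    o = np.asarray(outputs, dtype=float)
    t = np.asarray(teachers, dtype=float)
    if o.shape != t.shape:
        raise ValueError("outputs and teachers must have equal length")
    return 0.5 * float(np.sum((o - t) ** 2))


def gradients(net: NetworkModel, X: np.ndarray, T: np.ndarray):
    """Exact gradient of the half-squared error over the batch."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = np.atleast_1d(np.asarray(T, dtype=float))
    _, acts = forward(net, X)
    delta = (acts[-1] - T[:, None]) * acts[-1] * (1.0 - acts[-1])
    dW, db = [None] * len(net.weights), [None] * len(net.biases)
    for layer in range(len(net.weights) - 1, -1, -1):
        dW[layer] = delta.T @ acts[layer]
        db[layer] = delta.sum(axis=0)
        if layer > 0:
            delta = (delta @ net.weights[layer]) * acts[layer] * (1.0 - acts[layer])
    return dW, db


def backprop_step(net: NetworkModel, X: np.ndarray, T: np.ndarray,
                  learning_rate: float) -> NetworkModel:
    """One gradient-descent update over the batch (in place; net returned)."""
    if np.atleast_2d(X).shape[0] == 0:
        raise ValueError("batch must be non-empty")
    dW, db = gradients(net, X, T)
    for layer in range(len(net.weights)):
        net.weights[layer] -= learning_rate * dW[layer]
        net.biases[layer] -= learning_rate * db[layer]
    return net


def _ir_confusion(outputs: np.ndarray, teachers: np.ndarray, tau: float):
    """Minimal ambiguity-band confusion counts (positive class: OP, teacher 0)."""
    o = np.asarray(outputs, float)
    t = np.asarray(teachers, float)
    pred_op = (o <= tau) & (o != 0.5)
    pred_ok = (o >= 1.0 - tau) & (o != 0.5)
    true_op = t == 0.0
    tp = int(np.sum(pred_op & true_op))
    fp = int(np.sum(pred_op & ~true_op))
    tn = int(np.sum(pred_ok & ~true_op))
    fn = int(np.sum(pred_ok & true_op))
    return tp, fp, tn, fn


def train(net: NetworkModel, train_set, val_set,
          cfg: TrainingConfig | None = None):
    """Run epochs of back-propagation, tracking errors and checkpoints.

    `train_set` and `val_set` are (X, T) pairs; `val_set` may be None.
    Returns (net, TrainingHistory).  Fully deterministic for a given
    (net, data, config): examples are presented in a fixed order.
    """
    cfg = cfg or TrainingConfig()
    X, T = train_set
    X = np.atleast_2d(np.asarray(X, float))
    T = np.atleast_1d(np.asarray(T, float))
    if X.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    if val_set is not None:
        Xv = np.atleast_2d(np.asarray(val_set[0], float))
        Tv = np.atleast_1d(np.asarray(val_set[1], float))
    history = TrainingHistory()
    best_r = np.inf
    best_acc = -np.inf

    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.mode == "online":
            for i in range(X.shape[0]):
                backprop_step(net, X[i:i + 1], T[i:i + 1], cfg.learning_rate)
        else:
            backprop_step(net, X, T, cfg.learning_rate)

        e_train = error_energy(predict(net, X), T)
        history.train_error.append(e_train)
        if val_set is not None:
            out_v = predict(net, Xv)
            history.val_error.append(error_energy(out_v, Tv))
            tp, fp, tn, fn = _ir_confusion(out_v, Tv, cfg.tau)
            if tp > 0:
                r = (fp / max(1, fp + tn)) / (tp / (tp + fn)) if (tp + fn) else np.inf
                if r < cfg.checkpoint_ratio and r < best_r:
                    best_r = r
                    history.checkpoints["min_ratio"] = Checkpoint(
                        epoch, "min_ratio", net.copy(), r)
            decided = tp + fp + tn + fn
            if decided:
                acc = (tp + tn) / decided
                if acc > best_acc:
                    best_acc = acc
                    history.checkpoints["max_accuracy"] = Checkpoint(
                        epoch, "max_accuracy", net.copy(), acc)
        if e_train < cfg.stop_error:
            history.checkpoints["train_error"] = Checkpoint(
                epoch, "train_error", net.copy(), e_train)
            break

    return net, history
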