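"""Deep belief network regressor for instantaneous EMG-to-force mapping.

A four-layer network (input, two sigmoid hidden layers, one linear output)
maps a per-sample vector of representative activation signals to the
normalized force at that sample. Training follows the classic two-stage
recipe:

1. **Greedy pre-training.** Each hidden layer is trained as a restricted
   Boltzmann machine with one step of contrastive divergence (CD-1). The
   first RBM has Gaussian visible units on standardized inputs; the second
   has Bernoulli visible units fed the first RBM's hidden probabilities
   (probabilities, not samples, are propagated between stacked RBMs by
   default — lower variance).
2. **Fine-tuning.** The unrolled network is trained by full backpropagation
   on mean-squared error with mini-batch gradient descent plus momentum,
   early-stopped on a validation set; the best-validation snapshot is
   returned.

Everything is plain numpy and bit-reproducible under a fixed seed. Typical
topologies are (1, 80, 80, 1) for a single-component input and
(4, 100, 100, 1) when all four grids contribute one component each.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "DivergenceError",
    "RBMLayer",
    "DBNModel",
    "DBNConfig",
    "hidden_size_for_inputs",
    "cd1_update",
    "pretrain",
    "finetune",
    "predict",
    "loss_and_gradients",
    "train_dbn",
    "save_model",
    "load_model",
]


class DivergenceError(RuntimeError):
    """Raised when training produces non-finite parameters or losses."""


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class RBMLayer:
    """One restricted Boltzmann machine: visible x hidden weight matrix.

    ``visible_type`` is "gaussian" (real-valued standardized inputs, linear
    visible reconstruction) or "bernoulli" (probabilities in [0, 1],
    sigmoid visible reconstruction).
    """

    weights: np.ndarray  # (n_visible, n_hidden)
    visible_bias: np.ndarray  # (n_visible,)
    hidden_bias: np.ndarray  # (n_hidden,)
    visible_type: str = "gaussian"
    # momentum velocities (training state, not part of the learned model)
    v_weights: np.ndarray | None = None
    v_visible_bias: np.ndarray | None = None
    v_hidden_bias: np.ndarray | None = None

    def __post_init__(self):
        if self.visible_type not in ("gaussian", "bernoulli"):
            raise ValueError("visible_type must be 'gaussian' or 'bernoulli'")
        if self.v_weights is None:
            self.v_weights = np.zeros_like(self.weights)
            self.v_visible_bias = np.zeros_like(self.visible_bias)
            self.v_hidden_bias = np.zeros_like(self.hidden_bias)

    @classmethod
    def initialize(cls, n_visible: int, n_hidden: int, rng: np.random.Generator,
                   visible_type: str = "gaussian", scale: float = 0.01) -> "RBMLayer":
        return cls(
            weights=scale * rng.standard_normal((n_visible, n_hidden)),
            visible_bias=np.zeros(n_visible),
            hidden_bias=np.zeros(n_hidden),
            visible_type=visible_type,
        )

    def hidden_probabilities(self, v: np.ndarray) -> np.ndarray:
        return _sigmoid(v @ self.weights + self.hidden_bias)


def cd1_update(
    layer: RBMLayer,
    batch: np.ndarray,
    rng: np.random.Generator,
    lr: float = 0.05,
    momentum: float = 0.9,
) -> tuple[RBMLayer, float]:
    """One contrastive-divergence-1 step on a mini-batch (in place).

    Positive phase uses hidden probabilities; the negative phase
    reconstructs the visibles from a sampled hidden state (linear mean for
    Gaussian visibles, sigmoid for Bernoulli) and re-infers hidden
    probabilities. The weight update is proportional to the difference of
    the data and reconstruction correlations. Returns the layer and the
    mean squared reconstruction error.
    """
    v0 = np.atleast_2d(np.asarray(batch, dtype=float))
    if not np.isfinite(v0).all():
        raise DivergenceError("non-finite visible batch")
    b = v0.shape[0]
    # overflow here is the divergence signal, detected below — keep it silent
    with np.errstate(over="ignore", invalid="ignore"):
        h0 = layer.hidden_probabilities(v0)
        h_sample = (rng.random(h0.shape) < h0).astype(float)
        v1 = h_sample @ layer.weights.T + layer.visible_bias
        if layer.visible_type == "bernoulli":
            v1 = _sigmoid(v1)
        h1 = layer.hidden_probabilities(v1)

        d_w = (v0.T @ h0 - v1.T @ h1) / b
        d_vb = (v0 - v1).mean(axis=0)
        d_hb = (h0 - h1).mean(axis=0)

        layer.v_weights = momentum * layer.v_weights + lr * d_w
        layer.v_visible_bias = momentum * layer.v_visible_bias + lr * d_vb
        layer.v_hidden_bias = momentum * layer.v_hidden_bias + lr * d_hb
        layer.weights += layer.v_weights
        layer.visible_bias += layer.v_visible_bias
        layer.hidden_bias += layer.v_hidden_bias
        if not np.isfinite(layer.weights).all():
            raise DivergenceError("CD-1 update diverged (learning rate too high?)")
        err = float(np.mean((v0 - v1) ** 2))
    return layer, err


@dataclass
class DBNConfig:
    """Training hyperparameters with library defaults.

    These are implementation choices, exposed so experiments can tune them:
    CD-1 pre-training (epochs/lr), then mini-batch gradient descent with
    momentum and validation-based early stopping for fine-tuning.
    """

    pretrain_epochs: int = 10
    pretrain_lr: float = 0.05
    finetune_epochs: int = 200
    finetune_lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 64
    patience: int = 20
    sample_hidden_between_rbms: bool = False


def hidden_size_for_inputs(n_inputs: int) -> int:
    """Hidden-layer width: 80 units for 1-D input, 100 for multi-grid input."""
    return 80 if n_inputs == 1 else 100


@dataclass
class DBNModel:
    """Stacked-RBM regressor: parameters, standardization, training state."""

    layer_sizes: tuple[int, int, int, int]
    rbm_stack: list[RBMLayer]
    output_weights: np.ndarray  # (n_hidden2,)
    output_bias: float
    input_mean: np.ndarray | None = None
    input_std: np.ndarray | None = None
    seed: int = 0
    pretrained: bool = False
    finetuned: bool = False
    training_log: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.layer_sizes) != 4 or self.layer_sizes[3] != 1:
            raise ValueError("layer_sizes must be (n_in, n_h1, n_h2, 1)")

    @classmethod
    def initialize(cls, layer_sizes, seed: int = 0) -> "DBNModel":
        layer_sizes = tuple(int(s) for s in layer_sizes)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xD8]))
        rbm1 = RBMLayer.initialize(layer_sizes[0], layer_sizes[1], rng, "gaussian")
        rbm2 = RBMLayer.initialize(layer_sizes[1], layer_sizes[2], rng, "bernoulli")
        return cls(
            layer_sizes=layer_sizes,
            rbm_stack=[rbm1, rbm2],
            output_weights=0.01 * rng.standard_normal(layer_sizes[2]),
            output_bias=0.0,
            seed=seed,
        )

    @classmethod
    def for_inputs(cls, n_inputs: int, seed: int = 0) -> "DBNModel":
        h = hidden_size_for_inputs(n_inputs)
        return cls.initialize((n_inputs, h, h, 1), seed=seed)

    # -- forward ----------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.input_mean is None:
            return X
        return (X - self.input_mean) / self.input_std

    def set_standardization(self, X: np.ndarray) -> None:
        """Fix standardization constants from training data.

        One shared mean and scale across all input features, not
        per-feature: the inputs arrive jointly min-max normalized so that
        a strongly activated muscle has a larger-amplitude component than
        a weakly activated one, and that amplitude relation is information
        the model (and the impact-value ranking built on it) must see.
        """
        X = np.atleast_2d(X)
        std = float(X.std())
        self.input_mean = np.array([X.mean()])
        self.input_std = np.array([std if std > 0 else 1.0])

    def forward(self, X: np.ndarray):
        """Deterministic forward pass; returns (x_std, h1, h2, output)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.layer_sizes[0]:
            raise ValueError(
                f"expected {self.layer_sizes[0]} input features, got {X.shape[1]}"
            )
        xs = self._standardize(X)
        h1 = _sigmoid(xs @ self.rbm_stack[0].weights + self.rbm_stack[0].hidden_bias)
        h2 = _sigmoid(h1 @ self.rbm_stack[1].weights + self.rbm_stack[1].hidden_bias)
        out = h2 @ self.output_weights + self.output_bias
        return xs, h1, h2, out

    # -- parameter snapshots ----------------------------------------------

    def _params(self) -> dict[str, np.ndarray | float]:
        return {
            "W1": self.rbm_stack[0].weights,
            "b1": self.rbm_stack[0].hidden_bias,
            "W2": self.rbm_stack[1].weights,
            "b2": self.rbm_stack[1].hidden_bias,
            "w3": self.output_weights,
            "b3": self.output_bias,
        }

    def _snapshot(self) -> dict:
        return {k: (v.copy() if isinstance(v, np.ndarray) else v)
                for k, v in self._params().items()}

    def _restore(self, snap: dict) -> None:
        self.rbm_stack[0].weights = snap["W1"].copy()
        self.rbm_stack[0].hidden_bias = snap["b1"].copy()
        self.rbm_stack[1].weights = snap["W2"].copy()
        self.rbm_stack[1].hidden_bias = snap["b2"].copy()
        self.output_weights = snap["w3"].copy()
        self.output_bias = float(snap["b3"])


def predict(model: DBNModel, X: np.ndarray) -> np.ndarray:
    """Per-sample force estimates (deterministic, probabilities propagated).

    The output is not clipped; values slightly outside [0, 1] are part of
    the reported estimate.
    """
    return np.asarray(model.forward(X)[3]).ravel()


def loss_and_gradients(model: DBNModel, X: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and its analytic gradients.

    Returns (loss, grads) with grads keyed W1, b1, W2, b2, w3, b3 —
    matching ``DBNModel._params`` — for use by fine-tuning and by
    finite-difference verification.
    """
    y = np.asarray(y, dtype=float).ravel()
    xs, h1, h2, out = model.forward(X)
    b = y.size
    resid = out - y
    loss = float(np.mean(resid**2))
    g_out = 2.0 * resid / b
    g_w3 = h2.T @ g_out
    g_b3 = float(g_out.sum())
    g_h2 = np.outer(g_out, model.output_weights)
    g_z2 = g_h2 * h2 * (1.0 - h2)
    g_W2 = h1.T @ g_z2
    g_b2 = g_z2.sum(axis=0)
    g_h1 = g_z2 @ model.rbm_stack[1].weights.T
    g_z1 = g_h1 * h1 * (1.0 - h1)
    g_W1 = xs.T @ g_z1
    g_b1 = g_z1.sum(axis=0)
    grads = {"W1": g_W1, "b1": g_b1, "W2": g_W2, "b2": g_b2, "w3": g_w3, "b3": g_b3}
    return loss, grads


def pretrain(
    model: DBNModel,
    inputs: np.ndarray,
    config: DBNConfig = DBNConfig(),
    seed: int | None = None,
) -> DBNModel:
    """Greedy layer-wise CD-1 pre-training of the two RBMs (in place).

    RBM 1 (Gaussian visibles) trains on standardized inputs; RBM 2
    (Bernoulli visibles) trains on RBM 1's hidden probabilities (or sampled
    states if configured). With zero epochs the seeded random
    initialization is returned untouched.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError("feature count does not match the input layer size")
    if model.input_mean is None:
        model.set_standardization(X)
    if config.pretrain_epochs <= 0:
        return model
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed if seed is None else seed, 0xBE])
    )
    data = model._standardize(X)
    recon_log = []
    for layer in model.rbm_stack:
        for epoch in range(config.pretrain_epochs):
            perm = rng.permutation(data.shape[0])
            errs = []
            for start in range(0, data.shape[0], config.batch_size):
                batch = data[perm[start:start + config.batch_size]]
                try:
                    _, err = cd1_update(layer, batch, rng, config.pretrain_lr, config.momentum)
                except DivergenceError as exc:
                    raise DivergenceError(f"pre-training epoch {epoch}: {exc}") from exc
                errs.append(err)
            recon_log.append(float(np.mean(errs)))
        probs = layer.hidden_probabilities(data)
        if config.sample_hidden_between_rbms:
            probs = (rng.random(probs.shape) < probs).astype(float)
        data = probs
    model.training_log["pretrain_reconstruction_error"] = recon_log
    model.pretrained = True
    return model


def finetune(
    model: DBNModel,
    inputs: np.ndarray,
    targets: np.ndarray,
    val_inputs: np.ndarray,
    val_targets: np.ndarray,
    config: DBNConfig = DBNConfig(),
    seed: int | None = None,
) -> DBNModel:
    """Backpropagation fine-tuning with early stopping (in place).

    Mini-batch gradient descent with momentum on MSE; after each epoch the
    validation MSE is measured and the best-validation parameter snapshot
    is kept. Training stops when validation has not improved for
    ``config.patience`` epochs, and the best snapshot is restored.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    Xv = np.atleast_2d(np.asarray(val_inputs, dtype=float))
    yv = np.asarray(val_targets, dtype=float).ravel()
    if Xv.size == 0 or yv.size == 0:
        raise ValueError("validation set must be nonempty")
    if model.input_mean is None:
        model.set_standardization(X)
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed if seed is None else seed, 0xF7])
    )
    velocity = {k: np.zeros_like(v) if isinstance(v, np.ndarray) else 0.0
                for k, v in model._params().items()}
    best_val = float(np.mean((predict(model, Xv) - yv) ** 2))
    best_snap = model._snapshot()
    since_best = 0
    train_curve, val_curve = [], []
    for epoch in range(config.finetune_epochs):
        perm = rng.permutation(X.shape[0])
        epoch_losses = []
        for start in range(0, X.shape[0], config.batch_size):
            idx = perm[start:start + config.batch_size]
            loss, grads = loss_and_gradients(model, X[idx], y[idx])
            if not np.isfinite(loss):
                raise DivergenceError(f"fine-tuning diverged at epoch {epoch}")
            for k, g in grads.items():
                velocity[k] = config.momentum * velocity[k] - config.finetune_lr * g
            model.rbm_stack[0].weights += velocity["W1"]
            model.rbm_stack[0].hidden_bias += velocity["b1"]
            model.rbm_stack[1].weights += velocity["W2"]
            model.rbm_stack[1].hidden_bias += velocity["b2"]
            model.output_weights += velocity["w3"]
            model.output_bias += velocity["b3"]
            epoch_losses.append(loss)
        val_mse = float(np.mean((predict(model, Xv) - yv) ** 2))
        train_curve.append(float(np.mean(epoch_losses)))
        val_curve.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_snap = model._snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model._restore(best_snap)
    model.training_log["finetune_train_mse"] = train_curve
    model.training_log["finetune_val_mse"] = val_curve
    model.training_log["best_val_mse"] = best_val
    model.finetuned = True
    return model


def train_dbn(
    inputs: np.ndarray,
    targets: np.ndarray,
    val_inputs: np.ndarray,
    val_targets: np.ndarray,
    layer_sizes=None,
    config: DBNConfig = DBNConfig(),
    seed: int = 0,
) -> DBNModel:
    """Convenience wrapper: initialize, pre-train, fine-tune."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if layer_sizes is None:
        model = DBNModel.for_inputs(X.shape[1], seed=seed)
    else:
        model = DBNModel.initialize(layer_sizes, seed=seed)
    model.set_standardization(X)
    pretrain(model, X, config)
    finetune(model, X, targets, val_inputs, val_targets, config)
    return model


# ---------------------------------------------------------------------------
# Serialization (single portable HDF5 file)
# ---------------------------------------------------------------------------

def save_model(model: DBNModel, path) -> None:
    with h5py.File(Path(path), "w") as f:
        f.attrs["layer_sizes"] = model.layer_sizes
        f.attrs["seed"] = model.seed
        f.attrs["pretrained"] = model.pretrained
        f.attrs["finetuned"] = model.finetuned
        f.attrs["output_bias"] = model.output_bias
        for i, layer in enumerate(model.rbm_stack):
            g = f.create_group(f"rbm{i}")
            g.attrs["visible_type"] = layer.visible_type
            g.create_dataset("weights", data=layer.weights)
            g.create_dataset("visible_bias", data=layer.visible_bias)
            g.create_dataset("hidden_bias", data=layer.hidden_bias)
        f.create_dataset("output_weights", data=model.output_weights)
        if model.input_mean is not None:
            f.create_dataset("input_mean", data=model.input_mean)
            f.create_dataset("input_std", data=model.input_std)


def load_model(path) -> DBNModel:
    with h5py.File(Path(path), "r") as f:
        stack = []
        for i in range(2):
            g = f[f"rbm{i}"]
            stack.append(
                RBMLayer(
                    weights=g["weights"][...],
                    visible_bias=g["visible_bias"][...],
                    hidden_bias=g["hidden_bias"][...],
                    visible_type=g.attrs["visible_type"],
                )
            )
        model = DBNModel(
            layer_sizes=tuple(int(s) for s in f.attrs["layer_sizes"]),
            rbm_stack=stack,
            output_weights=f["output_weights"][...],
            output_bias=float(f.attrs["output_bias"]),
            input_mean=f["input_mean"][...] if "input_mean" in f else None,
            input_std=f["input_std"][...] if "input_std" in f else None,
            seed=int(f.attrs["seed"]),
            pretrained=bool(f.attrs["pretrained"]),
            finetuned=bool(f.attrs["finetuned"]),
        )
    return model
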