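"""Four-compartment convolutional predictor over profile-encoded proteins.

Architecture (length-agnostic):

* 1D convolution, 256 filters of width 19, stride 1, symmetric zero
  padding of (width-1)/2 so an L-row input yields an Lx256 feature map;
  ReLU activation.
* Global max pooling and global average pooling applied in parallel over
  the sequence axis, each yielding 256 values, concatenated into a
  512-vector.
* Fully connected layer of 256 hidden units (ReLU), then a 4-way softmax
  over the sub-mitochondrial compartments; the prediction is the argmax,
  ties broken toward the lowest class index.

Training uses categorical cross-entropy with inverse-frequency class
weights (the compartments are heavily imbalanced in real proteomes) and
the Adam optimizer.  The network is implemented directly on NumPy with
analytic gradients; sequences are processed at their native length, so
the "convolution output has length L" contract holds exactly without any
padding-and-masking machinery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from enum import IntEnum
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoding import EncodedProtein, N_CHANNELS


class CompartmentLabel(IntEnum):
    """The four sub-mitochondrial compartments, in fixed index order."""

    outer_membrane = 0
    inner_membrane = 1
    intermembrane_space = 2
    matrix = 3


N_CLASSES = len(CompartmentLabel)


@dataclass(frozen=True)
class ModelConfig:
    n_filters: int = 256
    kernel_width: int = 19
    n_hidden: int = 256
    n_classes: int = N_CLASSES
    conv_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel_width % 2 == 0:
            raise ValueError("kernel_width must be odd (symmetric padding)")
        if self.n_classes != N_CLASSES:
            raise ValueError(f"n_classes is fixed at {N_CLASSES}")
        if self.conv_activation != "relu":
            raise ValueError("only ReLU convolution activation is supported")
        if min(self.n_filters, self.n_hidden) < 1:
            raise ValueError("layer sizes must be positive")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 100
    learning_rate: float = 1e-3
    batch_size: int = 16
    class_weighting: bool = True
    loss: str = "categorical_crossentropy"
    optimizer: str = "adam"
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.loss != "categorical_crossentropy" or self.optimizer != "adam":
            raise ValueError("unsupported loss/optimizer")


@dataclass(frozen=True)
class PredictionResult:
    protein_id: str
    probabilities: np.ndarray  # (4,)
    label: CompartmentLabel

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.shape != (N_CLASSES,) or (p < 0).any():
            raise ValueError("probabilities must be 4 non-negative reals")
        if abs(p.sum() - 1.0) > 1e-4:
            raise ValueError(f"probabilities sum to {p.sum()}, not 1")
        object.__setattr__(self, "probabilities", p)


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max())
    return e / e.sum()


class Model:
    """The convolutional network: weights plus forward/backward passes."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        k, f, h, c = (
            config.kernel_width,
            config.n_filters,
            config.n_hidden,
            config.n_classes,
        )
        fan_conv = k * N_CHANNELS
        # He initialization for the ReLU layers
        self.W1 = rng.normal(0.0, np.sqrt(2.0 / fan_conv), (fan_conv, f))
        self.b1 = np.zeros(f)
        self.W2 = rng.normal(0.0, np.sqrt(2.0 / (2 * f)), (2 * f, h))
        self.b2 = np.zeros(h)
        self.W3 = rng.normal(0.0, np.sqrt(1.0 / h), (h, c))
        self.b3 = np.zeros(c)

    # -- parameter plumbing ------------------------------------------------

    _PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3", "b3")

    def parameters(self) -> list[np.ndarray]:
        return [getattr(self, n) for n in self._PARAM_NAMES]

    def set_parameters(self, values: Sequence[np.ndarray]) -> None:
        for name, val in zip(self._PARAM_NAMES, values):
            setattr(self, name, np.asarray(val, dtype=np.float64))

    # -- forward / backward ------------------------------------------------

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        k = self.config.kernel_width
        pad = (k - 1) // 2
        L = x.shape[0]
        xp = np.zeros((L + 2 * pad, N_CHANNELS))
        xp[pad : pad + L] = x
        windows = np.lib.stride_tricks.sliding_window_view(xp, (k, N_CHANNELS))
        return windows.reshape(L, k * N_CHANNELS)

    def _forward(self, x: np.ndarray) -> dict:
        cols = self._im2col(x)  # (L, k*30)
        z1 = cols @ self.W1 + self.b1  # (L, F)
        a1 = np.maximum(z1, 0.0)
        argmax = a1.argmax(axis=0)  # (F,)
        pmax = a1[argmax, np.arange(a1.shape[1])]
        pavg = a1.mean(axis=0)
        pooled = np.concatenate([pmax, pavg])  # (2F,)
        z2 = pooled @ self.W2 + self.b2
        a2 = np.maximum(z2, 0.0)
        z3 = a2 @ self.W3 + self.b3
        probs = _softmax(z3)
        return dict(
            cols=cols, z1=z1, a1=a1, argmax=argmax, pooled=pooled,
            z2=z2, a2=a2, probs=probs,
        )

    def conv_feature_map(self, x: EncodedProtein) -> np.ndarray:
        """The post-ReLU Lx(n_filters) feature map (for inspection/tests)."""
        return self._forward(np.asarray(x.matrix))["a1"]

    def pooled_vector(self, x: EncodedProtein) -> np.ndarray:
        """The concatenated max+average pooled vector of length 2*n_filters."""
        return self._forward(np.asarray(x.matrix))["pooled"]

    def predict_proba(self, x: EncodedProtein) -> np.ndarray:
        m = np.asarray(x.matrix)
        if m.ndim != 2 or m.shape[1] != N_CHANNELS:
            raise ValueError(f"input must have {N_CHANNELS} channels, got {m.shape}")
        return self._forward(m)["probs"]

    def _backward(self, cache: dict, y: int, weight: float) -> list[np.ndarray]:
        F = self.config.n_filters
        L = cache["cols"].shape[0]
        dz3 = cache["probs"].copy()
        dz3[y] -= 1.0
        dz3 *= weight
        dW3 = np.outer(cache["a2"], dz3)
        db3 = dz3
        da2 = self.W3 @ dz3
        dz2 = da2 * (cache["z2"] > 0)
        dW2 = np.outer(cache["pooled"], dz2)
        db2 = dz2
        dpool = self.W2 @ dz2  # (2F,)
        da1 = np.tile(dpool[F:] / L, (L, 1))
        da1[cache["argmax"], np.arange(F)] += dpool[:F]
        dz1 = da1 * (cache["z1"] > 0)
        dW1 = cache["cols"].T @ dz1
        db1 = dz1.sum(axis=0)
        return [dW1, db1, dW2, db2, dW3, db3]

    def loss_and_gradients(
        self, batch: Sequence[tuple[np.ndarray, int]], class_weights: np.ndarray
    ) -> tuple[float, list[np.ndarray]]:
        grads = [np.zeros_like(p) for p in self.parameters()]
        total_loss = 0.0
        for x, y in batch:
            cache = self._forward(x)
            w = class_weights[y]
            total_loss += -w * np.log(max(cache["probs"][y], 1e-300))
            for g, gi in zip(grads, self._backward(cache, y, w)):
                g += gi
        n = len(batch)
        return total_loss / n, [g / n for g in grads]


def build_model(config: ModelConfig | None = None) -> Model:
    """Construct the network with seeded random initial weights."""
    return Model(config or ModelConfig())


def predict(model: Model, x: EncodedProtein) -> PredictionResult:
    """Compartment probabilities and argmax label for one encoded protein."""
    probs = model.predict_proba(x)
    return PredictionResult(
        protein_id=x.protein_id,
        probabilities=probs,
        label=CompartmentLabel(int(np.argmax(probs))),
    )


def predict_many(model: Model, xs: Sequence[EncodedProtein]) -> list[PredictionResult]:
    return [predict(model, x) for x in xs]


def _class_weights(labels: Sequence[int], enabled: bool) -> np.ndarray:
    counts = np.bincount(labels, minlength=N_CLASSES).astype(float)
    if not enabled:
        return np.ones(N_CLASSES)
    present = counts > 0
    w = np.zeros(N_CLASSES)
    # inverse frequency, normalized to mean 1 over present classes
    w[present] = counts[present].sum() / (present.sum() * counts[present])
    return w


def train(
    model: Model,
    data: Sequence[tuple[EncodedProtein, CompartmentLabel]],
    cfg: TrainConfig | None = None,
    validation: Sequence[tuple[EncodedProtein, CompartmentLabel]] | None = None,
) -> tuple[Model, list[float]]:
    """Fit the model by minibatch Adam; returns the model and per-epoch loss.

    With a fixed seed the loss trace is reproducible run-to-run on the
    same platform.  If validation data is supplied, training stops early
    once validation loss has not improved for ``early_stopping_patience``
    epochs and the best-validation weights are restored.
    """
    cfg = cfg or TrainConfig()
    if len(data) == 0:
        raise ValueError("empty training data")
    ys = [int(label) for _, label in data]
    if len(set(ys)) < 2:
        raise ValueError("training data must contain at least 2 classes")
    xs = [np.asarray(e.matrix) for e, _ in data]
    weights = _class_weights(ys, cfg.class_weighting)

    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    m_t = [np.zeros_like(p) for p in params]
    v_t = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def eval_loss(pairs) -> float:
        total = 0.0
        for e, label in pairs:
            p = model.predict_proba(e)
            total += -np.log(max(p[int(label)], 1e-300))
        return total / len(pairs)

    history: list[float] = []
    best_val = np.inf
    best_params: list[np.ndarray] | None = None
    stale = 0
    n = len(data)
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [(xs[i], ys[i]) for i in idx]
            loss, grads = model.loss_and_gradients(batch, weights)
            epoch_loss += loss * len(batch)
            step += 1
            for j, (p, g) in enumerate(zip(params, grads)):
                m_t[j] = beta1 * m_t[j] + (1 - beta1) * g
                v_t[j] = beta2 * v_t[j] + (1 - beta2) * g * g
                mhat = m_t[j] / (1 - beta1**step)
                vhat = v_t[j] / (1 - beta2**step)
                p -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        history.append(epoch_loss / n)
        if validation is not None:
            val = eval_loss(validation)
            if val < best_val - 1e-6:
                best_val = val
                best_params = [p.copy() for p in params]
                stale = 0
            else:
                stale += 1
                if stale >= cfg.early_stopping_patience:
                    break
    if best_params is not None:
        model.set_parameters(best_params)
    return model, history


def save_checkpoint(path: str | Path, model: Model) -> None:
    """Self-describing checkpoint: config JSON + weights + channel metadata."""
    from .encoding import CHANNEL_LAYOUT

    arrays = dict(zip(Model._PARAM_NAMES, model.parameters()))
    arrays["config_json"] = np.array(json.dumps(asdict(model.config)))
    arrays["channel_layout"] = np.array(CHANNEL_LAYOUT)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> Model:
    from .encoding import CHANNEL_LAYOUT

    with np.load(path, allow_pickle=False) as bundle:
        layout = str(bundle["channel_layout"])
        if layout != CHANNEL_LAYOUT:
            raise ValueError(f"checkpoint encoded with incompatible layout {layout!r}")
        config = ModelConfig(**json.loads(str(bundle["config_json"])))
        model = Model(config)
        model.set_parameters([bundle[n] for n in Model._PARAM_NAMES])
    return model
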