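"""Multilayer-perceptron classifiers trained with Adam.

Two models share this machinery: a binary malignant/benign classifier and
a pan-cancer multi-class model (cancer types plus normal).  Both are
fully-connected ReLU networks with a softmax head trained on
cross-entropy.  Unselected CpG loci are zeroed at the input (equivalent
to zero first-layer weights for those probes), so model output is a
function of the selected features only.

Adam keeps exponential moving averages of the gradient (first moment) and
squared gradient (second moment) with decay rates ``beta1=0.9`` and
``beta2=0.999``, applies the standard bias correction and an ``epsilon``
guard against division by zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .olga import FeatureMask

__all__ = [
    "AdamState",
    "MlpSpec",
    "FittedModel",
    "adam_step",
    "mask_input",
    "train_model",
    "grid_search",
    "predict",
    "halving_widths",
]


@dataclass
class AdamState:
    """Optimizer state for one list of parameter arrays."""

    m: list[np.ndarray]
    v: list[np.ndarray]
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    step_count: int = 0
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta1 < 1.0 and 0.0 <= self.beta2 < 1.0):
            raise ValueError("beta1 and beta2 must lie in [0, 1)")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")

    @classmethod
    def zeros_like(cls, params: Sequence[np.ndarray], learning_rate: float = 0.001,
                   **kwargs) -> "AdamState":
        return cls(m=[np.zeros_like(p) for p in params],
                   v=[np.zeros_like(p) for p in params],
                   learning_rate=learning_rate, **kwargs)


def adam_step(state: AdamState, params: Sequence[np.ndarray],
              grads: Sequence[np.ndarray]) -> tuple[AdamState, list[np.ndarray]]:
    """One Adam update.  Returns the new state and updated parameters.

    Moments: ``m_t = b1*m + (1-b1)*g``, ``v_t = b2*v + (1-b2)*g^2``; the
    parameter step uses the bias-corrected ``m_hat = m_t/(1-b1^t)`` and
    ``v_hat = v_t/(1-b2^t)``:
    ``theta' = theta - lr * m_hat / (sqrt(v_hat) + eps)``.
    """
    if len(params) != len(grads) or any(p.shape != g.shape
                                        for p, g in zip(params, grads)):
        raise ValueError("parameter/gradient shape mismatch")
    t = state.step_count + 1
    b1, b2 = state.beta1, state.beta2
    new_m, new_v, new_params = [], [], []
    for p, g, m, v in zip(params, grads, state.m, state.v):
        m_t = b1 * m + (1.0 - b1) * g
        v_t = b2 * v + (1.0 - b2) * g * g
        m_hat = m_t / (1.0 - b1**t)
        v_hat = v_t / (1.0 - b2**t)
        new_params.append(p - state.learning_rate * m_hat /
                          (np.sqrt(v_hat) + state.epsilon))
        new_m.append(m_t)
        new_v.append(v_t)
    new_state = replace(state, m=new_m, v=new_v, step_count=t)
    return new_state, new_params


@dataclass(frozen=True)
class MlpSpec:
    """Architecture and optimisation hyperparameters of one model."""

    input_width: int
    hidden_layers: tuple[int, ...]
    classes: tuple[str, ...]
    learning_rate: float = 0.001

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden widths must be positive")
        if len(self.classes) < 2:
            raise ValueError("need at least 2 output classes")

    @property
    def n_parameters(self) -> int:
        widths = [self.input_width, *self.hidden_layers, len(self.classes)]
        return sum(a * b + b for a, b in zip(widths[:-1], widths[1:]))


def halving_widths(base: int, n_layers: int) -> tuple[int, ...]:
    """Hidden widths for an L-layer stack: base, base/2, base/4, ...

    e.g. ``halving_widths(256, 2) == (256, 128)``.
    """
    return tuple(max(1, base // 2**i) for i in range(n_layers))


def mask_input(x: np.ndarray, mask: FeatureMask | np.ndarray) -> np.ndarray:
    """Zero the unselected loci of a sample vector (or matrix of rows)."""
    bits = mask.bits if isinstance(mask, FeatureMask) else np.asarray(mask, bool)
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != bits.size:
        raise ValueError("input width does not match mask length")
    return np.where(bits, x, 0.0)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class FittedModel:
    """A trained MLP: spec, parameters, optional input mask, loss curve."""

    spec: MlpSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    feature_mask: np.ndarray | None = None
    train_loss: list[float] = field(default_factory=list)

    def _forward(self, X: np.ndarray) -> np.ndarray:
        a = X if self.feature_mask is None else mask_input(X, self.feature_mask)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)
        return a @ self.weights[-1] + self.biases[-1]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.spec.input_width:
            raise ValueError("sample width does not match model input width")
        return _softmax(self._forward(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.predict_proba(X)
        # classes are stored sorted, so argmax's first-index tie-break is
        # the lexicographically first class
        return np.array([self.spec.classes[i] for i in scores.argmax(axis=1)])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {"input_width": self.spec.input_width,
                "hidden_layers": list(self.spec.hidden_layers),
                "classes": list(self.spec.classes),
                "learning_rate": self.spec.learning_rate,
                "n_layers": len(self.weights)}
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        if self.feature_mask is not None:
            arrays["mask"] = self.feature_mask
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        data = np.load(path.with_suffix(".npz"))
        spec = MlpSpec(meta["input_width"], tuple(meta["hidden_layers"]),
                       tuple(meta["classes"]), meta["learning_rate"])
        n = meta["n_layers"]
        return cls(spec, [data[f"W{i}"] for i in range(n)],
                   [data[f"b{i}"] for i in range(n)],
                   feature_mask=data["mask"] if "mask" in data else None)


def _encode_labels(y: Sequence[str], classes: tuple[str, ...]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[label] for label in y])
    except KeyError as exc:
        raise ValueError(f"label {exc.args[0]!r} not in model classes") from None


def train_model(X: np.ndarray, y: Sequence[str], spec: MlpSpec,
                epochs: int = 100, batch_size: int = 32, seed: int = 0,
                feature_mask: FeatureMask | np.ndarray | None = None,
                validation: tuple[np.ndarray, Sequence[str]] | None = None,
                patience: int = 10) -> FittedModel:
    """Train an MLP with mini-batch Adam and cross-entropy loss.

    Deterministic for a fixed seed.  If ``validation`` is given, training
    stops early once validation loss has not improved for ``patience``
    epochs and the best parameters are restored.  Every class must have at
    least 2 training samples.
    """
    X = np.asarray(X, dtype=float)
    y_idx = _encode_labels(y, spec.classes)
    counts = np.bincount(y_idx, minlength=len(spec.classes))
    present = np.flatnonzero(counts)
    if (counts[present] < 2).any():
        thin = spec.classes[int(present[counts[present] < 2][0])]
        raise ValueError(f"class {thin!r} has fewer than 2 training samples")

    if feature_mask is not None:
        bits = (feature_mask.bits if isinstance(feature_mask, FeatureMask)
                else np.asarray(feature_mask, bool))
    else:
        bits = None

    rng = np.random.default_rng(seed)
    widths = [spec.input_width, *spec.hidden_layers, len(spec.classes)]
    weights = [rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b))
               for a, b in zip(widths[:-1], widths[1:])]
    biases = [np.zeros(b) for b in widths[1:]]
    params = weights + biases
    state = AdamState.zeros_like(params, learning_rate=spec.learning_rate)

    n = X.shape[0]
    X_in = X if bits is None else mask_input(X, bits)
    n_layers = len(weights)
    onehot = np.eye(len(spec.classes))[y_idx]

    def forward_backward(xb, yb):
        acts = [xb]
        a = xb
        for i in range(n_layers - 1):
            a = np.maximum(a @ params[i] + params[n_layers + i], 0.0)
            acts.append(a)
        logits = a @ params[n_layers - 1] + params[2 * n_layers - 1]
        probs = _softmax(logits)
        m = xb.shape[0]
        loss = -np.log(np.clip(probs[np.arange(m), yb.argmax(axis=1)],
                               1e-12, None)).mean()
        grads_w = [None] * n_layers
        grads_b = [None] * n_layers
        delta = (probs - yb) / m
        for i in range(n_layers - 1, -1, -1):
            grads_w[i] = acts[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ params[i].T) * (acts[i] > 0)
        return loss, grads_w + grads_b

    loss_curve: list[float] = []
    best_val, best_params, stale = np.inf, None, 0
    val_prepared = None
    if validation is not None:
        Xv = np.asarray(validation[0], dtype=float)
        Xv = Xv if bits is None else mask_input(Xv, bits)
        yv = np.eye(len(spec.classes))[_encode_labels(validation[1], spec.classes)]
        val_prepared = (Xv, yv)

    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            batch = order[start:start + batch_size]
            loss, grads = forward_backward(X_in[batch], onehot[batch])
            epoch_loss += loss * batch.size
            state, params = adam_step(state, params, grads)
        loss_curve.append(epoch_loss / n)
        if val_prepared is not None:
            Xv, yv = val_prepared
            vloss, _ = forward_backward(Xv, yv)
            if vloss < best_val - 1e-9:
                best_val, stale = vloss, 0
                best_params = [p.copy() for p in params]
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_params is not None:
        params = best_params
    return FittedModel(spec, params[:n_layers], params[n_layers:],
                       feature_mask=bits, train_loss=loss_curve)


def predict(model: FittedModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class scores (rows sum to 1) and arg-max labels."""
    scores = model.predict_proba(X)
    labels = model.predict(X)
    return scores, labels


def predictions_frame(model: FittedModel, X: np.ndarray,
                      sample_ids: Sequence[str]):
    """Prediction table: sample id, predicted class, one score column per
    class (the CSV written by the evaluate stage)."""
    import pandas as pd

    scores, labels = predict(model, X)
    frame = pd.DataFrame(scores, columns=[f"score_{c}" for c in
                                          model.spec.classes])
    frame.insert(0, "predicted_class", labels)
    frame.insert(0, "sample_id", list(sample_ids))
    return frame


def grid_search(X_train: np.ndarray, y_train: Sequence[str],
                X_eval: np.ndarray, y_eval: Sequence[str],
                classes: tuple[str, ...],
                learning_rates: Sequence[float] = (0.1, 0.01, 0.001),
                layer_sizes: Sequence[int] = (512, 256, 128, 64),
                layer_counts: Sequence[int] = (1, 2, 4),
                epochs: int = 50, batch_size: int = 32, seed: int = 0,
                feature_mask: FeatureMask | np.ndarray | None = None,
                ) -> tuple[MlpSpec, list[tuple[MlpSpec, float]]]:
    """Exhaustive hyperparameter search over the Cartesian grid.

    Multi-layer stacks halve the width per layer starting from each base
    size.  Returns the spec with the highest evaluation accuracy (ties
    broken toward fewer parameters, then lower learning rate) plus the
    full scored grid.
    """
    if not (len(learning_rates) and len(layer_sizes) and len(layer_counts)):
        raise ValueError("empty hyperparameter grid")
    X_eval = np.asarray(X_eval, dtype=float)
    y_eval = np.asarray(list(y_eval))
    results: list[tuple[MlpSpec, float]] = []
    for lr in learning_rates:
        for base in layer_sizes:
            for n_layers in layer_counts:
                spec = MlpSpec(X_train.shape[1], halving_widths(base, n_layers),
                               classes, learning_rate=lr)
                model = train_model(X_train, y_train, spec, epochs=epochs,
                                    batch_size=batch_size, seed=seed,
                                    feature_mask=feature_mask)
                acc = float((model.predict(X_eval) == y_eval).mean())
                results.append((spec, acc))
    best_spec, _ = min(
        results,
        key=lambda item: (-item[1], item[0].n_parameters, item[0].learning_rate))
    return best_spec, results
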