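"""Stacked denoising autoencoder with tied weights.

Each layer maps x -> y = f(Wx + b) and reconstructs z = g(W^T y + b') with
the decoder weight constrained to the transpose of the encoder weight
(tied weights); f and g are logistic sigmoids.  Layers are pretrained
greedily bottom-up on masked (denoising) input by minimizing mean squared
reconstruction error with Adam.  A supervised fine-tuning phase attaches a
single sigmoid output unit to the concatenated top layers of the protein
and RNA sub-networks and backpropagates binary cross-entropy through all
encoder layers with SGD + momentum.

The top hidden layer before fine-tuning gives the SDA feature set; after
fine-tuning it gives the SDA-FT feature set.  Fine-tuning always operates
on copies, so both feature sets remain extractable from one training run.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "AutoencoderLayer",
    "StackedDenoisingAutoencoder",
    "FineTuneHead",
    "pretrain_sda",
    "fine_tune",
    "extract_pair_features",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class AutoencoderLayer:
    """One tied-weight denoising autoencoder layer.

    ``W`` has shape (out_dim, in_dim); the decoder uses ``W.T`` by
    construction, so the tied-weights constraint cannot be violated.
    """

    W: np.ndarray
    b: np.ndarray        # encoder bias, shape (out_dim,)
    b_prime: np.ndarray  # decoder bias, shape (in_dim,)

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    @property
    def out_dim(self) -> int:
        return self.W.shape[0]

    def encode(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(X @ self.W.T + self.b)

    def decode(self, Y: np.ndarray) -> np.ndarray:
        return _sigmoid(Y @ self.W + self.b_prime)

    def reconstruction_mse(self, X: np.ndarray) -> float:
        Z = self.decode(self.encode(X))
        return float(np.mean(np.sum((Z - X) ** 2, axis=1)))


def _init_layer(in_dim: int, out_dim: int, rng: np.random.Generator) -> AutoencoderLayer:
    # Glorot-uniform range; biases start at zero
    limit = np.sqrt(6.0 / (in_dim + out_dim))
    W = rng.uniform(-limit, limit, size=(out_dim, in_dim))
    return AutoencoderLayer(W=W, b=np.zeros(out_dim), b_prime=np.zeros(in_dim))


class _Adam:
    """Minimal Adam optimizer over a list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            m_hat = m / (1 - self.beta1 ** self.t)
            v_hat = v / (1 - self.beta2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _pretrain_layer(
    layer: AutoencoderLayer,
    X: np.ndarray,
    noise_prob: float,
    epochs: int,
    batch_size: int,
    lr: float,
    rng: np.random.Generator,
) -> list[float]:
    """Train one layer on (masked X -> X) reconstruction; returns epoch losses."""
    n = X.shape[0]
    opt = _Adam([layer.W, layer.b, layer.b_prime], lr=lr)
    losses = []
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            Xb = X[idx]
            B = Xb.shape[0]
            if noise_prob > 0:
                mask = rng.random(Xb.shape) >= noise_prob
                Xt = Xb * mask
            else:
                Xt = Xb
            Y = layer.encode(Xt)
            Z = layer.decode(Y)
            diff = Z - Xb
            epoch_loss += float(np.sum(diff ** 2))
            # backprop through tied weights: W gets encoder + decoder grads
            d2 = (2.0 / B) * diff * Z * (1.0 - Z)          # (B, in)
            g_bprime = d2.sum(axis=0)
            gW_dec = Y.T @ d2                               # (out, in)
            d1 = (d2 @ layer.W.T) * Y * (1.0 - Y)           # (B, out)
            g_b = d1.sum(axis=0)
            gW_enc = d1.T @ Xt
            opt.step([gW_enc + gW_dec, g_b, g_bprime])
        losses.append(epoch_loss / n)
    return losses


class StackedDenoisingAutoencoder(BaseEstimator, TransformerMixin):
    """Greedy layer-wise pretrained stack of tied-weight denoising autoencoders.

    Parameters
    ----------
    architecture : sequence of int, default (256, 128, 64)
        Hidden-layer widths, bottom to top.  ``transform`` returns the top
        layer's activations.
    noise_prob : float, default 0.5
        Masking-noise probability applied to each layer's input during
        pretraining only; inference is noise-free.
    epochs, batch_size : int, default 100
        Pretraining schedule, applied per layer.
    learning_rate : float, default 1e-3
        Adam step size.
    random_state : int or None
        Seeds weight init, noise masks and batch shuffling.

    Attributes
    ----------
    layers_ : list of AutoencoderLayer
    loss_history_ : list of list of float
        Per-layer mean reconstruction MSE per epoch.
    """

    def __init__(
        self,
        architecture: Sequence[int] = (256, 128, 64),
        noise_prob: float = 0.5,
        epochs: int = 100,
        batch_size: int = 100,
        learning_rate: float = 1e-3,
        random_state: int | None = None,
    ):
        self.architecture = architecture
        self.noise_prob = noise_prob
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X: np.ndarray, y=None) -> "StackedDenoisingAutoencoder":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] == 0:
            raise ValueError("pretraining requires a non-empty 2D matrix")
        arch = list(self.architecture)
        if not arch or any(int(h) <= 0 for h in arch):
            raise ValueError("architecture entries must be positive")
        if not 0.0 <= self.noise_prob < 1.0:
            raise ValueError("noise_prob must be in [0, 1)")
        rng = np.random.default_rng(self.random_state)
        self.n_features_in_ = X.shape[1]
        self.layers_ = []
        self.loss_history_ = []
        rep = X
        in_dim = X.shape[1]
        for width in arch:
            layer = _init_layer(in_dim, int(width), rng)
            losses = _pretrain_layer(
                layer, rep, self.noise_prob, self.epochs,
                self.batch_size, self.learning_rate, rng,
            )
            self.layers_.append(layer)
            self.loss_history_.append(losses)
            rep = layer.encode(rep)  # clean representation feeds the next layer
            in_dim = layer.out_dim
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "layers_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        rep = X
        for layer in self.layers_:
            rep = layer.encode(rep)
        return rep

    @property
    def output_dim_(self) -> int:
        check_is_fitted(self, "layers_")
        return self.layers_[-1].out_dim

    # -- serialization ----------------------------------------------------
    def to_arrays(self) -> dict[str, np.ndarray]:
        check_is_fitted(self, "layers_")
        out = {}
        for i, layer in enumerate(self.layers_):
            out[f"W{i}"] = layer.W
            out[f"b{i}"] = layer.b
            out[f"bp{i}"] = layer.b_prime
        return out

    def load_arrays(self, arrays: dict[str, np.ndarray]) -> "StackedDenoisingAutoencoder":
        self.layers_ = []
        i = 0
        while f"W{i}" in arrays:
            self.layers_.append(
                AutoencoderLayer(W=arrays[f"W{i}"], b=arrays[f"b{i}"],
                                 b_prime=arrays[f"bp{i}"])
            )
            i += 1
        if not self.layers_:
            raise ValueError("no layers found in arrays")
        self.n_features_in_ = self.layers_[0].in_dim
        self.loss_history_ = []
        return self


@dataclass
class FineTuneHead:
    """Sigmoid output unit over the concatenated sub-network top layers."""

    w: np.ndarray
    bias: float
    velocity: dict = field(default_factory=dict, repr=False)

    def predict_proba(self, H: np.ndarray) -> np.ndarray:
        return _sigmoid(H @ self.w + self.bias)


def pretrain_sda(
    X: np.ndarray,
    architecture: Sequence[int] = (256, 128, 64),
    noise_prob: float = 0.5,
    epochs: int = 100,
    batch_size: int = 100,
    learning_rate: float = 1e-3,
    seed: int | None = None,
) -> StackedDenoisingAutoencoder:
    """Functional wrapper: greedy layer-wise pretraining of one sub-network."""
    return StackedDenoisingAutoencoder(
        architecture=architecture, noise_prob=noise_prob, epochs=epochs,
        batch_size=batch_size, learning_rate=learning_rate, random_state=seed,
    ).fit(X)


def _forward_stack(layers: list[AutoencoderLayer], X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input first: [X, h1, ..., h_top]."""
    acts = [X]
    for layer in layers:
        acts.append(layer.encode(acts[-1]))
    return acts


def fine_tune(
    protein_model: StackedDenoisingAutoencoder,
    rna_model: StackedDenoisingAutoencoder,
    Xp: np.ndarray,
    Xr: np.ndarray,
    labels: np.ndarray,
    epochs: int = 100,
    batch_size: int = 100,
    learning_rate: float = 0.01,
    momentum: float = 0.9,
    seed: int | None = None,
) -> tuple[StackedDenoisingAutoencoder, StackedDenoisingAutoencoder, FineTuneHead]:
    """Supervised fine-tuning of both sub-networks through a merged sigmoid head.

    A single sigmoid unit on the concatenation of the two top hidden layers
    is trained jointly with all encoder weights by minimizing binary
    cross-entropy with SGD (momentum 0.9).  The input models are deep-copied;
    the originals keep their pre-fine-tuning weights.

    Returns (fine-tuned protein model, fine-tuned RNA model, head).
    """
    Xp = np.asarray(Xp, dtype=float)
    Xr = np.asarray(Xr, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if not (Xp.shape[0] == Xr.shape[0] == y.shape[0]):
        raise ValueError("Xp, Xr and labels must be row-aligned")
    if len(np.unique(y)) < 2:
        raise ValueError("fine-tuning requires both classes")
    pm = copy.deepcopy(protein_model)
    rm = copy.deepcopy(rna_model)
    rng = np.random.default_rng(seed)
    hp = pm.output_dim_
    hr = rm.output_dim_
    limit = np.sqrt(6.0 / (hp + hr + 1))
    head = FineTuneHead(w=rng.uniform(-limit, limit, size=hp + hr), bias=0.0)

    params: list[np.ndarray] = []
    for model in (pm, rm):
        for layer in model.layers_:
            params.extend([layer.W, layer.b])
    params.append(head.w)
    bias_vel = 0.0
    vel = [np.zeros_like(p) for p in params]

    n = Xp.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            B = len(idx)
            acts_p = _forward_stack(pm.layers_, Xp[idx])
            acts_r = _forward_stack(rm.layers_, Xr[idx])
            H = np.hstack([acts_p[-1], acts_r[-1]])
            p = head.predict_proba(H)
            # BCE gradient wrt pre-sigmoid logit
            dlogit = (p - y[idx]) / B                        # (B,)
            g_head_w = H.T @ dlogit
            g_head_b = float(dlogit.sum())
            dH = np.outer(dlogit, head.w)                    # (B, hp+hr)
            grads: list[np.ndarray] = []
            for model, acts, dtop in (
                (pm, acts_p, dH[:, :hp]),
                (rm, acts_r, dH[:, hp:]),
            ):
                delta = dtop * acts[-1] * (1.0 - acts[-1])
                layer_grads: list[np.ndarray] = []
                for li in range(len(model.layers_) - 1, -1, -1):
                    layer = model.layers_[li]
                    gW = delta.T @ acts[li]
                    gb = delta.sum(axis=0)
                    layer_grads[:0] = [gW, gb]
                    if li > 0:
                        delta = (delta @ layer.W) * acts[li] * (1.0 - acts[li])
                grads.extend(layer_grads)
            grads.append(g_head_w)
            for pvec, g, v in zip(params, grads, vel):
                v *= momentum
                v -= learning_rate * g
                pvec += v
            bias_vel = momentum * bias_vel - learning_rate * g_head_b
            head.bias += bias_vel
    head.velocity = {}
    return pm, rm, head


def extract_pair_features(
    protein_model: StackedDenoisingAutoencoder,
    rna_model: StackedDenoisingAutoencoder,
    Xp: np.ndarray,
    Xr: np.ndarray,
) -> np.ndarray:
    """Concatenated top-layer activations of the two sub-networks, per pair."""
    Xp = np.asarray(Xp, dtype=float)
    Xr = np.asarray(Xr, dtype=float)
    if Xp.shape[0] != Xr.shape[0]:
        raise ValueError("Xp and Xr must be row-aligned")
    return np.hstack([protein_model.transform(Xp), rna_model.transform(Xr)])


# -- on-disk model format -------------------------------------------------

SDA_SCHEMA_VERSION = 1


def save_sda(model: StackedDenoisingAutoencoder, path: str | Path,
             head: FineTuneHead | None = None) -> None:
    """Serialize an SDA (and optionally a fine-tune head) to an .npz file.

    The schema stores per-layer W/b/b' arrays plus a JSON metadata blob;
    loading is bit-exact.
    """
    meta = {
        "schema_version": SDA_SCHEMA_VERSION,
        "architecture": [int(a) for a in model.architecture],
        "noise_prob": model.noise_prob,
        "epochs": model.epochs,
        "batch_size": model.batch_size,
        "learning_rate": model.learning_rate,
        "random_state": model.random_state,
        "has_head": head is not None,
    }
    arrays = model.to_arrays()
    if head is not None:
        arrays["head_w"] = head.w
        arrays["head_bias"] = np.asarray([head.bias])
    arrays["_meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_sda(path: str | Path) -> tuple[StackedDenoisingAutoencoder, FineTuneHead | None]:
    with np.load(str(path)) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta["schema_version"] != SDA_SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {meta['schema_version']}")
        model = StackedDenoisingAutoencoder(
            architecture=meta["architecture"],
            noise_prob=meta["noise_prob"],
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            learning_rate=meta["learning_rate"],
            random_state=meta["random_state"],
        )
        model.load_arrays({k: data[k] for k in data.files if k != "_meta"})
        head = None
        if meta["has_head"]:
            head = FineTuneHead(w=data["head_w"], bias=float(data["head_bias"][0]))
    return model, head
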