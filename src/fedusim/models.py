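"""Desk-scale differentiable classifiers with exact per-sample gradients.

Two families are provided behind a uniform flat-parameter-vector contract:
multinomial logistic regression and a one-hidden-layer tanh network. Gradients
are closed form (no autodiff, no numeric differentiation), which is what makes
per-sample clipping in the privacy module cheap and exact. The seven large
ImageNet architectures of the emulated study appear only as parameter-count
metadata feeding the communication-cost model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .synthdata import ImageSample

FAMILIES = ("multinomial_logistic", "one_hidden_mlp")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "multinomial_logistic"
    input_dim: int = 64
    hidden_dim: int | None = None
    n_classes: int = 2
    init_scale: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigurationError(f"family: {self.family!r} not in {FAMILIES}")
        if self.input_dim < 1:
            raise ConfigurationError(f"input_dim: {self.input_dim} < 1")
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes: {self.n_classes} < 2")
        if self.family == "one_hidden_mlp" and (self.hidden_dim or 0) < 1:
            raise ConfigurationError("hidden_dim: required for one_hidden_mlp")

    @property
    def n_params(self) -> int:
        d, c = self.input_dim, self.n_classes
        if self.family == "multinomial_logistic":
            return d * c + c
        h = self.hidden_dim
        return d * h + h + h * c + c


@dataclass(frozen=True)
class ArchitectureMeta:
    """Name and parameter count (millions) of one large reference architecture."""

    name: str
    params_millions: float

    def __post_init__(self):
        if self.params_millions <= 0:
            raise ConfigurationError(f"params_millions: {self.params_millions} <= 0")


# ---------------------------------------------------------------------------
# Parameter vector handling
# ---------------------------------------------------------------------------

def init_model(spec: ModelSpec) -> np.ndarray:
    """Deterministic initial flat parameter vector.

    Logistic models start at zero (convex objective, canonical start); the MLP
    uses symmetric uniform draws scaled by ``init_scale``.
    """
    if spec.family == "multinomial_logistic":
        return np.zeros(spec.n_params)
    rng = np.random.default_rng(spec.seed)
    return rng.uniform(-spec.init_scale, spec.init_scale, size=spec.n_params)


def _unpack(spec: ModelSpec, w: np.ndarray):
    d, c = spec.input_dim, spec.n_classes
    if w.shape != (spec.n_params,):
        raise ConfigurationError(
            f"parameter vector: length {w.shape} != {spec.n_params}")
    if spec.family == "multinomial_logistic":
        W = w[:d * c].reshape(d, c)
        b = w[d * c:]
        return W, b
    h = spec.hidden_dim
    i = 0
    W1 = w[i:i + d * h].reshape(d, h); i += d * h
    b1 = w[i:i + h]; i += h
    W2 = w[i:i + h * c].reshape(h, c); i += h * c
    b2 = w[i:]
    return W1, b1, W2, b2


def _check_batch(spec: ModelSpec, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise ConfigurationError(
            f"batch: shape {X.shape} incompatible with input_dim {spec.input_dim}")
    return X


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict_logits(spec: ModelSpec, w: np.ndarray, X: np.ndarray) -> np.ndarray:
    X = _check_batch(spec, X)
    if spec.family == "multinomial_logistic":
        W, b = _unpack(spec, w)
        return X @ W + b
    W1, b1, W2, b2 = _unpack(spec, w)
    return np.tanh(X @ W1 + b1) @ W2 + b2


def predict_proba(spec: ModelSpec, w: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Per-class probability rows (softmax over class scores)."""
    return _softmax(predict_logits(spec, w, X))


def mean_loss(spec: ModelSpec, w: np.ndarray, X: np.ndarray,
              y: np.ndarray) -> float:
    p = predict_proba(spec, w, X)
    n = len(y)
    return float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))


def per_sample_gradients(spec: ModelSpec, w: np.ndarray, X: np.ndarray,
                         y: np.ndarray) -> tuple[np.ndarray, float]:
    """Closed-form cross-entropy gradients, one row per sample.

    Returns (G, mean_loss) with G of shape (n, n_params); the mean of the rows
    equals the full-batch gradient by linearity.
    """
    X = _check_batch(spec, X)
    y = np.asarray(y)
    if len(y) == 0:
        raise ConfigurationError("batch: empty")
    n = len(y)
    onehot = np.zeros((n, spec.n_classes))
    onehot[np.arange(n), y] = 1.0
    if spec.family == "multinomial_logistic":
        W, b = _unpack(spec, w)
        p = _softmax(X @ W + b)
        delta = p - onehot                                   # (n, c)
        gW = np.einsum("nd,nc->ndc", X, delta).reshape(n, -1)
        G = np.concatenate([gW, delta], axis=1)
    else:
        W1, b1, W2, b2 = _unpack(spec, w)
        H = np.tanh(X @ W1 + b1)                             # (n, h)
        p = _softmax(H @ W2 + b2)
        d2 = p - onehot                                      # (n, c)
        gW2 = np.einsum("nh,nc->nhc", H, d2).reshape(n, -1)
        dpre = (d2 @ W2.T) * (1.0 - H * H)                   # (n, h)
        gW1 = np.einsum("nd,nh->ndh", X, dpre).reshape(n, -1)
        G = np.concatenate([gW1, dpre, gW2, d2], axis=1)
    loss = float(-np.mean(np.log(p[np.arange(n), y] + 1e-300)))
    return G, loss


def batch_gradient(spec: ModelSpec, w: np.ndarray, X: np.ndarray,
                   y: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean gradient over the batch (equals the mean of per-sample rows)."""
    G, loss = per_sample_gradients(spec, w, X, y)
    return G.mean(axis=0), loss


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def pool_features(pixels: np.ndarray, grid: int = 8) -> np.ndarray:
    """Mean-pool a square image to ``grid x grid`` block means, flattened.

    The image side need not divide the grid exactly; trailing rows/columns are
    folded into the last block.
    """
    n = pixels.shape[0]
    if grid >= n:
        return pixels.ravel().astype(float)
    edges = np.linspace(0, n, grid + 1).astype(int)
    out = np.empty((grid, grid))
    for i in range(grid):
        for j in range(grid):
            out[i, j] = pixels[edges[i]:edges[i + 1],
                               edges[j]:edges[j + 1]].mean()
    return out.ravel()


def extract_features(samples: list[ImageSample], grid: int = 8,
                     standardize_stats: tuple | None = None) -> np.ndarray:
    """Pooled feature matrix for a list of samples.

    If ``standardize_stats`` (mean, sd arrays) is given, features are z-scored
    with those statistics; pass the training-set stats when transforming
    validation/test data.
    """
    X = np.stack([pool_features(s.pixels, grid) for s in samples])
    if standardize_stats is not None:
        mean, sd = standardize_stats
        X = (X - mean) / sd
    return X


def feature_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return X.mean(axis=0), sd


# ---------------------------------------------------------------------------
# Communication-cost model and architecture metadata
# ---------------------------------------------------------------------------

def comm_cost_mb(params_millions: float, K: int) -> float:
    """Per-round federated communication cost in MB (1 MB = 10^6 bytes).

    One upload and one download of 32-bit parameters per participating client:
    2 x |theta| x 4 bytes x K.
    """
    if params_millions < 0 or K < 0:
        raise ConfigurationError("comm_cost_mb: inputs must be nonnegative")
    return 2.0 * params_millions * 1e6 * 4.0 * K / 1e6


def load_architecture_table() -> list[ArchitectureMeta]:
    """The packaged reference-architecture metadata (name, parameter count)."""
    path = resources.files("fedusim.data") / "architectures.csv"
    frame = pd.read_csv(path)
    return [ArchitectureMeta(r.name, float(r.params_millions))
            for r in frame.itertuples(index=False)]


def cost_table(K: int = 8) -> pd.DataFrame:
    """Architecture name, parameter count and per-round cost at K clients."""
    rows = [{"architecture": a.name, "params_millions": a.params_millions,
             "comm_cost_mb": comm_cost_mb(a.params_millions, K)}
            for a in load_architecture_table()]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Checkpoints: flat float64 vector with a JSON header
# ---------------------------------------------------------------------------

def save_checkpoint(spec: ModelSpec, w: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    header = {"family": spec.family, "input_dim": spec.input_dim,
              "hidden_dim": spec.hidden_dim, "n_classes": spec.n_classes,
              "init_scale": spec.init_scale, "seed": spec.seed}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(header))
    np.savetxt(path, w)


def load_checkpoint(path: str | Path) -> tuple[ModelSpec, np.ndarray]:
    path = Path(path)
    header = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ModelSpec(**header), np.loadtxt(path)
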