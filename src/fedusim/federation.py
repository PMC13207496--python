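"""The communication-round loop and the three aggregation algorithms.

Each round the server broadcasts the global weights, every client runs E local
epochs of mini-batch descent (optionally differentially private, optionally
with a FedProx proximal pull toward the broadcast weights), and the server
aggregates the returned weight vectors:

* ``fedavg``  — arithmetic mean of client weights (sample-size weighting behind
  a flag; the unweighted mean is the default, matching the printed update rule
  of the procedure being emulated);
* ``fedprox`` — same aggregation, clients add mu*(w - w_global) to every local
  gradient;
* ``fedopt``  — the server treats Delta_t = w_t - mean(w_k) as a pseudo-gradient
  and applies an Adam-style update with moments (m_t, v_t); no bias-correction
  terms by default, matching the printed recurrences.

Weights, never gradients, leave the clients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import child_seed
from .errors import ConfigurationError
from .models import ModelSpec, batch_gradient, init_model, predict_proba
from .privacy import DPConfig, batches_per_epoch, build_ledger, dp_local_step

ALGORITHMS = ("fedavg", "fedprox", "fedopt")


@dataclass(frozen=True)
class FLConfig:
    """Round-loop hyperparameters (defaults follow the emulated configuration)."""

    rounds: int = 100
    local_epochs: int = 5
    batch_size: int = 32
    algorithm: str = "fedavg"
    mu: float = 0.01
    server_lr: float = 0.01
    beta1: float = 0.9
    beta2: float = 0.99
    adam_eps: float = 1e-8
    client_lr: float = 1e-3
    lr_decay_rounds: tuple[int, ...] = (50, 80)
    lr_decay_factor: float = 0.1
    weighted_avg: bool = False
    local_optimizer: str = "sgd"  # {"sgd", "adam"}; adam only when DP is off
    bias_correction: bool = False
    allow_small_client: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.rounds, self.local_epochs, self.batch_size) < 1:
            raise ConfigurationError("rounds/local_epochs/batch_size must be >= 1")
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(f"algorithm: {self.algorithm!r}")
        if self.mu < 0:
            raise ConfigurationError(f"mu: {self.mu} < 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ConfigurationError("beta1/beta2 must lie in [0, 1)")
        if self.local_optimizer not in ("sgd", "adam"):
            raise ConfigurationError(f"local_optimizer: {self.local_optimizer!r}")


@dataclass
class RoundState:
    """Global weights plus server optimizer moments across rounds."""

    round: int
    weights: np.ndarray
    m: np.ndarray
    v: np.ndarray

    @classmethod
    def initial(cls, w0: np.ndarray) -> "RoundState":
        return cls(0, w0.copy(), np.zeros_like(w0), np.zeros_like(w0))


@dataclass(frozen=True)
class ClientUpdate:
    client_id: int
    weights: np.ndarray
    n_k: int


@dataclass(frozen=True)
class FederationResult:
    weights: np.ndarray
    log: pd.DataFrame


# ---------------------------------------------------------------------------
# Client side
# ---------------------------------------------------------------------------

def lr_at_round(config: FLConfig, round_r: int) -> float:
    """Client learning rate under the step-decay schedule (1-indexed rounds);
    the decay applies from each listed round onward."""
    passed = sum(round_r >= t for t in config.lr_decay_rounds)
    return config.client_lr * config.lr_decay_factor ** passed


def fedprox_gradient(grad_local: np.ndarray, w: np.ndarray,
                     w_global: np.ndarray, mu: float) -> np.ndarray:
    """Local gradient plus the proximal pull mu*(w - w_global)."""
    if grad_local.shape != w.shape or w.shape != w_global.shape:
        raise ConfigurationError("fedprox_gradient: length mismatch")
    return grad_local + mu * (w - w_global)


def local_train(w_global: np.ndarray, X: np.ndarray, y: np.ndarray,
                model_spec: ModelSpec, fl_config: FLConfig,
                dp_config: DPConfig | None, round_r: int,
                seed: int) -> ClientUpdate:
    """E local epochs of mini-batch training starting from the broadcast weights.

    Each epoch shuffles the client's data and visits floor(n/B) full batches
    (the trailing partial batch is dropped; a client smaller than one batch is
    an error unless ``allow_small_client`` permits a single undersized batch).
    With DP enabled each step is the clipped/noised step of the privacy
    module; otherwise it is plain SGD (or local Adam when selected). FedProx
    adds the proximal gradient to every step.
    """
    dp = dp_config if dp_config is not None else DPConfig(enabled=False)
    n = len(y)
    B = fl_config.batch_size
    nb = n // B
    sizes = [B] * nb
    if nb == 0:
        if not fl_config.allow_small_client:
            raise ConfigurationError(
                f"local_train: client has {n} samples < batch size {B}")
        sizes = [n]
    rng = np.random.default_rng(seed)
    lr = lr_at_round(fl_config, round_r)
    w = w_global.copy()
    use_adam = fl_config.local_optimizer == "adam" and not dp.enabled
    if use_adam:
        m = np.zeros_like(w)
        v = np.zeros_like(w)
        t = 0
    for _ in range(fl_config.local_epochs):
        perm = rng.permutation(n)
        start = 0
        for size in sizes:
            idx = perm[start:start + size]
            start += size
            Xb, yb = X[idx], y[idx]
            if dp.enabled:
                w_next = dp_local_step(w, Xb, yb, model_spec, dp, lr, rng)
                if fl_config.algorithm == "fedprox":
                    # proximal pull is data-independent: applied after the
                    # clipped/noised gradient, outside the sensitivity bound
                    w_next = w_next - lr * fl_config.mu * (w - w_global)
                w = w_next
            else:
                g, _ = batch_gradient(model_spec, w, Xb, yb)
                if fl_config.algorithm == "fedprox":
                    g = fedprox_gradient(g, w, w_global, fl_config.mu)
                if use_adam:
                    t += 1
                    m = fl_config.beta1 * m + (1 - fl_config.beta1) * g
                    v = fl_config.beta2 * v + (1 - fl_config.beta2) * g * g
                    if fl_config.bias_correction:
                        mh = m / (1 - fl_config.beta1 ** t)
                        vh = v / (1 - fl_config.beta2 ** t)
                    else:
                        mh, vh = m, v
                    w = w - lr * mh / (np.sqrt(vh) + fl_config.adam_eps)
                else:
                    w = w - lr * g
    return ClientUpdate(client_id=-1, weights=w, n_k=n)


# ---------------------------------------------------------------------------
# Server side
# ---------------------------------------------------------------------------

def aggregate_fedavg(updates: list[ClientUpdate],
                     weighted: bool = False) -> np.ndarray:
    """Mean of client weight vectors; n_k-proportional when ``weighted``."""
    if not updates:
        raise ConfigurationError("aggregate_fedavg: no updates")
    length = updates[0].weights.shape
    if any(u.weights.shape != length for u in updates):
        raise ConfigurationError("aggregate_fedavg: length mismatch")
    stack = np.stack([u.weights for u in updates])
    if not weighted:
        return stack.mean(axis=0)
    n = np.array([u.n_k for u in updates], dtype=float)
    return (stack * (n / n.sum())[:, None]).sum(axis=0)


def server_update_fedopt(state: RoundState, updates: list[ClientUpdate],
                         fl_config: FLConfig) -> RoundState:
    """Adam-style server step on the pseudo-gradient Delta_t = w_t - mean(w_k).

    The subtraction w - lr * m/(sqrt(v)+eps) therefore moves the global model
    toward the clients. No bias correction by default.
    """
    mean_w = aggregate_fedavg(updates, weighted=fl_config.weighted_avg)
    if mean_w.shape != state.weights.shape:
        raise ConfigurationError("server_update_fedopt: length mismatch")
    delta = state.weights - mean_w
    m = fl_config.beta1 * state.m + (1 - fl_config.beta1) * delta
    v = fl_config.beta2 * state.v + (1 - fl_config.beta2) * delta * delta
    t = state.round + 1
    if fl_config.bias_correction:
        mh = m / (1 - fl_config.beta1 ** t)
        vh = v / (1 - fl_config.beta2 ** t)
    else:
        mh, vh = m, v
    w_new = state.weights - fl_config.server_lr * mh / (np.sqrt(vh) + fl_config.adam_eps)
    return RoundState(round=t, weights=w_new, m=m, v=v)


# ---------------------------------------------------------------------------
# Round loop
# ---------------------------------------------------------------------------

def run_federation(train_sets: list[tuple[np.ndarray, np.ndarray]],
                   test_set: tuple[np.ndarray, np.ndarray] | None,
                   model_spec: ModelSpec, fl_config: FLConfig,
                   dp_config: DPConfig | None = None) -> FederationResult:
    """Execute R communication rounds with full participation.

    ``train_sets`` holds one (X, y) pair per client (resolved from client
    manifests by the orchestration layer); ``test_set`` is the shared global
    test set evaluated each round. Per-client round seeds derive from
    (fl_config.seed, client, round), so the trajectory is a pure function of
    configs and data. The per-round log reports train loss, test accuracy,
    macro F1, and — when DP is on — the running epsilon of the
    busiest client under both composition rules.
    """
    from .evaluation import evaluate_predictions

    dp = dp_config if dp_config is not None else DPConfig(enabled=False)
    state = RoundState.initial(init_model(model_spec))
    records = []
    max_batches = max(batches_per_epoch(len(y), fl_config.batch_size) or 1
                      for _, y in train_sets)
    for r in range(1, fl_config.rounds + 1):
        updates = []
        losses = []
        for k, (Xk, yk) in enumerate(train_sets):
            seed_kr = child_seed(fl_config.seed, "local", k, r)
            upd = local_train(state.weights, Xk, yk, model_spec, fl_config,
                              dp, r, seed_kr)
            updates.append(replace(upd, client_id=k))
            _, loss = batch_gradient(model_spec, state.weights, Xk, yk)
            losses.append(loss)
        if fl_config.algorithm == "fedopt":
            state = server_update_fedopt(state, updates, fl_config)
        else:
            w_new = aggregate_fedavg(updates, weighted=fl_config.weighted_avg)
            state = RoundState(round=r, weights=w_new, m=state.m, v=state.v)
        record = {"round": r, "algorithm": fl_config.algorithm,
                  "train_loss": float(np.mean(losses))}
        if test_set is not None:
            Xt, yt = test_set
            pred = predict_proba(model_spec, state.weights, Xt).argmax(axis=1)
            report = evaluate_predictions(yt, pred, model_spec.n_classes)
            record["test_accuracy"] = report.accuracy
            record["macro_f1"] = report.macro_f1
        if dp.enabled:
            ledger = build_ledger(dp, r, fl_config.local_epochs, max_batches)
            record["eps_basic"] = ledger.eps_basic
            record["eps_sublinear"] = ledger.eps_sublinear
        records.append(record)
    return FederationResult(weights=state.weights, log=pd.DataFrame(records))
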