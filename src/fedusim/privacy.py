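"""Client-side differential privacy: clip -> average -> noise -> step, plus
closed-form Gaussian-mechanism accounting.

The mechanism clips each per-sample gradient to an l2 bound C, averages the
clipped gradients over the mini-batch, and adds isotropic Gaussian noise with
per-coordinate standard deviation eta*C *on the batch average*. That noise
placement follows the procedure being emulated exactly; the common DP-SGD
convention instead calibrates sigma*C to the clipped *sum* (i.e. eta*C/B on the
average) and is available through the ``convention`` flag for sensitivity
analysis.

Accounting is closed form: each step is (eps_step, delta)-DP with
eps_step = sqrt(2 ln(1.25/delta)) / eta, composed either linearly over T steps
(basic composition) or as sqrt(T)*eps_step (the advanced-composition growth
rate). The same delta = 1e-5 is substituted into the per-step formula and
quoted as the total — this conflates per-step and total delta, but it is the
arithmetic the accounting reproduces, so it is kept as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

NORM_FLOOR = 1e-7


@dataclass(frozen=True)
class DPConfig:
    enabled: bool = False
    C: float = 1.5
    eta: float = 2.0
    delta: float = 1e-5
    norm_floor: float = NORM_FLOOR
    convention: str = "average"  # {"average": std=eta*C; "sum_scaled": std=eta*C/B}

    def __post_init__(self):
        if self.C <= 0:
            raise ConfigurationError(f"C: {self.C} <= 0")
        if self.eta < 0:
            raise ConfigurationError(f"eta: {self.eta} < 0")
        if not 0 < self.delta < 1:
            raise ConfigurationError(f"delta: {self.delta} outside (0, 1)")
        if self.convention not in ("average", "sum_scaled"):
            raise ConfigurationError(f"convention: {self.convention!r}")


@dataclass(frozen=True)
class PrivacyLedger:
    """Privacy budget bookkeeping for one training configuration.

    ``eps_basic`` is exactly T * eps_step; ``eps_sublinear`` is the
    sqrt(T)-growth estimate. The ``*_printed`` fields follow the reporting
    protocol of the emulated study: eps_step rounded to two decimals before
    linear composition.
    """

    T: int
    eps_step: float
    eps_basic: float
    eps_sublinear: float
    delta: float
    eps_step_printed: float
    eps_basic_printed: float


# ---------------------------------------------------------------------------
# Mechanism
# ---------------------------------------------------------------------------

def clip_per_sample(g: np.ndarray, C: float,
                    norm_floor: float = NORM_FLOOR) -> np.ndarray:
    """Scale ``g`` to l2 norm at most C, preserving direction.

    The norm is floored at ``norm_floor`` before division, so the zero vector
    maps to itself without a division error.
    """
    if C <= 0:
        raise ConfigurationError(f"C: {C} <= 0")
    norm = float(np.linalg.norm(g))
    return g * min(1.0, C / max(norm, norm_floor))


def noisy_batch_gradient(clipped: list[np.ndarray] | np.ndarray, C: float,
                         eta: float, rng: np.random.Generator,
                         convention: str = "average") -> np.ndarray:
    """Mean of clipped gradients plus isotropic Gaussian noise.

    Per-coordinate noise std is eta*C under the default ``average`` convention
    and eta*C/B under ``sum_scaled``.
    """
    arr = np.asarray(clipped, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ConfigurationError("clipped: need a nonempty list of gradient rows")
    if eta < 0:
        raise ConfigurationError(f"eta: {eta} < 0")
    mean = arr.mean(axis=0)
    if eta == 0:
        return mean
    std = eta * C if convention == "average" else eta * C / arr.shape[0]
    return mean + rng.normal(0.0, std, size=mean.shape)


def dp_local_step(w: np.ndarray, X: np.ndarray, y: np.ndarray, model_spec,
                  dp_config: DPConfig, lr: float,
                  rng: np.random.Generator) -> np.ndarray:
    """One differentially private gradient step on a mini-batch.

    Per-sample gradients are clipped individually, averaged, noised, and the
    noisy estimate applied as a plain gradient step. With eta=0 and C above
    every per-sample norm this reduces to the ordinary SGD step.
    """
    from .models import per_sample_gradients

    if not dp_config.enabled:
        raise ConfigurationError("dp_local_step: DP is not enabled")
    G, _ = per_sample_gradients(model_spec, w, X, y)
    clipped = [clip_per_sample(g, dp_config.C, dp_config.norm_floor) for g in G]
    g_hat = noisy_batch_gradient(clipped, dp_config.C, dp_config.eta, rng,
                                 convention=dp_config.convention)
    return w - lr * g_hat


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def epsilon_step(eta: float, delta: float) -> float:
    """Per-step epsilon of the Gaussian mechanism: sqrt(2 ln(1.25/delta))/eta.

    eta=0 means no noise, i.e. an unbounded budget: returns ``math.inf`` as a
    distinguished value rather than raising.
    """
    if not 0 < delta < 1:
        raise ConfigurationError(f"delta: {delta} outside (0, 1)")
    if eta < 0:
        raise ConfigurationError(f"eta: {eta} < 0")
    if eta == 0:
        return math.inf
    return math.sqrt(2.0 * math.log(1.25 / delta)) / eta


def compose_basic(eps_step: float, T: int) -> float:
    """Linear (basic) composition over T steps: T * eps_step."""
    if T < 0:
        raise ConfigurationError(f"T: {T} < 0")
    return T * eps_step


def compose_sublinear(eps_step: float, T: int) -> float:
    """sqrt(T) * eps_step — the advanced-composition growth-rate estimate."""
    if T < 0:
        raise ConfigurationError(f"T: {T} < 0")
    return math.sqrt(T) * eps_step


def steps_count(R: int, E: int, batches_per_epoch: int) -> int:
    """Total gradient steps: rounds x local epochs x batches per epoch."""
    if min(R, E, batches_per_epoch) < 1:
        raise ConfigurationError("steps_count: all inputs must be >= 1")
    return R * E * batches_per_epoch


def batches_per_epoch(n_k: int, B: int) -> int:
    """Full batches per local epoch (partial batches dropped)."""
    if B < 1:
        raise ConfigurationError(f"B: {B} < 1")
    return n_k // B


def build_ledger(dp_config: DPConfig, R: int, E: int,
                 batches: int) -> PrivacyLedger:
    """Populate the privacy ledger for a training configuration."""
    T = steps_count(R, E, batches)
    eps = epsilon_step(dp_config.eta, dp_config.delta)
    eps_printed = round(eps, 2) if math.isfinite(eps) else eps
    return PrivacyLedger(
        T=T,
        eps_step=eps,
        eps_basic=compose_basic(eps, T),
        eps_sublinear=compose_sublinear(eps, T),
        delta=dp_config.delta,
        eps_step_printed=eps_printed,
        eps_basic_printed=compose_basic(eps_printed, T),
    )


def budget_table(eta_list, delta: float = 1e-5, R: int = 100, E: int = 5,
                 batches: int = 25, C: float = 1.5) -> pd.DataFrame:
    """Budget-table report: one row per noise multiplier."""
    rows = []
    for eta in eta_list:
        ledger = build_ledger(DPConfig(enabled=True, C=C, eta=eta, delta=delta),
                              R, E, batches)
        rows.append({"eta": eta, "T": ledger.T,
                     "eps_step": ledger.eps_step,
                     "eps_basic": ledger.eps_basic,
                     "eps_basic_printed": ledger.eps_basic_printed,
                     "eps_sublinear": ledger.eps_sublinear})
    return pd.DataFrame(rows)
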