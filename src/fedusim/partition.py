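"""Client partitioning: IID and three-way non-IID (label, quantity, feature skew).

The non-IID recipe composes, in order: Dirichlet label skew (each client's class
proportions drawn from Dir(alpha * p), p the global class distribution), log-normal
quantity skew (client sizes re-targeted, total conserved), and feature skew (one
fixed brightness/contrast/rotation draw per client, applied lazily at image-load
time so stored pixels remain canonical).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import rotate as nd_rotate

from ._rng import child_rng
from .errors import ConfigurationError
from .synthdata import LABELS, ImageSample


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSkewRanges:
    """Per-client augmentation draw ranges (lo, hi)."""

    brightness: tuple[float, float] = (-0.2, 0.2)
    contrast: tuple[float, float] = (0.8, 1.2)
    rotation: tuple[float, float] = (-15.0, 15.0)

    def __post_init__(self):
        for name in ("brightness", "contrast", "rotation"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name}: lo {lo} > hi {hi}")

    @classmethod
    def identity(cls) -> "FeatureSkewRanges":
        return cls(brightness=(0.0, 0.0), contrast=(1.0, 1.0), rotation=(0.0, 0.0))


@dataclass(frozen=True)
class AugmentationSpec:
    """One client's fixed augmentation: applied to all its images at load time."""

    brightness_delta: float = 0.0
    contrast_factor: float = 1.0
    rotation_deg: float = 0.0

    @property
    def is_identity(self) -> bool:
        return (self.brightness_delta == 0.0 and self.contrast_factor == 1.0
                and self.rotation_deg == 0.0)


@dataclass
class ClientManifest:
    """Training samples assigned to one simulated client."""

    client_id: int
    sample_ids: list[str]
    augmentation_spec: AugmentationSpec = field(default_factory=AugmentationSpec)

    @property
    def n_k(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class PartitionConfig:
    """Mode and parameters for distributing the training split across clients."""

    mode: str = "noniid"  # {"iid", "noniid"}
    K: int = 8
    alpha: float = 0.5
    quantity_log_sd: float = 0.5
    feature_skew_ranges: FeatureSkewRanges = field(default_factory=FeatureSkewRanges)
    allow_empty_clients: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("iid", "noniid"):
            raise ConfigurationError(f"mode: {self.mode!r}")
        if self.K < 1:
            raise ConfigurationError(f"K: {self.K} < 1")
        if self.alpha <= 0:
            raise ConfigurationError(f"alpha: {self.alpha} <= 0")
        if self.quantity_log_sd < 0:
            raise ConfigurationError(f"quantity_log_sd: {self.quantity_log_sd} < 0")


@dataclass(frozen=True)
class PartitionSummary:
    """Per-client totals and class percentages plus a global row."""

    table: pd.DataFrame
    class_names: tuple

    def render(self) -> str:
        return self.table.to_string(index=False)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer quotas summing to ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        weights = np.ones_like(weights)
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    residue = total - base.sum()
    if residue > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:residue]] += 1
    return base


def _group_by_label(samples: list[ImageSample]) -> dict:
    pools: dict[str, list[str]] = {}
    for s in samples:
        pools.setdefault(s.label, []).append(s.sample_id)
    return pools


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def partition_iid(samples: list[ImageSample], K: int,
                  seed: int = 0) -> list[ClientManifest]:
    """Stratified round-robin split: sizes differ by at most 1 and each client's
    class mix matches the global mix as closely as integer rounding permits."""
    if K < 1:
        raise ConfigurationError(f"K: {K} < 1")
    if K > len(samples):
        raise ConfigurationError(f"K: {K} exceeds sample count {len(samples)}")
    pools = _group_by_label(samples)
    assignments: list[list[str]] = [[] for _ in range(K)]
    cursor = 0
    for label in sorted(pools):
        ids = sorted(pools[label])
        rng = child_rng(seed, "iid", label)
        rng.shuffle(ids)
        for sid in ids:
            assignments[cursor % K].append(sid)
            cursor += 1
    return [ClientManifest(k, assignments[k]) for k in range(K)]


def partition_dirichlet(samples: list[ImageSample], K: int, alpha: float,
                        seed: int = 0, allow_empty: bool = False,
                        max_attempts: int = 100) -> list[ClientManifest]:
    """Label-skewed partition via Dirichlet allocation.

    Each client draws class proportions from Dir(alpha * p) with p the global
    class distribution; each class pool is then divided across clients by
    largest-remainder rounding of the drawn proportions and filled by sampling
    without replacement, so the result is always an exact partition. A draw
    leaving some client empty is retried up to ``max_attempts`` times unless
    ``allow_empty`` is set.
    """
    if alpha <= 0:
        raise ConfigurationError(f"alpha: {alpha} <= 0")
    if K < 1:
        raise ConfigurationError(f"K: {K} < 1")
    pools = _group_by_label(samples)
    labels_present = sorted(pools)
    n = len(samples)
    p = np.array([len(pools[c]) / n for c in labels_present])
    for attempt in range(max_attempts):
        rng = child_rng(seed, "dirichlet", attempt)
        props = rng.dirichlet(alpha * p, size=K)  # (K, C)
        assignments: list[list[str]] = [[] for _ in range(K)]
        for ci, label in enumerate(labels_present):
            ids = sorted(pools[label])
            rng.shuffle(ids)
            quotas = _largest_remainder(props[:, ci], len(ids))
            start = 0
            for k in range(K):
                assignments[k].extend(ids[start:start + quotas[k]])
                start += quotas[k]
        sizes = [len(a) for a in assignments]
        if allow_empty or min(sizes) >= 1:
            return [ClientManifest(k, assignments[k]) for k in range(K)]
    raise ConfigurationError(
        f"partition_dirichlet: a client received zero samples in each of "
        f"{max_attempts} attempts (K={K}, alpha={alpha})")


def apply_quantity_skew(manifests: list[ClientManifest], quantity_log_sd: float,
                        seed: int, labels: dict,
                        max_attempts: int = 100) -> list[ClientManifest]:
    """Re-target client sizes with multiplicative log-normal factors.

    Each current size is multiplied by an independent LogNormal(0, sd) factor
    and the targets rescaled so their sum equals the training total (the
    largest client absorbs the rounding residue). Samples are then
    re-allocated from per-class pools so each client's class proportions are
    preserved as closely as the integer targets allow; the final client
    receives whatever remains, which conserves the total exactly.
    ``labels`` maps sample_id -> original class label.
    """
    if quantity_log_sd < 0:
        raise ConfigurationError(f"quantity_log_sd: {quantity_log_sd} < 0")
    K = len(manifests)
    sizes = np.array([m.n_k for m in manifests], dtype=float)
    total = int(sizes.sum())
    if quantity_log_sd == 0:
        return [replace(m, sample_ids=list(m.sample_ids)) for m in manifests]
    for attempt in range(max_attempts):
        rng = child_rng(seed, "quantity", attempt)
        factors = rng.lognormal(mean=0.0, sigma=quantity_log_sd, size=K)
        raw = sizes * factors
        targets = np.floor(raw / raw.sum() * total).astype(int)
        targets[int(np.argmax(targets))] += total - targets.sum()
        if targets.min() >= 1:
            break
    else:
        raise ConfigurationError(
            f"apply_quantity_skew: target size < 1 in each of {max_attempts} attempts")

    # Per-class pools; each pool shuffled once, consumed in order.
    pools: dict[str, list[str]] = {}
    for m in manifests:
        for sid in m.sample_ids:
            pools.setdefault(labels[sid], []).append(sid)
    rng = child_rng(seed, "quantity-fill")
    for label in sorted(pools):
        pools[label].sort()
        rng.shuffle(pools[label])

    out = []
    for k, m in enumerate(manifests):
        if k == K - 1:  # last client takes the remainder: exact conservation
            chosen = [sid for label in sorted(pools) for sid in pools[label]]
            out.append(replace(m, sample_ids=chosen))
            break
        # class quotas proportional to the client's current class mix
        counts = {}
        for sid in m.sample_ids:
            counts[labels[sid]] = counts.get(labels[sid], 0) + 1
        class_order = sorted(pools)
        weights = np.array([counts.get(c, 0) for c in class_order], dtype=float)
        quotas = _largest_remainder(weights, int(targets[k]))
        chosen: list[str] = []
        shortfall = 0
        for c, q in zip(class_order, quotas):
            take = min(int(q), len(pools[c]))
            shortfall += int(q) - take
            chosen.extend(pools[c][:take])
            del pools[c][:take]
        # depleted pools: fill the shortfall from whatever classes remain
        for c in class_order:
            while shortfall > 0 and pools[c]:
                chosen.append(pools[c].pop(0))
                shortfall -= 1
        out.append(replace(m, sample_ids=chosen))
    return out


def assign_feature_skew(manifests: list[ClientManifest],
                        ranges: FeatureSkewRanges,
                        seed: int = 0) -> list[ClientManifest]:
    """Give each client one fixed (brightness, contrast, rotation) draw.

    The draw is a pure function of (client_id, seed), independent of K and of
    the manifest contents.
    """
    out = []
    for m in manifests:
        rng = child_rng(seed, "feature-skew", m.client_id)
        spec = AugmentationSpec(
            brightness_delta=float(rng.uniform(*ranges.brightness)),
            contrast_factor=float(rng.uniform(*ranges.contrast)),
            rotation_deg=float(rng.uniform(*ranges.rotation)),
        )
        out.append(replace(m, augmentation_spec=spec))
    return out


def apply_augmentation(pixels: np.ndarray, spec: AugmentationSpec) -> np.ndarray:
    """Apply a client's fixed augmentation to one image (load-time transform)."""
    out = pixels
    if spec.rotation_deg != 0.0:
        out = nd_rotate(out, spec.rotation_deg, reshape=False, order=1,
                        mode="nearest")
    if spec.contrast_factor != 1.0:
        mean = out.mean()
        out = mean + spec.contrast_factor * (out - mean)
    if spec.brightness_delta != 0.0:
        out = out + spec.brightness_delta
    return np.clip(out, 0.0, 1.0)


def partition_training_set(samples: list[ImageSample],
                           config: PartitionConfig,
                           labels: dict | None = None) -> list[ClientManifest]:
    """Full partitioning pipeline for one PartitionConfig.

    ``noniid`` composes label skew, then quantity skew, then feature skew, in
    that order; ``iid`` is the stratified round-robin split with identity
    augmentations.
    """
    labels = labels if labels is not None else {s.sample_id: s.label for s in samples}
    if config.mode == "iid":
        return partition_iid(samples, config.K, seed=config.seed)
    manifests = partition_dirichlet(samples, config.K, config.alpha,
                                    seed=config.seed,
                                    allow_empty=config.allow_empty_clients)
    if config.quantity_log_sd > 0:
        manifests = apply_quantity_skew(manifests, config.quantity_log_sd,
                                        config.seed, labels)
    manifests = assign_feature_skew(manifests, config.feature_skew_ranges,
                                    seed=config.seed)
    return manifests


def summarize_partition(manifests: list[ClientManifest], labels: dict,
                        class_names: tuple = LABELS) -> PartitionSummary:
    """Per-client totals and class percentages with a global row."""
    rows = []
    global_counts = np.zeros(len(class_names), dtype=int)
    for m in manifests:
        counts = np.zeros(len(class_names), dtype=int)
        for sid in m.sample_ids:
            counts[class_names.index(labels[sid])] += 1
        global_counts += counts
        row = {"client": f"Client {m.client_id + 1}", "total": int(m.n_k)}
        for c, k in zip(class_names, counts):
            row[f"{c}_pct"] = round(100.0 * k / max(m.n_k, 1), 1)
        rows.append(row)
    total = int(global_counts.sum())
    grow = {"client": "Total", "total": total}
    for c, k in zip(class_names, global_counts):
        grow[f"{c}_pct"] = round(100.0 * k / max(total, 1), 1)
    rows.append(grow)
    return PartitionSummary(table=pd.DataFrame(rows), class_names=tuple(class_names))


# ---------------------------------------------------------------------------
# Packaged reference partition (transcribed client-wise table)
# ---------------------------------------------------------------------------

def load_reference_partition() -> tuple[list[ClientManifest], dict]:
    """The packaged 8-client reference manifest (synthetic sample ids).

    Client totals and class percentages are transcribed from the emulated
    study's published client table; integer per-class counts were
    reconstructed once by largest-remainder so the percentages round back to
    the printed one-decimal values. Sample ids are synthetic placeholders.
    """
    path = resources.files("fedusim.data") / "reference_partition.csv"
    frame = pd.read_csv(path)
    manifests, labels = [], {}
    for row in frame.itertuples():
        ids = []
        for label in LABELS:
            for i in range(int(getattr(row, label))):
                sid = f"c{row.client}-{label}-{i:04d}"
                ids.append(sid)
                labels[sid] = label
        manifests.append(ClientManifest(int(row.client) - 1, ids))
    return manifests, labels


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_manifests(manifests: list[ClientManifest], outdir: str | Path) -> None:
    """Manifests as CSV (client_id, sample_id) plus a JSON augmentation sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [{"client_id": m.client_id, "sample_id": sid}
            for m in manifests for sid in m.sample_ids]
    pd.DataFrame(rows).to_csv(outdir / "manifests.csv", index=False)
    sidecar = {str(m.client_id): {
        "brightness_delta": m.augmentation_spec.brightness_delta,
        "contrast_factor": m.augmentation_spec.contrast_factor,
        "rotation_deg": m.augmentation_spec.rotation_deg,
    } for m in manifests}
    (outdir / "augmentations.json").write_text(json.dumps(sidecar, indent=2))


def load_manifests(outdir: str | Path) -> list[ClientManifest]:
    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "manifests.csv")
    sidecar = json.loads((outdir / "augmentations.json").read_text())
    manifests = []
    for cid, group in frame.groupby("client_id"):
        aug = sidecar.get(str(cid), {})
        manifests.append(ClientManifest(
            int(cid), list(group["sample_id"]),
            AugmentationSpec(**aug) if aug else AugmentationSpec()))
    return manifests
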