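"""Synthetic ultrasound-like image generation, task construction, preprocessing, splits.

The generator produces grayscale speckled phantoms in three classes that mimic the
*relative* difficulty structure of breast-ultrasound classification, not clinical
appearance:

* ``normal``    — multiplicative speckle over a smooth tissue background, no lesion;
* ``benign``    — a hypoechoic (dark) elliptical lesion with a smooth, anti-aliased
  margin;
* ``malignant`` — a hypoechoic lesion whose boundary is perturbed by radial spicules
  plus a faint posterior shadow band.

Lesion size, depth and contrast distributions are shared between the two lesion
classes, so detecting *any* lesion (screening) is driven by a large, salient
intensity cue while separating benign from malignant hinges on subtle margin
irregularity — a classifier therefore does much better on the screening task than
on the diagnostic one, which is the difficulty ordering the pipeline is built to
exercise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

from ._rng import child_rng
from .errors import ConfigurationError, PipelineError

LABELS = ("normal", "benign", "malignant")
TASKS = ("screen", "diagnose", "threeclass")
SPLIT_TAGS = ("train", "val", "test")

# RGB normalization statistics used by ImageNet-pretrained networks.
IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)
# Single-channel fallback: mean of the channel means / sds.
GRAY_MEAN = float(np.mean(IMAGENET_MEAN))
GRAY_STD = float(np.mean(IMAGENET_STD))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class ImageSample:
    """One grayscale image with its class label; the atom of the pipeline."""

    sample_id: str
    pixels: np.ndarray
    label: str
    split_tag: str | None = None
    audit: dict | None = None

    def validate(self) -> None:
        if self.label not in LABELS:
            raise ConfigurationError(f"label: {self.label!r} not in {LABELS}")
        if not np.all(np.isfinite(self.pixels)):
            raise PipelineError(f"sample {self.sample_id}: non-finite pixels")


@dataclass(frozen=True)
class DatasetSpec:
    """Generation parameters for one synthetic dataset realization.

    Counts default to a desk-scale dataset of 1,200 images whose class ratios
    mirror the 33/43/23 normal/benign/malignant mix of the emulated corpus.
    Axis ranges are fractions of the image side; the two lesion classes share
    them deliberately (see module docstring).
    """

    n_normal: int = 400
    n_benign: int = 520
    n_malignant: int = 280
    image_size: int = 64
    speckle_strength: float = 0.35
    benign_axis_range: tuple[float, float] = (0.12, 0.22)
    malignant_axis_range: tuple[float, float] = (0.12, 0.22)
    spicule_count_range: tuple[int, int] = (8, 14)
    spicule_amplitude: float = 0.25
    lesion_contrast: float = 0.45
    shadow_strength: float = 0.12
    seed: int = 0

    def __post_init__(self):
        for name in ("n_normal", "n_benign", "n_malignant"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name}: negative count {getattr(self, name)}")
        if self.image_size < 16:
            raise ConfigurationError(f"image_size: {self.image_size} < 16")
        if self.speckle_strength <= 0:
            raise ConfigurationError(f"speckle_strength: must be positive")
        if self.spicule_amplitude < 0:
            raise ConfigurationError("spicule_amplitude: must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_normal + self.n_benign + self.n_malignant


@dataclass(frozen=True)
class TaskView:
    """A relabeled view of the dataset for one classification task."""

    task: str
    relabel_map: dict  # original label -> task label
    sample_ids: tuple
    class_names: tuple  # task label vocabulary, index = integer class


@dataclass(frozen=True)
class SplitAssignment:
    """Image-level train/val/test assignment; test drawn first and shared."""

    fractions: tuple[float, float, float]
    tags: dict  # sample_id -> split tag
    seed: int

    def ids_for(self, tag: str) -> list:
        return [sid for sid, t in self.tags.items() if t == tag]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _speckle_background(rng: np.random.Generator, n: int, strength: float) -> np.ndarray:
    # Smooth "tissue" field modulated by folded-normal multiplicative speckle.
    field = gaussian_filter(rng.standard_normal((n, n)), sigma=n / 8.0)
    sd = field.std()
    if sd > 0:
        field = field / sd
    background = 0.55 + 0.10 * field
    speckle = np.abs(rng.normal(1.0, strength, size=(n, n)))
    return background * speckle


def _lesion_field(rng: np.random.Generator, n: int, spec: DatasetSpec,
                  malignant: bool) -> tuple[np.ndarray, float, float]:
    """Soft lesion mask in [0,1] plus (center row, vertical extent)."""
    axis_range = spec.malignant_axis_range if malignant else spec.benign_axis_range
    cy = rng.uniform(0.35 * n, 0.65 * n)
    cx = rng.uniform(0.35 * n, 0.65 * n)
    a = rng.uniform(*axis_range) * n
    b = rng.uniform(*axis_range) * n
    phi = rng.uniform(0.0, np.pi)
    yy, xx = np.mgrid[0:n, 0:n]
    dy = yy - cy
    dx = xx - cx
    u = (dx * np.cos(phi) + dy * np.sin(phi)) / a
    v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b
    rho = np.sqrt(u * u + v * v)
    if malignant:
        theta = np.arctan2(v, u)
        lo, hi = spec.spicule_count_range
        m = int(rng.integers(lo, hi + 1))
        s = (np.cos(m * theta + rng.uniform(0, 2 * np.pi))
             + 0.5 * np.cos(max(2, m // 2) * theta + rng.uniform(0, 2 * np.pi))) / 1.5
        boundary = 1.0 + spec.spicule_amplitude * s
        edge = 0.8 / min(a, b)  # sharp, irregular margin
    else:
        boundary = 1.0
        edge = 2.0 / min(a, b)  # smooth margin
    mask = 1.0 / (1.0 + np.exp((rho - boundary) / edge))
    return mask, cy, b


def _render(spec: DatasetSpec, label: str, rng: np.random.Generator) -> np.ndarray:
    n = spec.image_size
    img = _speckle_background(rng, n, spec.speckle_strength)
    if label != "normal":
        malignant = label == "malignant"
        mask, cy, b = _lesion_field(rng, n, spec, malignant)
        img = img * (1.0 - (1.0 - spec.lesion_contrast) * mask)
        if malignant and spec.shadow_strength > 0:
            col = mask.max(axis=0)
            rows = np.arange(n, dtype=float)[:, None]
            below = 1.0 / (1.0 + np.exp(-(rows - (cy + b)) / 2.0))
            img = img * (1.0 - spec.shadow_strength * col[None, :] * below)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(spec: DatasetSpec) -> list[ImageSample]:
    """Generate the dataset described by ``spec``; pure function of (spec, seed).

    Each sample's stream is keyed by (seed, label, index), so the pixels of a
    given sample never depend on how many samples of other classes exist.
    """
    samples: list[ImageSample] = []
    counts = {"normal": spec.n_normal, "benign": spec.n_benign,
              "malignant": spec.n_malignant}
    for label in LABELS:
        for i in range(counts[label]):
            rng = child_rng(spec.seed, "image", label, i)
            pixels = _render(spec, label, rng)
            samples.append(ImageSample(f"{label}-{i:05d}", pixels, label))
    return samples


# ---------------------------------------------------------------------------
# Task construction
# ---------------------------------------------------------------------------

_TASK_MAPS = {
    "screen": {"normal": "normal", "benign": "abnormal", "malignant": "abnormal"},
    "diagnose": {"benign": "benign", "malignant": "malignant"},
    "threeclass": {"normal": "normal", "benign": "benign", "malignant": "malignant"},
}
_TASK_CLASSES = {
    "screen": ("normal", "abnormal"),
    "diagnose": ("benign", "malignant"),
    "threeclass": LABELS,
}


def construct_task(samples: list[ImageSample], task: str) -> TaskView:
    """Build the relabeled view for one of the three classification tasks.

    ``screen`` merges benign+malignant into "abnormal"; ``diagnose`` drops
    normals; ``threeclass`` is the identity. A task with an empty class is
    untrainable and raises.
    """
    if task not in TASKS:
        raise ConfigurationError(f"task: {task!r} not in {TASKS}")
    relabel = _TASK_MAPS[task]
    members = [s for s in samples if s.label in relabel]
    class_names = _TASK_CLASSES[task]
    counts = {c: 0 for c in class_names}
    for s in members:
        counts[relabel[s.label]] += 1
    for c, k in counts.items():
        if k == 0:
            raise ConfigurationError(
                f"task {task!r}: empty class {c!r} (untrainable task)")
    return TaskView(task=task, relabel_map=dict(relabel),
                    sample_ids=tuple(s.sample_id for s in members),
                    class_names=tuple(class_names))


def task_labels(view: TaskView, samples: list[ImageSample]) -> np.ndarray:
    """Integer task labels for ``samples`` (all must belong to the view)."""
    index = {c: i for i, c in enumerate(view.class_names)}
    out = np.empty(len(samples), dtype=np.int64)
    for j, s in enumerate(samples):
        if s.label not in view.relabel_map:
            raise ConfigurationError(
                f"sample {s.sample_id}: label {s.label!r} outside task {view.task!r}")
        out[j] = index[view.relabel_map[s.label]]
    return out


# ---------------------------------------------------------------------------
# Preprocessing chain: resize -> CLAHE -> Gaussian denoise -> standardize
# ---------------------------------------------------------------------------

def resize_bicubic(pixels: np.ndarray, target_size: int) -> np.ndarray:
    from skimage.transform import resize
    if target_size < 16:
        raise ConfigurationError(f"target_size: {target_size} < 16")
    anti_alias = pixels.shape[0] > target_size
    out = resize(pixels.astype(float), (target_size, target_size), order=3,
                 mode="reflect", anti_aliasing=anti_alias)
    return np.clip(out, 0.0, 1.0)


def apply_clahe(pixels: np.ndarray, clip_limit: float = 2.0,
                tile_grid: int = 8, nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` follows the OpenCV convention (2.0 by default); it is mapped
    to skimage's normalized clip limit as clip_limit/nbins.
    """
    from skimage import exposure
    if np.ptp(pixels) == 0:
        return pixels.copy()  # flat image: equalization is the identity
    kernel = max(1, pixels.shape[0] // tile_grid)
    return exposure.equalize_adapthist(
        np.clip(pixels, 0.0, 1.0), kernel_size=kernel,
        clip_limit=clip_limit / nbins, nbins=nbins)


def gaussian_denoise(pixels: np.ndarray, kernel_size: int = 3,
                     sigma: float = 0.8) -> np.ndarray:
    """Gaussian smoothing with a (kernel_size x kernel_size) support."""
    return gaussian_filter(pixels, sigma=sigma, radius=kernel_size // 2,
                           mode="nearest")


def standardize(pixels: np.ndarray, channel_mode: str = "single") -> np.ndarray:
    """Normalize with the fixed ImageNet statistics.

    ``replicate`` returns a (3, H, W) array, the grayscale image replicated and
    standardized per RGB channel; ``single`` keeps one channel and uses the
    mean of the channel means/sds.
    """
    if channel_mode == "single":
        return (pixels - GRAY_MEAN) / GRAY_STD
    if channel_mode == "replicate":
        chans = [(pixels - m) / s for m, s in zip(IMAGENET_MEAN, IMAGENET_STD)]
        return np.stack(chans, axis=0)
    raise ConfigurationError(f"channel_mode: {channel_mode!r}")


def preprocess(sample: ImageSample, target_size: int = 64,
               clahe_clip: float = 2.0, kernel_size: int = 3,
               channel_mode: str = "single", tile_grid: int = 8) -> ImageSample:
    """Run the full preprocessing chain on one sample.

    Stage order: bicubic resize, CLAHE, Gaussian noise reduction, per-channel
    standardization. Per-stage output statistics are kept on the returned
    sample's ``audit`` dict; a non-finite intermediate raises a
    :class:`PipelineError` naming the stage.
    """
    stages = [
        ("resize", lambda p: resize_bicubic(p, target_size)),
        ("clahe", lambda p: apply_clahe(p, clahe_clip, tile_grid)),
        ("denoise", lambda p: gaussian_denoise(p, kernel_size)),
        ("standardize", lambda p: standardize(p, channel_mode)),
    ]
    pixels = sample.pixels
    audit = {}
    for name, fn in stages:
        pixels = fn(pixels)
        if not np.all(np.isfinite(pixels)):
            raise PipelineError(f"non-finite pixels after stage {name!r}")
        audit[name] = {"mean": float(np.mean(pixels)), "std": float(np.std(pixels))}
    return ImageSample(sample.sample_id, pixels, sample.label,
                       split_tag=sample.split_tag, audit=audit)


# ---------------------------------------------------------------------------
# Splitting
# ---------------------------------------------------------------------------

def split_dataset(samples: list[ImageSample],
                  fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
                  seed: int = 0) -> SplitAssignment:
    """Image-level train/val/test split.

    The test block is drawn first from the seeded permutation, so every
    configuration sharing the same samples and seed holds out the identical
    global test set; validation comes next, training is the remainder. Counts
    use round-half-even of fraction*N for test and val.
    """
    f_train, f_val, f_test = fractions
    if min(fractions) <= 0:
        raise ConfigurationError(f"fractions: all must be positive, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError(f"fractions: sum {sum(fractions)} != 1")
    ids = sorted(s.sample_id for s in samples)
    n = len(ids)
    n_test = int(np.rint(f_test * n))
    n_val = int(np.rint(f_val * n))
    if n_test + n_val > n:
        raise ConfigurationError("fractions: val+test exceed dataset size")
    order = np.random.default_rng(seed).permutation(n)
    tags = {}
    for rank, idx in enumerate(order):
        if rank < n_test:
            tag = "test"
        elif rank < n_test + n_val:
            tag = "val"
        else:
            tag = "train"
        tags[ids[idx]] = tag
    return SplitAssignment(fractions=tuple(fractions), tags=tags, seed=seed)


def apply_split(samples: list[ImageSample],
                assignment: SplitAssignment) -> list[ImageSample]:
    """Tag samples in place with their split assignment and return them."""
    for s in samples:
        s.split_tag = assignment.tags[s.sample_id]
    return samples


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_dataset(samples: list[ImageSample], outdir: str | Path) -> Path:
    """Persist images as 8-bit grayscale PNG plus a CSV manifest; returns the
    manifest path."""
    from PIL import Image

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        rel = f"images/{s.sample_id}.png"
        arr = np.clip(s.pixels, 0.0, 1.0)
        Image.fromarray((arr * 255).astype(np.uint8), mode="L").save(outdir / rel)
        rows.append({"sample_id": s.sample_id, "path": rel, "label": s.label,
                     "split_tag": s.split_tag or ""})
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(outdir: str | Path) -> list[ImageSample]:
    from PIL import Image

    outdir = Path(outdir)
    frame = pd.read_csv(outdir / "manifest.csv", keep_default_na=False)
    samples = []
    for row in frame.itertuples():
        arr = np.asarray(Image.open(outdir / row.path), dtype=float) / 255.0
        samples.append(ImageSample(row.sample_id, arr, row.label,
                                   split_tag=row.split_tag or None))
    return samples


def save_spec(spec: DatasetSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(spec)))


def load_spec(path: str | Path) -> DatasetSpec:
    raw = yaml.safe_load(Path(path).read_text())
    for key in ("benign_axis_range", "malignant_axis_range", "spicule_count_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return DatasetSpec(**raw)
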