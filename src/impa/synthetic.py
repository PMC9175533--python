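"""Synthetic inputs: benchmark objectives and a two-class image generator.

The image generator emulates the structure of a screening task at desk
scale: class 0 is a smooth random background texture, class 1 is the
same texture plus one bright elliptical blob of random position and
eccentricity.  The ``separation`` parameter is the blob's contrast in
units of the texture's pixel standard deviation, giving a graded
difficulty dial — at separation >= 3 a plain mean-intensity threshold
already classifies well, so a small CNN must too.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from PIL import Image
from scipy import ndimage

from impa.driver import ObjectiveAdapter
from impa.search_space import DimensionSpec, SearchSpace

__all__ = [
    "BenchmarkObjective",
    "LabeledImageSet",
    "make_benchmark",
    "generate_image_dataset",
    "stratified_split",
    "write_png_layout",
    "load_png_layout",
]


@dataclass(frozen=True)
class BenchmarkObjective:
    """A standard test function with known optimum."""

    name: str
    dimension: int
    bounds: tuple[float, float]
    global_minimum_position: np.ndarray
    global_minimum_value: float
    fn: Callable[[np.ndarray], float]

    def __call__(self, x: np.ndarray) -> float:
        return self.fn(np.asarray(x, dtype=float))

    def space(self) -> SearchSpace:
        lo, hi = self.bounds
        return SearchSpace(
            tuple(
                DimensionSpec(f"x{i}", "continuous", lo, hi)
                for i in range(self.dimension)
            )
        )

    def adapter(self) -> ObjectiveAdapter:
        return ObjectiveAdapter(self.fn, direction="minimize")


def _sphere(x: np.ndarray) -> float:
    return float(np.sum(x * x))


def _rastrigin(x: np.ndarray) -> float:
    return float(10.0 * x.size + np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x)))


def _rosenbrock(x: np.ndarray) -> float:
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


_BENCHMARKS = {
    "sphere": (_sphere, (-10.0, 10.0), 0.0, 0.0),
    "rastrigin": (_rastrigin, (-5.12, 5.12), 0.0, 0.0),
    "rosenbrock": (_rosenbrock, (-5.0, 10.0), 1.0, 0.0),
}


def make_benchmark(name: str, dimension: int = 8) -> BenchmarkObjective:
    """Build one of the standard test functions (sphere, rastrigin, rosenbrock)."""
    if name not in _BENCHMARKS:
        raise ValueError(f"unknown benchmark {name!r}; choose from {sorted(_BENCHMARKS)}")
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    fn, bounds, opt_coord, opt_val = _BENCHMARKS[name]
    return BenchmarkObjective(
        name=name,
        dimension=dimension,
        bounds=bounds,
        global_minimum_position=np.full(dimension, opt_coord),
        global_minimum_value=opt_val,
        fn=fn,
    )


@dataclass(frozen=True)
class LabeledImageSet:
    """Balanced grayscale images with binary labels; bit-reproducible per seed."""

    images: np.ndarray  # (N, H, W) floats in [0, 1]
    labels: np.ndarray  # (N,) ints, 1 = blob present (abnormal)
    seed: int
    separation: float
    contrasts: np.ndarray | None = None  # per-image blob contrast in texture SDs (0 for class 0)

    def __len__(self) -> int:
        return self.images.shape[0]

    def class_counts(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def _texture(size: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    noise = rng.standard_normal((size, size))
    smooth = ndimage.gaussian_filter(noise, sigma=1.5)
    return smooth, float(smooth.std())


def _elliptical_blob(size: int, rng: np.random.Generator) -> np.ndarray:
    cy, cx = rng.uniform(0.35 * size, 0.65 * size, size=2)
    a = rng.uniform(0.18, 0.28) * size  # semi-axes
    b = a * rng.uniform(0.6, 1.0)  # eccentricity
    theta = rng.uniform(0, np.pi)
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    yr = np.cos(theta) * y - np.sin(theta) * x
    xr = np.sin(theta) * y + np.cos(theta) * x
    d2 = (yr / a) ** 2 + (xr / b) ** 2
    return np.exp(-d2)  # smooth-edged ellipse, peak 1, e^-1 at the boundary


def generate_image_dataset(
    n_per_class: int,
    size: int = 64,
    separation: float = 4.0,
    seed: int = 0,
) -> LabeledImageSet:
    """Generate a balanced two-class blob-vs-texture image set.

    Class 1 images carry one bright elliptical blob whose peak contrast
    is ``separation`` texture standard deviations (with +-10% per-image
    jitter).  Pixel values are rescaled to [0, 1].
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if size < 16:
        raise ValueError("size must be >= 16")
    rng = np.random.default_rng(seed)
    images, labels, contrasts = [], [], []
    for label in (0, 1):
        for _ in range(n_per_class):
            tex, sd = _texture(size, rng)
            img = tex.copy()
            contrast = 0.0
            if label == 1:
                contrast = separation * (1.0 + rng.uniform(-0.1, 0.1))
                img = img + contrast * sd * _elliptical_blob(size, rng)
            images.append(img)
            labels.append(label)
            contrasts.append(contrast)
    stack = np.stack(images)
    lo, hi = stack.min(), stack.max()
    stack = (stack - lo) / (hi - lo)
    return LabeledImageSet(
        images=stack,
        labels=np.array(labels, dtype=int),
        seed=seed,
        separation=separation,
        contrasts=np.array(contrasts),
    )


def stratified_split(
    dataset: LabeledImageSet, test_fraction: float, seed: int = 0
) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Disjoint, exhaustive train/test split preserving class proportions."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in np.unique(dataset.labels):
        idx = rng.permutation(np.flatnonzero(dataset.labels == cls))
        test_idx.extend(idx[: int(round(test_fraction * idx.size))])
    mask = np.zeros(len(dataset), dtype=bool)
    mask[test_idx] = True

    def subset(m: np.ndarray) -> LabeledImageSet:
        return LabeledImageSet(
            images=dataset.images[m],
            labels=dataset.labels[m],
            seed=dataset.seed,
            separation=dataset.separation,
            contrasts=None if dataset.contrasts is None else dataset.contrasts[m],
        )

    return subset(~mask), subset(mask)


def write_png_layout(
    root: str | Path,
    train: LabeledImageSet,
    test: LabeledImageSet,
    class_names: tuple[str, str] = ("normal", "abnormal"),
) -> Path:
    """Write root/{train,test}/{class}/*.png — the loader's directory contract."""
    root = Path(root)
    for split_name, split in (("train", train), ("test", test)):
        for i, (img, label) in enumerate(zip(split.images, split.labels)):
            d = root / split_name / class_names[int(label)]
            d.mkdir(parents=True, exist_ok=True)
            arr = np.clip(img * 255.0, 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(d / f"img_{i:05d}.png")
    return root


def load_png_layout(
    root: str | Path,
    class_names: tuple[str, str] = ("normal", "abnormal"),
) -> tuple[dict[str, tuple[np.ndarray, np.ndarray]], dict[str, dict[str, int]]]:
    """Load the PNG directory layout; returns per-split arrays and class counts."""
    root = Path(root)
    splits: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    counts: dict[str, dict[str, int]] = {}
    for split_name in ("train", "test"):
        split_dir = root / split_name
        if not split_dir.is_dir():
            continue
        images, labels = [], []
        counts[split_name] = {}
        for label, cls in enumerate(class_names):
            files = sorted((split_dir / cls).glob("*.png")) if (split_dir / cls).is_dir() else []
            counts[split_name][cls] = len(files)
            for f in files:
                try:
                    with Image.open(f) as im:
                        images.append(np.asarray(im.convert("L"), dtype=float) / 255.0)
                except Exception as exc:
                    raise IOError(f"unreadable image file: {f}") from exc
                labels.append(label)
        splits[split_name] = (np.stack(images), np.array(labels, dtype=int))
    if not splits:
        raise IOError(f"no train/ or test/ split directories under {root}")
    return splits, counts
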