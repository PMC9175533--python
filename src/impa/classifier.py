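"""Transfer-learning classification harness.

A pretrained convolutional backbone is reused on a new two-class
image task: first the backbone is frozen and a fresh 8-layer dense
head is trained (feature extraction), then the last two convolutional
blocks are unfrozen and training continues jointly (fine-tuning).  The
head's widths and dropout rates, the learning rate and the batch size
are the eight quantities the optimizer searches; the harness exposes
them to the optimizer through :func:`fitness_of_config`, which scores
a candidate as 1 - validation accuracy.

The primary backbone is ``surrogate_cnn`` — a small convolutional
feature extractor with deterministic fixed weights that trains in
seconds on synthetic fixtures.  A ``resnet50`` backbone name is
reserved for runs with externally supplied pretrained weights; without
them it raises an explicit error.
"""

from __future__ import annotations

import math
import pickle
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

from impa import nn
from impa.search_space import ClassifierConfig, SearchSpace, decode

__all__ = [
    "AugmentationConfig",
    "BackboneSpec",
    "HeadSpec",
    "TrainedModel",
    "TrainingDivergedError",
    "build_head",
    "build_network",
    "preprocess",
    "augment_batch",
    "train_transfer",
    "fitness_of_config",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, config: ClassifierConfig, epoch: int):
        self.config = config
        super().__init__(
            f"non-finite loss at epoch {epoch} with config {config.as_dict()}"
        )


@dataclass(frozen=True)
class AugmentationConfig:
    """Training-stream augmentation ranges.

    Defaults are the mammography pipeline's settings: light shear and
    zoom, generous shifts, 15-degree rotations, both flips, reflect
    fill, and featurewise centring/std-normalization fitted on the
    training split.
    """

    shear: float = 0.1
    zoom: float = 0.1
    width_shift: float = 0.3
    height_shift: float = 0.3
    rotation: float = 15.0
    featurewise_center: bool = True
    featurewise_std_normalization: bool = True
    fill_mode: str = "reflect"
    vertical_flip: bool = True
    horizontal_flip: bool = True
    enabled: bool = True


@dataclass(frozen=True)
class BackboneSpec:
    """Which pretrained convolutional base to use.

    ``block_channels`` are the surrogate's per-block filter counts; the
    last two blocks are the ones unfrozen during fine-tuning.
    ``pretrain_seed`` fixes the surrogate's feature weights so every
    candidate configuration starts from the same "pretrained" base.
    """

    name: str = "surrogate_cnn"
    input_size: int = 32
    block_channels: tuple[int, ...] = (8, 8, 16)
    pretrain_seed: int = 1234

    def __post_init__(self) -> None:
        if self.name not in ("surrogate_cnn", "resnet50"):
            raise ValueError(f"unknown backbone {self.name!r}")
        if self.name == "resnet50":
            raise NotImplementedError(
                "the resnet50 backbone needs externally supplied pretrained "
                "weights and a GPU-scale training path; none are bundled — "
                "use the surrogate_cnn backbone"
            )
        if self.input_size % (2 ** len(self.block_channels)) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by "
                f"2^{len(self.block_channels)} for the pooling stack"
            )

    @property
    def feature_count(self) -> int:
        side = self.input_size // (2 ** len(self.block_channels))
        return side * side * self.block_channels[-1]

    @property
    def block_boundaries(self) -> tuple[str, str]:
        n = len(self.block_channels)
        return (f"block{n - 1}", f"block{n}")


@dataclass(frozen=True)
class HeadSpec:
    """The 8-layer replacement classifier.

    flatten; dense(u1, ReLU); dropout(r1); dense(u2, ReLU); dropout(r2);
    dense(u3, ReLU); dropout(r3); dense(1, sigmoid).
    """

    dense_units: tuple[int, int, int]
    dropout_rates: tuple[float, float, float]

    @property
    def layers(self) -> tuple[tuple[str, object], ...]:
        u, r = self.dense_units, self.dropout_rates
        return (
            ("flatten", None),
            ("dense_relu", u[0]),
            ("dropout", r[0]),
            ("dense_relu", u[1]),
            ("dropout", r[1]),
            ("dense_relu", u[2]),
            ("dropout", r[2]),
            ("dense_sigmoid", 1),
        )


def build_head(config: ClassifierConfig) -> HeadSpec:
    """Head specification carrying the optimized widths and dropout rates."""
    return HeadSpec(dense_units=config.dense_units, dropout_rates=config.dropout_rates)


def _build_backbone_blocks(spec: BackboneSpec) -> list[list[nn.Layer]]:
    rng = np.random.default_rng(spec.pretrain_seed)
    blocks: list[list[nn.Layer]] = []
    c_in = 1
    for c_out in spec.block_channels:
        blocks.append([nn.Conv2D(c_in, c_out, rng), nn.ReLU(), nn.MaxPool2()])
        c_in = c_out
    return blocks


def build_network(
    backbone: BackboneSpec, head: HeadSpec, rng: np.random.Generator
) -> tuple[nn.Sequential, list[list[nn.Layer]]]:
    """Materialize backbone + head as one layer stack.

    Returns the full network and the backbone's block structure (for
    freeze control).  The final dense layer outputs one logit; the
    sigmoid lives in the loss / prediction path.
    """
    blocks = _build_backbone_blocks(backbone)
    layers: list[nn.Layer] = [l for block in blocks for l in block]
    n_in = backbone.feature_count
    for kind, arg in head.layers:
        if kind == "flatten":
            layers.append(nn.Flatten())
        elif kind == "dense_relu":
            layers.append(nn.Dense(n_in, int(arg), rng))
            layers.append(nn.ReLU())
            n_in = int(arg)
        elif kind == "dropout":
            layers.append(nn.Dropout(float(arg), rng))
        elif kind == "dense_sigmoid":
            layers.append(nn.Dense(n_in, int(arg), rng))
    return nn.Sequential(layers), blocks


def _set_frozen(blocks: list[list[nn.Layer]], frozen: list[bool]) -> None:
    for block, fr in zip(blocks, frozen):
        for layer in block:
            layer.trainable = not fr


# ---------------------------------------------------------------------------
# Preprocessing and augmentation
# ---------------------------------------------------------------------------


def preprocess(
    images: np.ndarray | list,
    target_size: int = 32,
    denoise: bool = True,
) -> np.ndarray:
    """Resize to the backbone input size, optionally median-denoise, scale to [0, 1].

    Accepts a stack (N, H, W) or a list of 2-D grayscale arrays; RGB
    inputs are averaged to one channel.
    """
    out = []
    for img in images:
        arr = np.asarray(img, dtype=float)
        if arr.ndim == 3:  # RGB -> grayscale
            arr = arr.mean(axis=-1)
        if arr.max() > 1.0:
            arr = arr / 255.0
        if denoise:
            arr = ndimage.median_filter(arr, size=3)
        if arr.shape != (target_size, target_size):
            arr = _sk_resize(arr, (target_size, target_size), anti_aliasing=True)
        out.append(np.clip(arr, 0.0, 1.0))
    return np.stack(out)


def _random_affine(img: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = img.shape
    theta = math.radians(rng.uniform(-aug.rotation, aug.rotation))
    shear = rng.uniform(-aug.shear, aug.shear)
    zoom = 1.0 + rng.uniform(-aug.zoom, aug.zoom)
    tx = rng.uniform(-aug.height_shift, aug.height_shift) * h
    ty = rng.uniform(-aug.width_shift, aug.width_shift) * w
    c, s = math.cos(theta), math.sin(theta)
    mat = np.array([[c, -s], [s, c]]) @ np.array([[1.0, shear], [0.0, 1.0]]) / zoom
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center + np.array([tx, ty])
    out = ndimage.affine_transform(img, mat, offset=offset, order=1, mode=aug.fill_mode)
    if aug.vertical_flip and rng.uniform() < 0.5:
        out = out[::-1]
    if aug.horizontal_flip and rng.uniform() < 0.5:
        out = out[:, ::-1]
    return out


def augment_batch(
    images: np.ndarray, aug: AugmentationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Independent random geometric transform per image (training stream only)."""
    if not aug.enabled:
        return images
    return np.stack([_random_affine(img, aug, rng) for img in images])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained network plus everything needed to reproduce and reuse it."""

    network: nn.Sequential
    backbone: BackboneSpec
    head: HeadSpec
    config: ClassifierConfig
    seed: int
    history: list[dict]
    feature_mean: float = 0.0
    feature_std: float = 1.0

    def predict_scores(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid scores in [0, 1] for a stack of preprocessed images."""
        x = (np.asarray(images, dtype=float) - self.feature_mean) / self.feature_std
        logits = self.network.forward(x[:, None, :, :], train=False)
        return nn.sigmoid(logits).ravel()

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise TypeError(f"{path} does not contain a trained model artifact")
        return model


def _accuracy(scores: np.ndarray, labels: np.ndarray) -> float:
    return float(np.mean((scores >= 0.5).astype(int) == labels))


def train_transfer(
    backbone: BackboneSpec,
    head: HeadSpec,
    data: tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    config: ClassifierConfig,
    aug: AugmentationConfig | None = None,
    seed: int = 0,
    epochs: int | None = None,
    stage_split: float = 0.5,
) -> TrainedModel:
    """Two-stage transfer training.

    Stage A (feature extraction): every backbone block frozen, only the
    head trains, for ceil(stage_split * epochs) epochs.  Stage B
    (fine-tuning): the last two backbone blocks unfreeze and joint
    training continues for the remaining epochs.  Augmentation is
    applied to the training stream only; the featurewise
    centring/std-normalization is fitted on the training split and
    applied identically to both streams.

    ``data`` is ((train_images, train_labels), (val_images, val_labels))
    with images already preprocessed to the backbone's input size.
    """
    aug = aug if aug is not None else AugmentationConfig()
    epochs = epochs if epochs is not None else config.epochs
    (x_tr, y_tr), (x_val, y_val) = data
    x_tr = np.asarray(x_tr, dtype=float)
    x_val = np.asarray(x_val, dtype=float)
    y_tr = np.asarray(y_tr).astype(int)
    y_val = np.asarray(y_val).astype(int)

    mean, std = 0.0, 1.0
    if aug.featurewise_center:
        mean = float(x_tr.mean())
    if aug.featurewise_std_normalization:
        std = float(x_tr.std()) or 1.0

    rng = np.random.default_rng(seed)
    net, blocks = build_network(backbone, head, rng)
    n_blocks = len(blocks)
    optimizer = nn.Adam(lr=config.learning_rate)

    stage_a = math.ceil(stage_split * epochs)
    history: list[dict] = []
    x_val_n = (x_val - mean) / std

    for epoch in range(epochs):
        fine_tuning = epoch >= stage_a
        frozen = [True] * n_blocks
        if fine_tuning:  # unfreeze the last two convolutional blocks
            for i in range(max(0, n_blocks - 2), n_blocks):
                frozen[i] = False
        _set_frozen(blocks, frozen)

        order = rng.permutation(len(x_tr))
        xs = augment_batch(x_tr[order], aug, rng)
        xs = (xs - mean) / std
        ys = y_tr[order]

        losses = []
        for start in range(0, len(xs), config.batch_size):
            xb = xs[start : start + config.batch_size][:, None, :, :]
            yb = ys[start : start + config.batch_size]
            logits = net.forward(xb, train=True)
            loss, grad = nn.bce_with_logits(logits, yb)
            if not math.isfinite(loss):
                raise TrainingDivergedError(config, epoch)
            net.backward(grad)
            optimizer.step(net)
            losses.append(loss)

        val_scores = nn.sigmoid(net.forward(x_val_n[:, None, :, :], train=False)).ravel()
        history.append(
            {
                "epoch": epoch + 1,
                "stage": "fine_tune" if fine_tuning else "feature_extract",
                "loss": float(np.mean(losses)),
                "val_accuracy": _accuracy(val_scores, y_val),
            }
        )

    return TrainedModel(
        network=net,
        backbone=backbone,
        head=head,
        config=config,
        seed=seed,
        history=history,
        feature_mean=mean,
        feature_std=std,
    )


def stratified_indices(
    labels: np.ndarray, test_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled index split preserving proportions within one item."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    labels = np.asarray(labels)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_test = int(round(test_fraction * idx.size))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    return np.sort(np.array(train_idx)), np.sort(np.array(test_idx))


def fitness_of_config(
    position: np.ndarray,
    space: SearchSpace,
    dataset: tuple[np.ndarray, np.ndarray],
    backbone: BackboneSpec,
    budget: int = 2,
    seed: int = 0,
    aug: AugmentationConfig | None = None,
    val_fraction: float = 0.2,
) -> float:
    """Score one optimizer position: 1 - validation accuracy.

    The candidate is decoded, trained under a reduced epoch ``budget``
    on a stratified 80/20 train/validation split of ``dataset``, and
    scored on the held-out fifth.  Deterministic in (position, dataset,
    seed, budget).  A diverging training run scores the sentinel worst
    fitness 1.0.
    """
    images, labels = dataset
    config = decode(position, space)
    split_rng = np.random.default_rng(seed)
    tr, val = stratified_indices(np.asarray(labels), val_fraction, split_rng)
    data = ((images[tr], np.asarray(labels)[tr]), (images[val], np.asarray(labels)[val]))
    head = build_head(config)
    try:
        model = train_transfer(
            backbone, head, data, config, aug=aug, seed=seed, epochs=budget
        )
    except TrainingDivergedError as exc:
        warnings.warn(f"candidate diverged, scored 1.0: {exc}")
        return 1.0
    scores = model.predict_scores(images[val])
    return 1.0 - _accuracy(scores, np.asarray(labels)[val])
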