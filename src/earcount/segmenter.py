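"""Training loop and blob-counting inference for the point-supervised FCN.

The inference chain mirrors the method: forward pass → per-pixel softmax →
argmax binary mask (ties to background) → connected-component labeling →
the component count is the predicted ear count.

:class:`LCFCNCounter` wraps the whole method as a scikit-learn style
estimator: ``fit`` takes images plus per-image point annotations, ``predict``
returns integer counts, and all tunables are constructor parameters so the
estimator composes with sklearn model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator

from .backbones import SegmentationModel, build_model
from .io import AnnotatedImage
from .lcloss import _STRUCTS, lc_loss_gradient
from .nn import SGD, Adam

__all__ = [
    "TrainConfig",
    "CountPrediction",
    "count_blobs",
    "train_model",
    "predict_count",
    "save_model",
    "load_model",
    "LCFCNCounter",
]

LOG_COLUMNS = ["epoch", "L_I", "L_P", "L_S", "L_F", "total"]


@dataclass
class TrainConfig:
    """Training hyperparameters.

    Defaults are the published training recipe (batch size 1, momentum 0.9,
    weight decay 5e-4, learning rate 1e-5, 180 epochs) — tuned for a
    pretrained deep trunk; small from-scratch runs typically pass a larger
    learning rate.
    """

    backbone: str = "tiny"
    batch_size: int = 1
    momentum: float = 0.9
    weight_decay: float = 0.0005
    learning_rate: float = 1e-5
    epochs: int = 180
    seed: int = 0
    pretrained: str | None = None
    connectivity: int = 8
    topography_weight: float = 1.0
    normalize_loss: bool = False
    optimizer: str = "sgd"
    max_grad_norm: float | None = None

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")


@dataclass
class CountPrediction:
    """Binary mask, blob count and blob centroids for one image."""

    image_id: str
    binary_mask: np.ndarray
    blob_count: int
    blob_centroids: list[tuple[float, float]] = field(default_factory=list)


def count_blobs(mask: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Connected-component labeling of a binary mask."""
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary")
    labels, n = ndimage.label(mask.astype(bool), structure=_STRUCTS[connectivity])
    return labels, int(n)


def _normalize(img: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    return ((img.astype(np.float32) / 255.0) - mean) / std


def _to_batch(img: np.ndarray, stride: int) -> tuple[np.ndarray, tuple[int, int]]:
    """NCHW batch of one, edge-padded (bottom/right) to a stride multiple."""
    h, w = img.shape[:2]
    ph = (-h) % stride
    pw = (-w) % stride
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="edge")
    return img.transpose(2, 0, 1)[None], (h, w)


def _softmax2(logits: np.ndarray) -> np.ndarray:
    """(1, 2, H, W) logits → (H, W, 2) probabilities."""
    z = logits[0].transpose(1, 2, 0)
    z = z - z.max(axis=2, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=2, keepdims=True)


def forward_probabilities(
    model: SegmentationModel,
    img: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    train: bool = False,
):
    """Run the network on one uint8 image; returns (S, padded logits shape)."""
    x, (h, w) = _to_batch(_normalize(img, mean, std), model.stride)
    logits = model.forward(x, train=train)
    return _softmax2(logits)[:h, :w], logits.shape


def train_model(
    model: SegmentationModel,
    dataset: list[AnnotatedImage],
    config: TrainConfig,
    mean: np.ndarray | None = None,
    std: np.ndarray | None = None,
) -> tuple[SegmentationModel, pd.DataFrame]:
    """Optimize the model on point-annotated images; returns the loss log.

    One row per epoch with the mean of each loss term over the dataset.
    Fully deterministic given the config seed.
    """
    if not dataset:
        raise ValueError("training set is empty")
    for item in dataset:
        if item.count > item.pixels.shape[0] * item.pixels.shape[1]:
            raise ValueError(f"{item.image_id}: more points than pixels")
    if mean is None or std is None:
        mean, std = dataset_norm_stats(dataset)
    if config.optimizer == "sgd":
        opt = SGD(
            model.parameters(),
            lr=config.learning_rate,
            momentum=config.momentum,
            weight_decay=config.weight_decay,
            max_grad_norm=config.max_grad_norm,
        )
    elif config.optimizer == "adam":
        opt = Adam(
            model.parameters(),
            lr=config.learning_rate,
            weight_decay=config.weight_decay,
            max_grad_norm=config.max_grad_norm,
        )
    else:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    rng = np.random.default_rng(config.seed)
    rows = []
    n = len(dataset)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        sums = np.zeros(5)
        for start in range(0, n, config.batch_size):
            batch = order[start : start + config.batch_size]
            opt.zero_grad()
            for idx in batch:
                item = dataset[idx]
                x, (h, w) = _to_batch(
                    _normalize(item.pixels, mean, std), model.stride
                )
                logits = model.forward(x, train=True)
                s = _softmax2(logits)
                breakdown, g_s = lc_loss_gradient(
                    s[:h, :w],
                    item.points,
                    connectivity=config.connectivity,
                    topography_weight=config.topography_weight,
                    normalize=config.normalize_loss,
                )
                # softmax backward: dL/dz = S ⊙ (g − <g, S>)
                g_full = np.zeros_like(s)
                g_full[:h, :w] = g_s
                dz = s * (g_full - (g_full * s).sum(axis=2, keepdims=True))
                dlogits = dz.transpose(2, 0, 1)[None] / len(batch)
                model.backward(dlogits)
                sums += [
                    breakdown.image_level,
                    breakdown.point_level,
                    breakdown.split,
                    breakdown.false_positive,
                    breakdown.total,
                ]
            opt.step()
        rows.append([epoch + 1, *(sums / n)])
    log = pd.DataFrame(rows, columns=LOG_COLUMNS)
    return model, log


def predict_count(
    model: SegmentationModel,
    img: np.ndarray,
    mean: np.ndarray,
    std: np.ndarray,
    connectivity: int = 8,
    min_blob_size: int = 0,
    image_id: str = "",
) -> CountPrediction:
    """Fig.-4 style inference: softmax → argmax mask → blob count."""
    s, _ = forward_probabilities(model, img, mean, std, train=False)
    mask = s[..., 1] > s[..., 0]  # probability ties go to background
    labels, n = count_blobs(mask, connectivity)
    if min_blob_size > 0 and n:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        keep = np.flatnonzero(sizes >= min_blob_size) + 1
        mask = np.isin(labels, keep)
        labels, n = count_blobs(mask, connectivity)
    centroids = [
        (float(r), float(c))
        for r, c in ndimage.center_of_mass(mask, labels, range(1, n + 1))
    ]
    return CountPrediction(
        image_id=image_id, binary_mask=mask.astype(np.uint8),
        blob_count=n, blob_centroids=centroids,
    )


def dataset_norm_stats(dataset: list[AnnotatedImage]) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean/sd of the training images on the [0, 1] scale."""
    pixels = np.concatenate(
        [item.pixels.reshape(-1, 3).astype(np.float32) / 255.0 for item in dataset]
    )
    return pixels.mean(axis=0), np.maximum(pixels.std(axis=0), 1e-6)


def save_model(
    out_dir: str | Path,
    model: SegmentationModel,
    config: TrainConfig,
    mean: np.ndarray,
    std: np.ndarray,
) -> None:
    """Serialize weights plus config and seed for exact reproducibility."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savez(out / "weights.npz", mean=mean, std=std, **model.state_arrays())
    (out / "config.json").write_text(
        json.dumps({**config.__dict__, "backbone_seed": model.seed}, indent=2)
    )


def load_model(
    model_dir: str | Path,
) -> tuple[SegmentationModel, TrainConfig, np.ndarray, np.ndarray]:
    out = Path(model_dir)
    raw = json.loads((out / "config.json").read_text())
    seed = raw.pop("backbone_seed")
    config = TrainConfig(**raw)
    model = build_model(config.backbone, seed=seed)
    with np.load(out / "weights.npz") as data:
        state = dict(data)
    mean, std = state.pop("mean"), state.pop("std")
    model.load_state_arrays(state)
    return model, config, mean, std


class LCFCNCounter(BaseEstimator):
    """Point-supervised ear counter as a scikit-learn estimator.

    Parameters mirror :class:`TrainConfig`.  ``fit`` accepts either a list
    of :class:`AnnotatedImage` (``y=None``) or a list of H×W×3 uint8 arrays
    with ``y`` a list of per-image ``(row, col)`` point sequences.
    ``predict`` returns an integer count per image.
    """

    def __init__(
        self,
        backbone: str = "tiny",
        learning_rate: float = 1e-5,
        momentum: float = 0.9,
        weight_decay: float = 0.0005,
        batch_size: int = 1,
        epochs: int = 180,
        connectivity: int = 8,
        topography_weight: float = 1.0,
        normalize_loss: bool = False,
        optimizer: str = "sgd",
        max_grad_norm: float | None = None,
        min_blob_size: int = 0,
        seed: int = 0,
        pretrained: str | None = None,
    ):
        self.backbone = backbone
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.connectivity = connectivity
        self.topography_weight = topography_weight
        self.normalize_loss = normalize_loss
        self.optimizer = optimizer
        self.max_grad_norm = max_grad_norm
        self.min_blob_size = min_blob_size
        self.seed = seed
        self.pretrained = pretrained

    def _as_dataset(self, X, y=None) -> list[AnnotatedImage]:
        if y is None:
            if not all(isinstance(x, AnnotatedImage) for x in X):
                raise ValueError("y is required unless X holds AnnotatedImage items")
            return list(X)
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        return [
            AnnotatedImage(pixels=np.asarray(img), points=list(pts), image_id=str(i))
            for i, (img, pts) in enumerate(zip(X, y))
        ]

    def _config(self) -> TrainConfig:
        return TrainConfig(
            backbone=self.backbone,
            batch_size=self.batch_size,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.seed,
            pretrained=self.pretrained,
            connectivity=self.connectivity,
            topography_weight=self.topography_weight,
            normalize_loss=self.normalize_loss,
            optimizer=self.optimizer,
            max_grad_norm=self.max_grad_norm,
        )

    def fit(self, X, y=None) -> "LCFCNCounter":
        dataset = self._as_dataset(X, y)
        config = self._config()
        self.norm_mean_, self.norm_std_ = dataset_norm_stats(dataset)
        self.model_ = build_model(self.backbone, seed=self.seed, pretrained=self.pretrained)
        self.model_, self.loss_log_ = train_model(
            self.model_, dataset, config, self.norm_mean_, self.norm_std_
        )
        return self

    def predict_single(self, img, image_id: str = "") -> CountPrediction:
        img = img.pixels if isinstance(img, AnnotatedImage) else np.asarray(img)
        return predict_count(
            self.model_,
            img,
            self.norm_mean_,
            self.norm_std_,
            connectivity=self.connectivity,
            min_blob_size=self.min_blob_size,
            image_id=image_id,
        )

    def predict(self, X) -> np.ndarray:
        return np.array(
            [self.predict_single(x, image_id=str(i)).blob_count for i, x in enumerate(X)]
        )

    def score(self, X, y) -> float:
        """Negative mean absolute count error (sklearn: larger is better)."""
        pred = self.predict(X)
        return -float(np.mean(np.abs(pred - np.asarray(y, dtype=float))))
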