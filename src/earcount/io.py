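"""Domain types and readers/writers for images, point annotations, counts, splits.

The package-wide coordinate convention is 0-based ``(row, col)`` with the
origin at the top-left pixel.  LabelMe documents store ``(x, y)`` point
coordinates; they are converted to ``(row, col)`` at the reader boundary and
nowhere else.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "AnnotatedImage",
    "DatasetSplit",
    "read_image",
    "write_image",
    "read_point_mask",
    "write_point_mask",
    "read_labelme_points",
    "read_counts_csv",
    "write_counts_csv",
    "split_dataset",
    "load_dataset",
    "save_dataset",
]


@dataclass
class AnnotatedImage:
    """An RGB raster plus its point annotations (one point per ear).

    Attributes
    ----------
    pixels : ndarray of shape (H, W, 3), uint8
    points : list of (row, col) int tuples, one per annotated ear
    image_id : str
    """

    pixels: np.ndarray
    points: list[tuple[int, int]]
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8, got {self.pixels.dtype}")
        pts = [(int(r), int(c)) for r, c in self.points]
        h, w = self.pixels.shape[:2]
        for r, c in pts:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"point ({r}, {c}) outside {h}×{w} raster")
        deduped = list(dict.fromkeys(pts))
        if len(deduped) < len(pts):
            warnings.warn(
                f"{len(pts) - len(deduped)} duplicate annotation point(s) dropped "
                f"for image {self.image_id!r}",
                stacklevel=2,
            )
        self.points = deduped

    @property
    def count(self) -> int:
        """Ground-truth ear count; always equals the number of points."""
        return len(self.points)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class DatasetSplit:
    """A train/test partition of image ids at a fixed ratio (e.g. 7:3)."""

    train_ids: list[str]
    test_ids: list[str]
    ratio: tuple[int, int] = (7, 3)
    seed: int | None = None

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test ids overlap: {sorted(overlap)[:5]}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an H×W×3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    Image.fromarray(np.asarray(pixels, dtype=np.uint8)).save(path)


def read_point_mask(
    mask: np.ndarray | str | Path,
    image_shape: tuple[int, int] | None = None,
) -> list[tuple[int, int]]:
    """Extract annotation points from a single-channel point mask.

    Every nonzero pixel marks one ear.  Points are returned in row-major
    order.  If ``image_shape`` is given the mask must match it exactly.
    """
    if not isinstance(mask, np.ndarray):
        with Image.open(mask) as im:
            mask = np.asarray(im)
        if mask.ndim == 3:  # e.g. an RGB mask of red dots
            mask = mask.max(axis=2)
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"point mask must be single-channel, got shape {mask.shape}")
    if image_shape is not None and tuple(mask.shape) != tuple(image_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match image shape {tuple(image_shape)}"
        )
    rows, cols = np.nonzero(mask)
    return [(int(r), int(c)) for r, c in zip(rows, cols)]


def write_point_mask(
    points: list[tuple[int, int]],
    shape: tuple[int, int],
    path: str | Path | None = None,
) -> np.ndarray:
    """Render points as a single-channel uint8 mask (255 at each point).

    Round-trips with :func:`read_point_mask` for deduplicated point lists.
    """
    h, w = shape
    mask = np.zeros((h, w), dtype=np.uint8)
    for r, c in points:
        if not (0 <= r < h and 0 <= c < w):
            raise ValueError(f"point ({r}, {c}) out of bounds for shape {shape}")
        mask[r, c] = 255
    if path is not None:
        Image.fromarray(mask).save(path)
    return mask


def read_labelme_points(doc: dict | str | Path) -> list[tuple[int, int]]:
    """Read point annotations from a LabelMe JSON document.

    LabelMe stores ``(x, y)``; the result is ``(row, col)``.  Non-point
    shapes are skipped with a warning.
    """
    if not isinstance(doc, dict):
        text = Path(doc).read_text()
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"malformed LabelMe document: {exc}") from exc
    if "shapes" not in doc:
        raise ValueError("malformed LabelMe document: no 'shapes' key")
    points: list[tuple[int, int]] = []
    skipped = 0
    for shape in doc["shapes"]:
        if shape.get("shape_type") != "point":
            skipped += 1
            continue
        (x, y), *extra = shape["points"]
        points.append((int(round(y)), int(round(x))))
    if skipped:
        warnings.warn(f"skipped {skipped} non-point shape(s)", stacklevel=2)
    return points


def read_counts_csv(path: str | Path) -> dict[str, int]:
    """Read an ``image_id,count`` CSV into an ordered mapping."""
    df = pd.read_csv(path, dtype={"image_id": str})
    if list(df.columns) != ["image_id", "count"]:
        raise ValueError(f"expected header image_id,count; got {list(df.columns)}")
    return dict(zip(df["image_id"], df["count"].astype(int)))


def write_counts_csv(counts: dict[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"image_id": list(counts), "count": [int(v) for v in counts.values()]}
    ).to_csv(path, index=False)


def split_dataset(
    ids: list[str], ratio: tuple[int, int] = (7, 3), seed: int = 0
) -> DatasetSplit:
    """Randomly partition image ids into train/test at the given ratio.

    The train size is ``round(n * ratio[0] / sum(ratio))``; shuffling is
    deterministic under ``seed``.
    """
    if not ids:
        raise ValueError("cannot split an empty id list")
    a, b = ratio
    if a <= 0 or b <= 0:
        raise ValueError(f"ratio components must be positive, got {ratio}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n_train = int(round(len(order) * a / (a + b)))
    return DatasetSplit(
        train_ids=order[:n_train], test_ids=order[n_train:], ratio=(a, b), seed=seed
    )


def save_dataset(dataset: list[AnnotatedImage], out_dir: str | Path) -> None:
    """Write a dataset in the on-disk layout: ``images/``, ``masks/``, counts.csv."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    for item in dataset:
        write_image(out / "images" / f"{item.image_id}.png", item.pixels)
        write_point_mask(item.points, item.shape, out / "masks" / f"{item.image_id}.png")
        counts[item.image_id] = item.count
    write_counts_csv(counts, out / "counts.csv")


def load_dataset(in_dir: str | Path) -> list[AnnotatedImage]:
    """Read a dataset written by :func:`save_dataset`."""
    root = Path(in_dir)
    counts = read_counts_csv(root / "counts.csv")
    dataset = []
    for image_id in counts:
        pixels = read_image(root / "images" / f"{image_id}.png")
        points = read_point_mask(
            root / "masks" / f"{image_id}.png", image_shape=pixels.shape[:2]
        )
        item = AnnotatedImage(pixels=pixels, points=points, image_id=image_id)
        if item.count != counts[image_id]:
            raise ValueError(
                f"{image_id}: counts.csv says {counts[image_id]}, mask has {item.count}"
            )
        dataset.append(item)
    return dataset
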