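"""Classical image-processing ear counter (no learning).

A seven-step pipeline over the intensity channel of the HSI decomposition:

1. convert RGB to HSI and keep the intensity component I = (R+G+B)/3;
2. binarize I (Otsu by default);
3. area-filter the binary mask twice — a small-area pass for dirt/grain
   noise, then the main pass — to obtain the denoised foreground;
4. open the denoised mask (erosion then dilation with a disk) so that thin
   ears vanish while broad leaves survive: the "leaf image";
5. XOR the denoised mask with the leaf image, leaving the thin ears;
6. drop residual components smaller than the minimum ear area;
7. the surviving connected-component count is the ear count.

The pipeline is only sound when the erosion radius exceeds the ear
half-width and stays below the leaf half-width; the fixture configs in the
tests document this constraint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from sklearn.base import BaseEstimator
from skimage import filters, morphology

from .segmenter import count_blobs

__all__ = ["BaselineConfig", "rgb_to_intensity", "baseline_count", "ClassicalEarCounter"]


@dataclass
class BaselineConfig:
    binarize_method: str = "otsu"
    fixed_threshold: float | None = None
    min_noise_area: int = 4
    erosion_radius: int = 2
    dilation_radius: int = 2
    min_ear_area: int = 6
    connectivity: int = 8

    def __post_init__(self) -> None:
        if self.erosion_radius < 1 or self.dilation_radius < 1:
            raise ValueError("morphology radii must be >= 1")
        if self.min_noise_area < 0 or self.min_ear_area < 0:
            raise ValueError("area thresholds must be >= 0")
        if self.binarize_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown binarize_method {self.binarize_method!r}")
        if self.binarize_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed binarization needs fixed_threshold")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "BaselineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))


def rgb_to_intensity(image: np.ndarray) -> np.ndarray:
    """HSI intensity component, I = (R+G+B)/3, scaled to [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image, got shape {image.shape}")
    return image.astype(float).mean(axis=2) / 255.0


def _remove_small(mask: np.ndarray, min_area: int, connectivity: int) -> np.ndarray:
    if min_area <= 0:
        return mask
    labels, n = count_blobs(mask, connectivity)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_area) + 1
    return np.isin(labels, keep)


def baseline_count(
    image: np.ndarray, config: BaselineConfig | None = None
) -> tuple[int, dict[str, np.ndarray]]:
    """Run the seven steps; returns the count and every intermediate mask."""
    config = config or BaselineConfig()
    intensity = rgb_to_intensity(image)
    if config.binarize_method == "otsu":
        thresh = float(filters.threshold_otsu(intensity))
    else:
        thresh = float(config.fixed_threshold)
    binary = intensity > thresh

    denoised = _remove_small(binary, config.min_noise_area, config.connectivity)
    denoised = _remove_small(denoised, config.min_noise_area * 2, config.connectivity)

    leaf = morphology.erosion(denoised, morphology.disk(config.erosion_radius))
    leaf = morphology.dilation(leaf, morphology.disk(config.dilation_radius))

    ears = np.logical_xor(denoised, leaf) & denoised  # XOR may resurrect leaf rims
    ears = _remove_small(ears, config.min_ear_area, config.connectivity)
    labels, count = count_blobs(ears, config.connectivity)
    intermediates = {
        "intensity": intensity,
        "binary": binary,
        "denoised": denoised,
        "leaf": leaf,
        "ears": ears,
        "labels": labels,
    }
    return count, intermediates


class ClassicalEarCounter(BaseEstimator):
    """The classical pipeline wrapped as a (fit-free) sklearn estimator."""

    def __init__(
        self,
        binarize_method: str = "otsu",
        fixed_threshold: float | None = None,
        min_noise_area: int = 4,
        erosion_radius: int = 2,
        dilation_radius: int = 2,
        min_ear_area: int = 6,
        connectivity: int = 8,
    ):
        self.binarize_method = binarize_method
        self.fixed_threshold = fixed_threshold
        self.min_noise_area = min_noise_area
        self.erosion_radius = erosion_radius
        self.dilation_radius = dilation_radius
        self.min_ear_area = min_ear_area
        self.connectivity = connectivity

    def _config(self) -> BaselineConfig:
        return BaselineConfig(**self.get_params())

    def fit(self, X=None, y=None) -> "ClassicalEarCounter":
        """No learning; present for pipeline compatibility."""
        self.config_ = self._config()
        return self

    def predict(self, X) -> np.ndarray:
        config = self._config()
        counts = []
        for img in X:
            pixels = getattr(img, "pixels", img)
            counts.append(baseline_count(np.asarray(pixels), config)[0])
        return np.array(counts)
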