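"""Localization-counting loss for point-supervised segmentation.

The loss scores a per-pixel softmax map ``S`` (channel 0 = background,
channel 1 = ear) against point annotations ``T`` — one pixel per object —
as the sum of four non-negative terms:

* **image-level**: the classes present in the image (always the background;
  the ear class iff at least one point exists) must each be predicted with
  high confidence somewhere; absent classes must be predicted nowhere.
* **point-level**: every annotated pixel must be classified as ear.
  Unlabeled pixels are ignored by this term.
* **split**: a predicted blob (connected foreground component of
  ``argmax S``) containing two or more annotation points is straddling
  several ears; watershed ridge pixels between the points are pushed
  towards background, weighted by the number of points in the blob.
* **false positive**: every pixel of a blob containing no annotation point
  is pushed towards background.

A perfect prediction — one blob per point, nothing else — has zero loss.

The watershed used for the split term is a deterministic *geodesic midline*
variant.  Within each multi-point blob, each pixel's travel cost from every
seed is the sum of per-step costs ``1 + topography_weight * (1 - S_ear)``
over an 8-connected shortest path; pixels belong to the basin of their
cheapest seed (ties to the lowest seed index), and wherever two basins
touch, the pixel of the touching pair whose best/second-best cost margin is
smaller joins the ridge set (both on an exact tie).  The rule is
order-independent, reduces to the equidistant midline for uniform maps,
separates every pair of adjacent basins by construction, and never includes
a seed pixel.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BlobLabeling",
    "LossBreakdown",
    "check_probability_map",
    "compute_blobs",
    "image_level_loss",
    "point_level_loss",
    "watershed_boundaries",
    "split_loss",
    "false_positive_loss",
    "lc_loss",
    "lc_loss_gradient",
]

CLAMP = 1e-12  # floor for log arguments

_STRUCTS = {4: ndimage.generate_binary_structure(2, 1), 8: np.ones((3, 3), bool)}


def check_probability_map(s: np.ndarray) -> np.ndarray:
    """Validate an H×W×2 softmax field (non-negative, rows sum to 1)."""
    s = np.asarray(s, dtype=float)
    if s.ndim != 3 or s.shape[2] != 2:
        raise ValueError(f"probability map must be H×W×2, got {s.shape}")
    if (s < -1e-9).any():
        raise ValueError("probabilities must be non-negative")
    if not np.allclose(s.sum(axis=2), 1.0, atol=1e-6):
        raise ValueError("per-pixel probabilities must sum to 1")
    return s


@dataclass
class BlobLabeling:
    """Connected foreground components with per-blob annotation tallies."""

    labels: np.ndarray  # H×W int, 0 = background
    points_per_blob: dict[int, int]

    @property
    def n_blobs(self) -> int:
        return int(self.labels.max())


@dataclass
class LossBreakdown:
    image_level: float
    point_level: float
    split: float
    false_positive: float

    @property
    def total(self) -> float:
        return self.image_level + self.point_level + self.split + self.false_positive


def _log(x):
    return np.log(np.maximum(x, CLAMP))


def compute_blobs(
    s: np.ndarray, points, connectivity: int = 8
) -> BlobLabeling:
    """Label foreground blobs of ``argmax S`` and tally points per blob.

    Ties (ear probability exactly 0.5) go to background.
    """
    s = check_probability_map(s)
    fg = s[..., 1] > s[..., 0]
    labels, n = ndimage.label(fg, structure=_STRUCTS[connectivity])
    tally = {k: 0 for k in range(1, n + 1)}
    for r, c in points:
        lab = int(labels[r, c])
        if lab > 0:
            tally[lab] += 1
    return BlobLabeling(labels=labels, points_per_blob=tally)


def image_level_loss(s: np.ndarray, points) -> float:
    """Presence/absence term over the per-class maxima of ``S``."""
    s = check_probability_map(s)
    max_bg = s[..., 0].max()
    max_ear = s[..., 1].max()
    if len(points) > 0:
        return float(-(_log(max_bg) + _log(max_ear)) / 2.0)
    return float(-_log(max_bg) - _log(1.0 - max_ear))


def point_level_loss(s: np.ndarray, points) -> float:
    """Negative log ear-probability summed over the annotated pixels."""
    s = check_probability_map(s)
    return float(-sum(_log(s[r, c, 1]) for r, c in points))


def _blob_seed_costs(
    cost: np.ndarray, blob: np.ndarray, seeds: list[tuple[int, int]]
) -> np.ndarray:
    """Per-seed geodesic costs over the blob (Dijkstra, 8-connected)."""
    h, w = blob.shape
    out = np.full((len(seeds), h, w), np.inf)
    offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for k, seed in enumerate(seeds):
        dist = out[k]
        dist[seed] = 0.0
        heap = [(0.0, seed)]
        while heap:
            d, (r, c) = heapq.heappop(heap)
            if d > dist[r, c]:
                continue
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and blob[rr, cc]:
                    nd = d + cost[rr, cc]
                    if nd < dist[rr, cc] - 1e-12:
                        dist[rr, cc] = nd
                        heapq.heappush(heap, (nd, (rr, cc)))
    return out


def watershed_boundaries(
    s: np.ndarray,
    points,
    connectivity: int = 8,
    topography_weight: float = 1.0,
    labeling: BlobLabeling | None = None,
) -> np.ndarray:
    """Ridge pixels separating the annotation points inside each blob.

    Returns a boolean H×W mask ``E``.  Blobs containing at most one point
    contribute nothing; seed pixels are never ridge pixels.
    """
    s = check_probability_map(s)
    if labeling is None:
        labeling = compute_blobs(s, points, connectivity)
    e = np.zeros(s.shape[:2], dtype=bool)
    cost = 1.0 + topography_weight * (1.0 - s[..., 1])
    for lab, n_pts in labeling.points_per_blob.items():
        if n_pts < 2:
            continue
        blob = labeling.labels == lab
        seeds = [(r, c) for r, c in points if blob[r, c]]
        dists = _blob_seed_costs(cost, blob, seeds)
        basin = np.argmin(dists, axis=0)  # ties -> lowest seed index
        order = np.sort(dists, axis=0)
        with np.errstate(invalid="ignore"):  # inf-inf outside the blob
            margin = np.where(blob, order[1] - order[0], np.inf)
        ridge = np.zeros_like(blob)
        h, w = blob.shape
        for dr, dc in [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]:
            here = np.zeros_like(blob)
            src = (
                slice(max(0, -dr), h - max(0, dr)),
                slice(max(0, -dc), w - max(0, dc)),
            )
            dst = (
                slice(max(0, dr), h - max(0, -dr)),
                slice(max(0, dc), w - max(0, -dc)),
            )
            cross = blob[src] & blob[dst] & (basin[src] != basin[dst])
            here[src] = cross & (margin[src] <= margin[dst] + 1e-9)
            ridge |= here
        for seed in seeds:
            ridge[seed] = False
        e |= ridge
    return e


def split_loss(
    s: np.ndarray,
    e: np.ndarray,
    labeling: BlobLabeling,
    printed_variant: bool = False,
    normalize: bool = False,
) -> float:
    """Push watershed ridge pixels towards background.

    Each ridge pixel is weighted by the number of annotation points in its
    blob.  ``printed_variant`` switches to the mean ear-side probability
    over the ridge set (an alternative formulation that also vanishes for
    confident background ridges).
    """
    s = check_probability_map(s)
    if not e.any():
        return 0.0
    alpha = np.zeros(s.shape[:2])
    for lab, n_pts in labeling.points_per_blob.items():
        alpha[labeling.labels == lab] = n_pts
    if printed_variant:
        return float(s[..., 0][e].sum() / e.sum())
    val = float(-(alpha[e] * _log(s[..., 0][e])).sum())
    return val / e.sum() if normalize else val


def false_positive_loss(
    s: np.ndarray, labeling: BlobLabeling, normalize: bool = False
) -> float:
    """Push every pixel of a point-free blob towards background."""
    s = check_probability_map(s)
    fp_labels = [lab for lab, n in labeling.points_per_blob.items() if n == 0]
    if not fp_labels:
        return 0.0
    mask = np.isin(labeling.labels, fp_labels)
    val = float(-_log(s[..., 0][mask]).sum())
    return val / mask.sum() if normalize else val


def lc_loss(
    s: np.ndarray,
    points,
    connectivity: int = 8,
    topography_weight: float = 1.0,
    printed_split_variant: bool = False,
    normalize: bool = False,
) -> LossBreakdown:
    """All four loss terms for one image."""
    s = check_probability_map(s)
    labeling = compute_blobs(s, points, connectivity)
    e = watershed_boundaries(
        s, points, connectivity, topography_weight, labeling=labeling
    )
    return LossBreakdown(
        image_level=image_level_loss(s, points),
        point_level=point_level_loss(s, points),
        split=split_loss(s, e, labeling, printed_split_variant, normalize),
        false_positive=false_positive_loss(s, labeling, normalize),
    )


def _safe_inv(x):
    """d(-log max(x, CLAMP))/dx: zero inside the clamped region."""
    return np.where(x > CLAMP, 1.0 / np.maximum(x, CLAMP), 0.0)


def lc_loss_gradient(
    s: np.ndarray,
    points,
    connectivity: int = 8,
    topography_weight: float = 1.0,
    normalize: bool = False,
) -> tuple[LossBreakdown, np.ndarray]:
    """Loss and its analytic gradient with respect to ``S``.

    The combinatorial structure (blob labels, ridge set, per-class argmax
    pixels) is treated as locally constant, which holds away from argmax
    ties and decision boundaries.
    """
    s = check_probability_map(s)
    labeling = compute_blobs(s, points, connectivity)
    e = watershed_boundaries(
        s, points, connectivity, topography_weight, labeling=labeling
    )
    breakdown = LossBreakdown(
        image_level=image_level_loss(s, points),
        point_level=point_level_loss(s, points),
        split=split_loss(s, e, labeling, normalize=normalize),
        false_positive=false_positive_loss(s, labeling, normalize=normalize),
    )
    grad = np.zeros_like(s)

    # image-level: gradient concentrates at the per-class argmax pixels
    bg_flat = int(np.argmax(s[..., 0]))
    ear_flat = int(np.argmax(s[..., 1]))
    h, w = s.shape[:2]
    bg_idx, ear_idx = divmod(bg_flat, w), divmod(ear_flat, w)
    if len(points) > 0:
        grad[bg_idx[0], bg_idx[1], 0] += -0.5 * _safe_inv(s[..., 0].max())
        grad[ear_idx[0], ear_idx[1], 1] += -0.5 * _safe_inv(s[..., 1].max())
    else:
        grad[bg_idx[0], bg_idx[1], 0] += -_safe_inv(s[..., 0].max())
        one_minus = 1.0 - s[..., 1].max()
        grad[ear_idx[0], ear_idx[1], 1] += _safe_inv(one_minus)

    for r, c in points:
        grad[r, c, 1] += -_safe_inv(s[r, c, 1])

    if e.any():
        alpha = np.zeros((h, w))
        for lab, n_pts in labeling.points_per_blob.items():
            alpha[labeling.labels == lab] = n_pts
        scale = 1.0 / e.sum() if normalize else 1.0
        grad[..., 0][e] += -scale * alpha[e] * _safe_inv(s[..., 0][e])

    fp_labels = [lab for lab, n in labeling.points_per_blob.items() if n == 0]
    if fp_labels:
        mask = np.isin(labeling.labels, fp_labels)
        scale = 1.0 / mask.sum() if normalize else 1.0
        grad[..., 0][mask] += -scale * _safe_inv(s[..., 0][mask])

    return breakdown, grad
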