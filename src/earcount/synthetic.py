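"""Synthetic quadrat-image generator with exact ground truth.

Emulates the structure of dense rice-ear field photographs taken over a red
quadrat frame: a green canopy background built from broad leaf strokes,
elongated bright yellowish ears with speckled grain texture, controllable
overlap, per-image illumination, optional red frame, and exactly one
annotation point per ear.  Realism is bounded by design — the generator
targets the statistical structure a counting model must cope with (density,
occlusion, variable light), not photorealism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from skimage import draw as skdraw

from .io import AnnotatedImage, save_dataset

__all__ = [
    "EarGeometry",
    "FieldSimConfig",
    "simulate_image",
    "simulate_dataset",
    "quality_preset",
]


@dataclass
class EarGeometry:
    """Pixel-scale geometry of a rendered ear (an elongated ellipse)."""

    length: tuple[float, float] = (10.0, 18.0)
    width: tuple[float, float] = (3.0, 5.0)
    orientation_deg: tuple[float, float] = (0.0, 180.0)


@dataclass
class FieldSimConfig:
    """Parameters of the synthetic field scene.

    ``count_law`` is ``("fixed", k)``, ``("uniform", lo, hi)`` (inclusive
    integer range) or ``("poisson", mean)``.  ``illumination`` is the range
    of a per-image global brightness multiplier; ``color_cast`` multiplies
    the RGB channels (used by the red-shifted quality preset).
    """

    image_size: tuple[int, int] = (96, 96)
    count_law: tuple = ("uniform", 5, 25)
    ear_geometry: EarGeometry = field(default_factory=EarGeometry)
    overlap_fraction: float = 0.3
    illumination: tuple[float, float] = (0.75, 1.25)
    red_frame: bool = False
    frame_thickness: int = 5
    frame_margin: int = 6
    frame_angle_deg: float = 0.0
    noise_sd: float = 8.0
    color_cast: tuple[float, float, float] = (1.0, 1.0, 1.0)
    leaf_density: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError(f"image_size must be at least 32×32, got {h}×{w}")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        kind = self.count_law[0]
        if kind not in ("fixed", "uniform", "poisson"):
            raise ValueError(f"unknown count_law kind {kind!r}")
        if kind in ("fixed", "uniform") and any(v < 0 for v in self.count_law[1:]):
            raise ValueError("count_law support must be non-negative")
        if self.ear_geometry.length[1] >= min(h, w) - 2 * (
            self.frame_margin + self.frame_thickness + 2 if self.red_frame else 1
        ):
            raise ValueError("ear geometry cannot fit inside the image")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FieldSimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "ear_geometry" in raw:
            geo = raw.pop("ear_geometry")
            raw["ear_geometry"] = EarGeometry(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in geo.items()}
            )
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()}
        return cls(**raw)


def quality_preset(level: str, **overrides) -> FieldSimConfig:
    """Preset configs emulating the three acquisition-quality levels.

    ``"A"`` — clear, low noise; ``"B"`` — noisy; ``"C"`` — reddish cast,
    hardest to segment.
    """
    presets = {
        "A": dict(noise_sd=4.0, illumination=(0.9, 1.15)),
        "B": dict(noise_sd=18.0, illumination=(0.7, 1.3)),
        "C": dict(noise_sd=12.0, color_cast=(1.3, 0.85, 0.85)),
    }
    if level not in presets:
        raise ValueError(f"unknown quality level {level!r}; expected A, B or C")
    return FieldSimConfig(**{**presets[level], **overrides})


def _sample_count(law: tuple, rng: np.random.Generator) -> int:
    kind = law[0]
    if kind == "fixed":
        return int(law[1])
    if kind == "uniform":
        return int(rng.integers(law[1], law[2] + 1))
    return int(rng.poisson(law[1]))


def _rotate(points: np.ndarray, center: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return (points - center) @ rot.T + center


def _draw_frame(
    pixels: np.ndarray, cfg: FieldSimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Paint the red quadrat ring; return (inner-edge corners, hole mask).

    Corners are the intersections of the four inner-edge lines, i.e. the
    outermost red pixels a ray from the center meets — the same geometry
    the frame detector estimates.
    """
    h, w = pixels.shape[:2]
    a_out = float(cfg.frame_margin)
    a_in = a_out + cfg.frame_thickness
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])

    def quad(margin_r: float, margin_c: float) -> np.ndarray:
        return np.array(
            [
                [margin_r, margin_c],
                [margin_r, w - 1 - margin_c],
                [h - 1 - margin_r, w - 1 - margin_c],
                [h - 1 - margin_r, margin_c],
            ],
            dtype=float,
        )

    outer = _rotate(quad(a_out, a_out), center, cfg.frame_angle_deg)
    inner = _rotate(quad(a_in, a_in), center, cfg.frame_angle_deg)
    ring = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.polygon(outer[:, 0], outer[:, 1], shape=(h, w))
    ring[rr, cc] = True
    hole = np.zeros((h, w), dtype=bool)
    rr, cc = skdraw.polygon(inner[:, 0], inner[:, 1], shape=(h, w))
    hole[rr, cc] = True
    ring &= ~hole
    red = np.array([205, 35, 30], dtype=float)
    pixels[ring] = red + rng.normal(0, 6, size=(int(ring.sum()), 3))
    # inner-edge corners: the hole boundary, i.e. inner quad shrunk by ~1 px
    corners = _rotate(quad(a_in - 1, a_in - 1), center, cfg.frame_angle_deg)
    return corners, hole


def _paint_leaves(
    pixels: np.ndarray, cfg: FieldSimConfig, rng: np.random.Generator
) -> None:
    h, w = pixels.shape[:2]
    n_leaves = max(3, int(cfg.leaf_density * h * w / 500))
    for _ in range(n_leaves):
        r0, c0 = rng.uniform(0, h), rng.uniform(0, w)
        length = rng.uniform(0.2 * min(h, w), 0.5 * min(h, w))
        width = rng.uniform(4, 9)
        theta = rng.uniform(0, np.pi)
        shade = rng.uniform(0.55, 1.35)
        color = np.array([38, 86, 34]) * shade
        rr, cc = skdraw.ellipse(
            r0, c0, length / 2, width / 2, shape=(h, w), rotation=theta
        )
        pixels[rr, cc] = 0.65 * pixels[rr, cc] + 0.35 * color


def _place_ears(
    cfg: FieldSimConfig,
    n: int,
    allowed: np.ndarray,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Sample ``n`` ear support masks honouring the overlap fraction."""
    h, w = cfg.image_size
    geo = cfg.ear_geometry
    occupied = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)  # occupied, dilated: touching guard
    masks: list[np.ndarray] = []
    centers: list[tuple[float, float]] = []
    for k in range(n):
        want_overlap = bool(masks) and rng.random() < cfg.overlap_fraction
        placed = False
        for attempt in range(600):
            length = rng.uniform(*geo.length)
            width = rng.uniform(*geo.width)
            theta = np.deg2rad(rng.uniform(*geo.orientation_deg))
            if want_overlap and attempt < 300:
                br, bc = centers[int(rng.integers(len(centers)))]
                r0 = br + rng.normal(0, length / 2)
                c0 = bc + rng.normal(0, length / 2)
                r0, c0 = np.clip(r0, 0, h - 1), np.clip(c0, 0, w - 1)
            else:
                r0, c0 = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
            if not allowed[int(round(r0)), int(round(c0))]:
                continue
            mask = np.zeros((h, w), dtype=bool)
            rr, cc = skdraw.ellipse(
                r0, c0, length / 2, max(width / 2, 1.0), shape=(h, w), rotation=theta
            )
            mask[rr, cc] = True
            mask &= allowed
            if not mask.any():
                continue
            touches = (mask & blocked).any()
            if want_overlap and touches and (mask & ~occupied).sum() >= 4:
                pass  # overlapping placement, but the ear keeps visible pixels
            elif not touches:
                pass  # disjoint placement
            else:
                continue
            masks.append(mask)
            centers.append((r0, c0))
            occupied |= mask
            blocked = ndimage.binary_dilation(occupied, structure=np.ones((3, 3)))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"could not place ear {k + 1}/{n}; geometry too large for the scene"
            )
    return masks


def simulate_image(
    config: FieldSimConfig,
    seed: int | None = None,
    image_id: str = "sim",
    return_info: bool = False,
):
    """Render one annotated quadrat image.

    Deterministic for a given config and seed.  With ``return_info=True``
    also returns a dict holding the renderer's own ground truth: per-ear
    support masks, the red-frame inner corners, and the frame hole mask.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    h, w = config.image_size
    base = np.array([52, 92, 44], dtype=float)
    pixels = base + rng.normal(0, 10, size=(h, w, 3))
    _paint_leaves(pixels, config, rng)

    corners, hole = None, np.ones((h, w), dtype=bool)
    if config.red_frame:
        corners, hole = _draw_frame(pixels, config, rng)

    # ears may only occupy the frame interior, kept clear of its inner edge
    allowed = ndimage.binary_erosion(hole, np.ones((5, 5))) if config.red_frame else hole

    n = _sample_count(config.count_law, rng)
    masks = _place_ears(config, n, allowed, rng)

    ear_base = np.array([208, 186, 92], dtype=float)
    points: list[tuple[int, int]] = []
    taken: set[tuple[int, int]] = set()
    for mask in masks:
        shade = rng.uniform(0.85, 1.1)
        speckle = rng.normal(1.0, 0.16, size=(int(mask.sum()), 1)).clip(0.55, 1.45)
        pixels[mask] = ear_base * shade * speckle
        rs, cs = np.nonzero(mask)
        cr, cc = rs.mean(), cs.mean()
        minor = min(np.ptp(rs) + 1, np.ptp(cs) + 1)  # shorter side of the support
        pt = None
        for _ in range(40):
            jr = cr + rng.uniform(-0.2, 0.2) * minor
            jc = cc + rng.uniform(-0.2, 0.2) * minor
            cand = (int(round(jr)), int(round(jc)))
            if (
                0 <= cand[0] < h
                and 0 <= cand[1] < w
                and mask[cand]
                and cand not in taken
            ):
                pt = cand
                break
        if pt is None:  # fall back to the nearest in-mask pixel not yet taken
            for r, c in sorted(
                zip(rs, cs), key=lambda p: (p[0] - cr) ** 2 + (p[1] - cc) ** 2
            ):
                if (int(r), int(c)) not in taken:
                    pt = (int(r), int(c))
                    break
        if pt is None:
            raise ValueError("ear support fully consumed by earlier points")
        taken.add(pt)
        points.append(pt)

    gain = rng.uniform(*config.illumination)
    pixels *= gain * np.asarray(config.color_cast, dtype=float)
    if config.noise_sd > 0:
        pixels += rng.normal(0, config.noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0, 255).astype(np.uint8)

    image = AnnotatedImage(pixels=pixels, points=points, image_id=image_id)
    if return_info:
        return image, {"ear_masks": masks, "frame_corners": corners, "hole": hole}
    return image


def simulate_dataset(
    config: FieldSimConfig,
    n_images: int,
    out_dir: str | Path | None = None,
    master_seed: int | None = None,
) -> list[AnnotatedImage]:
    """Render ``n_images`` scenes with per-image seeds spawned from the master.

    When ``out_dir`` is given, images, point masks and ``counts.csv`` are
    written in the standard layout.
    """
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    master = config.seed if master_seed is None else master_seed
    seeds = np.random.SeedSequence(master).generate_state(n_images) % (2**31)
    dataset = [
        simulate_image(config, seed=int(s), image_id=f"sim_{i:05d}")
        for i, s in enumerate(seeds)
    ]
    if out_dir is not None:
        save_dataset(dataset, out_dir)
    return dataset
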