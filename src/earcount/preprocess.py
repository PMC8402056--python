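"""Red-frame detection and rectification, resizing, and flip/rotation
augmentation with exact annotation transport.

Field images are shot over a square red quadrat frame so that every image
covers the same ground area.  Only the area inside the frame is analysed:
the detector casts rays outward from near the image centre until they meet
red, fits a line per side through the two hit points, intersects adjacent
lines into the four inner-frame corners, and a projective warp stretches
that quadrilateral to a full output raster.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage import color as skcolor
from skimage import transform as sktransform

from .io import AnnotatedImage

__all__ = [
    "FrameNotFoundError",
    "FrameDetectionError",
    "QuadCorners",
    "detect_red_frame",
    "rectify",
    "resize_annotated",
    "flip_annotated",
    "rotate90_annotated",
    "augment",
]


class FrameNotFoundError(RuntimeError):
    """A probe ray left the image without meeting a red pixel."""


class FrameDetectionError(ValueError):
    """Ray hits were found but do not form a convex quadrilateral."""


class QuadCorners:
    """Four sub-pixel (row, col) corners, clockwise from top-left."""

    def __init__(self, corners: np.ndarray):
        corners = np.asarray(corners, dtype=float)
        if corners.shape != (4, 2):
            raise ValueError(f"expected 4×2 corner array, got {corners.shape}")
        # convexity: consistent turn direction around the cycle
        cross = []
        for i in range(4):
            a, b, c = corners[i], corners[(i + 1) % 4], corners[(i + 2) % 4]
            u, v = b - a, c - b
            cross.append(u[0] * v[1] - u[1] * v[0])
        if not (all(v > 1e-9 for v in cross) or all(v < -1e-9 for v in cross)):
            raise FrameDetectionError("corner set is not a convex quadrilateral")
        self.array = corners

    def __iter__(self):
        return iter(self.array)


def red_mask(
    image: np.ndarray,
    hue_window: float = 0.06,
    min_saturation: float = 0.35,
    min_value: float = 0.2,
) -> np.ndarray:
    """Pixels whose HSV hue sits near 0°/360° with enough saturation/value."""
    hsv = skcolor.rgb2hsv(image)
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    return ((h <= hue_window) | (h >= 1.0 - hue_window)) & (s >= min_saturation) & (
        v >= min_value
    )


def _march(
    red: np.ndarray, start: tuple[float, float], step: tuple[int, int], run: int = 4
):
    """First red pixel along the ray, confirmed by a mostly-red run behind it.

    The run requirement ("until a certain radius area is red") rejects
    isolated reddish canopy pixels that are not part of the frame.
    """
    h, w = red.shape
    r, c = int(round(start[0])), int(round(start[1]))
    while 0 <= r < h and 0 <= c < w:
        if red[r, c]:
            ahead = [
                red[r + k * step[0], c + k * step[1]]
                for k in range(1, run)
                if 0 <= r + k * step[0] < h and 0 <= c + k * step[1] < w
            ]
            if sum(ahead) >= max(1, len(ahead) - 1):
                return (r, c)
        r += step[0]
        c += step[1]
    raise FrameNotFoundError(
        f"ray from {start} along {step} left the image without meeting red"
    )


def _intersect_lines(l1: np.ndarray, l2: np.ndarray) -> np.ndarray:
    """Intersection of A_r·row + A_c·col + b = 0 lines."""
    a = np.array([l1[:2], l2[:2]])
    rhs = -np.array([l1[2], l2[2]])
    if abs(np.linalg.det(a)) < 1e-12:
        raise FrameDetectionError("frame side lines are parallel")
    return np.linalg.solve(a, rhs)


def _fit_side_line(hits: list[tuple[int, int]], horizontal: bool) -> np.ndarray:
    """Least-squares line through the ray hits, as (A_r, A_c, b) with
    A_r·row + A_c·col + b = 0.  Horizontal sides fit row as a function of
    col; vertical sides the transpose."""
    pts = np.asarray(hits, dtype=float)
    if horizontal:
        m, q = np.polyfit(pts[:, 1], pts[:, 0], 1)
        return np.array([-1.0, m, q])
    m, q = np.polyfit(pts[:, 0], pts[:, 1], 1)
    return np.array([m, -1.0, q])


def detect_red_frame(
    image: np.ndarray,
    offset_fraction: float = 0.2,
    rays_per_side: int = 5,
    **red_kwargs,
) -> QuadCorners:
    """Locate the inner edge of the red quadrat frame.

    A small fan of rays per side is cast outward from points offset up to
    ±``offset_fraction`` of the image extent around the centre; each ray
    records the first (run-confirmed) red pixel it meets, a least-squares
    line is fitted through each side's hits, and adjacent lines intersect
    in the corners.
    """
    image = np.asarray(image)
    red = red_mask(image, **red_kwargs)
    h, w = red.shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    offsets = np.linspace(-offset_fraction, offset_fraction, rays_per_side)
    sides = {
        "top": [_march(red, (cr, cc + o * w), (-1, 0)) for o in offsets],
        "bottom": [_march(red, (cr, cc + o * w), (1, 0)) for o in offsets],
        "left": [_march(red, (cr + o * h, cc), (0, -1)) for o in offsets],
        "right": [_march(red, (cr + o * h, cc), (0, 1)) for o in offsets],
    }
    lines = {
        name: _fit_side_line(hits, horizontal=name in ("top", "bottom"))
        for name, hits in sides.items()
    }
    corners = np.array(
        [
            _intersect_lines(lines["top"], lines["left"]),
            _intersect_lines(lines["top"], lines["right"]),
            _intersect_lines(lines["bottom"], lines["right"]),
            _intersect_lines(lines["bottom"], lines["left"]),
        ]
    )
    if (corners[:, 0] < -2) .any() or (corners[:, 0] > h + 1).any() or (
        corners[:, 1] < -2
    ).any() or (corners[:, 1] > w + 1).any():
        raise FrameDetectionError(f"corners fall outside the image: {corners}")
    return QuadCorners(corners)


def rectify(
    image: np.ndarray,
    corners: QuadCorners | np.ndarray,
    out_size: tuple[int, int],
    points: list[tuple[int, int]] | None = None,
):
    """Perspective-warp the frame interior onto a full ``out_size`` raster.

    Annotation points, when given, are transported by the same homography
    and returned alongside the warped image.
    """
    if not isinstance(corners, QuadCorners):
        corners = QuadCorners(np.asarray(corners))
    h_out, w_out = out_size
    src_xy = corners.array[:, ::-1]  # (row, col) -> (x, y)
    dst_xy = np.array(
        [[0, 0], [w_out - 1, 0], [w_out - 1, h_out - 1], [0, h_out - 1]], dtype=float
    )
    if hasattr(sktransform.ProjectiveTransform, "from_estimate"):
        tform = sktransform.ProjectiveTransform.from_estimate(src_xy, dst_xy)
        if not tform:
            raise ValueError("degenerate corner configuration")
    else:  # older scikit-image
        tform = sktransform.ProjectiveTransform()
        if not tform.estimate(src_xy, dst_xy):
            raise ValueError("degenerate corner configuration")
    warped = sktransform.warp(
        np.asarray(image).astype(float),
        inverse_map=tform.inverse,
        output_shape=(h_out, w_out),
        order=1,
        mode="edge",
        preserve_range=True,
    )
    warped = np.clip(warped, 0, 255).astype(np.uint8)
    if points is None:
        return warped
    if len(points):
        xy = np.asarray([(c, r) for r, c in points], dtype=float)
        out_xy = tform(xy)
        new_points = [
            (int(round(y)), int(round(x)))
            for x, y in out_xy
            if -0.5 <= y < h_out - 0.5 and -0.5 <= x < w_out - 0.5
        ]
    else:
        new_points = []
    return warped, new_points


def resize_annotated(
    image: np.ndarray,
    points: list[tuple[int, int]],
    scale: float,
    image_id: str = "",
    min_size: int = 32,
) -> AnnotatedImage:
    """Resample the raster by ``scale`` and transport the points with it.

    Points that land on the same pixel after rounding are deduplicated with
    a warning (a one-pixel point mask cannot encode multiplicity).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    h, w = np.asarray(image).shape[:2]
    nh, nw = int(round(h * scale)), int(round(w * scale))
    if nh < min_size or nw < min_size:
        raise ValueError(f"target size {nh}×{nw} below the minimum {min_size}")
    resized = sktransform.resize(
        np.asarray(image).astype(float),
        (nh, nw),
        order=1,
        anti_aliasing=scale < 1.0,
        preserve_range=True,
    )
    resized = np.clip(resized, 0, 255).astype(np.uint8)
    new_points = [
        (min(int(round(r * scale)), nh - 1), min(int(round(c * scale)), nw - 1))
        for r, c in points
    ]
    return AnnotatedImage(pixels=resized, points=new_points, image_id=image_id)


def flip_annotated(item: AnnotatedImage, suffix: str = "_flip") -> AnnotatedImage:
    """Horizontal mirror of pixels and points (an involution)."""
    w = item.pixels.shape[1]
    return AnnotatedImage(
        pixels=item.pixels[:, ::-1].copy(),
        points=[(r, w - 1 - c) for r, c in item.points],
        image_id=item.image_id + suffix,
    )


def rotate90_annotated(item: AnnotatedImage, suffix: str = "_rot90") -> AnnotatedImage:
    """90° counter-clockwise rotation of pixels and points."""
    w = item.pixels.shape[1]
    return AnnotatedImage(
        pixels=np.rot90(item.pixels).copy(),
        points=[(w - 1 - c, r) for r, c in item.points],
        image_id=item.image_id + suffix,
    )


def augment(
    dataset: list[AnnotatedImage], modes: set[str] | list[str]
) -> list[AnnotatedImage]:
    """Originals plus one flipped (and one rotated) copy per image.

    ``{"flip"}`` doubles the dataset; ``{"flip", "rotation"}`` triples it.
    Spatial maps are raster bijections, so per-image counts are preserved
    exactly.
    """
    modes = set(modes)
    unknown = modes - {"flip", "rotation"}
    if unknown:
        raise ValueError(f"unknown augmentation mode(s): {sorted(unknown)}")
    out = list(dataset)
    if "flip" in modes:
        out += [flip_annotated(item) for item in dataset]
    if "rotation" in modes:
        out += [rotate90_annotated(item) for item in dataset]
    return out
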