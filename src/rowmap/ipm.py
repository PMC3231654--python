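"""Inverse perspective mapping: homography estimation and bird's-eye warping.

A planar homography u' = s*H*u links the ground plane to the image plane,
so four point correspondences with no three collinear determine H up to
scale.  Per frame, the correspondences are the corners of the trapezoid
bounded by the two outermost tracked crop-row lines and the top/bottom
strip-center scanlines; they map to a rectangle of width equal to twice
the inter-row spacing, horizontally centered in the output.  Because the
source corners follow the tracked rows, recomputing H every frame cancels
the camera's lateral sway and the warped sequence is stabilized; freezing
H from frame 0 reproduces the unstabilized behaviour.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .row_tracking import RowObservation
from .synthetic_field import CameraModel, ground_forward_at_scanline


class DegenerateCorrespondencesError(ValueError):
    """More than two collinear points, or an invalid trapezoid."""


@dataclass(frozen=True)
class BirdsEyeSpec:
    """Geometry of the rectified top-down view.

    The target rectangle spans twice the inter-row spacing horizontally
    (mm_per_px_x sets the metric scale) and rows rect_top_px..rect_bottom_px
    vertically; mm_per_px_y is the vertical scale, obtained by calibration.
    """

    out_width_px: int = 560
    out_height_px: int = 288
    mm_per_px_x: float = 5.0
    mm_per_px_y: float = 20.0
    rect_top_px: float = 14.0
    rect_bottom_px: float = 274.0
    row_spacing_m: float = 0.7

    def __post_init__(self) -> None:
        if self.out_width_px <= 0 or self.out_height_px <= 0:
            raise ValueError("output dimensions must be positive")
        if self.mm_per_px_x <= 0 or self.mm_per_px_y <= 0:
            raise ValueError("metric scales must be > 0")
        if not 0 <= self.rect_top_px < self.rect_bottom_px <= self.out_height_px:
            raise ValueError("need 0 <= rect_top_px < rect_bottom_px <= out_height_px")
        if self.row_spacing_m <= 0:
            raise ValueError("row_spacing_m must be > 0")
        if self.rect_width_px > self.out_width_px:
            raise ValueError("rectangle wider than the output image")

    @property
    def rect_width_px(self) -> float:
        """Twice the inter-row spacing, in output pixels."""
        return 2.0 * self.row_spacing_m * 1000.0 / self.mm_per_px_x

    def rect_corners(self) -> np.ndarray:
        """(4, 2) target corners: top-left, top-right, bottom-left, bottom-right."""
        xl = self.out_width_px / 2.0 - self.rect_width_px / 2.0
        xr = self.out_width_px / 2.0 + self.rect_width_px / 2.0
        return np.array(
            [
                [xl, self.rect_top_px],
                [xr, self.rect_top_px],
                [xl, self.rect_bottom_px],
                [xr, self.rect_bottom_px],
            ]
        )


@dataclass(frozen=True)
class PointCorrespondences:
    """n >= 4 (source, target) point pairs, inhomogeneous (w normalized to 1)."""

    src: np.ndarray  # (n, 2)
    dst: np.ndarray  # (n, 2)

    def __post_init__(self) -> None:
        src = np.asarray(self.src, dtype=float)
        dst = np.asarray(self.dst, dtype=float)
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise ValueError("src and dst must both be (n, 2)")
        if src.shape[0] < 4:
            raise ValueError("at least 4 correspondences are required")
        object.__setattr__(self, "src", src)
        object.__setattr__(self, "dst", dst)

    def __len__(self) -> int:
        return self.src.shape[0]


def _has_collinear_triple(pts: np.ndarray, rel_tol: float = 1e-7) -> bool:
    """True if any three of the points are (nearly) collinear."""
    n = pts.shape[0]
    scale = max(np.ptp(pts, axis=0).max(), 1e-12)
    for i in range(n):
        for j in range(i + 1, n):
            for k in range(j + 1, n):
                a, b, c = pts[i], pts[j], pts[k]
                area2 = abs(
                    (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
                )
                if area2 <= rel_tol * scale * scale:
                    return True
    return False


def _normalization(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    centroid = pts.mean(axis=0)
    d = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    s = math.sqrt(2.0) / max(d, 1e-12)
    return np.array(
        [[s, 0, -s * centroid[0]], [0, s, -s * centroid[1]], [0, 0, 1]]
    )


def canonicalize(H: np.ndarray) -> np.ndarray:
    """Scale a homography so its largest-magnitude entry is +1."""
    idx = np.unravel_index(np.argmax(np.abs(H)), H.shape)
    return H / H[idx]


def estimate_homography(corr: PointCorrespondences) -> np.ndarray:
    """Direct linear transform with Hartley coordinate normalization.

    Returns the canonical 3x3 H mapping src -> dst.  Raises
    DegenerateCorrespondencesError when more than two source (or target)
    points are collinear.
    """
    if _has_collinear_triple(corr.src) or _has_collinear_triple(corr.dst):
        raise DegenerateCorrespondencesError(
            "more than two collinear correspondence points"
        )
    Ts, Td = _normalization(corr.src), _normalization(corr.dst)
    src = (Ts @ np.column_stack([corr.src, np.ones(len(corr))]).T).T
    dst = (Td @ np.column_stack([corr.dst, np.ones(len(corr))]).T).T
    rows = []
    for (x, y, _), (X, Y, _) in zip(src, dst):
        rows.append([-x, -y, -1, 0, 0, 0, X * x, X * y, X])
        rows.append([0, 0, 0, -x, -y, -1, Y * x, Y * y, Y])
    A = np.asarray(rows)
    _, sv, vt = np.linalg.svd(A)
    if sv[-2] < 1e-10 * sv[0]:
        raise DegenerateCorrespondencesError("rank-deficient correspondence system")
    Hn = vt[-1].reshape(3, 3)
    return canonicalize(np.linalg.inv(Td) @ Hn @ Ts)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Apply H to (n, 2) points; returns (n, 2) inhomogeneous results."""
    p = np.asarray(pts, dtype=float)
    hom = np.column_stack([p, np.ones(p.shape[0])]) @ H.T
    return hom[:, :2] / hom[:, 2:3]


def build_correspondences(
    obs: RowObservation, spec: BirdsEyeSpec
) -> PointCorrespondences:
    """Trapezoid corners from the outer tracked rows -> centered rectangle.

    Sources are the intersections of the left/right row lines with the top
    and bottom strip-center scanlines; targets are the rectangle corners in
    the same left/right, top/bottom pairing.
    """
    y_top, y_bottom = float(obs.strip_ys[0]), float(obs.strip_ys[-1])
    ml, cl = obs.lines[0]
    mr, cr = obs.lines[2]
    if not (np.isfinite([ml, cl, mr, cr]).all()):
        raise ValueError("outer row lines are undefined")
    xl_t, xl_b = ml * y_top + cl, ml * y_bottom + cl
    xr_t, xr_b = mr * y_top + cr, mr * y_bottom + cr
    if xl_t >= xr_t or xl_b >= xr_b:
        raise DegenerateCorrespondencesError(
            "outer row lines cross or swap inside the strip range"
        )
    src = np.array([[xl_t, y_top], [xr_t, y_top], [xl_b, y_bottom], [xr_b, y_bottom]])
    return PointCorrespondences(src=src, dst=spec.rect_corners())


def warp_to_birds_eye(
    mask: np.ndarray, H: np.ndarray, spec: BirdsEyeSpec
) -> np.ndarray:
    """Inverse-map nearest-neighbour warp of a binary mask to the bird's-eye view.

    Output pixel p takes the value of source pixel H^-1 p; nearest-neighbour
    keeps the mask binary, and pixels mapping outside the source are 0.
    """
    det = np.linalg.det(H)
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("homography is not invertible")
    Hinv = np.linalg.inv(H)
    m = np.asarray(mask)
    h, w = m.shape
    xs, ys = np.meshgrid(
        np.arange(spec.out_width_px, dtype=float),
        np.arange(spec.out_height_px, dtype=float),
    )
    denom = Hinv[2, 0] * xs + Hinv[2, 1] * ys + Hinv[2, 2]
    ok = np.abs(denom) > 1e-12
    denom = np.where(ok, denom, 1.0)
    su = (Hinv[0, 0] * xs + Hinv[0, 1] * ys + Hinv[0, 2]) / denom
    sv = (Hinv[1, 0] * xs + Hinv[1, 1] * ys + Hinv[1, 2]) / denom
    ui = np.rint(su).astype(np.int64)
    vi = np.rint(sv).astype(np.int64)
    inside = ok & (ui >= 0) & (ui < w) & (vi >= 0) & (vi < h)
    out = np.zeros((spec.out_height_px, spec.out_width_px), dtype=np.uint8)
    out[inside] = m[vi[inside], ui[inside]]
    return out


def birdseye_center_offset(be_mask: np.ndarray, spec: BirdsEyeSpec) -> float:
    """Signed px offset of the central row from the output centerline.

    Centroid of the white pixels within a band of +/- a quarter rectangle
    width around the center, over the rectangle rows; NaN when empty.
    """
    half_band = spec.rect_width_px / 4.0
    c0 = int(math.floor(spec.out_width_px / 2.0 - half_band))
    c1 = int(math.ceil(spec.out_width_px / 2.0 + half_band))
    r0 = int(math.ceil(spec.rect_top_px))
    r1 = int(math.floor(spec.rect_bottom_px)) + 1
    region = np.asarray(be_mask)[r0:r1, c0:c1]
    cols = np.nonzero(region)[1]
    if cols.size == 0:
        return float("nan")
    return float(cols.mean() + 0.5 + c0 - spec.out_width_px / 2.0)


def calibrate_vertical_scale(
    camera: CameraModel, spec: BirdsEyeSpec, n_strips: int = 4
) -> float:
    """mm per output pixel vertically, from a known camera geometry.

    Plays the role of measuring an object of known length in the scene: the
    ground distance between the top and bottom strip-center scanlines is
    computed from the camera model and divided by the rectangle height.
    """
    from .row_tracking import strip_scanlines

    half = camera.image_h - camera.image_h // 2
    vs = camera.image_h // 2 + strip_scanlines(half, n_strips)
    d = ground_forward_at_scanline(camera, float(vs[0])) - ground_forward_at_scanline(
        camera, float(vs[-1])
    )
    return 1000.0 * d / (spec.rect_bottom_px - spec.rect_top_px)
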