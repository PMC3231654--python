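"""Synthetic wide-row crop field video with pixel-accurate ground truth.

Renders what a camera mounted ~2.15 m above the ground with a ~10 degree
downward pitch sees while the vehicle drives along parallel crop rows
(0.7 m apart for maize) at treatment speed: anti-aliased green plants on
textured brown soil, weed blobs in the inter-row space, sowing gaps, and a
lateral sway trajectory that displaces the camera sideways frame to frame.

The world is laid out once on a 10 mm ground-plane grid from the scene
seed; every frame is then rendered deterministically by back-projecting
each (sub)pixel ray onto the ground plane, so the imagery, the per-frame
true row-center pixels and the world occupancy labels all derive from the
same pinhole geometry.  That makes the generator the oracle for the
tracking, inverse-perspective and mapping stages.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .row_tracking import strip_scanlines

WORLD_CELL_M = 0.01          # ground-plane raster resolution
CLASS_SOIL, CLASS_CROP, CLASS_WEED = 0, 1, 2

_SOIL_RGB = np.array([125.0, 105.0, 85.0])
_SKY_RGB = np.array([168.0, 178.0, 196.0])
_CROP_RGB = np.array([45.0, 180.0, 40.0])
_WEED_RGB = np.array([62.0, 158.0, 52.0])
_SUPERSAMPLE = 2


# ---------------------------------------------------------------------------
# camera model and projection
# ---------------------------------------------------------------------------

def focal_for_row_spacing(
    height_m: float = 2.15,
    pitch_deg: float = 10.0,
    image_h: int = 576,
    row_spacing_m: float = 0.7,
    target_spacing_px: float = 140.0,
    n_strips: int = 4,
) -> float:
    """Focal length (px) that projects the inter-row spacing to a target
    pixel distance at the bottom-strip center scanline of the lower half.

    The horizontal scale at scanline v is f*(sin(p) + t*cos(p))/h px per
    meter with t = (v - cy)/f, which is linear in f and solvable in closed
    form.  With the defaults (0.7 m -> 140 px at v = 540 of 576) this gives
    f ~= 1047.1 px.
    """
    th = math.radians(pitch_deg)
    half = image_h - image_h // 2
    v = float(image_h // 2 + strip_scanlines(half, n_strips)[-1])
    cy = image_h / 2.0
    return float(
        (target_spacing_px * height_m / row_spacing_m - (v - cy) * math.cos(th))
        / math.sin(th)
    )


DEFAULT_FOCAL_PX = focal_for_row_spacing()


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera on the vehicle: height above ground, downward pitch,
    focal length in pixels, sensor size, and a signed lateral sway offset.

    The principal point is fixed at the image center.  World frame: x
    lateral (rightward), y forward along the rows, z up; the ground is z=0.
    """

    height_m: float = 2.15
    pitch_deg: float = 10.0
    focal_px: float = DEFAULT_FOCAL_PX
    image_w: int = 720
    image_h: int = 576
    lateral_offset_m: float = 0.0

    def __post_init__(self) -> None:
        if self.height_m <= 0:
            raise ValueError("height_m must be > 0")
        if not 0.0 < self.pitch_deg < 90.0:
            raise ValueError("pitch_deg must be in (0, 90)")
        if self.focal_px <= 0:
            raise ValueError("focal_px must be > 0")
        if self.image_w <= 0 or self.image_h <= 0:
            raise ValueError("image dimensions must be positive")

    @property
    def cx(self) -> float:
        return self.image_w / 2.0

    @property
    def cy(self) -> float:
        return self.image_h / 2.0


def project_world_to_image(
    camera: CameraModel,
    point: tuple[float, float],
    forward_m: float = 0.0,
) -> Optional[tuple[float, float]]:
    """Project a ground-plane point (x, y) to pixel (u, v); None if out of view.

    ``forward_m`` is the camera's position along the travel direction; the
    camera's lateral position is ``camera.lateral_offset_m``.  Points behind
    the camera or at/above the horizon return None.  Ground lines project to
    image lines, and parallel ground lines meet at a common vanishing point.
    """
    s, c = math.sin(math.radians(camera.pitch_deg)), math.cos(math.radians(camera.pitch_deg))
    dx = point[0] - camera.lateral_offset_m
    dy = point[1] - forward_m
    zc = c * dy + s * camera.height_m
    if zc <= 1e-9:
        return None
    yc = camera.height_m * c - s * dy
    u = camera.cx + camera.focal_px * dx / zc
    v = camera.cy + camera.focal_px * yc / zc
    return (u, v)


def ground_forward_at_scanline(camera: CameraModel, v: float) -> float:
    """Forward ground distance (m, camera-relative) imaged at scanline v on
    the vertical centerline.  Defined only below the horizon."""
    s, c = math.sin(math.radians(camera.pitch_deg)), math.cos(math.radians(camera.pitch_deg))
    t = (v - camera.cy) / camera.focal_px
    den = s + t * c
    if den <= 1e-9:
        raise ValueError(f"scanline v={v} is at or above the horizon")
    return camera.height_m * (c - t * s) / den


# ---------------------------------------------------------------------------
# scene layout and sway
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SceneSpec:
    """World-plane layout of the synthetic field.

    Defaults emulate a maize field: 5 rows 0.7 m apart with a ~0.2 m canopy,
    ~15 plants per meter of row, occasional sowing gaps, and sparse weed
    blobs in the inter-row space.
    """

    n_rows: int = 5
    row_spacing_m: float = 0.7
    row_width_m: float = 0.2
    plant_density: float = 15.0
    gap_prob: float = 0.05
    weed_rate: float = 0.3          # expected blobs per m^2 of inter-row area
    weed_radius_m: float = 0.06
    field_length_m: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 3:
            raise ValueError("n_rows must be >= 3 (three central rows are tracked)")
        if not self.row_spacing_m > self.row_width_m > 0:
            raise ValueError("need row_spacing_m > row_width_m > 0")
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ValueError("gap_prob must be in [0, 1]")
        if self.weed_rate < 0 or self.weed_radius_m < 0:
            raise ValueError("weed parameters must be >= 0")
        if self.plant_density <= 0 or self.field_length_m <= 0:
            raise ValueError("plant_density and field_length_m must be > 0")

    @property
    def row_offsets_m(self) -> np.ndarray:
        """Lateral centerline of every row, centered on the vehicle path."""
        return (np.arange(self.n_rows) - (self.n_rows - 1) / 2.0) * self.row_spacing_m

    @property
    def central_row_indices(self) -> np.ndarray:
        mid = self.n_rows // 2
        return np.array([mid - 1, mid, mid + 1])


@dataclass(frozen=True)
class SwayTrajectory:
    """Per-frame signed lateral camera displacement (m); roll defaults to 0."""

    lateral_offset_m: np.ndarray
    roll_deg: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lateral_offset_m", np.asarray(self.lateral_offset_m, dtype=float)
        )
        if self.roll_deg is not None:
            roll = np.asarray(self.roll_deg, dtype=float)
            if roll.shape != self.lateral_offset_m.shape:
                raise ValueError("roll_deg must match lateral_offset_m in length")
            object.__setattr__(self, "roll_deg", roll)

    def __len__(self) -> int:
        return int(self.lateral_offset_m.size)

    @classmethod
    def zero(cls, n_frames: int) -> "SwayTrajectory":
        return cls(np.zeros(n_frames))

    @classmethod
    def sinusoidal(
        cls,
        n_frames: int,
        amplitude_m: float,
        period_frames: float,
        phase_rad: float = 0.0,
    ) -> "SwayTrajectory":
        k = np.arange(n_frames)
        return cls(amplitude_m * np.sin(2 * np.pi * k / period_frames + phase_rad))

    @classmethod
    def default(
        cls, n_frames: int, row_spacing_m: float = 0.7, seed: int = 0
    ) -> "SwayTrajectory":
        """Terrain-like sway: two incommensurate sinusoids plus small jitter."""
        rng = np.random.default_rng(seed)
        k = np.arange(n_frames)
        off = 0.25 * row_spacing_m * np.sin(2 * np.pi * k / 120.0)
        off += 0.08 * row_spacing_m * np.sin(2 * np.pi * k / 37.0 + 1.1)
        off += rng.normal(0.0, 0.005, n_frames)
        return cls(off)


@dataclass(frozen=True)
class GroundTruth:
    """Per-frame oracle values plus the world occupancy labels.

    ``row_centers_px[k, r, s]`` is the true x-pixel of central row r at the
    strip-s center scanline of frame k, computed by projecting the world row
    centerline with the frame's camera pose (NaN when out of view).
    """

    row_centers_px: np.ndarray       # (n_frames, 3, n_strips)
    lateral_offset_m: np.ndarray     # (n_frames,)
    forward_m: np.ndarray            # (n_frames,)
    strip_scanlines_v: np.ndarray    # (n_strips,) full-frame scanlines
    central_row_offsets_m: np.ndarray  # (3,) world lateral positions
    occupancy: np.ndarray            # (ny, nx) uint8 soil/crop/weed world grid
    world_cell_m: float
    world_x_min_m: float

    def to_json_dict(self) -> dict:
        return {
            "n_frames": int(self.row_centers_px.shape[0]),
            "strip_scanlines_v": self.strip_scanlines_v.tolist(),
            "central_row_offsets_m": self.central_row_offsets_m.tolist(),
            "world_cell_m": self.world_cell_m,
            "world_x_min_m": self.world_x_min_m,
            "frames": [
                {
                    "frame": k,
                    "lateral_offset_m": float(self.lateral_offset_m[k]),
                    "forward_m": float(self.forward_m[k]),
                    "row_centers_px": self.row_centers_px[k].tolist(),
                }
                for k in range(self.row_centers_px.shape[0])
            ],
        }


# ---------------------------------------------------------------------------
# scene construction and rendering
# ---------------------------------------------------------------------------

class SyntheticScene:
    """A seeded world raster plus a camera trajectory; renders frames on demand."""

    def __init__(
        self,
        spec: SceneSpec,
        camera: CameraModel,
        sway: SwayTrajectory,
        speed_mps: float = 1.667,
        fps: float = 25.0,
    ) -> None:
        if speed_mps < 0:
            raise ValueError("speed_mps must be >= 0")
        if fps <= 0:
            raise ValueError("fps must be > 0")
        if sway.roll_deg is not None and np.any(sway.roll_deg != 0):
            raise ValueError("non-zero roll rendering is not supported")
        self.spec = spec
        self.camera = camera
        self.sway = sway
        self.speed_mps = speed_mps
        self.fps = fps
        self._build_world()
        self._build_ray_tables()

    # -- world raster ------------------------------------------------------

    def _build_world(self) -> None:
        spec = self.spec
        rng = np.random.default_rng(spec.seed)
        cell = WORLD_CELL_M
        half_w = (spec.n_rows - 1) / 2.0 * spec.row_spacing_m + 1.5
        self.world_x_min = -half_w
        nx = int(round(2 * half_w / cell))
        ny = int(round(spec.field_length_m / cell))
        plant_id = np.zeros((ny, nx), dtype=np.int32)
        classes = np.zeros((ny, nx), dtype=np.uint8)
        colors = [np.zeros(3)]  # index 0 unused (soil)

        def paint_ellipse(x0, y0, rx, ry, pid, cls):
            ix0 = int(np.floor((x0 - rx - self.world_x_min) / cell))
            ix1 = int(np.ceil((x0 + rx - self.world_x_min) / cell)) + 1
            iy0 = int(np.floor((y0 - ry) / cell))
            iy1 = int(np.ceil((y0 + ry) / cell)) + 1
            ix0, ix1 = max(ix0, 0), min(ix1, nx)
            iy0, iy1 = max(iy0, 0), min(iy1, ny)
            if ix0 >= ix1 or iy0 >= iy1:
                return
            xs = self.world_x_min + (np.arange(ix0, ix1) + 0.5) * cell
            ys = (np.arange(iy0, iy1) + 0.5) * cell
            inside = ((xs[None, :] - x0) / rx) ** 2 + (
                (ys[:, None] - y0) / ry
            ) ** 2 <= 1.0
            plant_id[iy0:iy1, ix0:ix1][inside] = pid
            classes[iy0:iy1, ix0:ix1][inside] = cls

        step = 1.0 / spec.plant_density
        base_ry = max(0.8 * step, 0.035)
        for row_x in spec.row_offsets_m:
            n_plants = int(spec.field_length_m / step)
            for k in range(n_plants):
                gap = rng.random() < spec.gap_prob
                y0 = k * step + rng.normal(0.0, 0.008)
                x0 = row_x + rng.normal(0.0, 0.008)
                rx = spec.row_width_m / 2.0 * rng.uniform(0.9, 1.1)
                ry = base_ry * rng.uniform(0.85, 1.15)
                jitter = rng.normal(0.0, [14.0, 18.0, 10.0])
                if gap:
                    continue
                pid = len(colors)
                colors.append(np.clip(_CROP_RGB + jitter, 0, 255))
                paint_ellipse(x0, y0, rx, ry, pid, CLASS_CROP)

        inter_row_area = (spec.n_rows - 1) * spec.row_spacing_m * spec.field_length_m
        n_weeds = rng.poisson(spec.weed_rate * inter_row_area)
        span = (spec.n_rows - 1) / 2.0 * spec.row_spacing_m + spec.row_spacing_m / 2.0
        placed = 0
        guard = 0
        while placed < n_weeds and guard < 50 * (n_weeds + 1):
            guard += 1
            x0 = rng.uniform(-span, span)
            y0 = rng.uniform(0.0, spec.field_length_m)
            r = spec.weed_radius_m * rng.uniform(0.7, 1.3)
            if np.min(np.abs(x0 - spec.row_offsets_m)) < spec.row_width_m:
                continue
            pid = len(colors)
            colors.append(
                np.clip(_WEED_RGB + rng.normal(0.0, [12.0, 16.0, 10.0]), 0, 255)
            )
            paint_ellipse(x0, y0, r, r, pid, CLASS_WEED)
            placed += 1

        self._plant_id = plant_id
        self._classes = classes
        self._colors = np.array(colors, dtype=np.float32)
        # multiplicative soil texture keeps the greenness index negative on soil
        self._shade = (1.0 + rng.normal(0.0, 0.06, (ny, nx))).clip(0.6, 1.4).astype(
            np.float32
        )

    # -- per-frame geometry ------------------------------------------------

    def camera_pose(self, k: int) -> tuple[float, float]:
        """(lateral_m, forward_m) of the camera at frame k."""
        lat = self.camera.lateral_offset_m + float(self.sway.lateral_offset_m[k])
        fwd = k * self.speed_mps / self.fps
        return lat, fwd

    def _build_ray_tables(self) -> None:
        cam = self.camera
        ss = _SUPERSAMPLE
        s = math.sin(math.radians(cam.pitch_deg))
        c = math.cos(math.radians(cam.pitch_deg))
        us = (np.arange(cam.image_w * ss) + 0.5) / ss - 0.5
        vs = (np.arange(cam.image_h * ss) + 0.5) / ss - 0.5
        a = (us - cam.cx) / cam.focal_px
        b = (vs - cam.cy) / cam.focal_px
        den = c * b + s
        ground = den > 1e-6
        t = np.where(ground, cam.height_m / np.where(ground, den, 1.0), np.nan)
        self._ray_a = a                       # per sub-column
        self._ray_t = t                       # per sub-row: range along ray
        self._ray_fwd = t * (c - s * b)       # per sub-row: forward offset
        self._ray_ground = ground

    def _sample_world(self, k: int):
        """Ground-cell indices and validity for every subpixel of frame k."""
        lat, fwd = self.camera_pose(k)
        px = lat + self._ray_t[:, None] * self._ray_a[None, :]
        py = fwd + self._ray_fwd[:, None] + np.zeros_like(px)
        cell = WORLD_CELL_M
        ground = self._ray_ground[:, None] & np.isfinite(px)
        ix = np.floor(
            np.where(ground, (px - self.world_x_min) / cell, -1.0)
        ).astype(np.int64)
        iy = np.floor(np.where(ground, py / cell, -1.0)).astype(np.int64)
        ny, nx = self._plant_id.shape
        infield = ground & (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        ix = np.clip(ix, 0, nx - 1)
        iy = np.clip(iy, 0, ny - 1)
        return ground, infield, iy, ix

    def render_frame(self, k: int) -> np.ndarray:
        """Anti-aliased RGB frame (uint8, image_h x image_w x 3) at frame k."""
        ground, infield, iy, ix = self._sample_world(k)
        pid = np.where(infield, self._plant_id[iy, ix], 0)
        shade = np.where(infield, self._shade[iy, ix], 1.0).astype(np.float32)
        color = _SOIL_RGB[None, None, :] * shade[..., None]
        veg = pid > 0
        color[veg] = self._colors[pid[veg]]
        color[~ground] = _SKY_RGB
        ss = _SUPERSAMPLE
        h, w = self.camera.image_h, self.camera.image_w
        img = color.reshape(h, ss, w, ss, 3).mean(axis=(1, 3))
        return np.clip(np.round(img), 0, 255).astype(np.uint8)

    def pixel_classes(self, k: int) -> np.ndarray:
        """Per-pixel truth label (uint8) consistent with the rendering.

        A pixel counts as vegetation when a strict majority (>2 of 4) of its
        colour subsamples hit a plant; ties go to soil, so every labelled
        vegetation pixel is at least 75% vegetation-coloured.
        """
        _, infield, iy, ix = self._sample_world(k)
        cls = np.where(infield, self._classes[iy, ix], CLASS_SOIL)
        ss = _SUPERSAMPLE
        h, w = self.camera.image_h, self.camera.image_w
        sub = cls.reshape(h, ss, w, ss)
        crop = (sub == CLASS_CROP).sum(axis=(1, 3))
        weed = (sub == CLASS_WEED).sum(axis=(1, 3))
        veg = crop + weed
        out = np.zeros((h, w), dtype=np.uint8)
        majority = veg > (ss * ss) // 2
        out[majority & (crop >= weed)] = CLASS_CROP
        out[majority & (weed > crop)] = CLASS_WEED
        return out

    def truth_row_centers(self, k: int, n_strips: int = 4) -> np.ndarray:
        """True x-pixels of the 3 central rows at the strip-center scanlines.

        Each world row centerline is a straight ground line, so its image is
        a straight image line; the truth is that line's intersection with the
        strip scanline.
        """
        cam = self.camera
        lat, fwd = self.camera_pose(k)
        cam_k = dataclasses.replace(cam, lateral_offset_m=lat)
        half = cam.image_h - cam.image_h // 2
        vs = cam.image_h // 2 + strip_scanlines(half, n_strips)
        out = np.full((3, n_strips), np.nan)
        for i, r in enumerate(self.spec.central_row_indices):
            row_x = self.spec.row_offsets_m[r]
            p1 = project_world_to_image(cam_k, (row_x, fwd + 4.0), forward_m=fwd)
            p2 = project_world_to_image(cam_k, (row_x, fwd + 12.0), forward_m=fwd)
            if p1 is None or p2 is None:
                continue
            (u1, v1), (u2, v2) = p1, p2
            out[i] = u1 + (u2 - u1) * (vs - v1) / (v2 - v1)
        return out


def generate_sequence(
    spec: SceneSpec,
    camera: CameraModel,
    sway: SwayTrajectory,
    n_frames: int,
    speed_mps: float = 1.667,
    fps: float = 25.0,
    n_strips: int = 4,
) -> tuple[np.ndarray, GroundTruth]:
    """Render ``n_frames`` frames and the matching ground truth.

    Frame k images the field with the camera advanced ``speed_mps/fps``
    meters per frame and laterally displaced by ``sway[k]``.  Output is
    bit-identical for identical specs and seeds.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if len(sway) < n_frames:
        raise ValueError(f"sway has {len(sway)} entries for {n_frames} frames")
    scene = SyntheticScene(spec, camera, sway, speed_mps=speed_mps, fps=fps)
    frames = np.empty(
        (n_frames, camera.image_h, camera.image_w, 3), dtype=np.uint8
    )
    centers = np.empty((n_frames, 3, n_strips))
    forward = np.empty(n_frames)
    for k in range(n_frames):
        frames[k] = scene.render_frame(k)
        centers[k] = scene.truth_row_centers(k, n_strips)
        forward[k] = scene.camera_pose(k)[1]
    half = camera.image_h - camera.image_h // 2
    truth = GroundTruth(
        row_centers_px=centers,
        lateral_offset_m=sway.lateral_offset_m[:n_frames].copy(),
        forward_m=forward,
        strip_scanlines_v=camera.image_h // 2 + strip_scanlines(half, n_strips),
        central_row_offsets_m=spec.row_offsets_m[spec.central_row_indices],
        occupancy=scene._classes.copy(),
        world_cell_m=WORLD_CELL_M,
        world_x_min_m=scene.world_x_min,
    )
    return frames, truth


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_sequence(out_dir, frames: np.ndarray, truth: GroundTruth) -> None:
    """Write numbered PNG frames, a truth JSON and a row-centers CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k in range(frames.shape[0]):
        iio.imwrite(out / f"frame_{k:04d}.png", frames[k])
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1)
    with open(out / "row_centers.csv", "w") as fh:
        fh.write("frame,strip_index,row_index,x_px\n")
        n_frames, n_rows, n_strips = truth.row_centers_px.shape
        for k in range(n_frames):
            for s in range(n_strips):
                for r in range(n_rows):
                    fh.write(
                        f"{k},{s},{r},{truth.row_centers_px[k, r, s]:.3f}\n"
                    )
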