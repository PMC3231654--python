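"""Accumulation of bird's-eye frames into a field-length evidence map.

The field is discretized into square cells (10 mm by default, fine
enough to resolve both weed blobs and the row-straightness scales that the
stabilization comparison measures).  Every
bird's-eye frame is anchored at a reference that advances with the vehicle
(speed/fps meters per frame, 66.68 mm at 6 km/h and 25 fps); each cell hit
by at least one white pixel of a frame gains one count, so a cell's final
value is the number of frames in which vegetation was observed there — a
per-cell level of certainty.  Thresholding at a fraction of the maximum
count (25% by default: a maximum of 17 keeps counts of 4 and up) removes
spurious single-frame segmentation errors, and the result renders as a
grayscale map, lighter where the evidence is stronger.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ipm import BirdsEyeSpec


@dataclass(frozen=True)
class AdvanceModel:
    """Forward motion of the map reference between consecutive frames."""

    speed_mps: float = 1.667
    fps: float = 25.0

    def __post_init__(self) -> None:
        if self.speed_mps <= 0:
            raise ValueError("speed_mps must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @classmethod
    def from_kmh(cls, speed_kmh: float, fps: float = 25.0) -> "AdvanceModel":
        """6 km/h -> 1.667 m/s (rounded to mm/s, the usual printed precision)."""
        return cls(speed_mps=round(speed_kmh / 3.6, 3), fps=fps)

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def advance_per_frame_mm(self) -> float:
        return 1000.0 * self.speed_mps / self.fps


@dataclass
class FieldMap:
    """Integer evidence counts over field cells.

    Rows index the forward (travel) axis, columns the lateral axis centered
    on the vehicle path.  The reference offset is kept in exact millimeters
    and only rounded at cell lookup, so long sequences do not drift.
    """

    counts: np.ndarray            # (ny, nx) int32
    cell_mm: float = 10.0
    origin_forward_mm: float = 0.0
    per_frame_cells: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cell_mm <= 0:
            raise ValueError("cell_mm must be > 0")
        self.counts = np.asarray(self.counts, dtype=np.int32)

    @classmethod
    def empty(
        cls,
        spec: BirdsEyeSpec,
        cell_mm: float = 10.0,
        n_frames: int = 0,
        adv: "AdvanceModel | None" = None,
    ) -> "FieldMap":
        """Map sized for the bird's-eye lateral extent and n_frames of travel."""
        nx = int(math.ceil(spec.out_width_px * spec.mm_per_px_x / cell_mm))
        depth_mm = (spec.rect_bottom_px - spec.rect_top_px) * spec.mm_per_px_y
        travel_mm = n_frames * adv.advance_per_frame_mm if adv is not None else 0.0
        ny = max(int(math.ceil((travel_mm + depth_mm) / cell_mm)) + 1, 1)
        return cls(counts=np.zeros((ny, nx), dtype=np.int32), cell_mm=cell_mm)

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def _grow_to(self, ny_needed: int) -> None:
        ny, nx = self.counts.shape
        if ny_needed <= ny:
            return
        extra = np.zeros((max(ny_needed, int(1.5 * ny)) - ny, nx), dtype=np.int32)
        self.counts = np.vstack([self.counts, extra])


def accumulate_frame(
    fmap: FieldMap,
    be_mask: np.ndarray,
    spec: BirdsEyeSpec,
    frame_index: int,
    adv: AdvanceModel,
) -> FieldMap:
    """Add one bird's-eye frame's vegetation evidence to the map.

    Every white pixel inside the calibrated rectangle maps to world
    millimeters through the bird's-eye scales and the frame's reference
    offset, then to a cell; each distinct cell is incremented at most once
    per frame regardless of how many pixels land in it.
    """
    m = np.asarray(be_mask)
    r0 = int(math.ceil(spec.rect_top_px))
    r1 = int(math.floor(spec.rect_bottom_px))
    rows, cols = np.nonzero(m[r0 : r1 + 1])
    if rows.size == 0:
        fmap.per_frame_cells.append(0)
        return fmap
    rows = rows + r0
    offset_mm = fmap.origin_forward_mm + frame_index * adv.advance_per_frame_mm
    forward_mm = offset_mm + (spec.rect_bottom_px - rows) * spec.mm_per_px_y
    lateral_mm = (cols + 0.5 - spec.out_width_px / 2.0) * spec.mm_per_px_x
    nx = fmap.counts.shape[1]
    iy = np.floor(forward_mm / fmap.cell_mm).astype(np.int64)
    ix = np.floor(lateral_mm / fmap.cell_mm).astype(np.int64) + nx // 2
    keep = (ix >= 0) & (ix < nx) & (iy >= 0)
    iy, ix = iy[keep], ix[keep]
    if iy.size == 0:
        fmap.per_frame_cells.append(0)
        return fmap
    fmap._grow_to(int(iy.max()) + 1)
    flat = np.unique(iy * nx + ix)
    fmap.counts.flat[flat] += 1
    fmap.per_frame_cells.append(int(flat.size))
    return fmap


def map_threshold_value(max_count: int, fraction: float = 0.25) -> int:
    """Cutoff count: round(fraction * max), half away from zero (17 -> 4)."""
    if max_count < 0:
        raise ValueError("max_count must be >= 0")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return int(math.floor(fraction * max_count + 0.5))


def finalize_map(
    fmap: FieldMap, fraction: float = 0.25
) -> tuple[FieldMap, np.ndarray]:
    """Threshold the map and render it to grayscale.

    Counts below round(fraction * max) are zeroed; the image scales counts
    linearly so the maximum count maps to 255 (lighter = more evidence).
    """
    max_count = int(fmap.counts.max()) if fmap.counts.size else 0
    cutoff = map_threshold_value(max_count, fraction)
    kept = np.where(fmap.counts >= cutoff, fmap.counts, 0).astype(np.int32)
    thresholded = FieldMap(
        counts=kept,
        cell_mm=fmap.cell_mm,
        origin_forward_mm=fmap.origin_forward_mm,
        per_frame_cells=list(fmap.per_frame_cells),
    )
    if max_count == 0:
        image = np.zeros(fmap.counts.shape, dtype=np.uint8)
    else:
        image = np.rint(kept.astype(float) / max_count * 255.0).astype(np.uint8)
    return thresholded, image


def _band_residual(
    ys: np.ndarray, xs: np.ndarray, w: np.ndarray
) -> float:
    """RMS perpendicular residual of a line fitted to per-forward-row centroids."""
    rows_u = np.unique(ys)
    if rows_u.size < 2:
        return float("nan")
    xbar = np.array([np.average(xs[ys == r], weights=w[ys == r]) for r in rows_u])
    m, c = np.polyfit(rows_u.astype(float), xbar, 1)
    res = xbar - (m * rows_u + c)
    return math.sqrt(float(np.mean(res**2))) / math.sqrt(1.0 + m * m)


def map_row_straightness(fmap: FieldMap, n_rows: int) -> np.ndarray:
    """Per-row RMS perpendicular residual (cells) of the mapped crop rows.

    Above-threshold cells are clustered into vertical bands: maximal runs of
    occupied lateral columns, which are separated by empty inter-row gaps in
    the thresholded map; the ``n_rows`` most massive bands are kept (the map
    border may clip further neighbouring rows to slivers), ordered left to
    right.  Within each band the count-weighted lateral centroid is taken per
    forward cell row and a line x = m*y + c is fitted.  Straight mapped rows
    give ~0; a row swaying as a sinusoid of amplitude A cells gives ~A/sqrt(2).

    Falls back to a weighted 1-D k-means on the lateral index when the gaps
    have closed up (fewer occupied runs than ``n_rows``).
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    ys, xs = np.nonzero(fmap.counts > 0)
    if ys.size == 0:
        raise ValueError("empty map")
    w = fmap.counts[ys, xs].astype(float)
    xf = xs.astype(float)

    col_mass = np.bincount(xs, weights=w, minlength=fmap.counts.shape[1])
    occupied = np.concatenate(([False], col_mass > 0, [False]))
    edges = np.flatnonzero(np.diff(occupied.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    if starts.size >= n_rows:
        mass = np.array([col_mass[s:e].sum() for s, e in zip(starts, ends)])
        keep = np.sort(np.argsort(mass)[::-1][:n_rows])
        out = np.empty(n_rows)
        for rank, i in enumerate(keep):
            sel = (xs >= starts[i]) & (xs < ends[i])
            out[rank] = _band_residual(ys[sel], xf[sel], w[sel])
        return out

    # fallback: weighted k-means with quantile seeding
    order = np.argsort(xs, kind="stable")
    cum = np.cumsum(w[order])
    centers = np.array(
        [
            xf[order][np.searchsorted(cum, (i + 0.5) / n_rows * cum[-1])]
            for i in range(n_rows)
        ]
    )
    assign = np.zeros(xs.size, dtype=int)
    for _ in range(50):
        assign = np.argmin(np.abs(xf[:, None] - centers[None, :]), axis=1)
        new = centers.copy()
        for i in range(n_rows):
            sel = assign == i
            if sel.any():
                new[i] = np.average(xf[sel], weights=w[sel])
        if np.allclose(new, centers):
            break
        centers = new
    out = np.full(n_rows, np.nan)
    for rank, i in enumerate(np.argsort(centers)):
        sel = assign == i
        if sel.any():
            out[rank] = _band_residual(ys[sel], xf[sel], w[sel])
    return out
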