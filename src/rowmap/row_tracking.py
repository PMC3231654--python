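"""Crop-row detection and frame-to-frame tracking on binary vegetation masks.

The lower half of each segmented frame is divided into four horizontal
strips.  Averaging the mask down each column of a strip gives a *fill
profile* whose wide above-threshold runs locate the crop rows (weeds make
narrow runs because they seldom extend over much vertical distance).  The
three central rows are found in the first frame around the image center
+/- the expected inter-row pixel distance (140 px at the default scale) and
then tracked by searching a window around the previous frame's centers.
A line x = m*y + c is fitted to each row's strip centers; the signed
distance between the central row line and the image vertical centerline,
evaluated near the bottom of the frame, measures how much lateral sway the
stabilization has to absorb.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class TrackerInitializationError(RuntimeError):
    """Raised when too few crop rows are detected in the first frame."""


# ---------------------------------------------------------------------------
# strips and profiles
# ---------------------------------------------------------------------------

def strip_bounds(height: int, n_strips: int = 4) -> list[tuple[int, int]]:
    """Half-open row ranges of ``n_strips`` equal-height strips.

    Remainder rows (when ``height`` is not divisible) go to the bottom strip.
    """
    if n_strips < 1:
        raise ValueError("n_strips must be >= 1")
    q = height // n_strips
    if q < 1:
        raise ValueError(f"n_strips={n_strips} exceeds mask height {height}")
    bounds = [(s * q, (s + 1) * q) for s in range(n_strips)]
    bounds[-1] = (bounds[-1][0], height)
    return bounds


def strip_scanlines(height: int, n_strips: int = 4) -> np.ndarray:
    """Integer center scanline of each strip (e.g. 36, 108, 180, 252 for h=288)."""
    return np.array(
        [start + (end - start) // 2 for start, end in strip_bounds(height, n_strips)],
        dtype=float,
    )


@dataclass(frozen=True)
class StripProfile:
    """Per-column mean foreground fraction over one horizontal strip."""

    strip_index: int
    y_center_px: float
    fill: np.ndarray  # (width,) in [0, 1]


def compute_strip_profiles(mask: np.ndarray, n_strips: int = 4) -> list[StripProfile]:
    """Column fill profiles of ``n_strips`` equal-height strips of a binary mask."""
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    h, _ = m.shape
    ys = strip_scanlines(h, n_strips)
    out = []
    for s, (start, end) in enumerate(strip_bounds(h, n_strips)):
        fill = m[start:end].astype(float).mean(axis=0)
        out.append(StripProfile(strip_index=s, y_center_px=float(ys[s]), fill=fill))
    return out


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """Maximal run of columns whose fill reaches the threshold, [start, end)."""

    start_col: int
    end_col: int

    @property
    def width(self) -> int:
        return self.end_col - self.start_col

    @property
    def center(self) -> float:
        return (self.start_col + self.end_col) / 2.0


def profile_to_blocks(profile: StripProfile, fill_threshold: float = 0.5) -> list[Block]:
    """Left-to-right maximal runs of columns with fill >= fill_threshold."""
    if not 0.0 < fill_threshold < 1.0:
        raise ValueError("fill_threshold must be in (0, 1)")
    above = profile.fill >= fill_threshold
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [Block(int(s), int(e)) for s, e in zip(starts, ends)]


def pick_row_centers(
    blocks: Sequence[Block],
    expected_x: Sequence[float],
    search_halfwidth: float,
    min_row_width: float,
    fill: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Match expected row positions to wide blocks; NaN where nothing qualifies.

    For each expected center the widest block with width >= min_row_width whose
    center lies within +/- search_halfwidth is selected (ties broken by
    proximity, then leftmost).  If two expected centers select the same block,
    the nearer one keeps it and the other is reported missing.

    When the strip's ``fill`` profile is supplied, the returned position is the
    fill-weighted subpixel centroid of the selected block, which coincides with
    the block midpoint (start+end)/2 for flat profiles but averages out the
    single-column jitter of the run boundaries on real ones.
    """
    expected = np.asarray(expected_x, dtype=float)
    chosen: list[Optional[Block]] = []
    for e in expected:
        cands = [
            b
            for b in blocks
            if b.width >= min_row_width and abs(b.center - e) <= search_halfwidth
        ]
        if not cands:
            chosen.append(None)
            continue
        cands.sort(key=lambda b: (-b.width, abs(b.center - e), b.start_col))
        chosen.append(cands[0])
    # resolve conflicts: nearer expected center wins, the other goes missing
    for i in range(len(chosen)):
        for j in range(i + 1, len(chosen)):
            bi, bj = chosen[i], chosen[j]
            if bi is None or bj is None or bi is not bj:
                continue
            if abs(bi.center - expected[i]) <= abs(bj.center - expected[j]):
                chosen[j] = None
            else:
                chosen[i] = None

    def _center(b: Block) -> float:
        if fill is None:
            return b.center
        w = np.asarray(fill, dtype=float)[b.start_col : b.end_col]
        cols = np.arange(b.start_col, b.end_col) + 0.5
        return float(np.sum(cols * w) / np.sum(w))

    return np.array([_center(b) if b is not None else np.nan for b in chosen])


def merge_close_blocks(blocks: Sequence[Block], max_gap: int = 3) -> list[Block]:
    """Bridge runs separated by gaps of at most ``max_gap`` columns.

    A crop-row block can split where a sowing irregularity dips the fill
    profile just under the threshold for a column or two; bridging such
    gaps restores the full-width block (standard run-length smoothing).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    merged: list[Block] = []
    for b in blocks:
        if merged and b.start_col - merged[-1].end_col <= max_gap:
            merged[-1] = Block(merged[-1].start_col, b.end_col)
        else:
            merged.append(b)
    return merged


# ---------------------------------------------------------------------------
# line fitting
# ---------------------------------------------------------------------------

def fit_row_line(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Least-squares fit of x = m*y + c through (y, x) points.

    Regressing x on y keeps near-vertical crop rows finite-sloped.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValueError("need at least two (y, x) points")
    y, x = pts[:, 0], pts[:, 1]
    if np.unique(y).size < 2:
        raise ValueError("need at least two distinct y values")
    m, c = np.polyfit(y, x, 1)
    return float(m), float(c)


# ---------------------------------------------------------------------------
# tracker
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrackerParams:
    """Tunable knobs of the strip-profile row tracker.

    row_spacing_px is the expected image-plane inter-row distance near the
    bottom of the frame (140 px for 0.7 m rows at the reference geometry).
    min_row_width_px separates wide crop-row blocks from narrow weed blocks.
    """

    n_strips: int = 4
    fill_threshold: float = 0.5
    search_halfwidth_px: float = 40.0
    row_spacing_px: float = 140.0
    min_row_width_px: float = 14.0
    init_consistency_tol_px: float = 10.0
    block_merge_gap_px: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.fill_threshold < 1.0:
            raise ValueError("fill_threshold must be in (0, 1)")
        if self.search_halfwidth_px <= 0 or self.row_spacing_px <= 0:
            raise ValueError("search_halfwidth_px and row_spacing_px must be > 0")
        if self.min_row_width_px < 0:
            raise ValueError("min_row_width_px must be >= 0")
        if self.n_strips < 1:
            raise ValueError("n_strips must be >= 1")

    @classmethod
    def for_spacing(cls, row_spacing_px: float, **kw) -> "TrackerParams":
        kw.setdefault("min_row_width_px", 0.1 * row_spacing_px)
        return cls(row_spacing_px=row_spacing_px, **kw)


@dataclass(frozen=True)
class RowObservation:
    """Tracked centers and fitted lines of the three central rows in one frame."""

    frame_index: int
    centers: np.ndarray      # (3, n_strips) x-pixels
    lines: np.ndarray        # (3, 2) slope m and intercept c of x = m*y + c
    found_mask: np.ndarray   # (3, n_strips) True where detected this frame
    strip_ys: np.ndarray     # (n_strips,) strip center scanlines
    image_w: int


@dataclass(frozen=True)
class TrackerState:
    last_centers: np.ndarray  # (3, n_strips)
    strip_ys: np.ndarray
    image_w: int
    params: TrackerParams
    frame_count: int = 0


def _strictly_ordered(col: np.ndarray) -> bool:
    return bool(col[0] < col[1] < col[2])


def initialize_tracker(
    first_mask: np.ndarray, params: TrackerParams = TrackerParams()
) -> TrackerState:
    """Locate the three central rows around W/2 +/- row_spacing_px.

    Fails unless at least two of the three rows are found in at least two
    strips.  The expected positions hold exactly only near the bottom of the
    frame (rows converge upward under perspective), so picks in upper strips
    are kept only when consistent with the straight image line through the
    two bottom-most detections of that row; surviving detections define the
    row line and fill the remaining strips, so tracking starts with a
    complete, ordered 3 x n_strips center array.
    """
    m = np.asarray(first_mask)
    h, w = m.shape
    p = params
    expected = np.array(
        [w / 2.0 - p.row_spacing_px, w / 2.0, w / 2.0 + p.row_spacing_px]
    )
    profiles = compute_strip_profiles(m, p.n_strips)
    strip_ys = np.array([pr.y_center_px for pr in profiles])
    all_blocks = [
        merge_close_blocks(
            profile_to_blocks(pr, p.fill_threshold), p.block_merge_gap_px
        )
        for pr in profiles
    ]
    centers = np.full((3, p.n_strips), np.nan)
    for s, pr in enumerate(profiles):
        centers[:, s] = pick_row_centers(
            all_blocks[s], expected, p.search_halfwidth_px, p.min_row_width_px, pr.fill
        )
    found = ~np.isnan(centers)
    # reject picks inconsistent with the line through the bottom-most two
    # detections of the row (a neighbouring row caught by the search window
    # sits a large, perspective-dependent distance off that line)
    for r in range(3):
        fnd = np.flatnonzero(found[r])
        if fnd.size < 3 or p.n_strips < 3:
            continue
        anchor = fnd[-2:]
        mm, cc = fit_row_line(list(zip(strip_ys[anchor], centers[r, anchor])))
        resid = np.abs(centers[r] - (mm * strip_ys + cc))
        bad = found[r] & (resid > p.init_consistency_tol_px)
        found[r, bad] = False
        centers[r, bad] = np.nan
    rows_ok = (found.sum(axis=1) >= 2).sum()
    if rows_ok < 2:
        raise TrackerInitializationError(
            f"only {rows_ok} of 3 rows found in >=2 strips"
        )
    # second pass: strips the fixed windows missed are re-searched around the
    # row line's prediction, so upper-strip centers are detected rather than
    # extrapolated wherever a block exists there
    predicted = centers.copy()
    for r in range(3):
        if found[r].sum() >= 2:
            mm, cc = fit_row_line(list(zip(strip_ys[found[r]], centers[r, found[r]])))
            predicted[r, ~found[r]] = mm * strip_ys[~found[r]] + cc
        else:
            predicted[r, ~found[r]] = expected[r]
    for s, pr in enumerate(profiles):
        missing = ~found[:, s]
        if not missing.any():
            continue
        repick = pick_row_centers(
            all_blocks[s],
            predicted[:, s],
            p.search_halfwidth_px,
            p.min_row_width_px,
            pr.fill,
        )
        take = missing & ~np.isnan(repick)
        centers[take, s] = repick[take]
        found[take, s] = True
    filled = centers.copy()
    for r in range(3):
        missing = ~found[r]
        if not missing.any():
            continue
        if found[r].sum() >= 2:
            mm, cc = fit_row_line(
                list(zip(strip_ys[found[r]], centers[r, found[r]]))
            )
            filled[r, missing] = mm * strip_ys[missing] + cc
        else:
            filled[r, missing] = expected[r]
    # ordering must hold in every strip; fall back to expected where violated
    for s in range(p.n_strips):
        if not _strictly_ordered(filled[:, s]):
            filled[:, s] = expected
    return TrackerState(
        last_centers=filled,
        strip_ys=strip_ys,
        image_w=w,
        params=p,
        frame_count=0,
    )


def track_frame(
    state: TrackerState, mask: np.ndarray
) -> tuple[RowObservation, TrackerState]:
    """Track the three rows in a new frame around the previous centers.

    Centers not found are carried over from the previous frame and flagged.
    Row lines are fitted to the found centers when at least two exist,
    otherwise to all (carried) centers.
    """
    m = np.asarray(mask)
    h, w = m.shape
    p = state.params
    profiles = compute_strip_profiles(m, p.n_strips)
    picked = np.full((3, p.n_strips), np.nan)
    for s, pr in enumerate(profiles):
        blocks = merge_close_blocks(
            profile_to_blocks(pr, p.fill_threshold), p.block_merge_gap_px
        )
        picked[:, s] = pick_row_centers(
            blocks,
            state.last_centers[:, s],
            p.search_halfwidth_px,
            p.min_row_width_px,
            pr.fill,
        )
    found = ~np.isnan(picked)
    centers = np.where(found, picked, state.last_centers)
    # enforce left < middle < right per strip: drop the found center that
    # moved farthest from its previous position until order is restored
    for s in range(p.n_strips):
        while not _strictly_ordered(centers[:, s]) and found[:, s].any():
            moves = np.where(
                found[:, s],
                np.abs(centers[:, s] - state.last_centers[:, s]),
                -np.inf,
            )
            worst = int(np.argmax(moves))
            found[worst, s] = False
            centers[worst, s] = state.last_centers[worst, s]
    lines = np.full((3, 2), np.nan)
    for r in range(3):
        sel = found[r] if found[r].sum() >= 2 else np.ones(p.n_strips, bool)
        lines[r] = fit_row_line(list(zip(state.strip_ys[sel], centers[r, sel])))
    obs = RowObservation(
        frame_index=state.frame_count,
        centers=centers,
        lines=lines,
        found_mask=found,
        strip_ys=state.strip_ys.copy(),
        image_w=w,
    )
    new_state = dataclasses.replace(
        state, last_centers=centers, frame_count=state.frame_count + 1
    )
    return obs, new_state


# ---------------------------------------------------------------------------
# stabilization-quality statistic
# ---------------------------------------------------------------------------

def central_row_deviation(obs: RowObservation, eval_y: float = 215.0) -> float:
    """Signed px distance of the central row line from the image centerline.

    Evaluated at scanline ``eval_y`` (lower-half coordinates); positive means
    the row sits right of the frame's horizontal center.
    """
    m, c = obs.lines[1]
    if not np.isfinite(m) or not np.isfinite(c):
        raise ValueError("central row line is undefined")
    return float(m * eval_y + c - obs.image_w / 2.0)


def deviation_fraction_of_spacing(
    deviation_px: float, row_spacing_px: float = 140.0
) -> float:
    """|deviation| as a percentage of the inter-row image distance."""
    if row_spacing_px <= 0:
        raise ValueError("row_spacing_px must be > 0")
    return 100.0 * abs(deviation_px) / row_spacing_px


def deviation_stats(deviations: Sequence[float]) -> dict:
    """Summary of a per-frame deviation series (px): mean of |d|, SD, extremes."""
    d = np.asarray(deviations, dtype=float)
    if d.size == 0:
        raise ValueError("empty deviation series")
    return {
        "mean_abs_px": float(np.mean(np.abs(d))),
        "std_px": float(np.std(d)),
        "max_right_px": float(np.max(d)),
        "max_left_px": float(-np.min(d)),
    }
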