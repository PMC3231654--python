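"""End-to-end orchestration: config, the per-frame loop, and run artifacts.

One PipelineConfig carries every parameter of the chain — camera/vehicle,
greenness coefficients, morphology sizes, tracker windows, bird's-eye
geometry, advance model and map settings — so a run is reproducible from
its config echo alone.  run_pipeline() segments each frame's lower half,
tracks the three central rows, estimates the per-frame homography (or
freezes frame 0's when stabilization is off), warps to the bird's-eye
view and accumulates the evidence map.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import yaml

from .ipm import (
    BirdsEyeSpec,
    birdseye_center_offset,
    build_correspondences,
    estimate_homography,
    warp_to_birds_eye,
)
from .mapper import AdvanceModel, FieldMap, accumulate_frame, finalize_map, map_threshold_value
from .row_tracking import (
    RowObservation,
    TrackerParams,
    central_row_deviation,
    initialize_tracker,
    track_frame,
)
from .segmentation import (
    DEFAULT_COEFFICIENTS,
    DILATE_SIZE,
    ERODE_SIZE,
    SegCoefficients,
    segment_frame,
)
from .synthetic_field import (
    CameraModel,
    SceneSpec,
    SwayTrajectory,
    generate_sequence,
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (reported before any processing)."""


class PipelineError(RuntimeError):
    """Processing failure, annotated with the offending frame where known."""


@dataclass(frozen=True)
class SwaySpec:
    """Declarative sway model used by the simulator subcommand."""

    kind: str = "default"          # "default" | "sinusoid" | "zero"
    amplitude_m: float = 0.231     # 0.33 x the 0.7 m inter-row spacing
    # slower than the ~78-frame dwell of a field cell in the camera's view,
    # so the sway survives map accumulation instead of averaging out
    period_frames: float = 300.0
    phase_rad: float = 0.0

    def build(self, n_frames: int, row_spacing_m: float, seed: int) -> SwayTrajectory:
        if self.kind == "zero":
            return SwayTrajectory.zero(n_frames)
        if self.kind == "sinusoid":
            return SwayTrajectory.sinusoidal(
                n_frames, self.amplitude_m, self.period_frames, self.phase_rad
            )
        if self.kind == "default":
            return SwayTrajectory.default(n_frames, row_spacing_m, seed)
        raise ConfigError(f"unknown sway kind {self.kind!r}")


def _nested(cls, value):
    if isinstance(value, cls):
        return value
    if isinstance(value, dict):
        return cls(**value)
    raise ConfigError(f"cannot build {cls.__name__} from {type(value).__name__}")


@dataclass
class PipelineConfig:
    """All knobs of the mapping pipeline, with the reference defaults.

    The defaults reproduce the reference operating point: greenness
    coefficients (-0.884, 1.262, -0.311), 10x15 erosion and 10x20 dilation,
    4 strips, 140 px expected row spacing, 6 km/h at 25 fps, 0.7 m inter-row
    spacing and a 25% map threshold.
    """

    camera: CameraModel = field(default_factory=CameraModel)
    scene: SceneSpec = field(default_factory=SceneSpec)
    sway: SwaySpec = field(default_factory=SwaySpec)
    coefficients: SegCoefficients = field(default_factory=SegCoefficients)
    erode_size: tuple[int, int] = ERODE_SIZE
    dilate_size: tuple[int, int] = DILATE_SIZE
    tracker: TrackerParams = field(default_factory=TrackerParams)
    birdseye: BirdsEyeSpec = field(default_factory=BirdsEyeSpec)
    advance: AdvanceModel = field(default_factory=AdvanceModel)
    map_cell_mm: float = 10.0
    map_fraction: float = 0.25
    eval_y_px: float = 215.0
    stabilize: bool = True
    n_frames: int = 300
    seed: int = 0
    input_dir: Optional[str] = None
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        try:
            self.camera = _nested(CameraModel, self.camera)
            self.scene = _nested(SceneSpec, self.scene)
            self.sway = _nested(SwaySpec, self.sway)
            self.coefficients = _nested(SegCoefficients, self.coefficients)
            self.tracker = _nested(TrackerParams, self.tracker)
            self.birdseye = _nested(BirdsEyeSpec, self.birdseye)
            self.advance = _nested(AdvanceModel, self.advance)
            self.erode_size = tuple(self.erode_size)
            self.dilate_size = tuple(self.dilate_size)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        self.validate()

    def validate(self) -> None:
        problems = []
        if self.map_cell_mm <= 0:
            problems.append("map_cell_mm must be > 0")
        if not 0.0 < self.map_fraction < 1.0:
            problems.append("map_fraction must be in (0, 1)")
        if self.n_frames < 1:
            problems.append("n_frames must be >= 1")
        if self.eval_y_px < 0:
            problems.append("eval_y_px must be >= 0")
        if len(self.erode_size) != 2 or min(self.erode_size) < 1:
            problems.append("erode_size must be two positive ints")
        if len(self.dilate_size) != 2 or min(self.dilate_size) < 1:
            problems.append("dilate_size must be two positive ints")
        if problems:
            raise ConfigError("; ".join(problems))

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, np.generic):
                return v.item()
            return v

        return plain(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


@dataclass
class RunResult:
    """Everything a pipeline run produced, before any disk output."""

    observations: list
    deviations: np.ndarray        # signed px, per frame
    center_offsets: np.ndarray    # bird's-eye central-row offset, per frame
    homographies: np.ndarray      # (n_frames, 3, 3)
    field_map: FieldMap
    thresholded_map: FieldMap
    map_image: np.ndarray
    threshold: int
    summary: dict


def read_frames(frame_dir) -> np.ndarray:
    """Load a numbered PNG/JPEG image-sequence directory, sorted by name."""
    d = Path(frame_dir)
    paths = sorted(
        p for p in d.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
    )
    if not paths:
        raise PipelineError(f"no frames found in {d}")
    frames = []
    for p in paths:
        try:
            img = iio.imread(p)
        except Exception as exc:
            raise PipelineError(f"unreadable frame {p.name}: {exc}") from exc
        if img.ndim == 2:
            img = np.stack([img] * 3, axis=-1)
        frames.append(img[..., :3])
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise PipelineError(f"inconsistent frame shapes: {shapes}")
    return np.stack(frames)


def run_pipeline(
    config: PipelineConfig, frames: Optional[Sequence[np.ndarray]] = None
) -> RunResult:
    """Run segmentation, tracking, stabilization and mapping over a sequence.

    ``frames`` may be given in memory; otherwise they are read from
    ``config.input_dir``.  Deterministic for identical config and input.
    """
    config.validate()
    if frames is None:
        if config.input_dir is None:
            raise ConfigError("no frames given and input_dir not set")
        frames = read_frames(config.input_dir)
    n = len(frames)
    if n < 1:
        raise PipelineError("empty frame sequence")

    fmap = FieldMap.empty(
        config.birdseye, config.map_cell_mm, n_frames=n, adv=config.advance
    )
    observations: list[RowObservation] = []
    deviations = np.empty(n)
    center_offsets = np.empty(n)
    homographies = np.empty((n, 3, 3))
    state = None
    H0 = None
    for k in range(n):
        try:
            mask = segment_frame(
                frames[k], config.coefficients, config.erode_size, config.dilate_size
            )
            if k == 0:
                state = initialize_tracker(mask, config.tracker)
            obs, state = track_frame(state, mask)
            corr = build_correspondences(obs, config.birdseye)
            H = estimate_homography(corr)
            if k == 0:
                H0 = H
            if not config.stabilize:
                H = H0
            be = warp_to_birds_eye(mask, H, config.birdseye)
            accumulate_frame(fmap, be, config.birdseye, k, config.advance)
            observations.append(obs)
            deviations[k] = central_row_deviation(obs, config.eval_y_px)
            center_offsets[k] = birdseye_center_offset(be, config.birdseye)
            homographies[k] = H
        except (ConfigError, PipelineError):
            raise
        except Exception as exc:
            raise PipelineError(f"frame {k}: {exc}") from exc

    thresholded, image = finalize_map(fmap, config.map_fraction)
    max_count = int(fmap.counts.max()) if fmap.counts.size else 0
    threshold = map_threshold_value(max_count, config.map_fraction)
    carried = int(sum((~o.found_mask).sum() for o in observations))
    summary = {
        "frames": n,
        "carried_cells": carried,
        "frames_with_carry": int(
            sum(1 for o in observations if not o.found_mask.all())
        ),
        "map_max_count": max_count,
        "map_threshold": threshold,
        "advance_mm_per_frame": config.advance.advance_per_frame_mm,
        "total_cells_hit": int(sum(fmap.per_frame_cells)),
        "total_map_count": fmap.total_count,
        "stabilize": config.stabilize,
    }
    return RunResult(
        observations=observations,
        deviations=deviations,
        center_offsets=center_offsets,
        homographies=homographies,
        field_map=fmap,
        thresholded_map=thresholded,
        map_image=image,
        threshold=threshold,
        summary=summary,
    )


def simulate_sequence(config: PipelineConfig, n_frames: Optional[int] = None):
    """Generate the synthetic sequence described by a config (frames, truth)."""
    n = n_frames if n_frames is not None else config.n_frames
    scene = dataclasses.replace(config.scene, seed=config.seed)
    sway = config.sway.build(n, scene.row_spacing_m, config.seed)
    return generate_sequence(
        scene,
        config.camera,
        sway,
        n,
        speed_mps=config.advance.speed_mps,
        fps=config.advance.fps,
        n_strips=config.tracker.n_strips,
    )


# ---------------------------------------------------------------------------
# artifact output
# ---------------------------------------------------------------------------

def write_run_artifacts(result: RunResult, config: PipelineConfig, out_dir) -> None:
    """Write CSVs, the map matrix/PNG, a JSON summary and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "observations.csv", "w") as fh:
        fh.write("frame,strip,row,x_px,found,slope,intercept\n")
        for o in result.observations:
            for r in range(3):
                m, c = o.lines[r]
                for s in range(o.centers.shape[1]):
                    fh.write(
                        f"{o.frame_index},{s},{r},{o.centers[r, s]:.4f},"
                        f"{int(o.found_mask[r, s])},{m:.6f},{c:.4f}\n"
                    )
    with open(out / "deviations.csv", "w") as fh:
        fh.write("frame,deviation_px,birdseye_center_offset_px\n")
        for k in range(result.deviations.size):
            fh.write(
                f"{k},{result.deviations[k]:.4f},{result.center_offsets[k]:.4f}\n"
            )
    with open(out / "homographies.csv", "w") as fh:
        fh.write("frame," + ",".join(f"h{i}{j}" for i in range(3) for j in range(3)) + "\n")
        for k in range(result.homographies.shape[0]):
            flat = ",".join(f"{v:.9g}" for v in result.homographies[k].ravel())
            fh.write(f"{k},{flat}\n")
    np.savetxt(out / "map.csv", result.field_map.counts, fmt="%d", delimiter=",")
    iio.imwrite(out / "map.png", result.map_image)
    with open(out / "map_meta.json", "w") as fh:
        json.dump(
            {
                "cell_mm": result.field_map.cell_mm,
                "origin_forward_mm": result.field_map.origin_forward_mm,
                "advance_mm_per_frame": config.advance.advance_per_frame_mm,
                "map_fraction": config.map_fraction,
                "threshold": result.threshold,
                "per_frame_cells": result.field_map.per_frame_cells,
            },
            fh,
            indent=1,
        )
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1, sort_keys=True)
    config.to_yaml(out / "config_echo.yaml")
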