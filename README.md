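# rowmap

Mapping wide-row crop fields (maize-style, ~0.7 m inter-row spacing) from
video taken by a camera on top of a moving tractor. Terrain roughness makes
the camera sway sideways, so the raw footage cannot be accumulated into a
map directly: crop rows would come out as meandering S-shapes. `rowmap`
segments vegetation, tracks the three central crop rows, uses them to
stabilize the sequence via inverse perspective mapping, and integrates the
stabilized frames into a field-length vegetation evidence map showing crop
rows and the weeds between them — the data layer for site-specific weed
treatment.

It is written for researchers in agricultural image analysis / precision
agriculture who want a testable reference implementation of this classic
row-tracking stabilization pipeline, including a synthetic field-video
generator with exact ground truth so every stage can be validated without
recorded footage.

## Method

1. **Segmentation** — each frame's lower half (rows crowd together under
   perspective near the top) is converted to a greenness image
   `gray = r·R + g·G + b·B` with `r = −0.884, g = 1.262, b = −0.311`,
   thresholded per frame by Otsu's criterion, then opened morphologically
   (erosion 10×15, dilation 10×20, width × height) so crop rows stand out
   and small weed blobs disappear.
2. **Row tracking** — the mask is cut into 4 horizontal strips; per-column
   mean fill profiles are thresholded at 0.5 and the wide blocks are the
   rows. The first frame searches around `W/2 ± 140 px`; later frames
   search a ±40 px window around the previous centers. A line `x = m·y + c`
   is fitted per row.
3. **Inverse perspective mapping** — the trapezoid bounded by the two outer
   row lines and the top/bottom strip scanlines is mapped to a centered
   rectangle of width 2 × 0.7 m by a planar homography `u′ = s·H·u`,
   estimated from the 4 corner correspondences (DLT with Hartley
   normalization; 4 points with no 3 collinear determine H up to scale).
   Re-estimating H every frame cancels the sway; freezing frame 0's H
   reproduces the unstabilized behaviour.
4. **Mapping** — each bird's-eye frame is anchored at a reference that
   advances 66.68 mm per frame (6 km/h ≙ 1.667 m/s at 25 fps) and every
   cell (10 mm) hit by vegetation gains one count. Thresholding at 25% of
   the maximum count (a maximum of 17 keeps counts ≥ 4) removes spurious
   detections; the result renders as a grayscale map.

## Worked example

```python
import numpy as np, rowmap as rm

spec   = rm.SceneSpec(gap_prob=0.0, weed_rate=0.0, field_length_m=32.0, seed=1)
sway   = rm.SwayTrajectory.sinusoidal(300, 0.66 * 0.7, 600.0)  # 66% of spacing
frames, truth = rm.generate_sequence(spec, rm.CameraModel(), sway, 300)

res  = rm.run_pipeline(rm.PipelineConfig(scene=spec, n_frames=300), frames)
res0 = rm.run_pipeline(rm.PipelineConfig(scene=spec, n_frames=300,
                                         stabilize=False), frames)

print("centered frames:", (np.abs(res.center_offsets) <= 5).mean())
print("straightness stabilized  :", rm.map_row_straightness(res.thresholded_map, 3))
print("straightness unstabilized:", rm.map_row_straightness(res0.thresholded_map, 3))
```

prints

```
centered frames: 1.0
straightness stabilized  : [0.627 0.406 0.459]
straightness unstabilized: [12.94  12.985 12.86 ]
```

i.e. with per-frame homographies the central row stays within 5 px of the
output center in every frame and the mapped rows are straight to well under
one 10 mm cell (RMS residual of each row band about its fitted line), while
the same input mapped with a frozen homography meanders by ~13 cells —
the visual difference between a usable and an unusable weed map.

A CLI wraps the same steps:

```bash
rowmap simulate --out sim/ --seed 1 --frames 120
rowmap run --frames-dir sim/ --out run/
rowmap evaluate --run-dir run/
rowmap calibrate
```

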