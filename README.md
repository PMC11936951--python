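# ecgloc

Automated 3D localization and channel labeling of body-surface ECG
electrodes from multi-view RGB-D imagery.

Body surface potential mapping (BSPM) records ECG from ~100+ electrodes
arranged in color-coded strips over the whole torso.  Analyses built on it —
above all electrocardiographic imaging (ECGI), the inverse reconstruction of
cardiac surface potentials — need the accurate 3D position *and* the
acquisition-channel identity of every electrode.  CT gives both but costs
radiation; MRI is slow and hardware-constrained.  `ecgloc` implements a
camera-only alternative for researchers and clinical engineers running BSPM
studies: a depth camera circles the torso, and the electrode map falls out
of the geometry.

## Method

Given views i = 1..N with color raster, depth raster (mm) and pinhole
intrinsics (fx, fy, cx, cy):

1. **Back-projection.** Pixel (u, v) with depth d > 0 becomes
   x = (u−cx)d/fx, y = (v−cy)d/fy, z = d in the view's camera frame.
2. **Denoising.** DBSCAN clusters each cloud; only the largest cluster (the
   torso) is kept.
3. **Reconstruction.** Consecutive views are aligned by two-stage ICP
   (point-to-plane, then verification-gated point-to-point refinement) with
   distance-capped, trimmed correspondences; compositions T_i chain every
   view into the frame of view 0.
4. **Electrode extraction and fusion.** Per-view electrode detections
   (bounding box + class A–D) are averaged over their valid-depth pixels to
   3D centers; centers are mapped through T_i and same-class centers within
   14 mm are merged by single linkage, each group replaced by its mean.
5. **Labeling.** Channels are assigned by growing strips in class order:
   the seed pair is the two class electrodes projecting nearest pixel (0,0)
   of the seed view; growth accepts the candidate minimizing perpendicular
   distance to the current strip line subject to the gates
   ‖Δp‖ < 35 mm and |Δx| < 15 mm.
6. **Calibration and evaluation.** A scale-ambiguous map is rescaled by
   s = 30 mm / mean adjacent within-strip spacing.  Accuracy against a
   reference map is measured channel-by-channel after closed-form
   (Umeyama) least-squares alignment: per-electrode 3D and per-axis
   errors, mean ± SD, and chest/abdomen/sides breakdown.

A synthetic phantom simulator (parametric torso surface, 118 electrodes in
15 strips, analytic ray-cast RGB-D rendering, sensor-noise and respiration
models) makes the whole pipeline testable without hardware; see
`docs/methods.md` for the models and their assumptions.

## Worked example

Simulate a noisy acquisition (1 mm depth noise, 1 px detection jitter),
localize, and evaluate against the generator's ground truth:

```sh
ecgloc simulate scratch/demo --seed 1 --depth-sigma 1.0 --pixel-sigma 1.0
ecgloc localize scratch/demo scratch/demo_run
ecgloc evaluate scratch/demo_run/electrodes.csv scratch/demo/ground_truth.csv scratch/demo_eval
```

which prints (timings vary):

```
wrote 12 views, 118 electrodes -> scratch/demo
...
labeled 118 electrodes -> scratch/demo_run/electrodes.csv
mean 3D error 0.54 +/- 0.27 mm over 118 electrodes
```

All 118 electrodes were found, fused and labeled with their correct
channels; after rigid alignment the mean 3D distance to ground truth is
0.54 ± 0.27 mm (this run includes the ±0.5 mm depth quantization of the
on-disk 16-bit PNG format).  `scratch/demo_eval/report.json` holds the
per-axis means (~0.24–0.33 mm, no directional bias) and the per-region
breakdown; `per_electrode.csv` the individual errors.

The same stages are available as a library:

```python
import ecgloc

scene = ecgloc.build_phantom()                      # ground-truth world
rendered = ecgloc.render_views(scene)               # [(RGBDFrame, detections)]
result = ecgloc.localize_frames([f for f, _ in rendered],
                                [d for _, d in rendered])
report = ecgloc.localization_errors(result.labeled_map, scene.ground_truth)
print(f"{report.mean_3d:.2f} +/- {report.sd_3d:.2f} mm")   # 0.10 +/- 0.06 mm
```

## Acceptance script

`scripts/acceptance.py` recomputes the package's quantitative targets from
scratch by building the default phantom and running the full pipeline: the
number of uniquely labeled electrodes from 12 noiseless views, the mean
within-strip spacing after scale-calibrating a map shrunk 1000×, and the
mean 3D localization error under sensor noise (5 seeded replicates, rigid
alignment).  Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(~2 minutes on one CPU); results land in the JSON file given by `--out`.
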