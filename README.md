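# voxelhull

Voxel-based visual-hull reconstruction of articulated subjects from
calibrated multi-camera probability silhouettes, with a segmented variant
that carves each skeleton bone's body segment independently and merges the
results, plus surface-quality metrics against a reference point cloud and a
fully synthetic, analytically ground-truthed scene generator.

## What it does

* **Conventional carve (`sfs`)** — voxel centers are projected into every
  view; per-view silhouette confidences (8-bit, 0–255) are summed and
  compared against a threshold fraction of the views.  A coarse carve over
  the camera rig's bounding box locates the subject, then the occupied box
  is re-carved at a fine voxel size.
* **Segmented carve (`ssfs`)** — 2D joint detections are triangulated into
  a 3D skeleton; every hull voxel is labeled with its nearest bone; each
  segment is projected back into the views to build binary masks that gate
  the silhouettes; per-view segment quality is scored by the
  uncertain-pixel ratio `F = M / N` (uncertain pixels over mask pixels) and
  views with `F` above a threshold are skipped per segment; each segment is
  then carved on a shared voxel lattice and the results are merged by set
  union.
* **Evaluation (`eval`)** — erroneous-voxel count (voxels outside the
  reference surface by the normal-direction sign test, with a one-voxel
  exemption), point-to-surface (P2S) distances of the erosion-surface
  voxels, their RMS, and a 1 mm histogram (40 bins + overflow at 40 mm).
* **Synthetic scenes (`synth`)** — a 34-camera rig (15 columns × 2 cameras
  at 0.5–3 m plus 4 ceiling cameras at 3.5 m), articulated capsule bodies
  with named poses (`sphere`, `t-pose`, `armpit`, `one-bone`, `l-pose`),
  exact ray-traced silhouettes with seeded soft-edge/blob noise, noisy 2D
  joint projections, and uniform-area reference surface samples with exact
  outward normals.

## CLI

A full synthetic round trip:

```sh
voxelhull synth --pose armpit --noise-seed 7 --image-size 512 --out scene/
voxelhull sfs  --calib scene/calibration.json --silhouettes scene/silhouettes \
               --d0 0.064 --d1 0.008 --threshold 0.9 --out sfs.ply
voxelhull ssfs --calib scene/calibration.json --silhouettes scene/silhouettes \
               --joints scene/joints.json --skeleton scene/skeleton.json \
               --d0 0.064 --d1 0.008 --threshold 0.9 --ft 0.3 --out ssfs.ply
voxelhull eval --recon ssfs.ply --reference scene/reference.ply --out report.json
```

Reconstructions are written as PLY point clouds of occupied voxel centers
with a `.meta.json` sidecar (grid origin, voxel size, dims) so `eval` can
rebuild the grid.  Every subcommand accepts `--config file.yaml`; explicit
flags take precedence over config values, which take precedence over
defaults (defaults: `d0` 64 mm, `d1` 4 mm).

## Package layout

| module | contents |
| --- | --- |
| `voxelhull.geometry` | pinhole camera model, projection, pixel rays, multi-ray triangulation, rig bounding box |
| `voxelhull.grid` | voxel grids, coarse-to-fine refitting, erosion surface extraction |
| `voxelhull.carving` | probability-silhouette voting and threshold carving |
| `voxelhull.segmentation` | skeleton triangulation, bone labeling, segment masks, uncertain-ratio view filter |
| `voxelhull.pipeline` | segmented reconstruction orchestration and lattice-exact merging |
| `voxelhull.evaluation` | erroneous voxels, P2S/RMS/histogram, PCA normal estimation |
| `voxelhull.synthetic` | camera rig, capsule bodies, silhouette rendering, reference sampling |
| `voxelhull.io`, `voxelhull.cli` | JSON/PLY/PNG formats and the `voxelhull` command |

## Notes and limitations

* No lens-distortion model; images are assumed pre-undistorted.
* Pixel convention: pixel `(i, j)` covers `[i, i+1) × [j, j+1)`; lookups
  floor continuous coordinates.  Pose is world-to-camera, `x_cam = R x + t`.
* Out-of-frame projections contribute a zero vote by default; an
  alternative policy excluding such views from the denominator is
  available in `CarveConfig`.
* Erosion connectivity defaults to 6 (thinnest closed shell); 26 available.
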