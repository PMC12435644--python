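# mousefield

Finite-element modelling of the electric fields induced by transcranial
current stimulation (tES/tDCS) in small animals, on labeled tetrahedral
body meshes.

Planning a stimulation experiment in a mouse means choosing a montage —
electrode shapes, positions and currents — and often a surgical approach
(skin removal, a cranial recording window). The intracranial field those
choices produce cannot be measured before the experiment, but it can be
computed: tissue is an ohmic volume conductor, so the potential obeys the
current-conservation equation

    div( sigma grad V ) = 0,        E = -grad V,

with Neumann boundary conditions (prescribed normal current density
`J = I / A`) on the electrode contact surfaces. `mousefield` solves this
with linear (P1) tetrahedral finite elements on any labeled tet mesh —
the published whole-mouse meshes (~1M nodes, five tissues) or the built-in
phantom generators — and quantifies the result the way experimentalists
compare montages:

* **Summary statistics** of the field components `eX, eY, eZ` (stereotaxic
  axes: x left→right, y posterior→anterior, z inferior→superior) and the
  magnitude `eMag` (V/m), over whole tissues, box ROIs, or atlas regions.
* **Direction homogeneity** `sqrt(mean(eX_n)² + mean(eY_n)² + mean(eZ_n)²)`
  with `eX_n = eX/eMag`: 1 for a perfectly aligned field, 0 for fully
  opposing directions. Alignment with the neurons' principal axis matters
  as much as magnitude for neural effects.
* **Relative focality** `1 − |{reference nodes: eMag > P·q99.9(target)}| /
  |reference|`: 1 when the field is confined to the target region,
  0 when the whole reference area is stimulated as strongly (default
  P = 0.4, sensitive to diffuse off-target fields).

Montage machinery mirrors the lab bench: *surface* electrodes are gel pads
extruded orthogonally from the skin (disc or cuboid footprints), *insert*
electrodes are conductivity-overridden regions (e.g. a bone screw), and
*craniotomies* relabel the removed skin/bone column with a chosen fill —
air for a dry, insulated window, saline/CSF for a wet one. A bridge to
volumetric label images (NIfTI + affine, e.g. a brain atlas coregistered
to mesh space) resamples fields onto voxels for per-region reports.

## Worked example

A mouse-head-like layered sphere (gray matter core 4 mm; CSF, bone, skin
shells to 5.2 mm) with a dry 1 mm craniotomy at the dorsal pole and a local
anode–cathode pair (±0.2 mA) straddling it:

```python
import mousefield as mf

shells = [mf.Layer("gray_matter", 0.275, 4.0), mf.Layer("csf", 1.654, 4.4),
          mf.Layer("bone", 0.01, 4.8), mf.Layer("soft_tissue", 0.465, 5.2)]
sphere = mf.make_layered_sphere(shells, subdiv=3)

montage = mf.preset_montage("1x1_cran", target_mm=(0, 0, 5.2), pair_offset_mm=2.0)
applied = mf.apply_montage(sphere.mesh, sphere.tissues, montage)
solution = mf.solve(mf.build_problem(applied))

brain = mf.select_tissue_region(applied.mesh, [sphere.label_of["gray_matter"]], "brain")
roi = mf.select_box_roi(applied.mesh, mf.BoxRoiSpec((0, 0, 3.5), 2, 2, 1,
                        tissue_labels=[sphere.label_of["gray_matter"]]))
print(mf.summarize(solution, brain).to_text())
print("ROI focality:", mf.relative_focality(solution, roi, brain.minus(roi)))
```

prints (abridged)

```
region: brain (3853 samples)
         mean   median      std      min      max     norm
eX      0.002    0.002    0.294   -2.359    2.299    0.001
eY     -2.250   -2.030    1.020   -8.858   -0.564   -0.927
eZ      0.001    0.001    0.976   -4.424    4.397    0.001
eMag    2.441    2.175    1.088    1.033    8.863      NaN
direction homogeneity = 0.93
ROI focality: 0.89
```

The dominant negative `eY` is the anterior→posterior field of the local
pair; the focality of 0.89 means only ~11 % of the brain outside the
2×2×1 mm recording ROI sees a field comparable to the ROI itself. The
same comparison with the four-anode ring + back-return montage gives a
focality near 0 (strong fields everywhere), and refilling the window with
saline instead of air drops the whole-brain mean `eMag` by ~30 % — the
kind of montage contrast the model is built to expose. The scripts in
`examples/` walk through these cases and print the numbers they compute.

## Command-line pipeline

For batch use there is a staged, restartable pipeline driven by one YAML
config per run (see `examples/run_sphere.yaml`):

```bash
mousefield all --config examples/run_sphere.yaml --run runs/sphere
mousefield report --run runs/sphere      # tables + section images
```

Stages `init → mesh → solve → analyze` cache their artifacts in the run
folder; a completed stage is skipped unless `--force`, and a config that
drifted from the frozen snapshot is rejected. `report` writes per-region
tables and eMag section images (display values capped at the 98th
percentile).

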