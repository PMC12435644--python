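# Methods

## Physical model

Biological tissue at stimulation frequencies (DC to a few kHz) behaves as
an ohmic volume conductor: capacitive and inductive effects are
negligible, so the potential satisfies the steady current-conservation
equation `div(sigma grad V) = 0` with isotropic, piecewise-constant
conductivity `sigma` per tissue, and the field is `E = -grad V`. Current
enters and leaves through electrode contact surfaces as a Neumann
condition with uniform normal current density `J = I / A` (no
electrode–skin impedance model); the rest of the boundary is insulated.
Injected currents must balance to zero, and the potential is determined
only up to a constant.

Assumptions worth keeping in mind: conductivities of real tissues are
uncertain at the tens-of-percent level and segmentations are imperfect,
so absolute field magnitudes should be read as indicative; the model's
value is in *relative* comparisons between montages (which one is
stronger, better aligned, more focal).

## Discretization

Linear (P1) tetrahedral elements. The element stiffness is
`K_e = sigma_e * Vol_e * (grad phi_i . grad phi_j)`; mesh coordinates are
stored in millimetres (stereotaxic convention) and converted to metres
only inside the assembly, currents mA→A, so reported potentials are volts
and fields V/m with no post-hoc scaling. Contact loads distribute
`J*Area/3` to each triangle vertex; insert electrodes inject a uniform
volumetric density, `I * (Vol_e/RegionVol)/4` per vertex of each source
tet.

The pure-Neumann operator has the constants as null space. The system is
pinned at one node — the lowest-index node on the most negative
electrode's contact (node 0 if there is none) — and the reported
potential is mean-subtracted. This is deterministic and leaves every
current-balanced functional unchanged.

Solvers: sparse LU for meshes up to 50k nodes, Jacobi-preconditioned
conjugate gradients above (relative residual 1e-10 by default, iteration
cap 20k, residual history carried by the non-convergence error). Per-tet
fields `E = -sum_i V_i grad phi_i` are constant; node fields are the
volume-weighted average of incident tet fields, and node magnitudes are
computed *after* averaging so that node-count-weighted summary tables are
well defined. Near conductivity interfaces the true field is
discontinuous and the node average mixes the two sides; statistics over a
tissue are therefore slightly smoothed at its boundary (the slab oracles
in the tests stay one element away from interfaces for exactly this
reason).

Properties the test suite verifies: P1 completeness (globally linear
solutions — the Ohm's-law slab — are reproduced to solver tolerance),
the series-conductor field ratio `sigma1/sigma2` across a two-layer slab
to 1e-6, discrete reciprocity between electrode pairs (exact when
voltages are read with the load-conjugate, area-weighted node averaging),
linearity in the injected currents, and L2 convergence of observed order
~2 against a manufactured harmonic solution (`u = x^2 - z^2` with exact
Neumann data on the mesh's own faces) on both slab and sphere
refinements.

### Flux recovery

`check_flux` recovers each electrode's current as the surface integral of
`sigma * E . n` over its contact triangles with the owning tet's constant
field — deliberately *not* the algebraic load sum, which is exact by
construction and checks nothing. This gradient-based recovery converges
to the injected current as the extrusion is refined through the electrode
thickness: surface electrodes are therefore extruded in sublayers
(`n_layers`, default 8 in the pipeline). At 24 sublayers the recovered
currents on the sphere-phantom montages are within 1% of specification;
at coarse single-layer extrusion the cap integral can be off by ~15%
because the through-electrode gradient is unresolved and side walls leak
weakly-enforced flux.

## Montage construction

Membership everywhere is decided by centroids — boundary-triangle
centroids for electrode footprints, tet centroids for insert regions and
craniotomy columns — giving a deterministic partition that brute-force
oracles reproduce exactly.

*Surface electrodes.* The footprint is the connected patch of boundary
triangles facing the snapped center (surface normal on the same side),
inside the disc/cuboid column, and within an axial window of half the
footprint diagonal (so a thin body's far side is never captured). The
patch is extruded along per-vertex area-weighted normals by the electrode
thickness in `n_layers` sublayers; each prism splits into three tets with
a diagonal rule keyed on global node ids, so neighbouring prisms conform
and the electrode is watertight. The fresh label gets the gel
conductivity (0.3 S/m default). Current is injected through the outer
extruded cap — the "connector on top of the gel pad" choice; the physical
contact location inside a gel electrode is not well defined and this one
is deterministic. Extrusions never move or relabel pre-existing mesh
entities; an extrusion that would fold (non-positive prism volumes)
raises with the offending faces.

*Insert electrodes.* Tets with centroid inside the cylinder/cuboid are
relabeled with the electrode conductivity; injection is a uniform
volumetric source over the region (total current preserved). No nodes
move.

*Craniotomies.* Tets of removable tissues (default: skin/soft tissue and
bone) with centroid inside the footprint column are relabeled to the fill
conductivity — 2.5e-14 S/m (air) for a dry window, 1.654 S/m
(saline/CSF) for a wet one. The column axis defaults to the local skin
normal direction supplied by the caller (+z for the dorsal phantom
target) and runs through the whole mesh; the tissue filter is what
limits the carving depth. Other tissues are never touched, and
re-applying the same craniotomy is a geometric no-op.

*Presets.* Four study montages are provided around a target point:
`1xBack` (0.6 mm disc anode +0.2 mA, distant cuboid return −0.2 mA),
`1x4` (the anode plus four −0.05 mA disc cathodes on a ring),
`4xBack_cran` (four +0.05 mA anodes ringing a 1 mm craniotomy, distant
return) and `1x1_cran` (±0.2 mA pair straddling the craniotomy
anterior/posterior). Ring radius (default 2.5 mm), pair offset (2 mm),
back-pad location (default: the target's antipode through the origin,
suiting centred phantoms) and sizes are parameters: these geometric
details are lab choices, not fixed constants, and published tables do not
pin them.

## Field metrics

Statistics are node-weighted (each node counts once), matching summary
tables that report node counts; voxel-resampled atlas regions are
voxel-weighted for the same reason. Normalized components `e*_n = e*/eMag`
exclude nodes with `eMag < 1e-15 V/m` to avoid 0/0 without touching
physical fields; an all-zero region reports zero norms with a flag.
Direction homogeneity is the length of the mean normalized vector.

Relative focality uses `T = P * percentile(eMag_target, 99.9)` with
linear interpolation between order statistics (the numpy default — the
99.9th percentile of a large node set is rule-sensitive in its last
digit, so the rule is documented) and a *strict* comparison `eMag > T`,
so ties fall below threshold. Defaults `P = 0.4`, percentile 99.9.
Box ROIs are closed axis-aligned boxes `center ± size/2`, optionally
intersected with the nodes of given tissue labels. The display helper
`cap_percentile` clips values above a percentile (98 by default) for
plots only; statistics never see capped values.

## Atlas bridge

A label volume is a 3D integer array with a voxel→mm affine (NIfTI via
nibabel; orientation comes from the affine alone, no axis heuristics) and
a label→name table. Voxel centers are located in the mesh with a uniform
grid over tet bounding boxes and a barycentric test (tolerance 1e-9,
lowest tet index wins ties on shared faces); node fields are
barycentrically interpolated, which reproduces constants and any
per-element-linear field exactly. The magnitude is the norm of the
interpolated vector. Coregistration of a real atlas to mesh space is out
of scope: the module consumes an already-aligned volume, and the phantom
module can voxelize any mesh into a perfectly aligned label volume for
testing.

## Phantoms

The generators provide analytic ground truth at desk scale; they are
deterministic (bit-identical across runs) and pass full mesh validation.

*Slab*: a structured lattice of cuboid cells, each split into six tets by
the Kuhn (permutation) decomposition, which conforms across cells. Layer
interfaces must land on lattice planes, so the two-layer series oracle is
exact in the P1 space. Volumes are exact by construction.

*Layered sphere*: nested tissue shells built from a subdivided
icosahedral surface (subdiv 3 by default, 642 vertices per ring) with
radial rings snapped to every shell boundary; ring pairs are joined by
prisms split with the same global-id diagonal rule, and the core attaches
to a center node. The polyhedral boundary is closed (Euler characteristic
2) and its volume is within ~1% of the ball at subdiv 3 (the 5%
documented tolerance is conservative). Default study shells emulate a
mouse head: gray matter to 4 mm, CSF to 4.4, bone to 4.8, skin to
5.2 mm, with conductivities 0.275 / 1.654 / 0.01 / 0.465 S/m.

What the phantoms do *not* emulate: real cortical folding and anatomy,
eyes and air cavities, anisotropic conductivity, electrode–skin contact
impedance. Passing phantom tests therefore validates the numerics and the
montage/metric machinery, and the qualitative montage contrasts (a tight
center-surround montage yields a several-fold weaker whole-brain field
than a distant return; a local pair is far more focal at a dorsal ROI
than a ring with a distant return; a saline-filled window shunts ~30% of
the brain field relative to a dry one at this geometry) — not the
absolute field values in any particular animal.

## Problem sizes

Default test and acceptance runs use the subdiv-3 sphere (~6k nodes /
32k tets with electrodes) and 1 mm slabs (~1.3k nodes), which solve by
sparse LU in well under a second each; the flux-conservation runs use
24 extrusion sublayers as discussed above; the convergence study goes up
to the subdiv-4 sphere (~36k nodes). These sizes are chosen because every
oracle here is resolution-controlled — larger meshes change nothing but
runtime. The same code paths run the ~1M-node published mouse meshes via
the CG solver.

## Known limitations

* Isotropic conductivities only; no tensors, no higher-order elements,
  no adaptive refinement, no time-varying (tACS) phasors.
* Node-averaged fields smooth discontinuities at tissue interfaces by one
  element (see Discretization); per-tet fields are available when the
  jump matters.
* The element-to-node recovery rule is volume-weighted averaging; other
  FEM packages use different recovery schemes, so node-level tables can
  differ from theirs in the last digit even on identical meshes.
* Surface extrusion assumes a locally star-shaped skin patch; extreme
  concavities under a large pad would fold and are rejected rather than
  repaired.
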