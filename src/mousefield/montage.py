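"""Stimulation montages: electrodes, craniotomies and presets.

Surface electrodes are built by orthogonal extrusion of the skin surface
(one prism layer split into tets), so they mold to the body like a gel pad.
Insert electrodes and craniotomies do not change the geometry at all — they
reassign conductivities of existing tets. Membership everywhere is decided
by element/triangle *centroids*, which gives an unambiguous partition that
brute-force oracles can reproduce exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mesh import (
    BoundarySurface,
    MeshError,
    TetMesh,
    TissueTable,
    extract_boundary,
    split_prism,
    tet_geometry,
)

logger = logging.getLogger("mousefield")

__all__ = [
    "MontageError",
    "ElectrodeSpec",
    "CraniotomySpec",
    "MontageSpec",
    "ElectrodePlacement",
    "CraniotomyRecord",
    "MontageResult",
    "place_surface_electrode",
    "place_insert_electrode",
    "carve_craniotomy",
    "apply_montage",
    "preset_montage",
    "PRESET_NAMES",
]

CURRENT_BALANCE_TOL_MA = 1e-12


class MontageError(ValueError):
    """Raised for invalid montage specifications or placements."""


def _unit(v, what: str = "axis") -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if not np.isfinite(n) or n == 0:
        raise MontageError(f"{what} must be a nonzero vector")
    return v / n


def _tangent_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (deterministic choice)."""
    helper = np.array([0.0, 0.0, 1.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    t1 = _unit(np.cross(helper, axis))
    t2 = np.cross(axis, t1)
    return t1, t2


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class ElectrodeSpec:
    """One stimulation electrode.

    ``surface`` electrodes (disc or cuboid footprint) are extruded from the
    skin along local normals by ``thickness_mm``; ``insert`` electrodes
    relabel a cylindrical/cuboid region of existing tets (depth measured
    from ``center`` along ``axis``). Currents are in mA (anode > 0).
    """

    name: str
    kind: str  # surface | insert
    shape: str  # disc | cuboid
    center_mm: tuple[float, float, float]
    current_mA: float
    radius_mm: float | None = None
    width_mm: float | None = None
    length_mm: float | None = None
    thickness_mm: float = 1.0
    depth_mm: float | None = None
    axis: tuple[float, float, float] | None = None  # insert axis / cuboid orientation
    conductivity_S_per_m: float = 0.3  # electrode gel

    def __post_init__(self):
        if self.kind not in ("surface", "insert"):
            raise MontageError(f"electrode {self.name!r}: kind must be surface|insert")
        if self.shape not in ("disc", "cuboid"):
            raise MontageError(f"electrode {self.name!r}: shape must be disc|cuboid")
        if self.shape == "disc":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise MontageError(f"electrode {self.name!r}: disc needs radius_mm > 0")
        else:
            if not (self.width_mm and self.length_mm) or self.width_mm <= 0 or self.length_mm <= 0:
                raise MontageError(f"electrode {self.name!r}: cuboid needs width/length > 0")
        if self.kind == "surface" and self.thickness_mm <= 0:
            raise MontageError(f"electrode {self.name!r}: thickness_mm must be > 0")
        if self.kind == "insert" and (self.depth_mm is None or self.depth_mm <= 0):
            raise MontageError(f"electrode {self.name!r}: insert needs depth_mm > 0")
        if not np.isfinite(self.current_mA):
            raise MontageError(f"electrode {self.name!r}: current must be finite")
        if self.conductivity_S_per_m <= 0:
            raise MontageError(f"electrode {self.name!r}: conductivity must be > 0")


@dataclass
class CraniotomySpec:
    """Circular or rectangular bone/skin removal, modeled as a conductivity
    reassignment of the removed column (fill: air for a dry window,
    saline/CSF for a wet one)."""

    shape: str  # circular | rectangular
    center_mm: tuple[float, float, float]
    radius_mm: float | None = None
    width_mm: float | None = None
    length_mm: float | None = None
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    fill_conductivity_S_per_m: float = 2.5e-14  # dry (air)
    fill_name: str = "craniotomy"

    def __post_init__(self):
        if self.shape not in ("circular", "rectangular"):
            raise MontageError("craniotomy shape must be circular|rectangular")
        if self.shape == "circular":
            if self.radius_mm is None or self.radius_mm <= 0:
                raise MontageError("circular craniotomy needs radius_mm > 0")
        elif not (self.width_mm and self.length_mm) or self.width_mm <= 0 or self.length_mm <= 0:
            raise MontageError("rectangular craniotomy needs width/length > 0")
        if self.fill_conductivity_S_per_m <= 0:
            raise MontageError("fill conductivity must be > 0")


@dataclass
class MontageSpec:
    name: str
    electrodes: list[ElectrodeSpec]
    craniotomy: CraniotomySpec | None = None

    def validate(self) -> None:
        currents = np.array([e.current_mA for e in self.electrodes])
        if not (currents > 0).any() or not (currents < 0).any():
            raise MontageError(f"montage {self.name!r}: need at least one anode and one cathode")
        if abs(currents.sum()) > CURRENT_BALANCE_TOL_MA:
            raise MontageError(
                f"montage {self.name!r}: currents sum to {currents.sum():g} mA, not 0"
            )


# ---------------------------------------------------------------------------
# Placement records
# ---------------------------------------------------------------------------


@dataclass
class ElectrodePlacement:
    """What an electrode op did to the mesh: the fresh tissue label, the
    triangles through which current is injected (surface electrodes), or the
    relabeled tets acting as a uniform volumetric source (inserts)."""

    name: str
    label: int
    current_mA: float
    contact_tris: np.ndarray | None = None  # (K, 3) node ids, outward oriented
    contact_area_mm2: float | None = None
    source_tets: np.ndarray | None = None  # (K,) tet ids
    added_tets: np.ndarray | None = None  # tet ids appended by extrusion
    added_volume_mm3: float | None = None


@dataclass
class CraniotomyRecord:
    label: int
    relabeled_tets: np.ndarray
    previous_labels: np.ndarray


@dataclass
class MontageResult:
    mesh: TetMesh
    tissues: TissueTable
    placements: list[ElectrodePlacement]
    craniotomy: CraniotomyRecord | None = None


# ---------------------------------------------------------------------------
# Surface electrodes
# ---------------------------------------------------------------------------


def _snap_to_surface(
    surf: BoundarySurface, center: np.ndarray, snap_mm: float
) -> tuple[np.ndarray, np.ndarray, int]:
    d2 = np.einsum("ij,ij->i", surf.centroids - center, surf.centroids - center)
    i = int(np.argmin(d2))
    dist = float(np.sqrt(d2[i]))
    if dist > snap_mm:
        raise MontageError(
            f"electrode center {center.tolist()} is {dist:.2f} mm from the surface "
            f"(snap distance {snap_mm:g} mm)"
        )
    return surf.centroids[i], surf.normals[i], i


def _footprint_mask(
    spec: ElectrodeSpec | CraniotomySpec,
    points: np.ndarray,
    origin: np.ndarray,
    axis: np.ndarray,
) -> np.ndarray:
    """Centroid membership in the footprint (projected onto the plane through
    ``origin`` orthogonal to ``axis``)."""
    t1, t2 = _tangent_frame(axis)
    if getattr(spec, "axis", None) is not None and isinstance(spec, ElectrodeSpec):
        pass  # cuboid in-plane orientation uses the default deterministic frame
    d = points - origin
    u = d @ t1
    v = d @ t2
    circular = spec.shape in ("disc", "circular")
    if circular:
        return u * u + v * v <= spec.radius_mm**2
    return (np.abs(u) <= spec.width_mm / 2.0) & (np.abs(v) <= spec.length_mm / 2.0)


def _connected_patch(tris: np.ndarray, mask: np.ndarray, seed_row: int) -> np.ndarray:
    """Restrict ``mask`` to the edge-connected component containing
    ``seed_row`` (or, if the seed itself is outside the mask, the component
    nearest to it is kept by seeding from every masked triangle sharing a
    node with the seed)."""
    rows = np.nonzero(mask)[0]
    if rows.size == 0:
        return mask
    node_to_rows: dict[int, list[int]] = {}
    for r in rows:
        for n in tris[r]:
            node_to_rows.setdefault(int(n), []).append(int(r))
    if mask[seed_row]:
        frontier = [int(seed_row)]
    else:
        seed_nodes = set(int(n) for n in tris[seed_row])
        frontier = [r for n in seed_nodes for r in node_to_rows.get(n, [])]
        if not frontier:
            frontier = [int(rows[0])]
    visited = set(frontier)
    while frontier:
        r = frontier.pop()
        for n in tris[r]:
            for r2 in node_to_rows[int(n)]:
                if r2 not in visited:
                    visited.add(r2)
                    frontier.append(r2)
    keep = np.zeros_like(mask)
    keep[list(visited)] = True
    return keep & mask


def place_surface_electrode(
    mesh: TetMesh,
    tissues: TissueTable,
    spec: ElectrodeSpec,
    snap_mm: float = 2.0,
    n_layers: int = 3,
) -> tuple[TetMesh, TissueTable, ElectrodePlacement]:
    """Extrude a gel electrode outward from the skin.

    Boundary triangles whose centroids fall inside the footprint (around the
    spec center snapped to the surface) are extruded along per-vertex
    averaged outward normals by ``thickness_mm``; each prism is split into 3
    tets with a global-id diagonal rule so neighbouring prisms conform. The
    electrode gets a fresh tissue label; the returned placement carries the
    outer extruded cap as the contact surface for current injection.
    ``n_layers`` stacks the extrusion in sublayers so the through-electrode
    field is resolved (flux recovered at the cap converges to the injected
    current).

    Never modifies pre-existing tets' labels or node coordinates.
    """
    if spec.kind != "surface":
        raise MontageError(f"electrode {spec.name!r} is not a surface electrode")
    surf = extract_boundary(mesh)
    center = np.asarray(spec.center_mm, dtype=float)
    origin, normal, seed = _snap_to_surface(surf, center, snap_mm)

    # footprint = in-column triangles facing the same way, within an axial
    # window of the snap point (so a distant far side of the body is never
    # captured), restricted to the connected patch containing the snap point
    if spec.shape == "disc":
        halfdiag = spec.radius_mm
    else:
        halfdiag = 0.5 * float(np.hypot(spec.width_mm, spec.length_mm))
    axial = (surf.centroids - origin) @ normal
    same_side = surf.normals @ normal > 0.0
    inside = (
        _footprint_mask(spec, surf.centroids, origin, normal)
        & same_side
        & (np.abs(axial) <= halfdiag)
    )
    if not inside.any():
        raise MontageError(f"electrode {spec.name!r}: footprint misses the surface")
    inside = _connected_patch(surf.tris, inside, seed)
    if not inside.any():
        raise MontageError(f"electrode {spec.name!r}: footprint misses the surface")
    foot_tris = surf.tris[inside]

    # per-vertex area-weighted normals over all incident boundary triangles
    verts = np.unique(foot_tris)
    vnorm = np.zeros((mesh.n_nodes, 3))
    np.add.at(vnorm, surf.tris[:, 0], surf.normals * surf.areas[:, None])
    np.add.at(vnorm, surf.tris[:, 1], surf.normals * surf.areas[:, None])
    np.add.at(vnorm, surf.tris[:, 2], surf.normals * surf.areas[:, None])
    vn = vnorm[verts]
    norms = np.linalg.norm(vn, axis=1)
    if (norms == 0).any():
        raise MontageError(f"electrode {spec.name!r}: isolated footprint vertex")
    vn /= norms[:, None]

    if n_layers < 1:
        raise MontageError("n_layers must be >= 1")
    nv = len(verts)
    layer_nodes = [
        mesh.nodes[verts] + vn * (spec.thickness_mm * k / n_layers)
        for k in range(1, n_layers + 1)
    ]
    # ids: layer k occupies mesh.n_nodes + (k-1)*nv .. ; verts ascending, so
    # every layer's ids preserve the bottom order (diagonal rule consistent)
    layer_of = []
    for k in range(n_layers):
        ids = np.full(mesh.n_nodes, -1, dtype=np.int64)
        ids[verts] = mesh.n_nodes + k * nv + np.arange(nv)
        layer_of.append(ids)

    bottoms = [foot_tris] + [ids[foot_tris] for ids in layer_of[:-1]]
    tops = [ids[foot_tris] for ids in layer_of]
    new_tets = np.vstack([split_prism(b, t) for b, t in zip(bottoms, tops)])
    top_of = layer_of[-1]

    # self-intersection check: the 3 tets of each prism must be consistently
    # oriented with nonzero volume
    all_nodes = np.vstack([mesh.nodes, *layer_nodes])
    a, b, c, d = (all_nodes[new_tets[:, i]] for i in range(4))
    vol6 = np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a).reshape(-1, 3)
    tol = 1e-12 * max(np.abs(vol6).max(), 1.0)
    ok = (vol6 > tol).all(axis=1) | (vol6 < -tol).all(axis=1)
    if not ok.all():
        bad = np.unique(np.nonzero(~ok)[0] % len(foot_tris))
        raise MontageError(
            f"electrode {spec.name!r}: self-intersecting extrusion at footprint "
            f"faces {bad[:10].tolist()}"
        )

    tissues = tissues.copy()
    label = tissues.add(f"electrode:{spec.name}", spec.conductivity_S_per_m)
    new_mesh = TetMesh(
        all_nodes,
        np.vstack([mesh.tets, new_tets]),
        np.concatenate([mesh.tet_label, np.full(len(new_tets), label, dtype=np.int64)]),
    )

    contact = top_of[foot_tris]
    p0, p1, p2 = (all_nodes[contact[:, i]] for i in range(3))
    contact_area = float(0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1).sum())
    added = np.arange(mesh.n_tets, new_mesh.n_tets)
    added_volume = float(tet_geometry(new_mesh).volumes[added].sum())
    logger.info(
        "electrode %s: %d footprint faces, contact area %.3f mm^2, volume %.3f mm^3",
        spec.name, len(foot_tris), contact_area, added_volume,
    )
    return new_mesh, tissues, ElectrodePlacement(
        name=spec.name,
        label=label,
        current_mA=spec.current_mA,
        contact_tris=contact,
        contact_area_mm2=contact_area,
        added_tets=added,
        added_volume_mm3=added_volume,
    )


# ---------------------------------------------------------------------------
# Insert electrodes
# ---------------------------------------------------------------------------


def _region_mask(
    spec, centroids: np.ndarray, center: np.ndarray, axis: np.ndarray, depth: float | None
) -> np.ndarray:
    """Centroid membership in a (finite or infinite) cylinder/cuboid column."""
    d = centroids - center
    t = d @ axis
    circular = spec.shape in ("disc", "circular")
    if circular:
        radial2 = np.einsum("ij,ij->i", d, d) - t * t
        inside = radial2 <= spec.radius_mm**2
    else:
        t1, t2 = _tangent_frame(axis)
        inside = (np.abs(d @ t1) <= spec.width_mm / 2.0) & (np.abs(d @ t2) <= spec.length_mm / 2.0)
    if depth is not None:
        inside &= (t >= 0.0) & (t <= depth)
    return inside


def place_insert_electrode(
    mesh: TetMesh, tissues: TissueTable, spec: ElectrodeSpec
) -> tuple[TetMesh, TissueTable, ElectrodePlacement]:
    """Relabel a cylindrical/cuboid region as a (typically highly conductive)
    insert electrode; current is injected as a uniform volumetric source
    density over the region. No nodes or tets are added or moved."""
    if spec.kind != "insert":
        raise MontageError(f"electrode {spec.name!r} is not an insert electrode")
    axis = _unit(spec.axis if spec.axis is not None else (0.0, 0.0, -1.0))
    centroids = tet_geometry(mesh).centroids
    inside = _region_mask(spec, centroids, np.asarray(spec.center_mm, float), axis, spec.depth_mm)
    if not inside.any():
        raise MontageError(f"electrode {spec.name!r}: insert region contains no tets")
    tissues = tissues.copy()
    label = tissues.add(f"electrode:{spec.name}", spec.conductivity_S_per_m)
    new_labels = mesh.tet_label.copy()
    new_labels[inside] = label
    new_mesh = TetMesh(mesh.nodes, mesh.tets, new_labels)
    ids = np.nonzero(inside)[0]
    logger.info("insert electrode %s: relabeled %d tets", spec.name, len(ids))
    return new_mesh, tissues, ElectrodePlacement(
        name=spec.name, label=label, current_mA=spec.current_mA, source_tets=ids
    )


# ---------------------------------------------------------------------------
# Craniotomy
# ---------------------------------------------------------------------------


def carve_craniotomy(
    mesh: TetMesh,
    tissues: TissueTable,
    spec: CraniotomySpec,
    removable_labels: Sequence[int] | None = None,
) -> tuple[TetMesh, TissueTable, CraniotomyRecord]:
    """Relabel surgically removed skin/bone as the craniotomy fill material.

    Tets whose label is removable and whose centroid lies inside the
    footprint column (circular -> cylinder along ``axis``, rectangular ->
    box) get a fresh label with ``fill_conductivity_S_per_m``. Other tissues
    are never touched. Re-applying the same craniotomy is a geometric no-op.
    """
    if removable_labels is None:
        removable_labels = [
            label
            for label, e in tissues.items()
            if e.name in ("soft_tissue", "skin", "bone")
        ]
        if not removable_labels:
            raise MontageError("no default removable tissues (soft_tissue/skin/bone) in table")
    removable_labels = np.asarray(list(removable_labels), dtype=np.int64)
    unknown = set(removable_labels.tolist()) - set(tissues.labels)
    if unknown:
        raise MeshError(f"removable labels {sorted(unknown)} not in tissue table")

    axis = _unit(spec.axis)
    centroids = tet_geometry(mesh).centroids
    in_column = _region_mask(spec, centroids, np.asarray(spec.center_mm, float), axis, None)
    removable = np.isin(mesh.tet_label, removable_labels)
    target = in_column & removable
    if not target.any():
        already = in_column & np.isin(
            mesh.tet_label,
            [l for l, e in tissues.items() if e.name.startswith(spec.fill_name)],
        )
        if already.any():  # same craniotomy applied twice: no-op
            label = int(mesh.tet_label[np.nonzero(already)[0][0]])
            return mesh, tissues, CraniotomyRecord(
                label=label,
                relabeled_tets=np.empty(0, dtype=np.int64),
                previous_labels=np.empty(0, dtype=np.int64),
            )
        raise MontageError("craniotomy footprint intersects no removable tets")

    tissues = tissues.copy()
    label = tissues.add(spec.fill_name, spec.fill_conductivity_S_per_m)
    ids = np.nonzero(target)[0]
    prev = mesh.tet_label[ids].copy()
    new_labels = mesh.tet_label.copy()
    new_labels[ids] = label
    new_mesh = TetMesh(mesh.nodes, mesh.tets, new_labels)
    logger.info("craniotomy: relabeled %d tets to %s", len(ids), spec.fill_name)
    return new_mesh, tissues, CraniotomyRecord(label=label, relabeled_tets=ids, previous_labels=prev)


# ---------------------------------------------------------------------------
# Whole montages
# ---------------------------------------------------------------------------


def apply_montage(
    mesh: TetMesh,
    tissues: TissueTable,
    montage: MontageSpec,
    snap_mm: float = 2.0,
    removable_labels: Sequence[int] | None = None,
    n_layers: int = 3,
) -> MontageResult:
    """Carve the craniotomy (if any), then place every electrode in order."""
    montage.validate()
    cran = None
    if montage.craniotomy is not None:
        mesh, tissues, cran = carve_craniotomy(
            mesh, tissues, montage.craniotomy, removable_labels
        )
    placements = []
    for espec in montage.electrodes:
        if espec.kind == "surface":
            mesh, tissues, placement = place_surface_electrode(
                mesh, tissues, espec, snap_mm, n_layers=n_layers
            )
        else:
            mesh, tissues, placement = place_insert_electrode(mesh, tissues, espec)
        placements.append(placement)
    return MontageResult(mesh=mesh, tissues=tissues, placements=placements, craniotomy=cran)


PRESET_NAMES = ("1xBack", "1x4", "4xBack_cran", "1x1_cran")


def preset_montage(
    name: str,
    target_mm: Sequence[float],
    axis: Sequence[float] = (0.0, 0.0, 1.0),
    ring_radius_mm: float = 2.5,
    pair_offset_mm: float = 2.0,
    back_center_mm: Sequence[float] | None = None,
    back_size_mm: tuple[float, float] = (15.0, 15.0),
    disc_radius_mm: float = 0.6,
    thickness_mm: float = 1.0,
    craniotomy_radius_mm: float = 1.0,
    fill_conductivity_S_per_m: float = 2.5e-14,
    gel_conductivity_S_per_m: float = 0.3,
) -> MontageSpec:
    """The four study montages, parameterised around a surface target point.

    ``1xBack``: one disc anode (+0.2 mA) at the target, one large cuboid
    cathode (-0.2 mA) at ``back_center_mm``. ``1x4``: disc anode (+0.2 mA)
    with four disc cathodes (-0.05 mA each) on a surrounding ring.
    ``4xBack_cran``: circular craniotomy at the target, four disc anodes
    (+0.05 mA each) around it, cuboid back cathode (-0.2 mA). ``1x1_cran``:
    craniotomy at the target, disc anode (+0.2 mA) anterior and disc cathode
    (-0.2 mA) posterior of it.

    Ring radius, pair offset and the back-electrode location are geometry
    the user must choose for their animal; ``back_center_mm`` defaults to
    the target's antipode through the origin, which suits centred phantoms.
    """
    target = np.asarray(target_mm, dtype=float)
    ax = _unit(np.asarray(axis, float))
    t1, t2 = _tangent_frame(ax)
    if back_center_mm is None:
        back_center_mm = tuple((-target).tolist())

    def disc(nm, center, current):
        return ElectrodeSpec(
            name=nm, kind="surface", shape="disc", center_mm=tuple(np.asarray(center, float)),
            current_mA=current, radius_mm=disc_radius_mm, thickness_mm=thickness_mm,
            conductivity_S_per_m=gel_conductivity_S_per_m,
        )

    back = ElectrodeSpec(
        name="back_cathode", kind="surface", shape="cuboid",
        center_mm=tuple(np.asarray(back_center_mm, float)), current_mA=-0.2,
        width_mm=back_size_mm[0], length_mm=back_size_mm[1], thickness_mm=thickness_mm,
        conductivity_S_per_m=gel_conductivity_S_per_m,
    )
    ring = [target + ring_radius_mm * d for d in (t1, -t1, t2, -t2)]
    cran = CraniotomySpec(
        shape="circular", center_mm=tuple(target), radius_mm=craniotomy_radius_mm,
        axis=tuple(ax), fill_conductivity_S_per_m=fill_conductivity_S_per_m,
    )

    if name == "1xBack":
        return MontageSpec(name, [disc("anode", target, +0.2), back])
    if name == "1x4":
        cathodes = [disc(f"cathode{i+1}", c, -0.05) for i, c in enumerate(ring)]
        return MontageSpec(name, [disc("anode", target, +0.2), *cathodes])
    if name == "4xBack_cran":
        anodes = [disc(f"anode{i+1}", c, +0.05) for i, c in enumerate(ring)]
        return MontageSpec(name, [*anodes, back], craniotomy=cran)
    if name == "1x1_cran":
        anode = disc("anode", target + pair_offset_mm * t2, +0.2)
        cathode = disc("cathode", target - pair_offset_mm * t2, -0.2)
        return MontageSpec(name, [anode, cathode], craniotomy=cran)
    raise MontageError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
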