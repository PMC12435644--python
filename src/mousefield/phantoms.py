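"""Deterministic labeled test meshes with analytic ground truth.

``make_slab`` builds a structured lattice of cuboid cells split into six
tets each (Kuhn split, conforming across cells), with layer interfaces that
coincide with element faces — which makes series-conductor and Ohm's-law
oracles exact in the P1 space. ``make_layered_sphere`` builds nested
tissue shells from a subdivided icosahedral surface with radial rings
snapped to the shell boundaries (closed boundary, no external mesher).
Both are bit-identical across runs for a given spec.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas import LabelVolume, PointLocator
from .mesh import MeshError, TetMesh, TissueTable, split_prism

logger = logging.getLogger("mousefield")

__all__ = [
    "PhantomError",
    "Layer",
    "SlabPhantom",
    "SpherePhantom",
    "make_slab",
    "make_layered_sphere",
    "make_aligned_label_volume",
]


class PhantomError(ValueError):
    """Raised for unbuildable phantom specifications."""


@dataclass
class Layer:
    """One tissue layer: name, conductivity (S/m), and thickness (slab, mm)
    or outer radius (sphere, mm)."""

    name: str
    sigma: float
    extent_mm: float


@dataclass
class SlabPhantom:
    mesh: TetMesh
    tissues: TissueTable
    label_of: dict[str, int]
    tet_counts: dict[int, int]  # generator bookkeeping, by construction
    analytic_volume_mm3: float
    size_mm: tuple[float, float, float]


@dataclass
class SpherePhantom:
    mesh: TetMesh
    tissues: TissueTable
    label_of: dict[str, int]
    shell_radii_mm: list[float]
    analytic_volume_mm3: float


# Kuhn split of the unit cube into 6 tets: corner paths 000 -> 111 along
# each axis permutation. All cubes use the same split, so shared faces
# (whose diagonals always run corner 0 -> corner 3 of the face) conform.
_CUBE_TETS = []
for perm in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
    path = [np.zeros(3, dtype=int)]
    for axisid in perm:
        nxt = path[-1].copy()
        nxt[axisid] = 1
        path.append(nxt)
    _CUBE_TETS.append([p.tolist() for p in path])
_CUBE_TETS = np.array(_CUBE_TETS)  # (6, 4, 3) corner offsets


def make_slab(
    size_mm: Sequence[float] = (10.0, 10.0, 10.0),
    h_mm: float = 1.0,
    layers: Sequence[Layer] | None = None,
    origin_mm: Sequence[float] = (0.0, 0.0, 0.0),
    tissues: TissueTable | None = None,
) -> SlabPhantom:
    """Structured slab; ``layers`` stack along z (thicknesses must sum to the
    z extent and sit on lattice planes)."""
    size = np.asarray(size_mm, dtype=float)
    origin = np.asarray(origin_mm, dtype=float)
    if h_mm <= 0 or (size <= 0).any():
        raise PhantomError("slab size and lattice step must be positive")
    if layers is None:
        layers = [Layer("soft_tissue", 0.465, size[2])]
    thick = np.array([l.extent_mm for l in layers])
    if (thick <= 0).any():
        raise PhantomError("layer thicknesses must be positive")
    if abs(thick.sum() - size[2]) > 1e-9:
        raise PhantomError(f"layer thicknesses sum to {thick.sum()}, slab depth is {size[2]}")
    if h_mm > thick.min() + 1e-12:
        raise PhantomError(
            f"lattice step {h_mm} mm exceeds thinnest layer ({thick.min()} mm)"
        )
    ncells = np.rint(size / h_mm).astype(int)
    if not np.allclose(ncells * h_mm, size, atol=1e-9):
        raise PhantomError("slab size must be an integer multiple of the lattice step")
    interfaces = np.cumsum(thick)[:-1]
    if not np.allclose(np.rint(interfaces / h_mm) * h_mm, interfaces, atol=1e-9):
        raise PhantomError("layer interfaces must lie on lattice planes")

    nx, ny, nz = ncells
    xs = origin[0] + np.arange(nx + 1) * h_mm
    ys = origin[1] + np.arange(ny + 1) * h_mm
    zs = origin[2] + np.arange(nz + 1) * h_mm
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ci, cj, ck = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    tets = np.empty((len(ci) * 6, 4), dtype=np.int64)
    for t in range(6):
        for v in range(4):
            off = _CUBE_TETS[t, v]
            tets[t::6, v] = nid(ci + off[0], cj + off[1], ck + off[2])

    # label by cell-center z
    zc = origin[2] + (ck + 0.5) * h_mm
    bounds = origin[2] + np.concatenate([[0.0], np.cumsum(thick)])
    layer_of_cell = np.searchsorted(bounds, zc, side="right") - 1
    tissues = tissues.copy() if tissues is not None else TissueTable()
    label_of: dict[str, int] = {}
    for l in layers:
        if l.name not in label_of:
            try:
                label_of[l.name] = tissues.label_of(l.name)
            except MeshError:
                label_of[l.name] = tissues.add(l.name, l.sigma)
    layer_labels = np.array([label_of[l.name] for l in layers])
    tet_label = np.repeat(layer_labels[layer_of_cell], 6)

    mesh = TetMesh(nodes, tets, tet_label)
    counts_cells = np.bincount(layer_of_cell, minlength=len(layers)) * 6
    tet_counts = {}
    for li, l in enumerate(layers):
        tet_counts[label_of[l.name]] = tet_counts.get(label_of[l.name], 0) + int(counts_cells[li])
    logger.info("slab phantom: %d nodes, %d tets, layers %s", mesh.n_nodes, mesh.n_tets, label_of)
    return SlabPhantom(
        mesh=mesh,
        tissues=tissues,
        label_of=label_of,
        tet_counts=tet_counts,
        analytic_volume_mm3=float(np.prod(size)),
        size_mm=tuple(size),
    )


# ---------------------------------------------------------------------------
# Layered sphere
# ---------------------------------------------------------------------------

_ICO_T = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _ICO_T, 0], [1, _ICO_T, 0], [-1, -_ICO_T, 0], [1, -_ICO_T, 0],
        [0, -1, _ICO_T], [0, 1, _ICO_T], [0, -1, -_ICO_T], [0, 1, -_ICO_T],
        [_ICO_T, 0, -1], [_ICO_T, 0, 1], [-_ICO_T, 0, -1], [-_ICO_T, 0, 1],
    ],
    dtype=float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ]
)


def _icosphere(subdiv: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit icosphere by repeated 4-way triangle subdivision."""
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS, axis=1, keepdims=True)
    faces = _ICO_FACES.copy()
    for _ in range(subdiv):
        edge_mid: dict[tuple[int, int], int] = {}
        vlist = list(verts)
        new_faces = []

        def midpoint(i, j):
            key = (min(i, j), max(i, j))
            if key not in edge_mid:
                m = vlist[i] + vlist[j]
                vlist.append(m / np.linalg.norm(m))
                edge_mid[key] = len(vlist) - 1
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [ab, b, bc], [ca, bc, c], [ab, bc, ca]]
        verts = np.array(vlist)
        faces = np.array(new_faces)
    return verts, faces


def make_layered_sphere(
    shells: Sequence[Layer],
    subdiv: int = 3,
    radial_h_mm: float | None = None,
    center_mm: Sequence[float] = (0.0, 0.0, 0.0),
    tissues: TissueTable | None = None,
) -> SpherePhantom:
    """Nested tissue shells (``extent_mm`` = outer radius, strictly
    increasing, e.g. brain core then CSF/bone/skin shells).

    Radial rings of a subdivided icosphere are placed so that every shell
    boundary is a ring; the core attaches to a center node, and consecutive
    rings are joined by prisms split into conforming tets. Raises when the
    angular resolution is too coarse to represent the thinnest shell.
    """
    radii = np.array([s.extent_mm for s in shells], dtype=float)
    if len(radii) == 0 or (np.diff(radii) <= 0).any() or radii[0] <= 0:
        raise PhantomError("shell radii must be positive and strictly increasing")
    if subdiv < 1:
        raise PhantomError("subdiv must be >= 1")
    verts, faces = _icosphere(subdiv)
    R = radii[-1]
    edge_mm = float(np.linalg.norm(verts[faces[0][0]] - verts[faces[0][1]]) * R)
    thickness = np.diff(np.concatenate([[0.0], radii]))
    if edge_mm > 4.0 * thickness.min():
        raise PhantomError(
            f"angular edge length {edge_mm:.2f} mm too coarse for thinnest shell "
            f"({thickness.min():.2f} mm); increase subdiv"
        )
    if radial_h_mm is None:
        radial_h_mm = edge_mm

    # radial ring radii: each shell subdivided to ~radial_h, boundaries snapped
    ring_r = [0.0]
    for r_in, r_out in zip(np.concatenate([[0.0], radii[:-1]]), radii):
        n = max(1, int(round((r_out - r_in) / radial_h_mm)))
        ring_r.extend(r_in + (np.arange(1, n + 1) * (r_out - r_in) / n).tolist())
    ring_r = np.array(ring_r)  # ring_r[0] == 0 is the center point

    center = np.asarray(center_mm, dtype=float)
    nv = len(verts)
    nodes = [center[None, :]]
    for r in ring_r[1:]:
        nodes.append(center + verts * r)
    nodes = np.vstack(nodes)

    def ring_ids(k: int) -> np.ndarray:  # k >= 1
        return 1 + (k - 1) * nv + np.arange(nv)

    all_tets, all_labels = [], []
    tissues = tissues.copy() if tissues is not None else TissueTable()
    label_of: dict[str, int] = {}
    for s in shells:
        try:
            label_of[s.name] = tissues.label_of(s.name)
        except MeshError:
            label_of[s.name] = tissues.add(s.name, s.sigma)

    def shell_label(mid_r: float) -> int:
        si = int(np.searchsorted(radii, mid_r, side="left"))
        return label_of[shells[si].name]

    # core: center -> first ring
    r1 = ring_ids(1)
    core = np.column_stack(
        [np.zeros(len(faces), dtype=np.int64), r1[faces[:, 0]], r1[faces[:, 1]], r1[faces[:, 2]]]
    )
    all_tets.append(core)
    all_labels.append(np.full(len(core), shell_label(ring_r[1] / 2.0)))

    for k in range(1, len(ring_r) - 1):
        bot, top = ring_ids(k), ring_ids(k + 1)
        tets = split_prism(bot[faces], top[faces])
        all_tets.append(tets)
        mid = (ring_r[k] + ring_r[k + 1]) / 2.0
        all_labels.append(np.full(len(tets), shell_label(mid)))

    mesh = TetMesh(nodes, np.vstack(all_tets), np.concatenate(all_labels))
    logger.info(
        "sphere phantom: %d nodes, %d tets, R=%.2f mm, %d rings",
        mesh.n_nodes, mesh.n_tets, R, len(ring_r),
    )
    return SpherePhantom(
        mesh=mesh,
        tissues=tissues,
        label_of=label_of,
        shell_radii_mm=radii.tolist(),
        analytic_volume_mm3=float(4.0 / 3.0 * np.pi * R**3),
    )


def make_aligned_label_volume(
    mesh: TetMesh,
    voxel_mm: float = 0.1,
    label_map: dict[int, int] | None = None,
    pad_voxels: int = 1,
    locator: PointLocator | None = None,
) -> LabelVolume:
    """Voxelize a mesh's tissue labels onto a grid aligned with its bounding
    box (fixture for atlas workflows; background = 0).

    ``label_map`` optionally renames tet labels to atlas region labels.
    The affine maps voxel indices to voxel-center mm coordinates, so
    ``vox_to_mesh``/``mesh_to_vox`` round-trip exactly.
    """
    if voxel_mm <= 0:
        raise PhantomError("voxel size must be positive")
    lo, hi = mesh.bounding_box()
    lo = lo - pad_voxels * voxel_mm
    shape = np.ceil((hi - lo) / voxel_mm).astype(int) + 1 + pad_voxels
    affine = np.eye(4)
    affine[:3, :3] *= voxel_mm
    affine[:3, 3] = lo + voxel_mm / 2.0

    idx = np.indices(tuple(shape)).reshape(3, -1).T
    pts = idx * voxel_mm + (lo + voxel_mm / 2.0)
    locator = locator or PointLocator(mesh)
    tet_of = locator.locate(pts)
    labels = np.zeros(len(pts), dtype=np.int64)
    inside = tet_of >= 0
    labels[inside] = mesh.tet_label[tet_of[inside]]
    if label_map:
        mapped = labels.copy()
        for src, dst in label_map.items():
            mapped[labels == src] = dst
        labels = mapped
    return LabelVolume(labels.reshape(tuple(shape)), affine)
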