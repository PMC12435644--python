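"""Labeled tetrahedral meshes and their geometry.

A :class:`TetMesh` is the geometric substrate of every simulation: node
coordinates in millimetres (stereotaxic convention, x left->right,
y posterior->anterior, z inferior->superior), tetrahedra as 4-tuples of
0-based node indices, and one integer tissue label per tetrahedron.
A :class:`TissueTable` maps labels to tissue names and isotropic
conductivities in S/m.

Coordinates stay in mm throughout; conversion to SI metres happens only
inside the FEM assembly, so fields come out in V/m without rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

logger = logging.getLogger("mousefield")

__all__ = [
    "MeshError",
    "TetMesh",
    "TissueTable",
    "TetGeometry",
    "BoundarySurface",
    "tet_geometry",
    "extract_boundary",
    "split_prism",
]


class MeshError(ValueError):
    """Raised for invalid meshes or mesh files."""


# ---------------------------------------------------------------------------
# Tissue table
# ---------------------------------------------------------------------------


@dataclass
class TissueEntry:
    name: str
    conductivity: float  # S/m


class TissueTable:
    """Mapping from integer tissue label to (name, conductivity in S/m).

    Montage operations (electrodes, craniotomies) allocate fresh labels with
    :meth:`add`; conductivities must be strictly positive.
    """

    def __init__(self, entries: Mapping[int, tuple[str, float]] | None = None):
        self._entries: dict[int, TissueEntry] = {}
        if entries:
            for label, (name, sigma) in entries.items():
                self._set(int(label), name, float(sigma))

    def _set(self, label: int, name: str, sigma: float) -> None:
        if not np.isfinite(sigma) or sigma <= 0.0:
            raise MeshError(
                f"conductivity for label {label} ({name!r}) must be > 0 S/m, got {sigma}"
            )
        self._entries[label] = TissueEntry(name, sigma)

    # -- mapping-ish surface -------------------------------------------------
    def __contains__(self, label: int) -> bool:
        return int(label) in self._entries

    def __getitem__(self, label: int) -> TissueEntry:
        try:
            return self._entries[int(label)]
        except KeyError:
            raise MeshError(f"tissue label {label} not in table") from None

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries))

    def items(self):
        return ((k, self._entries[k]) for k in sorted(self._entries))

    @property
    def labels(self) -> list[int]:
        return sorted(self._entries)

    def label_of(self, name: str) -> int:
        for label, entry in self._entries.items():
            if entry.name == name:
                return label
        raise MeshError(f"no tissue named {name!r} in table")

    def conductivity_of(self, name: str) -> float:
        return self._entries[self.label_of(name)].conductivity

    def add(self, name: str, sigma: float, label: int | None = None) -> int:
        """Register a new tissue (e.g. an electrode or craniotomy fill).

        Returns the label used; defaults to ``max(labels) + 1``.
        """
        if label is None:
            label = max(self._entries, default=0) + 1
        label = int(label)
        if label in self._entries:
            raise MeshError(f"label {label} already present ({self._entries[label].name!r})")
        self._set(label, name, float(sigma))
        return label

    def sigma_array(self, labels: np.ndarray) -> np.ndarray:
        """Per-element conductivities for an array of labels."""
        labels = np.asarray(labels)
        unknown = set(np.unique(labels).tolist()) - set(self._entries)
        if unknown:
            raise MeshError(f"labels {sorted(unknown)} missing from tissue table")
        lut_labels = np.array(sorted(self._entries))
        lut_sigma = np.array([self._entries[l].conductivity for l in lut_labels])
        idx = np.searchsorted(lut_labels, labels)
        return lut_sigma[idx]

    def copy(self) -> "TissueTable":
        return TissueTable({l: (e.name, e.conductivity) for l, e in self._entries.items()})

    def __repr__(self) -> str:
        body = ", ".join(f"{l}:{e.name}({e.conductivity:g} S/m)" for l, e in self.items())
        return f"TissueTable({body})"


# ---------------------------------------------------------------------------
# TetMesh
# ---------------------------------------------------------------------------


@dataclass
class TetGeometry:
    """Per-tet geometry: volumes (mm^3), centroids (mm), and the gradients of
    the four linear barycentric shape functions (mm^-1, shape M x 4 x 3)."""

    volumes: np.ndarray
    centroids: np.ndarray
    grads: np.ndarray


@dataclass
class BoundarySurface:
    """Outer surface triangles of a tet mesh.

    ``tris`` are node triples oriented so the normal points away from the
    owning tet's centroid; ``owner`` is the owning tet index.
    """

    tris: np.ndarray  # (B, 3) node ids, outward oriented
    owner: np.ndarray  # (B,)
    normals: np.ndarray  # (B, 3) unit outward normals
    areas: np.ndarray  # (B,) mm^2
    centroids: np.ndarray  # (B, 3) mm

    def face_index(self) -> dict[tuple[int, int, int], int]:
        """Sorted-node-tuple -> row lookup for the boundary triangles."""
        keys = np.sort(self.tris, axis=1)
        return {tuple(k): i for i, k in enumerate(keys.tolist())}


class TetMesh:
    """Validated labeled tetrahedral mesh (coordinates in mm).

    Construction enforces the canonical tet orientation (signed volume > 0,
    achieved by swapping the first two vertices where needed) and rejects
    out-of-range indices, non-finite coordinates and degenerate elements.
    """

    def __init__(self, nodes: np.ndarray, tets: np.ndarray, tet_label: np.ndarray):
        nodes = np.ascontiguousarray(np.asarray(nodes, dtype=float))
        tets = np.ascontiguousarray(np.asarray(tets, dtype=np.int64))
        tet_label = np.ascontiguousarray(np.asarray(tet_label, dtype=np.int64))
        if nodes.ndim != 2 or nodes.shape[1] != 3:
            raise MeshError(f"nodes must be (N, 3), got {nodes.shape}")
        if tets.ndim != 2 or tets.shape[1] != 4:
            raise MeshError(f"tets must be (M, 4), got {tets.shape}")
        if tet_label.shape != (tets.shape[0],):
            raise MeshError("tet_label must have one entry per tet")
        if not np.isfinite(nodes).all():
            raise MeshError("non-finite node coordinates")
        if tets.size and (tets.min() < 0 or tets.max() >= len(nodes)):
            raise MeshError("tet node indices out of range")

        # canonical orientation: positive signed volume
        vol6 = _signed_volume6(nodes, tets)
        flip = vol6 < 0
        if flip.any():
            tets = tets.copy()
            tets[flip, 0], tets[flip, 1] = tets[flip, 1].copy(), tets[flip, 0].copy()
            vol6 = np.abs(vol6)
        scale = np.abs(vol6).max() if len(vol6) else 1.0
        degenerate = np.nonzero(np.abs(vol6) <= 1e-14 * max(scale, 1.0))[0]
        if degenerate.size:
            raise MeshError(
                f"degenerate tetrahedra (zero volume) at element indices {degenerate[:20].tolist()}"
            )

        self.nodes = nodes
        self.tets = tets
        self.tet_label = tet_label
        self._geometry: TetGeometry | None = None
        self._boundary: BoundarySurface | None = None

    # -- basic queries -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_tets(self) -> int:
        return len(self.tets)

    def label_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.tet_label, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def node_labels(self) -> dict[int, np.ndarray]:
        """Node index sets per tissue label (a node may carry several labels)."""
        out: dict[int, np.ndarray] = {}
        for label in np.unique(self.tet_label):
            out[int(label)] = np.unique(self.tets[self.tet_label == label])
        return out

    def nodes_with_label(self, labels: Iterable[int]) -> np.ndarray:
        labels = np.atleast_1d(np.asarray(list(labels), dtype=np.int64))
        mask = np.isin(self.tet_label, labels)
        return np.unique(self.tets[mask])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        return self.nodes.min(axis=0), self.nodes.max(axis=0)

    def total_volume(self) -> float:
        return float(tet_geometry(self).volumes.sum())

    def __repr__(self) -> str:
        return f"TetMesh(n_nodes={self.n_nodes}, n_tets={self.n_tets}, labels={sorted(self.label_counts())})"


def _signed_volume6(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    a, b, c, d = (nodes[tets[:, i]] for i in range(4))
    return np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)


def tet_geometry(mesh: TetMesh) -> TetGeometry:
    """Volumes, centroids and P1 shape-function gradients, cached on the mesh.

    Gradients satisfy the partition of unity (rows sum to the zero vector) and
    ``grad[e, i]`` is constant over tet *e* for the barycentric function that
    is 1 at local vertex *i*.
    """
    if mesh._geometry is not None:
        return mesh._geometry
    nodes, tets = mesh.nodes, mesh.tets
    a = nodes[tets[:, 0]]
    D = np.stack(
        [nodes[tets[:, 1]] - a, nodes[tets[:, 2]] - a, nodes[tets[:, 3]] - a], axis=1
    )  # (M, 3, 3), rows are edge vectors
    vol6 = np.linalg.det(D)
    if (vol6 <= 0).any():
        raise MeshError("negative/zero element volume (mesh not canonically oriented?)")
    Dinv = np.linalg.inv(D)  # columns of Dinv are gradients of barycentric coords 1..3
    g123 = np.transpose(Dinv, (0, 2, 1))  # (M, 3(vertex), 3(xyz))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (M, 4, 3)
    centroids = nodes[tets].mean(axis=1)
    geom = TetGeometry(volumes=vol6 / 6.0, centroids=centroids, grads=grads)
    mesh._geometry = geom
    return geom


_FACE_LOCAL = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])
# local vertex triples of the 4 faces, ordered so normals point outward for a
# positively oriented tet; face k is opposite local vertex k.


def extract_boundary(mesh: TetMesh) -> BoundarySurface:
    """Faces that belong to exactly one tet, outward-oriented; cached."""
    if mesh._boundary is not None:
        return mesh._boundary
    tets = mesh.tets
    faces = tets[:, _FACE_LOCAL]  # (M, 4, 3)
    faces = faces.reshape(-1, 3)
    owner = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    order = np.lexsort((key[:, 2], key[:, 1], key[:, 0]))
    key_sorted = key[order]
    new_group = np.ones(len(key_sorted), dtype=bool)
    new_group[1:] = (key_sorted[1:] != key_sorted[:-1]).any(axis=1)
    group_id = np.cumsum(new_group) - 1
    counts = np.bincount(group_id)
    boundary_rows = order[new_group.nonzero()[0][counts == 1]]

    btris = faces[boundary_rows]
    bowner = owner[boundary_rows]
    p0, p1, p2 = (mesh.nodes[btris[:, i]] for i in range(3))
    nvec = np.cross(p1 - p0, p2 - p0)
    areas = 0.5 * np.linalg.norm(nvec, axis=1)
    if (areas <= 0).any():
        raise MeshError("degenerate boundary triangle")
    normals = nvec / (2.0 * areas[:, None])
    centroids = (p0 + p1 + p2) / 3.0
    surf = BoundarySurface(
        tris=btris, owner=bowner, normals=normals, areas=areas, centroids=centroids
    )
    mesh._boundary = surf
    return surf


def split_prism(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each with a conforming diagonal rule.

    ``bottom``/``top`` are (P, 3) arrays of global node ids for the prism's
    two triangular caps (matched column-wise). On every quadrilateral side
    face the diagonal runs from the lower-global-id bottom node to the other
    column's top node; because the rule depends only on global ids, adjacent
    prisms sharing a side face always pick the same diagonal, so the
    resulting tets are face-conforming. Requires the relative order of top
    ids to mirror the bottom ids (true when top nodes are allocated in
    bottom-id order).

    Returns an (P*3, 4) array of tets.
    """
    bottom = np.asarray(bottom, dtype=np.int64)
    top = np.asarray(top, dtype=np.int64)
    order = np.argsort(bottom, axis=1)
    b = np.take_along_axis(bottom, order, axis=1)
    t = np.take_along_axis(top, order, axis=1)
    p, q, r = b[:, 0], b[:, 1], b[:, 2]
    P_, Q_, R_ = t[:, 0], t[:, 1], t[:, 2]
    tets = np.stack(
        [
            np.stack([p, q, r, R_], axis=1),
            np.stack([p, q, R_, Q_], axis=1),
            np.stack([p, Q_, R_, P_], axis=1),
        ],
        axis=1,
    )
    return tets.reshape(-1, 4)
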