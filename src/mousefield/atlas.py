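"""Bridge between volumetric label images and the mesh.

A :class:`LabelVolume` wraps a 3D integer label array (e.g. a brain atlas
already coregistered to mesh space) with its voxel->mm affine; fields are
resampled onto voxel centers by locating the containing tet and
barycentrically interpolating the node fields, after which the metrics
module's statistics apply voxel-weighted (each voxel counts once).

Point-in-tet lookup uses a uniform grid over tet bounding boxes with a
deterministic lowest-tet-index tie-break for points on shared faces.
Orientation is taken from the affine alone — no axis-flip heuristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .mesh import MeshError, TetMesh, tet_geometry
from .metrics import (
    FieldSummary,
    FocalityParams,
    MetricsError,
    RegionSelection,
    relative_focality_values,
    summarize,
)

logger = logging.getLogger("mousefield")

__all__ = [
    "AtlasError",
    "LabelVolume",
    "VoxelFieldSample",
    "PointLocator",
    "vox_to_mesh",
    "mesh_to_vox",
    "sample_field_to_volume",
    "region_summary",
    "region_focality",
]


class AtlasError(ValueError):
    """Raised for label-volume / mesh mismatches."""


@dataclass
class LabelVolume:
    """Integer label array + voxel-index -> mm affine + label names."""

    data: np.ndarray
    affine: np.ndarray
    regions: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or not np.issubdtype(self.data.dtype, np.integer):
            raise AtlasError("label volume must be a 3D integer array")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-300:
            raise AtlasError("affine must be an invertible 4x4 matrix")
        if self.data.min() < 0:
            raise AtlasError("labels must be >= 0 (0 = background)")

    @classmethod
    def from_nifti(
        cls, path: str | Path, regions: Mapping[int, str] | str | Path | None = None
    ) -> "LabelVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj).astype(np.int64)
        if isinstance(regions, (str, Path)):
            df = pd.read_csv(regions)
            regions = dict(zip(df["label"].astype(int), df["name"].astype(str)))
        return cls(data, img.affine, dict(regions or {}))

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int32), self.affine), str(path))

    def voxel_centers(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of every voxel center (C order)."""
        idx = np.indices(self.data.shape).reshape(3, -1).T
        return vox_to_mesh(self, idx)


def vox_to_mesh(volume: LabelVolume, ijk: np.ndarray) -> np.ndarray:
    """Voxel indices -> mm points via the affine."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    out = ijk @ volume.affine[:3, :3].T + volume.affine[:3, 3]
    return out if out.shape[0] > 1 else out[0]


def mesh_to_vox(volume: LabelVolume, xyz: np.ndarray, round_to_int: bool = True) -> np.ndarray:
    """mm points -> voxel indices (rounded by default); inverse of
    :func:`vox_to_mesh` on exact voxel centers."""
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    inv = np.linalg.inv(volume.affine)
    ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
    if round_to_int:
        ijk = np.rint(ijk).astype(np.int64)
    return ijk if ijk.shape[0] > 1 else ijk[0]


@dataclass
class VoxelFieldSample:
    """Per-voxel field sample; voxels outside every tet are masked out and
    carry NaN."""

    ex: np.ndarray
    ey: np.ndarray
    ez: np.ndarray
    emag: np.ndarray
    mask: np.ndarray  # True where the voxel center lies inside the mesh

    def vectors(self, where: np.ndarray) -> np.ndarray:
        return np.stack([self.ex[where], self.ey[where], self.ez[where]], axis=1)


class PointLocator:
    """Uniform-grid spatial index over tet bounding boxes.

    ``locate`` maps points to containing-tet indices (-1 outside), with a
    small barycentric tolerance and the lowest tet index winning ties on
    shared faces.
    """

    def __init__(self, mesh: TetMesh, tol: float = 1e-9):
        self.mesh = mesh
        self.tol = tol
        geom = tet_geometry(mesh)
        corners = mesh.nodes[mesh.tets]  # (M, 4, 3)
        self._lo = corners.min(axis=1)
        self._hi = corners.max(axis=1)
        self._origin = self._lo.min(axis=0)
        extent = self._hi.max(axis=0) - self._origin
        # cell size ~ mean tet bbox so few candidates per cell
        mean_size = (self._hi - self._lo).mean(axis=0)
        self._cell = np.maximum(mean_size, extent / 128.0)
        self._cell[self._cell <= 0] = 1.0
        self._ncell = np.maximum(np.ceil(extent / self._cell).astype(int) + 1, 1)

        lo_c = np.floor((self._lo - self._origin) / self._cell).astype(int)
        hi_c = np.floor((self._hi - self._origin) / self._cell).astype(int)
        cells: dict[tuple[int, int, int], list[int]] = {}
        for t in range(mesh.n_tets):
            for i in range(lo_c[t, 0], hi_c[t, 0] + 1):
                for j in range(lo_c[t, 1], hi_c[t, 1] + 1):
                    for k in range(lo_c[t, 2], hi_c[t, 2] + 1):
                        cells.setdefault((i, j, k), []).append(t)
        self._cells = {key: np.array(v, dtype=np.int64) for key, v in cells.items()}
        self._grads = geom.grads
        self._a = mesh.nodes[mesh.tets[:, 0]]

    def _bary(self, tets: np.ndarray, pts: np.ndarray) -> np.ndarray:
        """Barycentric coords of pts (P,3) w.r.t. tets (T,) -> (P, T, 4)."""
        d = pts[:, None, :] - self._a[tets][None, :, :]
        lam123 = np.einsum("ptd,tid->pti", d, self._grads[tets][:, 1:, :])
        lam0 = 1.0 - lam123.sum(axis=2, keepdims=True)
        return np.concatenate([lam0, lam123], axis=2)

    def locate(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        out = np.full(len(points), -1, dtype=np.int64)
        cell_idx = np.floor((points - self._origin) / self._cell).astype(int)
        keys, inverse = np.unique(cell_idx, axis=0, return_inverse=True)
        for g, key in enumerate(map(tuple, keys.tolist())):
            cand = self._cells.get(key)
            if cand is None:
                continue
            rows = np.nonzero(inverse == g)[0]
            lam = self._bary(cand, points[rows])  # (P, T, 4)
            inside = (lam >= -self.tol).all(axis=2)
            has = inside.any(axis=1)
            first = np.argmax(inside, axis=1)  # candidates ascend -> lowest tet wins
            out[rows[has]] = cand[first[has]]
        return out

    def interpolate(
        self, points: np.ndarray, node_values: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Barycentric interpolation of per-node values at points.

        Returns (values, inside_mask); values are NaN outside the mesh.
        Exact for fields linear over each tet (hence for constants).
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tet_of = self.locate(points)
        inside = tet_of >= 0
        shape = (len(points),) + np.asarray(node_values).shape[1:]
        values = np.full(shape, np.nan)
        if inside.any():
            t = tet_of[inside]
            lam123 = np.einsum(
                "pd,pid->pi", points[inside] - self._a[t], self._grads[t][:, 1:, :]
            )
            lam = np.concatenate([1.0 - lam123.sum(axis=1, keepdims=True), lam123], axis=1)
            vals = np.asarray(node_values)[self.mesh.tets[t]]  # (P, 4, ...)
            values[inside] = np.einsum("pi,pi...->p...", lam, vals)
        return values, inside


def sample_field_to_volume(
    solution, mesh: TetMesh, volume: LabelVolume, locator: PointLocator | None = None
) -> VoxelFieldSample:
    """Sample node fields at every voxel center of the volume.

    Components are interpolated barycentrically; the magnitude is the norm
    of the interpolated vector, so constant fields are reproduced exactly.
    Raises if no voxel center falls inside any tet.
    """
    locator = locator or PointLocator(mesh)
    pts = volume.voxel_centers()
    E, inside = locator.interpolate(pts, solution.E_node)
    if not inside.any():
        raise AtlasError("volume/mesh misalignment: no voxel center inside the mesh")
    shape = volume.data.shape
    ex = E[:, 0].reshape(shape)
    ey = E[:, 1].reshape(shape)
    ez = E[:, 2].reshape(shape)
    emag = np.linalg.norm(E, axis=1).reshape(shape)
    mask = inside.reshape(shape)
    logger.info("sampled field at %d/%d voxels inside mesh", int(mask.sum()), mask.size)
    return VoxelFieldSample(ex=ex, ey=ey, ez=ez, emag=emag, mask=mask)


class _VoxelSolutionView:
    """Adapts a VoxelFieldSample to the metrics module's solution interface
    (flat per-sample fields indexed like nodes)."""

    def __init__(self, sample: VoxelFieldSample):
        flat = sample.vectors(np.ones(sample.emag.shape, dtype=bool))
        self.E_node = np.where(np.isfinite(flat), flat, 0.0)
        emag = sample.emag.reshape(-1)
        self.emag_node = np.where(np.isfinite(emag), emag, 0.0)


def _region_voxels(
    sample: VoxelFieldSample, volume: LabelVolume, labels: Sequence[int]
) -> np.ndarray:
    member = np.isin(volume.data, np.asarray(list(labels), dtype=volume.data.dtype))
    rows = np.nonzero((member & sample.mask).reshape(-1))[0]
    if rows.size == 0:
        raise MetricsError(f"no unmasked voxels with labels {list(labels)}")
    return rows


def region_summary(
    sample: VoxelFieldSample, volume: LabelVolume, labels: Sequence[int], name: str = ""
) -> FieldSummary:
    """Voxel-weighted field summary over the atlas region(s) ``labels``."""
    rows = _region_voxels(sample, volume, labels)
    name = name or ",".join(
        volume.regions.get(int(l), str(l)) for l in labels
    )
    view = _VoxelSolutionView(sample)
    summary = summarize(view, RegionSelection(rows, name))
    return summary


def region_focality(
    sample: VoxelFieldSample,
    volume: LabelVolume,
    target_labels: Sequence[int],
    reference_labels: Sequence[int],
    params: FocalityParams | None = None,
) -> float:
    """Relative focality with atlas regions as target and reference; voxels
    in both sets count as target (reference excludes them)."""
    t_rows = _region_voxels(sample, volume, target_labels)
    r_rows = np.setdiff1d(_region_voxels(sample, volume, reference_labels), t_rows)
    if r_rows.size == 0:
        raise MetricsError("reference region empty after excluding target voxels")
    emag = sample.emag.reshape(-1)
    return relative_focality_values(emag[t_rows], emag[r_rows], params)
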