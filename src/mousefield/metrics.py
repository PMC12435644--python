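"""Field summary statistics: component stats, normalized components,
direction homogeneity, relative focality, and box ROIs.

Direction homogeneity is the length of the mean of per-node normalized
field vectors, ``sqrt(mean(eX_n)^2 + mean(eY_n)^2 + mean(eZ_n)^2)`` with
``eX_n = eX / eMag``: 1 for a perfectly aligned field, 0 when directions
cancel (e.g. half the nodes +x, half -x).

Relative focality compares a target region against a reference region:
``1 - |{reference nodes with eMag > T}| / |reference|`` where
``T = P * percentile(eMag_target, 99.9)``. P defaults to 0.40, which is
sensitive to diffuse off-target fields; 1 means the field is confined to
the target, 0 that the whole reference is stimulated as strongly.

Statistics are node-weighted by default (each node counts once, matching
node-count-based summary tables); pass per-node weights for a
volume-weighted variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .mesh import TetMesh

__all__ = [
    "MetricsError",
    "ZERO_FIELD_EPS",
    "RegionSelection",
    "BoxRoiSpec",
    "FocalityParams",
    "FieldSummary",
    "summarize",
    "direction_homogeneity",
    "relative_focality",
    "select_box_roi",
    "select_tissue_region",
    "cap_percentile",
]

ZERO_FIELD_EPS = 1e-15  # V/m; nodes below this are excluded from direction stats


class MetricsError(ValueError):
    """Raised for invalid regions or metric parameters."""


@dataclass
class RegionSelection:
    """A set of node (or voxel) indices with a provenance note."""

    indices: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.indices = np.unique(np.asarray(self.indices, dtype=np.int64))
        if len(self.indices) == 0:
            raise MetricsError(f"empty region ({self.provenance or 'unnamed'})")

    @property
    def n(self) -> int:
        return len(self.indices)

    def minus(self, other: "RegionSelection") -> "RegionSelection":
        keep = np.setdiff1d(self.indices, other.indices)
        return RegionSelection(keep, f"{self.provenance} minus {other.provenance}")


@dataclass
class BoxRoiSpec:
    """Axis-aligned box ROI: closed intervals center +- size/2 per axis,
    optionally restricted to nodes of given tissue labels."""

    center_mm: tuple[float, float, float]
    width_mm: float  # x extent
    length_mm: float  # y extent
    depth_mm: float  # z extent
    tissue_labels: Sequence[int] | None = None

    def __post_init__(self):
        if min(self.width_mm, self.length_mm, self.depth_mm) <= 0:
            raise MetricsError("box ROI dimensions must be positive")


@dataclass
class FocalityParams:
    P: float = 0.40
    target_percentile: float = 99.9

    def __post_init__(self):
        if not (0.0 < self.P <= 1.0):
            raise MetricsError("focality P must be in (0, 1]")
        if not (0.0 < self.target_percentile <= 100.0):
            raise MetricsError("target percentile must be in (0, 100]")


_QUANTITIES = ("eX", "eY", "eZ", "eMag")
_STATS = ("mean", "median", "std", "min", "max")


@dataclass
class FieldSummary:
    """One summary-table row set: per-quantity stats, mean normalized
    components, direction homogeneity, optional relative focality."""

    stats: pd.DataFrame  # index eX,eY,eZ,eMag; columns mean..max
    norm_means: np.ndarray  # (3,) mean normalized components
    homogeneity: float
    n: int
    zero_field: bool = False
    focality: float | None = None
    focality_params: FocalityParams | None = None
    reference: str | None = None
    region: str = ""

    def to_frame(self) -> pd.DataFrame:
        df = self.stats.copy()
        df["norm"] = [*self.norm_means, np.nan]
        return df

    def to_text(self) -> str:
        lines = [f"region: {self.region} ({self.n} samples)"]
        lines.append(self.to_frame().to_string(float_format=lambda x: f"{x:8.3f}"))
        lines.append(f"direction homogeneity = {self.homogeneity:.2f}")
        if self.focality is not None:
            p = self.focality_params
            lines.append(
                f"relative focality = {self.focality:.2f}"
                f" (P={p.P:g}, {p.target_percentile:g}th pct, reference: {self.reference})"
            )
        return "\n".join(lines)


def _field_vectors(solution, indices: np.ndarray) -> np.ndarray:
    return solution.E_node[indices]


def summarize(solution, region: RegionSelection) -> FieldSummary:
    """Component/magnitude statistics plus direction metrics over a region.

    Normalized components exclude nodes with ``eMag < ZERO_FIELD_EPS``; if
    every node is below threshold the norm row is zero and ``zero_field``
    is flagged.
    """
    E = _field_vectors(solution, region.indices)
    emag = solution.emag_node[region.indices]
    data = {
        "eX": E[:, 0],
        "eY": E[:, 1],
        "eZ": E[:, 2],
        "eMag": emag,
    }
    stats = pd.DataFrame(
        {
            "mean": [np.mean(v) for v in data.values()],
            "median": [np.median(v) for v in data.values()],
            "std": [np.std(v) for v in data.values()],
            "min": [np.min(v) for v in data.values()],
            "max": [np.max(v) for v in data.values()],
        },
        index=list(_QUANTITIES),
    )
    live = emag >= ZERO_FIELD_EPS
    if live.any():
        norm_means = (E[live] / emag[live, None]).mean(axis=0)
        zero_field = False
    else:
        norm_means = np.zeros(3)
        zero_field = True
    homogeneity = float(np.linalg.norm(norm_means)) if not zero_field else 0.0
    return FieldSummary(
        stats=stats,
        norm_means=norm_means,
        homogeneity=homogeneity,
        n=region.n,
        zero_field=zero_field,
        region=region.provenance,
    )


def direction_homogeneity(solution, region: RegionSelection) -> float:
    """Length of the mean normalized field vector over the region, in [0, 1].

    1 iff all included node directions coincide; antipodal halves give 0.
    Raises if no node carries a field above the zero-field threshold.
    """
    E = _field_vectors(solution, region.indices)
    emag = solution.emag_node[region.indices]
    live = emag >= ZERO_FIELD_EPS
    if not live.any():
        raise MetricsError("no field to orient (all nodes below zero-field threshold)")
    mean_dir = (E[live] / emag[live, None]).mean(axis=0)
    return float(np.linalg.norm(mean_dir))


def relative_focality(
    solution,
    target: RegionSelection,
    reference: RegionSelection,
    params: FocalityParams | None = None,
) -> float:
    """1 minus the fraction of reference nodes with eMag strictly greater
    than ``P x percentile(target eMag, 99.9)``. Target and reference must be
    disjoint. Percentiles use linear interpolation between order statistics.
    """
    params = params or FocalityParams()
    if np.intersect1d(target.indices, reference.indices).size:
        raise MetricsError("target and reference regions overlap")
    emag_t = solution.emag_node[target.indices]
    emag_r = solution.emag_node[reference.indices]
    return relative_focality_values(emag_t, emag_r, params)


def relative_focality_values(
    emag_target: np.ndarray, emag_reference: np.ndarray, params: FocalityParams | None = None
) -> float:
    """Focality from raw eMag samples (used for voxel-based regions too)."""
    params = params or FocalityParams()
    emag_target = np.asarray(emag_target, dtype=float)
    emag_reference = np.asarray(emag_reference, dtype=float)
    if emag_target.size == 0 or emag_reference.size == 0:
        raise MetricsError("focality needs non-empty target and reference")
    T = params.P * np.percentile(emag_target, params.target_percentile)
    exceed = np.count_nonzero(emag_reference > T)
    return float(1.0 - exceed / emag_reference.size)


def select_box_roi(mesh: TetMesh, spec: BoxRoiSpec) -> RegionSelection:
    """Nodes inside the closed axis-aligned box, optionally restricted to
    nodes touching tets of the given tissue labels."""
    lo = np.asarray(spec.center_mm) - 0.5 * np.array(
        [spec.width_mm, spec.length_mm, spec.depth_mm]
    )
    hi = np.asarray(spec.center_mm) + 0.5 * np.array(
        [spec.width_mm, spec.length_mm, spec.depth_mm]
    )
    inside = ((mesh.nodes >= lo) & (mesh.nodes <= hi)).all(axis=1)
    idx = np.nonzero(inside)[0]
    if spec.tissue_labels is not None:
        idx = np.intersect1d(idx, mesh.nodes_with_label(spec.tissue_labels))
    if idx.size == 0:
        raise MetricsError(
            f"box ROI at {tuple(spec.center_mm)} "
            f"({spec.width_mm}x{spec.length_mm}x{spec.depth_mm} mm) selects no nodes"
        )
    return RegionSelection(idx, f"box@{tuple(np.round(spec.center_mm, 3))}")


def select_tissue_region(mesh: TetMesh, labels: Sequence[int], name: str = "") -> RegionSelection:
    idx = mesh.nodes_with_label(labels)
    if idx.size == 0:
        raise MetricsError(f"no nodes with labels {list(labels)}")
    return RegionSelection(idx, name or f"tissue{list(labels)}")


def cap_percentile(values: np.ndarray, q: float = 98.0) -> np.ndarray:
    """Copy of ``values`` with everything above the q-th percentile clipped
    to it. Display helper only — never feeds statistics."""
    if not (0.0 < q <= 100.0):
        raise MetricsError("cap percentile must be in (0, 100]")
    values = np.asarray(values, dtype=float)
    cap = np.percentile(values, q)
    return np.minimum(values, cap)
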