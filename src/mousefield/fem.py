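"""Electrostatic finite-element solver on labeled tet meshes.

The induced potential obeys the current-conservation (Laplace) equation
``div(sigma grad V) = 0`` with Neumann boundary conditions on the electrode
contact surfaces: a uniform normal current density J = I / A over each
contact. P1 (linear tetrahedral) elements; element stiffness
``K_e = sigma_e * Vol_e * (grad phi_i . grad phi_j)`` with geometry converted
to SI metres inside the assembly, so potentials are volts and fields V/m.

The pure-Neumann operator has the constants as null space; the system is
made definite by pinning one node (the lowest-index node on the most
negative electrode's contact) to 0 V, and the reported potential is
mean-subtracted afterwards. Per-tet fields ``E = -sum_i V_i grad phi_i`` are
averaged to nodes with volume weights; node magnitudes are computed after
averaging, so node statistics match node-count-based summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import MeshError, TetMesh, TissueTable, extract_boundary, tet_geometry
from .montage import CURRENT_BALANCE_TOL_MA, ElectrodePlacement, MontageResult

logger = logging.getLogger("mousefield")

__all__ = [
    "SolverError",
    "ContactLoad",
    "VolumeSource",
    "FemProblem",
    "FieldSolution",
    "build_problem",
    "patch_contact",
    "assemble",
    "solve",
    "check_flux",
    "electrode_potentials",
]

MM_TO_M = 1e-3
MA_TO_A = 1e-3
DIRECT_SOLVE_MAX_NODES = 50_000


class SolverError(RuntimeError):
    """Raised when the linear solve fails to converge."""

    def __init__(self, message: str, residuals: list[float] | None = None):
        super().__init__(message)
        self.residuals = residuals or []


@dataclass
class ContactLoad:
    """Current injected through a set of boundary triangles with uniform
    normal current density (no contact-impedance model)."""

    name: str
    tris: np.ndarray  # (K, 3) node ids
    current_mA: float


@dataclass
class VolumeSource:
    """Current injected as a uniform volumetric density over a tet region
    (insert electrodes)."""

    name: str
    tets: np.ndarray  # (K,) tet ids
    current_mA: float


@dataclass
class FemProblem:
    mesh: TetMesh
    sigma: np.ndarray  # per-tet conductivity, S/m
    contacts: list[ContactLoad] = field(default_factory=list)
    sources: list[VolumeSource] = field(default_factory=list)
    pin_node: int | None = None  # override the default reference node

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.shape != (self.mesh.n_tets,):
            raise MeshError("sigma must have one entry per tet")
        if (self.sigma <= 0).any() or not np.isfinite(self.sigma).all():
            raise MeshError("conductivities must be finite and > 0")
        total = sum(c.current_mA for c in self.contacts) + sum(
            s.current_mA for s in self.sources
        )
        if abs(total) > CURRENT_BALANCE_TOL_MA:
            raise MeshError(f"injected currents sum to {total:g} mA, not 0")
        for c in self.contacts:
            if len(c.tris) == 0:
                raise MeshError(f"contact surface {c.name!r} is empty")
        for s in self.sources:
            if len(s.tets) == 0:
                raise MeshError(f"source region {s.name!r} is empty")

    def reference_node(self) -> int:
        """Lowest-index node on the most-negative electrode; node 0 if none."""
        if self.pin_node is not None:
            return int(self.pin_node)
        loads = [(c.current_mA, np.unique(c.tris)) for c in self.contacts] + [
            (s.current_mA, np.unique(self.mesh.tets[s.tets])) for s in self.sources
        ]
        if not loads:
            return 0
        current, nodes = min(loads, key=lambda x: x[0])
        return int(nodes.min())


@dataclass
class FieldSolution:
    """Per-node potential (V), field components/magnitude (V/m), the per-tet
    constant field, and solver diagnostics."""

    V: np.ndarray
    E_node: np.ndarray  # (N, 3)
    emag_node: np.ndarray
    E_tet: np.ndarray  # (M, 3)
    diagnostics: dict

    @property
    def eX(self) -> np.ndarray:
        return self.E_node[:, 0]

    @property
    def eY(self) -> np.ndarray:
        return self.E_node[:, 1]

    @property
    def eZ(self) -> np.ndarray:
        return self.E_node[:, 2]


def build_problem(result: MontageResult, pin_node: int | None = None) -> FemProblem:
    """FemProblem from an applied montage (contacts from surface-electrode
    caps, volume sources from insert regions)."""
    sigma = result.tissues.sigma_array(result.mesh.tet_label)
    contacts, sources = [], []
    for p in result.placements:
        if p.contact_tris is not None:
            contacts.append(ContactLoad(p.name, p.contact_tris, p.current_mA))
        else:
            sources.append(VolumeSource(p.name, p.source_tets, p.current_mA))
    return FemProblem(result.mesh, sigma, contacts, sources, pin_node)


def patch_contact(
    mesh: TetMesh, name: str, current_mA: float, where
) -> ContactLoad:
    """Contact over the boundary triangles whose centroids satisfy ``where``
    (a boolean mask function of the (B, 3) centroid array). Convenience for
    plate electrodes on phantom faces."""
    surf = extract_boundary(mesh)
    mask = where(surf.centroids)
    if not mask.any():
        raise MeshError(f"contact {name!r}: no boundary triangles selected")
    return ContactLoad(name, surf.tris[mask], current_mA)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble(problem: FemProblem) -> tuple[sp.csr_matrix, np.ndarray]:
    """Stiffness matrix (S) and load vector (A), SI units.

    K is symmetric positive semidefinite with the constant vector as null
    space; the load distributes J*Area/3 per contact-triangle vertex and
    I*(Vol_e/RegionVol)/4 per source-tet vertex, so the entries sum to zero
    for balanced currents.
    """
    mesh = problem.mesh
    geom = tet_geometry(mesh)
    vol_m3 = geom.volumes * MM_TO_M**3
    grads_m = geom.grads / MM_TO_M  # 1/m
    ke = np.einsum("e,eid,ejd->eij", problem.sigma * vol_m3, grads_m, grads_m)
    rows = np.repeat(mesh.tets, 4, axis=1).reshape(-1)
    cols = np.tile(mesh.tets, (1, 4)).reshape(-1)
    K = sp.coo_matrix(
        (ke.reshape(-1), (rows, cols)), shape=(mesh.n_nodes, mesh.n_nodes)
    ).tocsr()

    f = np.zeros(mesh.n_nodes)
    for c in problem.contacts:
        p0, p1, p2 = (mesh.nodes[c.tris[:, i]] * MM_TO_M for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
        total_area = areas.sum()
        if total_area <= 0:
            raise MeshError(f"contact {c.name!r} has zero area")
        J = c.current_mA * MA_TO_A / total_area  # A/m^2
        contribution = J * areas / 3.0
        for i in range(3):
            np.add.at(f, c.tris[:, i], contribution)
    for s in problem.sources:
        vols = vol_m3[s.tets]
        region_vol = vols.sum()
        contribution = s.current_mA * MA_TO_A * vols / region_vol / 4.0
        for i in range(4):
            np.add.at(f, mesh.tets[s.tets, i], contribution)
    return K, f


# ---------------------------------------------------------------------------
# Solve
# ---------------------------------------------------------------------------


def _apply_reference(K: sp.csr_matrix, f: np.ndarray, ref: int):
    """Pin node ``ref`` to zero by zeroing its row/column and setting a unit
    diagonal (keeps symmetry)."""
    K = K.tolil(copy=True)
    K[ref, :] = 0.0
    K[:, ref] = 0.0
    K[ref, ref] = 1.0
    f = f.copy()
    f[ref] = 0.0
    return K.tocsr(), f


def solve(
    problem: FemProblem,
    tol: float = 1e-10,
    max_iter: int = 20_000,
    method: str = "auto",
) -> FieldSolution:
    """Solve K V = f under the reference constraint and recover fields.

    ``method`` is ``auto`` (sparse LU below 50k nodes, else preconditioned
    conjugate gradients), ``direct`` or ``cg``. Raises :class:`SolverError`
    with the residual history on non-convergence.
    """
    mesh = problem.mesh
    K, f = assemble(problem)
    ref = problem.reference_node()
    Kc, fc = _apply_reference(K, f, ref)

    if method == "auto":
        method = "direct" if mesh.n_nodes <= DIRECT_SOLVE_MAX_NODES else "cg"
    fnorm = np.linalg.norm(fc)
    if fnorm == 0.0:
        V = np.zeros(mesh.n_nodes)
        iters = 0
    elif method == "direct":
        lu = spla.splu(Kc.tocsc())
        V = lu.solve(fc)
        iters = 1
    elif method == "cg":
        M = sp.diags(1.0 / Kc.diagonal())
        residuals: list[float] = []

        def cb(xk):
            residuals.append(float(np.linalg.norm(fc - Kc @ xk) / fnorm))

        V, info = spla.cg(Kc, fc, rtol=tol, atol=0.0, maxiter=max_iter, M=M, callback=cb)
        if info != 0:
            raise SolverError(
                f"CG failed to reach rtol={tol:g} within {max_iter} iterations "
                f"(last residual {residuals[-1] if residuals else float('nan'):.3e})",
                residuals,
            )
        iters = len(residuals)
    else:
        raise ValueError(f"unknown method {method!r}")

    residual = float(np.linalg.norm(fc - Kc @ V) / fnorm) if fnorm else 0.0
    if residual > max(tol * 100.0, 1e-8):
        raise SolverError(f"solver residual {residual:.3e} exceeds tolerance", [residual])
    V = V - V.mean()  # report relative to the mesh-mean potential

    geom = tet_geometry(mesh)
    grads_m = geom.grads / MM_TO_M
    E_tet = -np.einsum("ei,eid->ed", V[mesh.tets], grads_m)  # V/m, constant per tet

    # node field: volume-weighted average of incident tet fields
    E_node = np.zeros((mesh.n_nodes, 3))
    wsum = np.zeros(mesh.n_nodes)
    w = geom.volumes
    for i in range(4):
        np.add.at(E_node, mesh.tets[:, i], E_tet * w[:, None])
        np.add.at(wsum, mesh.tets[:, i], w)
    used = wsum > 0
    E_node[used] /= wsum[used, None]
    emag = np.linalg.norm(E_node, axis=1)

    logger.info("solved %d nodes (%s), residual %.2e", mesh.n_nodes, method, residual)
    return FieldSolution(
        V=V,
        E_node=E_node,
        emag_node=emag,
        E_tet=E_tet,
        diagnostics={"method": method, "iterations": iters, "residual": residual, "pin_node": ref},
    )


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------


def check_flux(solution: FieldSolution, problem: FemProblem) -> dict[str, float]:
    """Recovered current (mA) through each contact surface.

    Integrates ``sigma * E . n`` over the contact triangles using the owning
    tet's constant field and outward normal — an independent conservation
    check of the discrete solution (positive = current flowing in through
    an anode). Includes a ``net`` entry that should be ~0.
    """
    mesh = problem.mesh
    surf = extract_boundary(mesh)
    index = surf.face_index()
    out: dict[str, float] = {}
    net = 0.0
    for c in problem.contacts:
        keys = np.sort(np.asarray(c.tris), axis=1)
        rows = np.array([index[tuple(k)] for k in keys.tolist()])
        owners = surf.owner[rows]
        flux = np.einsum(
            "kd,kd,k->",
            solution.E_tet[owners] * problem.sigma[owners, None],
            -surf.normals[rows],  # current INTO the body through the contact
            surf.areas[rows] * MM_TO_M**2,
        )
        out[c.name] = float(flux / MA_TO_A)
        net += out[c.name]
    out["net"] = net
    return out


def electrode_potentials(solution: FieldSolution, problem: FemProblem) -> dict[str, float]:
    """Electrode voltages read out with the load-conjugate weighting
    (triangle-area weights over contact nodes, volume weights over source
    regions). With this readout, reciprocity between electrode pairs on the
    same mesh holds exactly in the discrete problem."""
    mesh = problem.mesh
    out = {}
    for c in problem.contacts:
        w = np.zeros(mesh.n_nodes)
        p0, p1, p2 = (mesh.nodes[c.tris[:, i]] for i in range(3))
        areas = 0.5 * np.linalg.norm(np.cross(p1 - p0, p2 - p0), axis=1)
        for i in range(3):
            np.add.at(w, c.tris[:, i], areas / 3.0)
        out[c.name] = float(solution.V @ w / w.sum())
    for s in problem.sources:
        vols = tet_geometry(mesh).volumes[s.tets]
        w = np.zeros(mesh.n_nodes)
        for i in range(4):
            np.add.at(w, mesh.tets[s.tets, i], vols / 4.0)
        out[s.name] = float(solution.V @ w / w.sum())
    return out
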