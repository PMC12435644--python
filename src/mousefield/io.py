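"""Mesh, tissue-table and solution I/O.

Supported mesh dialects:

* Gmsh ASCII ``.msh`` version 2.2 (read + write) and 4.1 (read). Element
  tags: the physical-group tag (v2.2 first tag; v4.1 via the ``$Entities``
  section, falling back to the geometric entity tag) becomes the tissue
  label. Gmsh's 1-based node ids are converted to 0-based indices at this
  boundary.
* A plain table dialect for fixtures: a directory holding ``nodes.csv``
  (columns x_mm,y_mm,z_mm), ``tets.csv`` (n0..n3, 0-based) and ``labels.csv``
  (label).

Tissue tables load from YAML (mapping ``label: {name, conductivity_S_per_m}``)
or CSV with columns ``label,name,conductivity_S_per_m``.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .mesh import MeshError, TetMesh, TissueTable

logger = logging.getLogger("mousefield")

__all__ = [
    "load_mesh",
    "save_mesh",
    "read_gmsh",
    "write_gmsh",
    "read_mesh_tables",
    "write_mesh_tables",
    "load_tissue_table",
    "save_tissue_table",
    "default_tissue_table",
    "solution_table",
    "write_solution_csv",
    "write_vtk",
]


# ---------------------------------------------------------------------------
# Gmsh ASCII
# ---------------------------------------------------------------------------

_GMSH_TET = 4
_GMSH_TRI = 2


def _read_sections(path: Path) -> dict[str, list[str]]:
    sections: dict[str, list[str]] = {}
    current: str | None = None
    buf: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("$End"):
                if current is not None:
                    sections[current] = buf
                current, buf = None, []
            elif line.startswith("$"):
                current, buf = line[1:], []
            elif current is not None:
                buf.append(line)
    return sections


def read_gmsh(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a Gmsh ASCII .msh file -> (nodes, tets, labels); 0-based indices."""
    path = Path(path)
    sections = _read_sections(path)
    if "MeshFormat" not in sections:
        raise MeshError(f"{path}: not a Gmsh mesh (missing $MeshFormat)")
    version = float(sections["MeshFormat"][0].split()[0])
    if int(sections["MeshFormat"][0].split()[1]) != 0:
        raise MeshError(f"{path}: binary .msh not supported; export ASCII")
    if version < 3:
        return _read_gmsh2(sections, path)
    return _read_gmsh4(sections, path)


def _read_gmsh2(sections, path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    node_lines = sections.get("Nodes")
    elem_lines = sections.get("Elements")
    if not node_lines or not elem_lines:
        raise MeshError(f"{path}: missing $Nodes or $Elements")
    n = int(node_lines[0])
    ids = np.empty(n, dtype=np.int64)
    coords = np.empty((n, 3))
    for i, line in enumerate(node_lines[1 : n + 1]):
        parts = line.split()
        ids[i] = int(parts[0])
        coords[i] = [float(p) for p in parts[1:4]]
    id_to_row = {int(t): i for i, t in enumerate(ids)}

    tets, labels, saw_tri = [], [], False
    m = int(elem_lines[0])
    for line in elem_lines[1 : m + 1]:
        parts = line.split()
        etype, ntags = int(parts[1]), int(parts[2])
        tags = parts[3 : 3 + ntags]
        conn = parts[3 + ntags :]
        if etype == _GMSH_TET:
            tets.append([id_to_row[int(c)] for c in conn])
            labels.append(int(tags[0]) if tags else 0)
        elif etype == _GMSH_TRI:
            saw_tri = True
    if not tets:
        extra = " (file contains only surface triangles)" if saw_tri else ""
        raise MeshError(f"{path}: no tetrahedral elements{extra}")
    return coords, np.array(tets, dtype=np.int64), np.array(labels, dtype=np.int64)


def _read_gmsh4(sections, path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # map 3D entity tag -> physical tag (first one), if $Entities is present
    phys_of_volume: dict[int, int] = {}
    ent = sections.get("Entities")
    if ent:
        counts = [int(x) for x in ent[0].split()[:4]]
        rows = ent[1:]
        idx = counts[0] + counts[1] + counts[2]  # skip points, curves, surfaces
        for line in rows[idx : idx + counts[3]]:
            parts = line.split()
            tag = int(parts[0])
            nphys = int(parts[7])
            if nphys > 0:
                phys_of_volume[tag] = int(parts[8])

    node_lines = sections.get("Nodes")
    elem_lines = sections.get("Elements")
    if not node_lines or not elem_lines:
        raise MeshError(f"{path}: missing $Nodes or $Elements")

    nblocks, ntotal = (int(x) for x in node_lines[0].split()[:2])
    ids = np.empty(ntotal, dtype=np.int64)
    coords = np.empty((ntotal, 3))
    row, pos = 0, 1
    for _ in range(nblocks):
        _, _, parametric, nb = (int(x) for x in node_lines[pos].split())
        pos += 1
        block_ids = [int(node_lines[pos + i]) for i in range(nb)]
        pos += nb
        for i in range(nb):
            coords[row + i] = [float(x) for x in node_lines[pos + i].split()[:3]]
            ids[row + i] = block_ids[i]
        pos += nb
        row += nb
    id_to_row = {int(t): i for i, t in enumerate(ids)}

    nblocks = int(elem_lines[0].split()[0])
    tets, labels, saw_tri = [], [], False
    pos = 1
    for _ in range(nblocks):
        dim, etag, etype, nb = (int(x) for x in elem_lines[pos].split())
        pos += 1
        for i in range(nb):
            parts = elem_lines[pos + i].split()
            if etype == _GMSH_TET:
                tets.append([id_to_row[int(c)] for c in parts[1:5]])
                labels.append(phys_of_volume.get(etag, etag))
            elif etype == _GMSH_TRI:
                saw_tri = True
        pos += nb
    if not tets:
        extra = " (file contains only surface triangles)" if saw_tri else ""
        raise MeshError(f"{path}: no tetrahedral elements{extra}")
    return coords, np.array(tets, dtype=np.int64), np.array(labels, dtype=np.int64)


def write_gmsh(path: str | Path, mesh: TetMesh) -> None:
    """Write a TetMesh as Gmsh ASCII v2.2 with the tissue label as physical tag."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        fh.write(f"$Nodes\n{mesh.n_nodes}\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i} {x:.17g} {y:.17g} {z:.17g}\n")
        fh.write("$EndNodes\n")
        fh.write(f"$Elements\n{mesh.n_tets}\n")
        for i, (tet, label) in enumerate(zip(mesh.tets + 1, mesh.tet_label), start=1):
            fh.write(f"{i} 4 2 {label} {label} {tet[0]} {tet[1]} {tet[2]} {tet[3]}\n")
        fh.write("$EndElements\n")


# ---------------------------------------------------------------------------
# CSV table dialect
# ---------------------------------------------------------------------------


def read_mesh_tables(directory: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    directory = Path(directory)
    try:
        nodes = pd.read_csv(directory / "nodes.csv")[["x_mm", "y_mm", "z_mm"]].to_numpy(float)
        tets = pd.read_csv(directory / "tets.csv")[["n0", "n1", "n2", "n3"]].to_numpy(np.int64)
        labels = pd.read_csv(directory / "labels.csv")["label"].to_numpy(np.int64)
    except (FileNotFoundError, KeyError) as exc:
        raise MeshError(f"{directory}: not a mesh table directory ({exc})") from exc
    return nodes, tets, labels


def write_mesh_tables(directory: str | Path, mesh: TetMesh) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(mesh.nodes, columns=["x_mm", "y_mm", "z_mm"]).to_csv(
        directory / "nodes.csv", index=False
    )
    pd.DataFrame(mesh.tets, columns=["n0", "n1", "n2", "n3"]).to_csv(
        directory / "tets.csv", index=False
    )
    pd.DataFrame({"label": mesh.tet_label}).to_csv(directory / "labels.csv", index=False)


# ---------------------------------------------------------------------------
# Front door
# ---------------------------------------------------------------------------


def load_mesh(
    path: str | Path,
    tissues: TissueTable | None = None,
    unit_scale: float = 1.0,
) -> TetMesh:
    """Load and validate a labeled tet mesh.

    Parameters
    ----------
    path
        A Gmsh ``.msh`` file or a table-dialect directory.
    tissues
        Optional tissue table; when given, every element tag must be present
        in it (unknown tags raise a :class:`MeshError` naming them).
    unit_scale
        Multiplier applied to coordinates to obtain millimetres (e.g. 1000.0
        for a mesh stored in metres). Mesh files rarely declare units, so the
        caller decides.
    """
    path = Path(path)
    if path.is_dir():
        nodes, tets, labels = read_mesh_tables(path)
    elif path.suffix == ".msh":
        nodes, tets, labels = read_gmsh(path)
    else:
        raise MeshError(f"{path}: unsupported mesh format {path.suffix!r}")
    if unit_scale != 1.0:
        nodes = nodes * float(unit_scale)
    if tissues is not None:
        unknown = sorted(set(np.unique(labels).tolist()) - set(tissues.labels))
        if unknown:
            raise MeshError(f"{path}: unknown tissue tags {unknown} (not in tissue table)")
    mesh = TetMesh(nodes, tets, labels)
    logger.info(
        "loaded %s: %d nodes, %d tets, per-label counts %s",
        path, mesh.n_nodes, mesh.n_tets, mesh.label_counts(),
    )
    return mesh


def save_mesh(path: str | Path, mesh: TetMesh) -> None:
    path = Path(path)
    if path.suffix == ".msh":
        write_gmsh(path, mesh)
    else:
        write_mesh_tables(path, mesh)


# ---------------------------------------------------------------------------
# Tissue tables
# ---------------------------------------------------------------------------


def load_tissue_table(path: str | Path) -> TissueTable:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        raw = yaml.safe_load(path.read_text())
        entries = {
            int(label): (rec["name"], float(rec["conductivity_S_per_m"]))
            for label, rec in raw.items()
        }
    else:
        df = pd.read_csv(path)
        entries = {
            int(r.label): (str(r.name), float(r.conductivity_S_per_m))
            for r in df.itertuples(index=False)
        }
    return TissueTable(entries)


def save_tissue_table(path: str | Path, tissues: TissueTable) -> None:
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        raw = {
            int(label): {"name": e.name, "conductivity_S_per_m": float(e.conductivity)}
            for label, e in tissues.items()
        }
        path.write_text(yaml.safe_dump(raw, sort_keys=True))
    else:
        pd.DataFrame(
            [(l, e.name, e.conductivity) for l, e in tissues.items()],
            columns=["label", "name", "conductivity_S_per_m"],
        ).to_csv(path, index=False)


def default_tissue_table() -> TissueTable:
    """The shipped five-tissue mouse table plus gel, air and saline fills."""
    with importlib.resources.as_file(
        importlib.resources.files("mousefield.data") / "tissues.yaml"
    ) as p:
        return load_tissue_table(p)


# ---------------------------------------------------------------------------
# Solution export
# ---------------------------------------------------------------------------


def solution_table(mesh: TetMesh, solution) -> pd.DataFrame:
    """Per-node table: node_id, x_mm..z_mm, V, eX, eY, eZ, eMag."""
    return pd.DataFrame(
        {
            "node_id": np.arange(mesh.n_nodes),
            "x_mm": mesh.nodes[:, 0],
            "y_mm": mesh.nodes[:, 1],
            "z_mm": mesh.nodes[:, 2],
            "V": solution.V,
            "eX": solution.E_node[:, 0],
            "eY": solution.E_node[:, 1],
            "eZ": solution.E_node[:, 2],
            "eMag": solution.emag_node,
        }
    )


def write_solution_csv(path: str | Path, mesh: TetMesh, solution) -> None:
    solution_table(mesh, solution).to_csv(path, index=False)


def write_vtk(path: str | Path, mesh: TetMesh, solution=None) -> None:
    """Legacy ASCII VTK unstructured grid (tissue labels + optional fields)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmousefield export\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(fh, mesh.nodes, fmt="%.10g")
        fh.write(f"CELLS {mesh.n_tets} {mesh.n_tets * 5}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(mesh.n_tets, 4), mesh.tets]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {mesh.n_tets}\n")
        np.savetxt(fh, np.full(mesh.n_tets, 10), fmt="%d")
        fh.write(f"CELL_DATA {mesh.n_tets}\n")
        fh.write("SCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, mesh.tet_label, fmt="%d")
        if solution is not None:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            fh.write("SCALARS V double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, solution.V, fmt="%.10g")
            fh.write("SCALARS eMag double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, solution.emag_node, fmt="%.10g")
            fh.write("VECTORS E double\n")
            np.savetxt(fh, solution.E_node, fmt="%.10g")
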