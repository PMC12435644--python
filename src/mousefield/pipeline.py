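"""Staged, restartable simulation pipeline around a run folder.

A run folder holds a config snapshot, stage markers, logs and intermediate
artifacts, so a simulation can be inspected and restarted stage by stage:

* ``init``    — create the folder and freeze the config snapshot;
* ``mesh``    — build/load the mesh and apply the montage (craniotomy,
  electrodes); writes the augmented mesh, tissue table and placements;
* ``solve``   — assemble and solve the electrostatic problem; writes the
  per-node solution table and flux diagnostics;
* ``analyze`` — region summaries (tissues, box ROIs), homogeneity and
  relative focality; writes one table per region plus a metrics JSON.

A stage runs only when its upstream markers exist; re-running a completed
stage is a no-op unless forced, and a config that drifted from the snapshot
is an error unless forced. Identical config + inputs give identical output
artifacts (timestamps live only in markers and logs).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .fem import ContactLoad, FemProblem, FieldSolution, VolumeSource, check_flux, solve
from .mesh import TetMesh, TissueTable
from .metrics import (
    BoxRoiSpec,
    FocalityParams,
    RegionSelection,
    cap_percentile,
    relative_focality,
    select_box_roi,
    select_tissue_region,
    summarize,
)
from .montage import (
    CraniotomySpec,
    ElectrodeSpec,
    MontageSpec,
    apply_montage,
    preset_montage,
)
from .phantoms import Layer, make_layered_sphere, make_slab

logger = logging.getLogger("mousefield")

__all__ = ["PipelineError", "RunFolder", "run_stage", "report", "STAGES"]

STAGES = ("init", "mesh", "solve", "analyze")


class PipelineError(ValueError):
    """User-facing pipeline errors (missing stages, config drift...)."""


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunFolder:
    path: Path

    @property
    def config_path(self) -> Path:
        return self.path / "config.yaml"

    def marker(self, stage: str) -> Path:
        return self.path / "markers" / f"{stage}.done"

    def done(self, stage: str) -> bool:
        return self.marker(stage).exists()

    def mark(self, stage: str) -> None:
        self.marker(stage).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "stage": stage,
            "config_sha256": _sha256(self.config_path),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        self.marker(stage).write_text(json.dumps(payload, indent=2))

    def require(self, *stages: str) -> None:
        for s in stages:
            if not self.done(s):
                raise PipelineError(f"stage '{s}' incomplete; run it first")

    def config(self) -> dict:
        if not self.config_path.exists():
            raise PipelineError(f"{self.path} is not an initialized run folder")
        return yaml.safe_load(self.config_path.read_text())


# ---------------------------------------------------------------------------
# Config parsing
# ---------------------------------------------------------------------------


def _build_base_mesh(cfg: dict) -> tuple[TetMesh, TissueTable, dict[str, int]]:
    if "phantom" in cfg:
        p = cfg["phantom"]
        kind = p.get("kind")
        layers = [
            Layer(l["name"], float(l.get("sigma_S_per_m", 0.0) or 0.0) or _sigma_default(l["name"]),
                  float(l["extent_mm"]))
            for l in p["layers"]
        ]
        if kind == "slab":
            ph = make_slab(
                size_mm=tuple(p.get("size_mm", (10.0, 10.0, 10.0))),
                h_mm=float(p.get("h_mm", 1.0)),
                layers=layers,
            )
        elif kind == "layered_sphere":
            ph = make_layered_sphere(layers, subdiv=int(p.get("subdiv", 3)))
        else:
            raise PipelineError(f"unknown phantom kind {kind!r}")
        return ph.mesh, ph.tissues, ph.label_of
    if "mesh" in cfg:
        m = cfg["mesh"]
        tissues = (
            mio.load_tissue_table(m["tissue_table"])
            if "tissue_table" in m
            else mio.default_tissue_table()
        )
        mesh = mio.load_mesh(m["path"], tissues, unit_scale=float(m.get("unit_scale", 1.0)))
        label_of = {e.name: l for l, e in tissues.items()}
        return mesh, tissues, label_of
    raise PipelineError("config needs a 'phantom' or 'mesh' section")


def _sigma_default(name: str) -> float:
    table = mio.default_tissue_table()
    return table.conductivity_of(name)


def _build_montage(cfg: dict) -> tuple[MontageSpec, dict]:
    m = cfg.get("montage")
    if m is None:
        raise PipelineError("config needs a 'montage' section")
    opts = {k: v for k, v in m.get("params", {}).items()}
    if "preset" in m:
        spec = preset_montage(m["preset"], tuple(m["target_mm"]), **{
            k: (tuple(v) if isinstance(v, list) else v) for k, v in opts.items()
        })
        return spec, m.get("apply", {})
    electrodes = [ElectrodeSpec(**{**e, "center_mm": tuple(e["center_mm"])}) for e in m["electrodes"]]
    cran = None
    if m.get("craniotomy"):
        c = dict(m["craniotomy"])
        c["center_mm"] = tuple(c["center_mm"])
        if "axis" in c:
            c["axis"] = tuple(c["axis"])
        cran = CraniotomySpec(**c)
    return MontageSpec(m.get("name", "custom"), electrodes, cran), m.get("apply", {})


def _regions(cfg: dict, mesh: TetMesh, label_of: dict[str, int]) -> dict[str, RegionSelection]:
    out: dict[str, RegionSelection] = {}
    for r in cfg.get("analysis", {}).get("regions", []):
        name = r["name"]
        if r["type"] == "tissue":
            labels = [label_of[t] for t in r["tissues"]]
            out[name] = select_tissue_region(mesh, labels, name)
        elif r["type"] == "box":
            size = r["size_mm"]
            labels = [label_of[t] for t in r.get("tissues", [])] or None
            out[name] = select_box_roi(
                mesh,
                BoxRoiSpec(tuple(r["center_mm"]), size[0], size[1], size[2], labels),
            )
            out[name].provenance = name
        else:
            raise PipelineError(f"unknown region type {r['type']!r} for region {name!r}")
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_init(run: RunFolder, config_path: Path, force: bool) -> None:
    run.path.mkdir(parents=True, exist_ok=True)
    (run.path / "logs").mkdir(exist_ok=True)
    if run.config_path.exists() and not force:
        if _sha256(run.config_path) != _sha256(config_path):
            raise PipelineError(
                "run folder already initialized with a different config (use --force)"
            )
    run.config_path.write_text(Path(config_path).read_text())
    run.mark("init")


def _stage_mesh(run: RunFolder, force: bool) -> None:
    run.require("init")
    if run.done("mesh") and not force:
        logger.info("stage 'mesh' already complete; skipping")
        return
    cfg = run.config()
    mesh, tissues, label_of = _build_base_mesh(cfg)
    montage, apply_opts = _build_montage(cfg)
    solver_cfg = cfg.get("solver", {})
    result = apply_montage(
        mesh,
        tissues,
        montage,
        snap_mm=float(apply_opts.get("snap_mm", 2.0)),
        n_layers=int(solver_cfg.get("n_layers", 8)),
    )
    mdir = run.path / "mesh"
    mio.write_mesh_tables(mdir, result.mesh)
    mio.save_tissue_table(mdir / "tissues.yaml", result.tissues)
    placements = []
    for p in result.placements:
        placements.append(
            {
                "name": p.name,
                "label": int(p.label),
                "current_mA": p.current_mA,
                "contact_tris": None if p.contact_tris is None else p.contact_tris.tolist(),
                "source_tets": None if p.source_tets is None else p.source_tets.tolist(),
            }
        )
    (mdir / "placements.json").write_text(json.dumps(placements))
    (mdir / "label_of.json").write_text(json.dumps(label_of))
    run.mark("mesh")


def _load_mesh_stage(run: RunFolder) -> tuple[TetMesh, TissueTable, list[dict], dict[str, int]]:
    mdir = run.path / "mesh"
    tissues = mio.load_tissue_table(mdir / "tissues.yaml")
    mesh = mio.load_mesh(mdir, tissues)
    placements = json.loads((mdir / "placements.json").read_text())
    label_of = json.loads((mdir / "label_of.json").read_text())
    return mesh, tissues, placements, label_of


def _stage_solve(run: RunFolder, force: bool) -> None:
    run.require("init", "mesh")
    if run.done("solve") and not force:
        logger.info("stage 'solve' already complete; skipping")
        return
    cfg = run.config()
    mesh, tissues, placements, _ = _load_mesh_stage(run)
    contacts, sources = [], []
    for p in placements:
        if p["contact_tris"] is not None:
            contacts.append(
                ContactLoad(p["name"], np.array(p["contact_tris"], dtype=np.int64), p["current_mA"])
            )
        else:
            sources.append(
                VolumeSource(p["name"], np.array(p["source_tets"], dtype=np.int64), p["current_mA"])
            )
    problem = FemProblem(mesh, tissues.sigma_array(mesh.tet_label), contacts, sources)
    solver_cfg = cfg.get("solver", {})
    solution = solve(
        problem,
        tol=float(solver_cfg.get("tol", 1e-10)),
        method=solver_cfg.get("method", "auto"),
    )
    mio.write_solution_csv(run.path / "solution.csv", mesh, solution)
    diag = dict(solution.diagnostics)
    diag["flux_mA"] = check_flux(solution, problem)
    (run.path / "flux.json").write_text(json.dumps(diag, indent=2, default=float))
    run.mark("solve")


def _load_solution(run: RunFolder, mesh: TetMesh) -> FieldSolution:
    df = pd.read_csv(run.path / "solution.csv")
    E = df[["eX", "eY", "eZ"]].to_numpy()
    return FieldSolution(
        V=df["V"].to_numpy(),
        E_node=E,
        emag_node=df["eMag"].to_numpy(),
        E_tet=np.empty((0, 3)),
        diagnostics={},
    )


def _stage_analyze(run: RunFolder, force: bool) -> None:
    run.require("init", "mesh", "solve")
    if run.done("analyze") and not force:
        logger.info("stage 'analyze' already complete; skipping")
        return
    cfg = run.config()
    mesh, tissues, placements, label_of = _load_mesh_stage(run)
    solution = _load_solution(run, mesh)
    regions = _regions(cfg, mesh, label_of)
    outdir = run.path / "summaries"
    outdir.mkdir(exist_ok=True)
    metrics_out: dict[str, dict] = {}
    focality_cfg = cfg.get("analysis", {}).get("focality")
    for name, region in regions.items():
        summary = summarize(solution, region)
        summary.region = name
        if focality_cfg and name == focality_cfg.get("target"):
            ref = regions[focality_cfg["reference"]].minus(region)
            params = FocalityParams(P=float(focality_cfg.get("P", 0.4)))
            summary.focality = relative_focality(solution, region, ref, params)
            summary.focality_params = params
            summary.reference = focality_cfg["reference"]
        summary.to_frame().to_csv(outdir / f"{name}.csv")
        metrics_out[name] = {
            "n": summary.n,
            "homogeneity": summary.homogeneity,
            "focality": summary.focality,
            "mean_eMag": float(summary.stats.loc["eMag", "mean"]),
        }
    (outdir / "metrics.json").write_text(json.dumps(metrics_out, indent=2))
    run.mark("analyze")


_STAGE_FNS = {"mesh": _stage_mesh, "solve": _stage_solve, "analyze": _stage_analyze}


def run_stage(
    stage: str, config_path: str | Path, run_dir: str | Path, force: bool = False
) -> RunFolder:
    """Run one pipeline stage (or ``all``) for the given config and folder."""
    config_path = Path(config_path)
    run = RunFolder(Path(run_dir))
    if stage not in (*STAGES, "all"):
        raise PipelineError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    if stage in ("init", "all"):
        _stage_init(run, config_path, force)
    if run.config_path.exists() and config_path.exists():
        if _sha256(run.config_path) != _sha256(config_path) and not force:
            raise PipelineError("config drifted from the run snapshot (use --force)")
    if stage == "all":
        for s in ("mesh", "solve", "analyze"):
            _STAGE_FNS[s](run, force)
    elif stage != "init":
        _STAGE_FNS[stage](run, force)
    return run


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------


def report(
    run_dir: str | Path,
    cap_q: float = 98.0,
    section_axes: str = "xyz",
    out_dir: str | Path | None = None,
) -> list[Path]:
    """Summary tables as text plus 2D section images of eMag.

    Field magnitudes in the images are capped at the ``cap_q``-th percentile
    (display only). Sections pass through the mesh bounding-box center,
    one per axis in ``section_axes``.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    run = RunFolder(Path(run_dir))
    run.require("analyze")
    mesh, tissues, placements, label_of = _load_mesh_stage(run)
    solution = _load_solution(run, mesh)
    cfg = run.config()
    out = Path(out_dir) if out_dir else run.path / "report"
    out.mkdir(exist_ok=True)
    written: list[Path] = []

    regions = _regions(cfg, mesh, label_of)
    focality_cfg = cfg.get("analysis", {}).get("focality")
    for name, region in regions.items():
        summary = summarize(solution, region)
        summary.region = name
        if focality_cfg and name == focality_cfg.get("target"):
            ref = regions[focality_cfg["reference"]].minus(region)
            params = FocalityParams(P=float(focality_cfg.get("P", 0.4)))
            summary.focality = relative_focality(solution, region, ref, params)
            summary.focality_params = params
            summary.reference = focality_cfg["reference"]
        p = out / f"{name}.txt"
        p.write_text(summary.to_text() + "\n")
        written.append(p)

    lo, hi = mesh.bounding_box()
    center = (lo + hi) / 2.0
    capped = cap_percentile(solution.emag_node, cap_q)
    axis_id = {"x": 0, "y": 1, "z": 2}
    plane_axes = {"x": (1, 2), "y": (0, 2), "z": (0, 1)}
    names = {"x": "sagittal", "y": "coronal", "z": "transverse"}
    for ax in section_axes:
        i = axis_id[ax]
        half = max((hi[i] - lo[i]) / 40.0, 0.25)
        sel = np.abs(mesh.nodes[:, i] - center[i]) <= half
        if not sel.any():
            continue
        j, k = plane_axes[ax]
        fig, axp = plt.subplots(figsize=(5, 4))
        sc = axp.scatter(
            mesh.nodes[sel, j], mesh.nodes[sel, k], c=capped[sel], s=4, cmap="viridis"
        )
        axp.set_aspect("equal")
        axp.set_xlabel("xyz"[j] + " (mm)")
        axp.set_ylabel("xyz"[k] + " (mm)")
        axp.set_title(f"{names[ax]} section, eMag (V/m, capped at p{cap_q:g})")
        fig.colorbar(sc, ax=axp, label="eMag (V/m)")
        p = out / f"section_{names[ax]}.png"
        fig.savefig(p, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(p)
    return written
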