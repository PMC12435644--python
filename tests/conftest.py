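"""Shared fixtures: phantom meshes and solved sphere-phantom montages.

Everything is generated programmatically; the sphere fixtures emulate a
mouse-head-like conductor (gray-matter core with CSF/bone/skin shells at
mouse scale) with the four study montages placed around a dorsal target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import mousefield as mf

BRAIN_R, CSF_R, BONE_R, SKIN_R = 4.0, 4.4, 4.8, 5.2  # mm
TARGET = np.array([0.0, 0.0, SKIN_R])
ROI_CENTER = (0.0, 0.0, 3.5)  # dorsal gray matter under the target


def mouse_shells():
    return [
        mf.Layer("gray_matter", 0.275, BRAIN_R),
        mf.Layer("csf", 1.654, CSF_R),
        mf.Layer("bone", 0.01, BONE_R),
        mf.Layer("soft_tissue", 0.465, SKIN_R),
    ]


@pytest.fixture(scope="session")
def slab10():
    """Homogeneous 10 mm gray-matter cube, 1 mm lattice."""
    return mf.make_slab(
        size_mm=(10.0, 10.0, 10.0), h_mm=1.0, layers=[mf.Layer("gray_matter", 0.275, 10.0)]
    )


@pytest.fixture(scope="session")
def slab_two_layer():
    """Soft tissue over bone, interface on element faces at z=5."""
    return mf.make_slab(
        size_mm=(10.0, 10.0, 10.0),
        h_mm=1.0,
        layers=[mf.Layer("soft_tissue", 0.465, 5.0), mf.Layer("bone", 0.01, 5.0)],
    )


@pytest.fixture(scope="session")
def sphere_phantom():
    return mf.make_layered_sphere(mouse_shells(), subdiv=3)


def slab_plate_problem(phantom, current_mA=0.1):
    """Full opposite z-faces as plate contacts (J = I/area, uniform)."""
    mesh = phantom.mesh
    zmax = mesh.nodes[:, 2].max()
    anode = mf.patch_contact(mesh, "anode", +current_mA, lambda c: np.isclose(c[:, 2], zmax))
    cathode = mf.patch_contact(mesh, "cathode", -current_mA, lambda c: np.isclose(c[:, 2], 0.0))
    sigma = phantom.tissues.sigma_array(mesh.tet_label)
    return mf.FemProblem(mesh, sigma, [anode, cathode])


@dataclass
class MontageRun:
    name: str
    result: mf.MontageResult
    problem: mf.FemProblem
    solution: mf.FieldSolution
    brain_label: int


def run_sphere_montage(sphere, name, fill=2.5e-14, n_layers=8):
    montage = mf.preset_montage(
        name,
        TARGET,
        back_size_mm=(4.0, 4.0),
        ring_radius_mm=2.0,
        pair_offset_mm=2.0,
        fill_conductivity_S_per_m=fill,
    )
    result = mf.apply_montage(sphere.mesh, sphere.tissues, montage, n_layers=n_layers)
    problem = mf.build_problem(result)
    solution = mf.solve(problem)
    return MontageRun(name, result, problem, solution, sphere.label_of["gray_matter"])


@pytest.fixture(scope="session")
def sphere_runs(sphere_phantom):
    """The study montages solved on the sphere phantom: standard two-electrode
    (1xBack), high-definition center-surround (1x4), ring + back return with a
    dry craniotomy (4xBack), and the local pair with dry and wet craniotomy."""
    runs = {
        "1xBack": run_sphere_montage(sphere_phantom, "1xBack"),
        "1x4": run_sphere_montage(sphere_phantom, "1x4"),
        "4xBack_cran": run_sphere_montage(sphere_phantom, "4xBack_cran"),
        "1x1_dry": run_sphere_montage(sphere_phantom, "1x1_cran", fill=2.5e-14),
        "1x1_wet": run_sphere_montage(sphere_phantom, "1x1_cran", fill=1.654),
    }
    return runs


def brain_region(run: MontageRun) -> mf.RegionSelection:
    return mf.select_tissue_region(run.result.mesh, [run.brain_label], "brain")


def target_roi(run: MontageRun) -> mf.RegionSelection:
    return mf.select_box_roi(
        run.result.mesh,
        mf.BoxRoiSpec(ROI_CENTER, 2.0, 2.0, 1.0, tissue_labels=[run.brain_label]),
    )
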