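"""Electrostatic solver: assembly identities, analytic oracles, conservation,
reciprocity, linearity and refinement convergence."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

import mousefield as mf
from mousefield.fem import MM_TO_M, _apply_reference, assemble
from mousefield.mesh import MeshError, extract_boundary, tet_geometry

from .conftest import slab_plate_problem

REF_NODES = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])

# unit reference tet, sigma=1, unit edge length: K = V * (G G^T)
K_UNIT = (
    np.array(
        [
            [3, -1, -1, -1],
            [-1, 1, 0, 0],
            [-1, 0, 1, 0],
            [-1, 0, 0, 1],
        ],
        dtype=float,
    )
    / 6.0
)


class TestAssembly:
    def test_single_tet_stiffness_matches_hand_computation(self):
        mesh = mf.TetMesh(REF_NODES, np.array([[0, 1, 2, 3]]), np.array([1]))
        K, f = assemble(mf.FemProblem(mesh, np.array([1.0]), [], []))
        # mm coordinates scaled to metres: K scales linearly with edge length
        np.testing.assert_allclose(K.toarray(), K_UNIT * MM_TO_M, atol=1e-18)
        assert np.all(f == 0)

    def test_constant_vector_in_null_space(self, slab_two_layer):
        problem = slab_plate_problem(slab_two_layer)
        K, f = assemble(problem)
        ones = np.ones(K.shape[0])
        assert np.abs(K @ ones).max() < 1e-10 * np.abs(K.data).max()

    def test_load_vector_sums_to_zero(self, sphere_runs):
        for run in sphere_runs.values():
            _, f = assemble(run.problem)
            assert abs(f.sum()) < 1e-15  # amps

    def test_unbalanced_currents_rejected(self, slab10):
        mesh = slab10.mesh
        anode = mf.patch_contact(mesh, "a", 0.2, lambda c: np.isclose(c[:, 2], 10.0))
        with pytest.raises(MeshError, match="sum"):
            mf.FemProblem(mesh, slab10.tissues.sigma_array(mesh.tet_label), [anode])

    def test_empty_contact_rejected(self, slab10):
        mesh = slab10.mesh
        with pytest.raises(MeshError, match="no boundary triangles"):
            mf.patch_contact(mesh, "x", 0.0, lambda c: np.zeros(len(c), bool))


class TestAnalyticSolutions:
    def test_homogeneous_slab_reproduces_ohms_law(self, slab10):
        # J = 1 A/m^2 over the 10x10 mm face -> I = 0.1 mA; E = J/sigma
        problem = slab_plate_problem(slab10, current_mA=0.1)
        sol = mf.solve(problem)
        expected = 1.0 / 0.275
        rel = np.abs(sol.emag_node - expected) / expected
        assert rel.max() < 1e-8  # linear solution lies in the P1 space
        # field is straight down the z axis
        assert np.abs(sol.eZ + expected).max() < 1e-8 * expected

    def test_two_layer_slab_field_ratio_is_sigma_ratio(self, slab_two_layer):
        problem = slab_plate_problem(slab_two_layer, current_mA=0.1)
        sol = mf.solve(problem)
        mesh = slab_two_layer.mesh
        soft = slab_two_layer.label_of["soft_tissue"]
        Ez_soft = sol.E_tet[mesh.tet_label == soft, 2]
        Ez_bone = sol.E_tet[mesh.tet_label != soft, 2]
        ratio = Ez_bone.mean() / Ez_soft.mean()
        assert ratio == pytest.approx(0.465 / 0.01, rel=1e-6)
        # piecewise-constant per layer, not just on average
        assert np.abs(Ez_bone / Ez_bone.mean() - 1).max() < 1e-8

    def test_zero_current_gives_zero_field(self, slab10):
        mesh = slab10.mesh
        problem = mf.FemProblem(mesh, slab10.tissues.sigma_array(mesh.tet_label), [], [])
        sol = mf.solve(problem)
        assert np.all(sol.V == 0)
        assert np.all(sol.emag_node == 0)

    def test_emag_consistent_with_components(self, sphere_runs):
        sol = sphere_runs["1xBack"].solution
        np.testing.assert_allclose(
            sol.emag_node, np.linalg.norm(sol.E_node, axis=1), rtol=1e-12
        )


class TestLinearityAndReciprocity:
    def test_doubling_currents_doubles_fields(self, slab_two_layer):
        p1 = slab_plate_problem(slab_two_layer, current_mA=0.1)
        p2 = slab_plate_problem(slab_two_layer, current_mA=0.2)
        s1, s2 = mf.solve(p1), mf.solve(p2)
        np.testing.assert_allclose(s2.V, 2 * s1.V, rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(s2.E_node, 2 * s1.E_node, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(s2.emag_node, 2 * s1.emag_node, rtol=1e-10, atol=1e-12)

    def test_reciprocity_between_electrode_pairs(self, sphere_phantom):
        # place two independent pairs; drive one, read the other, and swap
        mesh, tissues = sphere_phantom.mesh, sphere_phantom.tissues
        placements = {}
        for nm, c in (
            ("A+", (0, 0, 5.2)), ("A-", (0, 0, -5.2)),
            ("B+", (5.2, 0, 0)), ("B-", (-5.2, 0, 0)),
        ):
            spec = mf.ElectrodeSpec(
                name=nm, kind="surface", shape="disc", center_mm=c,
                current_mA=0.0, radius_mm=0.8,
            )
            mesh, tissues, p = mf.place_surface_electrode(mesh, tissues, spec, n_layers=4)
            placements[nm] = p
        sigma = tissues.sigma_array(mesh.tet_label)

        def drive(plus, minus, I=0.1):
            contacts = [
                mf.ContactLoad(plus, placements[plus].contact_tris, +I),
                mf.ContactLoad(minus, placements[minus].contact_tris, -I),
            ]
            problem = mf.FemProblem(mesh, sigma, contacts)
            sol = mf.solve(problem)
            probe = mf.FemProblem(
                mesh, sigma,
                [mf.ContactLoad(nm, placements[nm].contact_tris, 0.0) for nm in placements],
            )
            return mf.electrode_potentials(sol, probe)

        vA = drive("A+", "A-")
        vB = drive("B+", "B-")
        lhs = vA["B+"] - vA["B-"]
        rhs = vB["A+"] - vB["A-"]
        assert lhs == pytest.approx(rhs, rel=1e-8)


class TestConservation:
    def test_slab_plate_flux_matches_injected_current(self, slab_two_layer):
        problem = slab_plate_problem(slab_two_layer, current_mA=0.1)
        sol = mf.solve(problem)
        flux = mf.check_flux(sol, problem)
        assert flux["anode"] == pytest.approx(0.1, rel=1e-8)
        assert flux["cathode"] == pytest.approx(-0.1, rel=1e-8)
        assert abs(flux["net"]) < 1e-10

    def test_no_current_no_flux(self, slab10):
        mesh = slab10.mesh
        anode = mf.patch_contact(mesh, "a", 0.0, lambda c: np.isclose(c[:, 2], 10.0))
        problem = mf.FemProblem(mesh, slab10.tissues.sigma_array(mesh.tet_label), [anode])
        sol = mf.solve(problem)
        flux = mf.check_flux(sol, problem)
        assert flux["a"] == pytest.approx(0.0, abs=1e-14)


class TestSolverPaths:
    def test_cg_matches_direct(self, slab_two_layer):
        problem = slab_plate_problem(slab_two_layer, current_mA=0.1)
        direct = mf.solve(problem, method="direct")
        cg = mf.solve(problem, method="cg", tol=1e-12)
        np.testing.assert_allclose(cg.V, direct.V, atol=1e-8 * np.abs(direct.V).max())

    def test_nonconvergence_reports_residual_history(self, slab_two_layer):
        problem = slab_plate_problem(slab_two_layer, current_mA=0.1)
        with pytest.raises(mf.SolverError) as err:
            mf.solve(problem, method="cg", tol=1e-14, max_iter=3)
        assert len(err.value.residuals) > 0

    def test_craniotomy_conductive_fill_reduces_brain_field(self, sphere_runs):
        dry = sphere_runs["1x1_dry"]
        wet = sphere_runs["1x1_wet"]
        brain_dry = dry.solution.emag_node[
            dry.result.mesh.nodes_with_label([dry.brain_label])
        ].mean()
        brain_wet = wet.solution.emag_node[
            wet.result.mesh.nodes_with_label([wet.brain_label])
        ].mean()
        assert brain_wet < brain_dry  # saline shunts current away from the brain


KEAST4 = np.array(
    [
        [0.5854101966249685, 0.1381966011250105, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.5854101966249685, 0.1381966011250105, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.5854101966249685, 0.1381966011250105],
        [0.1381966011250105, 0.1381966011250105, 0.1381966011250105, 0.5854101966249685],
    ]
)


def _manufactured_l2_error(mesh, sigma_val=0.275):
    """L2 error against the harmonic u = x^2 - z^2 with exact Neumann data on
    the mesh's own boundary faces (centroid-rule loads, mean-balanced)."""
    surf = extract_boundary(mesh)
    c = surf.centroids * MM_TO_M
    g = sigma_val * (2 * c[:, 0] * surf.normals[:, 0] - 2 * c[:, 2] * surf.normals[:, 2])
    f = np.zeros(mesh.n_nodes)
    contrib = g * surf.areas * MM_TO_M**2 / 3.0
    for i in range(3):
        np.add.at(f, surf.tris[:, i], contrib)
    f -= f.sum() / len(f)
    K, _ = assemble(mf.FemProblem(mesh, np.full(mesh.n_tets, sigma_val), [], []))
    Kc, fc = _apply_reference(K, f, 0)
    V = spla.splu(Kc.tocsc()).solve(fc)
    geom = tet_geometry(mesh)
    vol = geom.volumes * MM_TO_M**3
    pts = np.einsum("qi,mid->mqd", KEAST4, mesh.nodes[mesh.tets] * MM_TO_M)
    u_q = pts[:, :, 0] ** 2 - pts[:, :, 2] ** 2
    vh_q = np.einsum("qi,mi->mq", KEAST4, V[mesh.tets])
    w = np.repeat(vol[:, None] / 4.0, 4, axis=1)
    diff = vh_q - u_q
    diff -= (diff * w).sum() / w.sum()
    return float(np.sqrt((diff**2 * w).sum()))


class TestRefinementConvergence:
    def test_slab_l2_order_at_least_1_8(self):
        errors = []
        for h in (2.0, 1.0, 0.5):
            ph = mf.make_slab(size_mm=(10, 10, 10), h_mm=h,
                              layers=[mf.Layer("gray_matter", 0.275, 10.0)])
            errors.append(_manufactured_l2_error(ph.mesh))
        orders = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert (orders >= 1.8).all(), orders

    def test_sphere_l2_order_at_least_1_8(self):
        errors = []
        for subdiv in (3, 4):
            sp = mf.make_layered_sphere([mf.Layer("gray_matter", 0.275, 5.0)], subdiv=subdiv)
            errors.append(_manufactured_l2_error(sp.mesh))
        order = np.log2(errors[0] / errors[1])
        assert order >= 1.8, order
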