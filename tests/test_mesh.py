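"""Mesh validation, geometry, boundary extraction and I/O round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mousefield as mf
from mousefield.mesh import MeshError, split_prism
from mousefield.io import read_gmsh, write_gmsh

REF_NODES = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
REF_TET = np.array([[0, 1, 2, 3]])


def single_tet():
    return mf.TetMesh(REF_NODES, REF_TET, np.array([1]))


class TestGeometry:
    def test_reference_tet_volume_and_gradients(self):
        geom = mf.tet_geometry(single_tet())
        assert geom.volumes[0] == pytest.approx(1.0 / 6.0, rel=1e-14)
        expected = np.array([[-1, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        np.testing.assert_allclose(geom.grads[0], expected, atol=1e-14)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=12, max_size=12))
    def test_random_tet_volume_matches_determinant_oracle(self, coords):
        nodes = np.array(coords).reshape(4, 3)
        a, b, c, d = nodes
        det6 = abs(np.linalg.det(np.stack([b - a, c - a, d - a])))
        if det6 < 1e-6:  # too close to degenerate to compare reliably
            return
        mesh = mf.TetMesh(nodes, REF_TET, np.array([1]))
        geom = mf.tet_geometry(mesh)
        assert geom.volumes[0] == pytest.approx(det6 / 6.0, rel=1e-9)
        # partition of unity: shape-function gradients cancel
        np.testing.assert_allclose(geom.grads[0].sum(axis=0), 0.0, atol=1e-12 * max(1, det6))

    def test_canonical_orientation_flips_inverted_tets(self):
        inverted = np.array([[0, 2, 1, 3]])  # negative signed volume
        mesh = mf.TetMesh(REF_NODES, inverted, np.array([1]))
        assert mf.tet_geometry(mesh).volumes[0] > 0

    def test_degenerate_tet_rejected_with_indices(self):
        nodes = np.vstack([REF_NODES, [[0.5, 0.5, 0.0]]])
        flat = np.array([[0, 1, 2, 4]])  # coplanar
        with pytest.raises(MeshError, match="degenerate"):
            mf.TetMesh(nodes, flat, np.array([1]))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(MeshError, match="out of range"):
            mf.TetMesh(REF_NODES, np.array([[0, 1, 2, 7]]), np.array([1]))


class TestBoundary:
    def test_single_tet_has_four_boundary_faces(self):
        surf = mf.extract_boundary(single_tet())
        assert len(surf.tris) == 4

    def test_unit_cube_boundary_area(self, slab10):
        cube = mf.make_slab(size_mm=(1, 1, 1), h_mm=1.0, layers=[mf.Layer("soft_tissue", 0.465, 1.0)])
        surf = mf.extract_boundary(cube.mesh)
        assert surf.areas.sum() == pytest.approx(6.0, rel=1e-12)

    def test_normals_point_outward(self, slab10):
        surf = mf.extract_boundary(slab10.mesh)
        center = slab10.mesh.nodes.mean(axis=0)
        outward = np.einsum("ij,ij->i", surf.centroids - center, surf.normals)
        assert (outward > 0).all()

    def test_extraction_is_stable_across_reruns(self, slab10):
        mesh = slab10.mesh
        first = mf.extract_boundary(mesh)
        mesh._boundary = None  # force recomputation
        second = mf.extract_boundary(mesh)
        np.testing.assert_array_equal(first.tris, second.tris)

    def test_sphere_boundary_area_close_to_analytic(self, sphere_phantom):
        surf = mf.extract_boundary(sphere_phantom.mesh)
        R = sphere_phantom.shell_radii_mm[-1]
        assert surf.areas.sum() == pytest.approx(4 * np.pi * R**2, rel=0.05)


class TestSplitPrism:
    def test_adjacent_prisms_share_diagonals(self):
        # two prisms sharing the quad face over edge (1, 2)
        bottom = np.array([[0, 1, 2], [1, 3, 2]])
        top = np.array([[10, 11, 12], [11, 13, 12]])
        tets = split_prism(bottom, top)
        faces = set()
        for tet in tets:
            for f in ([0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]):
                faces.add(tuple(sorted(tet[f])))
        # the shared quad (1,2,12,11) must be split the same way on both
        # sides: exactly one of its two diagonals appears as face edges
        diag_a = {(1, 2, 12), (1, 11, 12)}  # diagonal 1-12
        diag_b = {(1, 2, 11), (2, 11, 12)}  # diagonal 2-11
        assert diag_a <= faces or diag_b <= faces
        assert not (diag_a <= faces and diag_b <= faces)


class TestTissueTable:
    def test_rejects_nonpositive_conductivity(self):
        with pytest.raises(MeshError, match="> 0"):
            mf.TissueTable({1: ("bad", 0.0)})

    def test_add_allocates_fresh_label(self):
        t = mf.TissueTable({1: ("gray_matter", 0.275)})
        label = t.add("gel", 0.3)
        assert label == 2
        assert t[label].conductivity == 0.3
        assert t.label_of("gel") == 2

    def test_sigma_array_flags_unknown_labels(self):
        t = mf.TissueTable({1: ("gray_matter", 0.275)})
        with pytest.raises(MeshError, match="missing"):
            t.sigma_array(np.array([1, 2]))

    def test_default_table_has_study_tissues(self):
        t = mf.default_tissue_table()
        assert t.conductivity_of("gray_matter") == 0.275
        assert t.conductivity_of("csf") == 1.654
        assert t.conductivity_of("bone") == 0.01
        assert t.conductivity_of("soft_tissue") == 0.465
        assert t.conductivity_of("eyeball") == 0.5
        assert t.conductivity_of("air") == 2.5e-14


GMSH41_CUBE = """$MeshFormat
4.1 0 8
$EndMeshFormat
$Entities
0 0 0 1
1 0 0 0 1 1 1 1 42 0
$EndEntities
$Nodes
1 {nn} 1 {nn}
3 1 0 {nn}
{ids}
{coords}
$EndNodes
$Elements
1 {nt} 1 {nt}
3 1 4 {nt}
{elems}
$EndElements
"""


class TestIO:
    def test_gmsh2_round_trip_preserves_labels(self, tmp_path, slab_two_layer):
        mesh = slab_two_layer.mesh
        path = tmp_path / "slab.msh"
        write_gmsh(path, mesh)
        loaded = mf.load_mesh(path, slab_two_layer.tissues)
        np.testing.assert_allclose(loaded.nodes, mesh.nodes)
        assert loaded.label_counts() == mesh.label_counts()
        assert loaded.total_volume() == pytest.approx(mesh.total_volume(), rel=1e-12)

    def test_csv_table_round_trip(self, tmp_path, slab10):
        mesh = slab10.mesh
        mf.save_mesh(tmp_path / "tables", mesh)
        loaded = mf.load_mesh(tmp_path / "tables")
        np.testing.assert_allclose(loaded.nodes, mesh.nodes)
        np.testing.assert_array_equal(loaded.tets, mesh.tets)
        np.testing.assert_array_equal(loaded.tet_label, mesh.tet_label)

    def test_gmsh41_reader_with_entities_physical_tags(self, tmp_path):
        cube = mf.make_slab(size_mm=(1, 1, 1), h_mm=1.0, layers=[mf.Layer("soft_tissue", 0.465, 1.0)])
        mesh = cube.mesh
        nn, nt = mesh.n_nodes, mesh.n_tets
        text = GMSH41_CUBE.format(
            nn=nn,
            nt=nt,
            ids="\n".join(str(i + 1) for i in range(nn)),
            coords="\n".join(" ".join(f"{x:.9g}" for x in row) for row in mesh.nodes),
            elems="\n".join(
                f"{i + 1} " + " ".join(str(n + 1) for n in tet) for i, tet in enumerate(mesh.tets)
            ),
        )
        path = tmp_path / "cube41.msh"
        path.write_text(text)
        nodes, tets, labels = read_gmsh(path)
        loaded = mf.TetMesh(nodes, tets, labels)
        assert loaded.total_volume() == pytest.approx(1.0, rel=1e-12)
        assert set(labels) == {42}  # physical tag resolved via $Entities

    def test_triangle_only_file_rejected(self, tmp_path):
        path = tmp_path / "surface.msh"
        path.write_text(
            "$MeshFormat\n2.2 0 8\n$EndMeshFormat\n"
            "$Nodes\n3\n1 0 0 0\n2 1 0 0\n3 0 1 0\n$EndNodes\n"
            "$Elements\n1\n1 2 2 1 1 1 2 3\n$EndElements\n"
        )
        with pytest.raises(MeshError, match="no tetrahedral elements"):
            read_gmsh(path)

    def test_unknown_tissue_tag_named_in_error(self, tmp_path, slab10):
        path = tmp_path / "slab.msh"
        write_gmsh(path, slab10.mesh)
        table = mf.TissueTable({99: ("other", 1.0)})
        with pytest.raises(MeshError, match=r"\[1\]"):
            mf.load_mesh(path, table)

    def test_unit_scale_converts_to_mm(self, tmp_path, slab10):
        path = tmp_path / "slab.msh"
        write_gmsh(path, slab10.mesh)
        loaded = mf.load_mesh(path, unit_scale=0.001)
        assert loaded.nodes.max() == pytest.approx(0.01)

    def test_tissue_table_yaml_csv_round_trip(self, tmp_path):
        t = mf.default_tissue_table()
        for name in ("t.yaml", "t.csv"):
            mf.save_tissue_table(tmp_path / name, t)
            loaded = mf.load_tissue_table(tmp_path / name)
            assert loaded.labels == t.labels
            for label in t.labels:
                assert loaded[label].conductivity == pytest.approx(t[label].conductivity)
                assert loaded[label].name == t[label].name
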