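"""Electrode placement, craniotomies and montage presets."""

import numpy as np
import pytest

import mousefield as mf
from mousefield.montage import MontageError, _region_mask
from mousefield.mesh import tet_geometry


@pytest.fixture(scope="module")
def flat_patch():
    """Fine flat slab for footprint-accuracy checks."""
    return mf.make_slab(size_mm=(4.0, 4.0, 1.0), h_mm=0.2,
                        layers=[mf.Layer("soft_tissue", 0.465, 1.0)])


class TestSurfaceElectrode:
    def test_disc_extrusion_volume_matches_footprint(self, flat_patch):
        spec = mf.ElectrodeSpec(
            name="a", kind="surface", shape="disc", center_mm=(2.0, 2.0, 1.0),
            current_mA=0.1, radius_mm=0.6, thickness_mm=1.0,
        )
        _, _, p = mf.place_surface_electrode(flat_patch.mesh, flat_patch.tissues, spec)
        analytic = np.pi * 0.6**2 * 1.0
        assert p.added_volume_mm3 == pytest.approx(analytic, rel=0.10)
        assert p.contact_area_mm2 == pytest.approx(np.pi * 0.6**2, rel=0.10)

    def test_cuboid_contact_area_matches_pad_size(self):
        back = mf.make_slab(size_mm=(40.0, 40.0, 4.0), h_mm=1.0,
                            layers=[mf.Layer("soft_tissue", 0.465, 4.0)])
        spec = mf.ElectrodeSpec(
            name="pad", kind="surface", shape="cuboid", center_mm=(20.0, 20.0, 4.0),
            current_mA=-0.2, width_mm=15.0, length_mm=15.0, thickness_mm=1.0,
        )
        _, _, p = mf.place_surface_electrode(back.mesh, back.tissues, spec)
        assert p.contact_area_mm2 == pytest.approx(225.0, rel=0.10)

    def test_off_mesh_footprint_rejected(self, flat_patch):
        spec = mf.ElectrodeSpec(
            name="far", kind="surface", shape="disc", center_mm=(2.0, 2.0, 30.0),
            current_mA=0.1, radius_mm=0.6,
        )
        with pytest.raises(MontageError, match="snap distance|misses"):
            mf.place_surface_electrode(flat_patch.mesh, flat_patch.tissues, spec)

    def test_existing_mesh_untouched_by_extrusion(self, flat_patch):
        mesh = flat_patch.mesh
        spec = mf.ElectrodeSpec(
            name="a", kind="surface", shape="disc", center_mm=(2.0, 2.0, 1.0),
            current_mA=0.1, radius_mm=0.6,
        )
        new_mesh, _, p = mf.place_surface_electrode(mesh, flat_patch.tissues, spec)
        np.testing.assert_array_equal(new_mesh.nodes[: mesh.n_nodes], mesh.nodes)
        np.testing.assert_array_equal(new_mesh.tet_label[: mesh.n_tets], mesh.tet_label)
        np.testing.assert_array_equal(new_mesh.tets[: mesh.n_tets], mesh.tets)
        assert p.label not in flat_patch.tissues  # input table not mutated

    def test_contact_surface_is_on_new_boundary(self, flat_patch):
        spec = mf.ElectrodeSpec(
            name="a", kind="surface", shape="disc", center_mm=(2.0, 2.0, 1.0),
            current_mA=0.1, radius_mm=0.6,
        )
        new_mesh, _, p = mf.place_surface_electrode(flat_patch.mesh, flat_patch.tissues, spec)
        index = mf.extract_boundary(new_mesh).face_index()
        for tri in np.sort(p.contact_tris, axis=1):
            assert tuple(tri) in index


class TestInsertElectrode:
    def test_relabeled_set_matches_centroid_oracle(self, slab10):
        spec = mf.ElectrodeSpec(
            name="screw", kind="insert", shape="disc", center_mm=(5.0, 5.0, 10.0),
            current_mA=0.1, radius_mm=1.5, depth_mm=4.0, axis=(0, 0, -1),
            conductivity_S_per_m=1e6,
        )
        new_mesh, tissues, p = mf.place_insert_electrode(slab10.mesh, slab10.tissues, spec)
        c = tet_geometry(slab10.mesh).centroids
        d = c - np.array([5.0, 5.0, 10.0])
        t = d @ np.array([0, 0, -1.0])
        radial2 = np.einsum("ij,ij->i", d, d) - t**2
        oracle = np.nonzero((t >= 0) & (t <= 4.0) & (radial2 <= 1.5**2))[0]
        np.testing.assert_array_equal(np.sort(p.source_tets), oracle)
        assert tissues[p.label].conductivity == 1e6
        assert new_mesh.n_nodes == slab10.mesh.n_nodes  # nothing added

    def test_region_outside_mesh_rejected(self, slab10):
        spec = mf.ElectrodeSpec(
            name="off", kind="insert", shape="disc", center_mm=(50.0, 50.0, 50.0),
            current_mA=0.1, radius_mm=1.0, depth_mm=2.0,
        )
        with pytest.raises(MontageError, match="no tets"):
            mf.place_insert_electrode(slab10.mesh, slab10.tissues, spec)

    def test_zero_radius_rejected_at_spec_validation(self):
        with pytest.raises(MontageError, match="radius"):
            mf.ElectrodeSpec(
                name="bad", kind="insert", shape="disc", center_mm=(0, 0, 0),
                current_mA=0.1, radius_mm=0.0, depth_mm=1.0,
            )


@pytest.fixture(scope="module")
def head_slab():
    """Brain under bone under skin, stacked along z."""
    return mf.make_slab(
        size_mm=(10.0, 10.0, 10.0), h_mm=1.0,
        layers=[
            mf.Layer("gray_matter", 0.275, 6.0),
            mf.Layer("bone", 0.01, 2.0),
            mf.Layer("soft_tissue", 0.465, 2.0),
        ],
    )


class TestCraniotomy:
    def spec(self, fill=2.5e-14):
        return mf.CraniotomySpec(
            shape="circular", center_mm=(5.0, 5.0, 10.0), radius_mm=2.0,
            axis=(0, 0, 1), fill_conductivity_S_per_m=fill,
        )

    def test_brain_never_relabeled(self, head_slab):
        new_mesh, _, rec = mf.carve_craniotomy(head_slab.mesh, head_slab.tissues, self.spec())
        brain = head_slab.label_of["gray_matter"]
        np.testing.assert_array_equal(
            new_mesh.tet_label == brain, head_slab.mesh.tet_label == brain
        )

    def test_relabeled_set_matches_exhaustive_oracle(self, head_slab):
        mesh = head_slab.mesh
        _, _, rec = mf.carve_craniotomy(mesh, head_slab.tissues, self.spec())
        c = tet_geometry(mesh).centroids
        in_col = (c[:, 0] - 5.0) ** 2 + (c[:, 1] - 5.0) ** 2 <= 4.0
        removable = np.isin(
            mesh.tet_label,
            [head_slab.label_of["bone"], head_slab.label_of["soft_tissue"]],
        )
        np.testing.assert_array_equal(np.sort(rec.relabeled_tets), np.nonzero(in_col & removable)[0])

    def test_dry_and_wet_fill_same_geometry_different_sigma(self, head_slab):
        m_dry, t_dry, r_dry = mf.carve_craniotomy(head_slab.mesh, head_slab.tissues, self.spec(2.5e-14))
        m_wet, t_wet, r_wet = mf.carve_craniotomy(head_slab.mesh, head_slab.tissues, self.spec(1.654))
        np.testing.assert_array_equal(r_dry.relabeled_tets, r_wet.relabeled_tets)
        assert t_dry[r_dry.label].conductivity == 2.5e-14
        assert t_wet[r_wet.label].conductivity == 1.654

    def test_second_application_is_geometric_noop(self, head_slab):
        m1, t1, r1 = mf.carve_craniotomy(head_slab.mesh, head_slab.tissues, self.spec())
        m2, t2, r2 = mf.carve_craniotomy(m1, t1, self.spec())
        assert len(r2.relabeled_tets) == 0
        np.testing.assert_array_equal(m2.tet_label, m1.tet_label)

    def test_footprint_missing_removable_tissue_rejected(self, head_slab):
        spec = mf.CraniotomySpec(
            shape="circular", center_mm=(50.0, 50.0, 0.0), radius_mm=1.0,
        )
        with pytest.raises(MontageError, match="no removable"):
            mf.carve_craniotomy(head_slab.mesh, head_slab.tissues, spec)


class TestPresets:
    @pytest.mark.parametrize(
        "name, n_electrodes, currents, has_cran",
        [
            ("1xBack", 2, [0.2, -0.2], False),
            ("1x4", 5, [0.2, -0.05, -0.05, -0.05, -0.05], False),
            ("4xBack_cran", 5, [0.05, 0.05, 0.05, 0.05, -0.2], True),
            ("1x1_cran", 2, [0.2, -0.2], True),
        ],
    )
    def test_preset_counts_shapes_and_currents(self, name, n_electrodes, currents, has_cran):
        m = mf.preset_montage(name, (0.0, 0.0, 5.0))
        m.validate()
        assert len(m.electrodes) == n_electrodes
        assert [e.current_mA for e in m.electrodes] == pytest.approx(currents)
        assert abs(sum(e.current_mA for e in m.electrodes)) < 1e-12
        assert (m.craniotomy is not None) == has_cran
        discs = [e for e in m.electrodes if e.shape == "disc"]
        for e in discs:
            assert e.radius_mm == 0.6 and e.thickness_mm == 1.0

    def test_back_electrode_is_large_pad(self):
        m = mf.preset_montage("1xBack", (0.0, 0.0, 5.0))
        back = m.electrodes[-1]
        assert back.shape == "cuboid" and back.width_mm == 15.0 and back.length_mm == 15.0

    def test_unknown_preset_rejected(self):
        with pytest.raises(MontageError, match="unknown preset"):
            mf.preset_montage("2x2", (0, 0, 0))

    def test_unbalanced_montage_rejected(self):
        e = mf.ElectrodeSpec(name="a", kind="surface", shape="disc",
                             center_mm=(0, 0, 0), current_mA=0.2, radius_mm=0.6)
        c = mf.ElectrodeSpec(name="b", kind="surface", shape="disc",
                             center_mm=(0, 0, 1), current_mA=-0.1, radius_mm=0.6)
        with pytest.raises(MontageError, match="sum"):
            mf.MontageSpec("bad", [e, c]).validate()

    def test_all_cathode_montage_rejected(self):
        c1 = mf.ElectrodeSpec(name="a", kind="surface", shape="disc",
                              center_mm=(0, 0, 0), current_mA=-0.1, radius_mm=0.6)
        c2 = mf.ElectrodeSpec(name="b", kind="surface", shape="disc",
                              center_mm=(0, 0, 1), current_mA=0.1, radius_mm=0.6)
        spec = mf.MontageSpec("ok", [c1, c2])
        spec.validate()  # balanced pair passes
        c2.current_mA = -0.1
        with pytest.raises(MontageError, match="anode"):
            mf.MontageSpec("bad", [c1, c2]).validate()
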