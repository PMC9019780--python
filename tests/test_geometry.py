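import numpy as np
import pytest

from lvmech.geometry import (GeometryError, LVGeometrySpec, build_lv_mesh,
                             label_aha17, transmural_coordinate,
                             truncated_ellipsoid_volume,
                             reference_cavity_volume)


def test_spherical_degenerate_volume_matches_closed_form(hemisphere_mesh,
                                                         hemisphere_spec):
    """Equal radii + uniform wall: cavity volume equals the truncated-sphere
    closed form within 1%."""
    analytic = truncated_ellipsoid_volume(hemisphere_spec.endo_short_radius,
                                          hemisphere_spec.endo_long_radius,
                                          hemisphere_spec.truncation_height)
    mesh_vol = reference_cavity_volume(hemisphere_mesh)
    assert abs(mesh_vol - analytic) / analytic < 0.01


def test_target_edv_reached(default_mesh):
    vol = reference_cavity_volume(default_mesh)
    assert 176.4 <= vol <= 183.6


def test_determinism_same_seed():
    spec = LVGeometrySpec(mesh_edge_length=14.0)
    m1 = build_lv_mesh(spec, seed=7)
    m2 = build_lv_mesh(spec, seed=7)
    assert m1.nodes.tobytes() == m2.nodes.tobytes()
    assert np.array_equal(m1.elements, m2.elements)


def test_refinement_changes_volume_below_half_percent():
    v_coarse = reference_cavity_volume(
        build_lv_mesh(LVGeometrySpec(mesh_edge_length=13.0), seed=0))
    v_fine = reference_cavity_volume(
        build_lv_mesh(LVGeometrySpec(mesh_edge_length=6.5), seed=0))
    assert abs(v_fine - v_coarse) / v_fine < 0.005


@pytest.mark.parametrize("field,value", [
    ("endo_long_radius", -1.0), ("wall_thickness_base", 0.0),
    ("truncation_height", 50.0),
])
def test_invalid_specs_raise(field, value):
    spec = LVGeometrySpec(**{field: value})
    with pytest.raises(GeometryError):
        spec.validate()


def test_infeasible_target_edv_names_constraint():
    spec = LVGeometrySpec(target_edv=2000.0)
    with pytest.raises(GeometryError, match="target_edv"):
        build_lv_mesh(spec, seed=0)


class TestAha17:
    def test_all_17_labels_present(self, default_mesh):
        assert set(np.unique(default_mesh.segment_label)) == set(range(1, 18))

    def test_labels_partition_elements(self, default_mesh):
        lab = default_mesh.segment_label
        assert lab.shape[0] == default_mesh.n_elements
        assert ((lab >= 1) & (lab <= 17)).all()

    def test_apex_tip_is_segment_17(self, default_mesh):
        cen = default_mesh.element_centroids()
        tip = int(np.argmin(cen[:, 2]))
        assert default_mesh.segment_label[tip] == 17

    def test_rotation_by_60_deg_permutes_basal_labels(self):
        """Brute-force relabel of the rotated mesh: basal sector labels shift
        cyclically by one."""
        mesh = build_lv_mesh(LVGeometrySpec(mesh_edge_length=14.0), seed=0)
        base = mesh.segment_label.copy()
        th = np.deg2rad(60.0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        mesh.nodes = mesh.nodes @ R.T
        rotated = label_aha17(mesh).segment_label
        basal = base <= 6
        expected = (base[basal] % 6) + 1
        assert np.array_equal(rotated[basal], expected)

    def test_missing_base_tag_raises(self, default_mesh):
        import copy
        m = copy.copy(default_mesh)
        m.surface_tags = {k: v for k, v in default_mesh.surface_tags.items()
                          if k != "base"}
        with pytest.raises(GeometryError):
            label_aha17(m)


class TestTransmural:
    def test_boundary_values(self, default_mesh):
        w = default_mesh.transmural_coord
        endo = np.unique(default_mesh.surface_tags["endocardium"].ravel())
        epi = np.unique(default_mesh.surface_tags["epicardium"].ravel())
        assert np.all(w[endo] == 0.0)
        assert np.all(w[epi] == 1.0)
        assert w.min() >= 0.0 and w.max() <= 1.0

    def test_concentric_spheres_midwall(self, hemisphere_mesh):
        """Wall radii 25 and 35 mm: nodes near r = 30 mm sit at depth 0.5."""
        w = transmural_coordinate(hemisphere_mesh)
        r = np.linalg.norm(hemisphere_mesh.nodes, axis=1)
        mid = np.abs(r - 30.0) < 0.3
        assert mid.any()
        assert np.all(np.abs(w[mid] - 0.5) < 0.05)

    def test_no_interior_local_extrema(self, default_mesh):
        """Discrete maximum principle: no strict interior extremum."""
        w = default_mesh.transmural_coord
        boundary = np.unique(np.concatenate(
            [v.ravel() for v in default_mesh.surface_tags.values()]))
        neighbors = {}
        for e in default_mesh.elements:
            for a in e:
                neighbors.setdefault(int(a), set()).update(int(b) for b in e)
        for n, nb in neighbors.items():
            if n in boundary:
                continue
            nb = nb - {n}
            vals = w[list(nb)]
            assert w[n] < vals.max() + 1e-12
            assert w[n] > vals.min() - 1e-12

    def test_untagged_surfaces_raise(self, default_mesh):
        import copy
        m = copy.copy(default_mesh)
        m.surface_tags = {}
        with pytest.raises(GeometryError):
            transmural_coordinate(m)
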