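"""Bifurcation outline construction, meshing, tagging and perturbation."""

import math

import numpy as np
import pytest

from vaoflow.geometry import (BifurcationSpec, GeometryError,
                              build_bifurcation, channel_mesh, generate_mesh,
                              measured_branch_angle, mesh_fingerprint,
                              perturb_geometry, tag_regions)

ANGLES = (30.0, 50.0, 70.0, 90.0, 110.0)


@pytest.fixture(scope="module", params=ANGLES)
def meshed(request):
    spec = BifurcationSpec(theta=request.param)
    outline = build_bifurcation(spec)
    return spec, outline, generate_mesh(outline, 0.55)


class TestOutline:
    def test_realised_angle_within_half_degree(self, meshed):
        spec, outline, _ = meshed
        assert measured_branch_angle(outline) == pytest.approx(spec.theta,
                                                               abs=0.5)

    def test_perpendicular_branch_at_90(self):
        spec = BifurcationSpec(theta=90.0)
        assert abs(spec.branch_dir @ np.array([1.0, 0.0])) < 1e-12

    def test_branch_centerline_length(self, meshed):
        spec, outline, _ = meshed
        # centerline from ostium centre to the outlet cap centre
        mid_out = 0.5 * (outline.segment("va_outlet")[0]
                         + outline.segment("va_outlet")[-1])
        length = np.linalg.norm(mid_out - spec.junction_center)
        assert length == pytest.approx(40.0, abs=2 * spec.fillet_radius)

    def test_invalid_specs_rejected(self):
        with pytest.raises(GeometryError):
            BifurcationSpec(theta=0.0)
        with pytest.raises(GeometryError):
            BifurcationSpec(d_va=9.0)  # wider than the SCA
        with pytest.raises(GeometryError):
            BifurcationSpec(l_vao=-1.0)

    def test_oversized_fillet_names_conflict(self):
        with pytest.raises(GeometryError):
            build_bifurcation(BifurcationSpec(theta=30.0, fillet_radius=25.0))


class TestMesh:
    def test_all_positive_areas_and_quality_floor(self, meshed):
        _, _, mesh = meshed
        assert np.all(mesh.triangle_areas() > 0)
        assert mesh.quality().min() > 0.02

    def test_boundary_fully_tagged(self, meshed):
        _, _, mesh = meshed
        allowed = {"inlet", "sca_outlet", "va_outlet", "wall_medial",
                   "wall_lateral", "wall_other"}
        assert set(mesh.edge_tags) <= allowed
        for tag in ("inlet", "sca_outlet", "va_outlet", "wall_medial",
                    "wall_lateral"):
            assert np.sum(mesh.edge_tags == tag) > 0

    def test_refinement_increases_element_count(self):
        outline = build_bifurcation(BifurcationSpec(theta=70.0))
        n_coarse = len(generate_mesh(outline, 1.0).triangles)
        n_fine = len(generate_mesh(outline, 0.5).triangles)
        assert n_fine >= 2 * n_coarse

    def test_rejects_nonpositive_h(self):
        outline = build_bifurcation(BifurcationSpec(theta=70.0))
        with pytest.raises(ValueError):
            generate_mesh(outline, 0.0)

    def test_channel_mesh_tags(self):
        m = channel_mesh(8.4, 25.2, 0.6)
        assert np.all(m.triangle_areas() > 0)
        assert {"inlet", "sca_outlet", "wall_other"} == set(m.edge_tags)

    def test_deterministic_fingerprint(self):
        outline = build_bifurcation(BifurcationSpec(theta=50.0))
        m1 = generate_mesh(outline, 0.7)
        m2 = generate_mesh(outline, 0.7)
        assert mesh_fingerprint(m1) == mesh_fingerprint(m2)


class TestRegionTags:
    def test_medial_lateral_partition_branch_walls(self, meshed):
        spec, _, mesh = meshed
        med = mesh.edge_tags == "wall_medial"
        lat = mesh.edge_tags == "wall_lateral"
        # every VAO wall facet (above the SCA wall) is medial or lateral
        mids = mesh.edge_midpoints()
        wall = np.array([t.startswith("wall") for t in mesh.edge_tags])
        above = wall & (mids[:, 1] > spec.d_sca + 1e-9)
        assert np.all(med[above] | lat[above])
        assert not np.any(med & lat)

    def test_arclength_monotone_from_ostium(self, meshed):
        _, _, mesh = meshed
        for tag in ("wall_medial", "wall_lateral"):
            sel = mesh.edge_tags == tag
            al = mesh.edge_arclength[sel]
            assert np.all(np.isfinite(al))
            assert al.min() < 1.0  # starts at the ostium
            assert al.max() > 30.0  # spans most of the 40 mm branch

    def test_arc_length_difference_bound(self, meshed):
        spec, _, mesh = meshed
        lengths = mesh.edge_lengths()
        l_med = lengths[mesh.edge_tags == "wall_medial"].sum()
        l_lat = lengths[mesh.edge_tags == "wall_lateral"].sum()
        th = math.radians(spec.theta)
        bound = spec.d_va * abs(math.cos(th) / math.sin(th)) \
            + 2 * spec.fillet_radius + 2 * 0.55
        assert abs(l_med - l_lat) <= bound

    def test_mirror_symmetry_at_90(self):
        spec = BifurcationSpec(theta=90.0)
        mesh = generate_mesh(build_bifurcation(spec), 0.55)
        cx = spec.junction_center[0]
        med = np.sort(mesh.edge_arclength[mesh.edge_tags == "wall_medial"])
        lat = np.sort(mesh.edge_arclength[mesh.edge_tags == "wall_lateral"])
        assert np.allclose(med, lat, atol=0.55)
        # medial wall x-positions mirror lateral across the VA centerline
        mids = mesh.edge_midpoints()
        xm = np.sort(mids[mesh.edge_tags == "wall_medial", 0] - cx)
        xl = np.sort(cx - mids[mesh.edge_tags == "wall_lateral", 0])
        assert np.allclose(np.sort(xm), np.sort(xl), atol=0.55)

    def test_retagging_is_idempotent(self, meshed):
        spec, _, mesh = meshed
        before = mesh.edge_tags.copy()
        tag_regions(mesh, spec)
        assert np.array_equal(before, mesh.edge_tags)


class TestPerturbation:
    def test_zero_amplitude_is_identity(self):
        spec = BifurcationSpec(theta=70.0)
        o0 = perturb_geometry(spec, 0.0, 99)
        ob = build_bifurcation(spec)
        for (t0, p0), (t1, p1) in zip(o0.segments, ob.segments):
            assert t0 == t1
            assert np.array_equal(p0, p1)

    def test_deterministic_given_seed(self):
        spec = BifurcationSpec(theta=70.0)
        a = perturb_geometry(spec, 0.15, 7)
        b = perturb_geometry(spec, 0.15, 7)
        for (_, pa), (_, pb) in zip(a.segments, b.segments):
            assert np.array_equal(pa, pb)

    @pytest.mark.parametrize("seed", range(12))
    def test_angle_preserved_within_5_degrees(self, seed):
        spec = BifurcationSpec(theta=70.0)
        outline = perturb_geometry(spec, 0.1, seed)
        assert measured_branch_angle(outline) == pytest.approx(70.0, abs=5.0)

    def test_perturbed_mesh_still_valid(self):
        spec = BifurcationSpec(theta=70.0)
        mesh = generate_mesh(perturb_geometry(spec, 0.2, 3), 0.55)
        assert np.all(mesh.triangle_areas() > 0)
        assert {"wall_medial", "wall_lateral"} <= set(mesh.edge_tags)

    def test_amplitude_out_of_range(self):
        with pytest.raises(ValueError):
            perturb_geometry(BifurcationSpec(theta=70.0), 0.5, 0)
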