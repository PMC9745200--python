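"""Surface construction: lofting, capping, branch grafting, smoothing,
remeshing, validation.

Topology note: the boundary surface of a thick-walled tube (annulus x
interval) is a genus-1 closed manifold, so its Euler characteristic is 0;
one grafted branch adds a handle (chi = -2).
"""

import numpy as np
import pytest
import trimesh

from ivus2fe.centerline import compute_frames, place_contours
from ivus2fe.surface_mesh import (FaceTag, SurfaceMesh, build_branch, cap_ends,
                                  hc_smooth, laplacian_smooth, loft_tube,
                                  remesh_isotropic, validate_surface)
from ivus2fe.vh_image import build_contour_set


def cylinder_contours(n_frames=8, n_pts=72, r_in=1.5, r_out=2.5, spacing=0.5):
    """OrientedContours of a perfect straight cylinder (analytic)."""
    from ivus2fe.centerline import OrientedContours

    ang = np.arange(n_pts) * (2 * np.pi / n_pts)
    ring_in = np.column_stack([r_in * np.cos(ang), r_in * np.sin(ang)])
    ring_out = np.column_stack([r_out * np.cos(ang), r_out * np.sin(ang)])
    lum = np.empty((n_frames, n_pts, 3))
    out = np.empty((n_frames, n_pts, 3))
    for i in range(n_frames):
        z = spacing * i
        lum[i] = np.column_stack([ring_in, np.full(n_pts, z)])
        out[i] = np.column_stack([ring_out, np.full(n_pts, z)])
    return OrientedContours(
        lumen=lum, outer=out, branch_mask=np.zeros((n_frames, n_pts), dtype=bool),
        stations=spacing * np.arange(n_frames),
        centers=np.column_stack([np.zeros(n_frames), np.zeros(n_frames),
                                 spacing * np.arange(n_frames)]))


class TestLoft:
    def test_band_triangle_count(self):
        oc = cylinder_contours(n_frames=2)
        tube = loft_tube(oc)
        # 2n triangles per band; one lumen + one outer band
        assert (tube.tags == FaceTag.LUMEN).sum() == 144
        assert (tube.tags == FaceTag.OUTER).sum() == 144

    def test_capped_cylinder_volume_matches_closed_form(self):
        oc = cylinder_contours(n_frames=8)
        tube = cap_ends(loft_tube(oc))
        exact = np.pi * (2.5**2 - 1.5**2) * 3.5
        assert tube.enclosed_volume() == pytest.approx(exact, rel=0.02)

    def test_phantom_tube_watertight_after_capping(self, capped_tube):
        assert capped_tube.is_watertight
        assert capped_tube.is_oriented
        assert capped_tube.enclosed_volume() > 0

    def test_capped_tube_is_genus_one(self, capped_tube):
        assert capped_tube.euler_characteristic == 0
        assert capped_tube.genus == 1

    def test_cap_triangle_counts(self):
        oc = cylinder_contours(n_frames=3, n_pts=40)
        tube = cap_ends(loft_tube(oc))
        assert (tube.tags == FaceTag.CAP_PROXIMAL).sum() == 2 * 40
        assert (tube.tags == FaceTag.CAP_DISTAL).sum() == 2 * 40

    def test_capping_closed_mesh_rejected(self, capped_tube):
        with pytest.raises(ValueError, match="closed"):
            cap_ends(capped_tube)


class TestBranch:
    def test_no_flags_is_noop(self, capped_tube):
        out = build_branch(capped_tube)
        assert np.array_equal(out.faces, capped_tube.faces)

    def test_branch_topology_and_tags(self, branch_surface):
        assert branch_surface.is_watertight
        assert branch_surface.is_oriented
        assert branch_surface.euler_characteristic == -2
        assert branch_surface.genus == 2
        assert (branch_surface.tags == FaceTag.BRANCH_CAP).any()
        assert (branch_surface.tags == FaceTag.BRANCH_WALL).any()
        assert branch_surface.enclosed_volume() > 0

    def test_branch_cap_is_single_planar_annulus(self, branch_surface):
        cap = branch_surface.faces[branch_surface.tags == FaceTag.BRANCH_CAP]
        pts = branch_surface.vertices[np.unique(cap)]
        # all cap vertices coplanar
        c = pts.mean(axis=0)
        _, s, vh = np.linalg.svd(pts - c)
        assert s[2] < 1e-6 * s[0]

    def test_branch_points_outward(self, phantom_branch, frames_branch):
        """The branch cap centroid lies radially outside the outer wall."""
        from ivus2fe.centerline import load_centerline

        _, stack = phantom_branch
        cs = build_contour_set(frames_branch)
        c = compute_frames(load_centerline(stack.centerline_csv))
        oc = place_contours(cs, c, px_scale=0.02)
        tube = cap_ends(loft_tube(oc))
        br = build_branch(tube)
        cap = br.faces[br.tags == FaceTag.BRANCH_CAP]
        cap_c = br.vertices[np.unique(cap)].mean(axis=0)
        # distance from the centerline exceeds the max outer radius
        d = np.linalg.norm(c.points - cap_c, axis=1).min()
        max_outer = 0.02 * max(np.linalg.norm(e.outer_ring(), axis=1).max()
                               for e in cs.entries)
        assert d > max_outer


class TestSmoothing:
    def test_zero_iterations_identity(self, capped_tube):
        out = hc_smooth(capped_tube, iterations=0)
        assert np.array_equal(out.vertices, capped_tube.vertices)

    def test_hc_preserves_volume_where_laplacian_shrinks(self):
        sphere = trimesh.creation.icosphere(3)
        m = SurfaceMesh(sphere.vertices.copy(), sphere.faces.copy(),
                        np.ones(len(sphere.faces), dtype=np.int8))
        v0 = m.enclosed_volume()
        hc = hc_smooth(m, iterations=20)
        lap = laplacian_smooth(m, iterations=20)
        hc_loss = abs(1 - hc.enclosed_volume() / v0)
        lap_loss = abs(1 - lap.enclosed_volume() / v0)
        assert hc_loss < 0.02
        assert lap_loss > 0.10

    def test_hc_deviation_bounded_by_laplacian(self, capped_tube):
        hc = hc_smooth(capped_tube, iterations=10, preserve_features=False)
        lap = laplacian_smooth(capped_tube, iterations=10)
        d_hc = np.linalg.norm(hc.vertices - capped_tube.vertices, axis=1).max()
        d_lap = np.linalg.norm(lap.vertices - capped_tube.vertices, axis=1).max()
        assert d_hc <= d_lap

    def test_connectivity_unchanged(self, capped_tube):
        out = hc_smooth(capped_tube, iterations=5)
        assert np.array_equal(out.faces, capped_tube.faces)
        assert np.array_equal(out.tags, capped_tube.tags)

    def test_invalid_weights_rejected(self, capped_tube):
        with pytest.raises(ValueError):
            hc_smooth(capped_tube, alpha=1.5)


@pytest.fixture(scope="module")
def remeshed(capped_tube):
    return remesh_isotropic(hc_smooth(capped_tube), 0.2)


class TestRemesh:
    def test_mean_edge_hits_target(self, remeshed):
        el = remeshed.edge_lengths()
        assert 0.18 <= el.mean() <= 0.22
        assert el.std() / el.mean() < 0.25

    def test_topology_and_volume_preserved(self, capped_tube, remeshed):
        assert remeshed.is_watertight
        assert remeshed.is_oriented
        assert remeshed.euler_characteristic == capped_tube.euler_characteristic
        assert remeshed.enclosed_volume() == pytest.approx(
            capped_tube.enclosed_volume(), rel=0.02)

    def test_near_idempotence(self, remeshed):
        again = remesh_isotropic(remeshed, 0.2, max_iters=3)
        assert again.edge_lengths().mean() == pytest.approx(
            remeshed.edge_lengths().mean(), rel=0.05)

    def test_every_face_keeps_exactly_one_tag(self, remeshed):
        assert len(remeshed.tags) == len(remeshed.faces)
        assert set(np.unique(remeshed.tags)) <= {int(t) for t in FaceTag}

    def test_unresolvable_wall_rejected(self, capped_tube):
        with pytest.raises(ValueError, match="wall"):
            remesh_isotropic(capped_tube, 2.0)


class TestValidate:
    def test_closed_tube_reported_healthy(self, capped_tube):
        rep = validate_surface(capped_tube)
        assert rep.watertight and rep.oriented
        assert rep.n_boundary_edges == 0

    def test_deleted_face_reported(self, capped_tube):
        broken = capped_tube.copy()
        broken.faces = broken.faces[1:]
        broken.tags = broken.tags[1:]
        rep = validate_surface(broken)
        assert not rep.watertight
        assert rep.n_boundary_edges == 3

    def test_inverted_patch_flagged(self, capped_tube):
        bad = capped_tube.copy()
        bad.faces[7] = bad.faces[7][::-1]
        rep = validate_surface(bad)
        assert not rep.oriented
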