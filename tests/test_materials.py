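"""Material table, pixel cloud placement, sectioned nearest-neighbor
assignment and its brute-force equivalence."""

import numpy as np
import pytest

from ivus2fe.labels import Tissue
from ivus2fe.materials import (Material, PixelCloud, assign_materials,
                               build_pixel_cloud, build_sections,
                               material_table)
from ivus2fe.volume_mesh import TetMesh


def brute_force_nearest(centroids: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Exhaustive O(N*M) nearest-neighbor (lowest index wins ties)."""
    out = np.empty(len(centroids), dtype=np.int64)
    for i, c in enumerate(centroids):
        d2 = np.einsum("mj,mj->m", points - c, points - c)
        out[i] = int(np.argmin(d2))  # argmin returns the first (lowest) index
    return out


def tiny_mesh(centroid_targets: np.ndarray) -> TetMesh:
    """One small tet per requested centroid."""
    nodes, elements = [], []
    offs = np.array([[0, 0, 0], [0.01, 0, 0], [0, 0.01, 0], [0, 0, 0.01]])
    for k, c in enumerate(centroid_targets):
        base = c - offs.mean(axis=0)
        nodes.extend(base + offs)
        elements.append([4 * k, 4 * k + 1, 4 * k + 2, 4 * k + 3])
    return TetMesh(nodes=np.array(nodes), elements=np.array(elements))


def cloud_from_points(points, labels, stations=None) -> PixelCloud:
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    stations = np.zeros(len(points)) if stations is None else np.asarray(stations)
    zmax = max(1.0, float(stations.max())) if len(stations) else 1.0
    cl = np.column_stack([np.zeros(2), np.zeros(2), [0.0, zmax]])
    return PixelCloud(points=points, labels=np.asarray(labels, dtype=np.int16),
                      stations=stations, centerline_points=cl,
                      centerline_stations=cl[:, 2])


class TestMaterialTable:
    def test_defaults_are_the_published_linear_elastic_values(self):
        t = material_table()
        assert t[Tissue.WALL].youngs_modulus_mpa == 0.3
        assert t[Tissue.FIBROUS].youngs_modulus_mpa == 0.6
        assert t[Tissue.FIBROFATTY].youngs_modulus_mpa == 0.5
        assert t[Tissue.CALCIUM].youngs_modulus_mpa == 10.0
        assert t[Tissue.NECROTIC].youngs_modulus_mpa == 0.02
        assert t[Tissue.SLEEVE].youngs_modulus_mpa == 0.4
        for lbl in t.labels():
            assert t[lbl].poisson_ratio == 0.48

    def test_override_changes_only_target(self):
        t = material_table({"sleeve": {"youngs_modulus_mpa": 0.3}})
        assert t[Tissue.SLEEVE].youngs_modulus_mpa == 0.3
        assert t[Tissue.WALL].youngs_modulus_mpa == 0.3
        assert t[Tissue.CALCIUM].youngs_modulus_mpa == 10.0

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ValueError, match="0.5"):
            Material("bad", 1.0, poisson_ratio=0.5)

    def test_kpa_conversion(self):
        t = material_table()
        assert t.youngs_kpa(np.array([int(Tissue.CALCIUM)]))[0] == 10000.0


class TestPixelCloud:
    def test_cloud_count_equals_truth_tissue_pixels(self, frames_small,
                                                    centerline_small,
                                                    phantom_small):
        _, stack = phantom_small
        cloud = build_pixel_cloud(frames_small, centerline_small)
        # frames include the sleeve; recount from the classified frames
        expected = sum(int(f.tissue_mask.sum()) for f in frames_small)
        assert len(cloud) == expected

    def test_straight_mode_pixels_share_axial_coordinate(self, frames_small,
                                                         centerline_small):
        cloud = build_pixel_cloud(frames_small, centerline_small, straight=True)
        for s in np.unique(cloud.stations)[:3]:
            sel = cloud.stations == s
            assert np.allclose(cloud.points[sel, 2], s, atol=1e-12)

    def test_labels_subset_of_frame_labels(self, frames_small, centerline_small):
        cloud = build_pixel_cloud(frames_small, centerline_small)
        frame_labels = set()
        for f in frames_small:
            frame_labels |= set(np.unique(f.labels))
        assert set(np.unique(cloud.labels)) <= frame_labels - {0}


class TestSections:
    def test_two_sections_with_shared_overlap_zone(self):
        pts = np.column_stack([np.zeros(100), np.zeros(100), np.linspace(0, 10, 100)])
        cloud = cloud_from_points(pts, np.ones(100), stations=pts[:, 2])
        idx = build_sections(cloud, section_length=5.0, overlap=1.0)
        assert idx.n_sections == 2
        at_4_5 = np.flatnonzero(np.abs(cloud.stations - 4.5) < 0.05)
        for s in range(2):
            assert np.isin(at_4_5, idx.point_indices[s]).all()

    def test_every_point_in_at_least_one_section(self):
        rng = np.random.default_rng(1)
        st = rng.uniform(0, 17, 500)
        pts = np.column_stack([np.zeros(500), np.zeros(500), st])
        cloud = cloud_from_points(pts, np.ones(500), stations=st)
        idx = build_sections(cloud, 5.0, 1.0)
        covered = np.zeros(500, dtype=bool)
        for lst in idx.point_indices:
            covered[lst] = True
        assert covered.all()

    def test_overlap_must_be_smaller_than_section(self):
        cloud = cloud_from_points([[0, 0, 0], [0, 0, 5]], [1, 1], stations=[0, 5])
        with pytest.raises(ValueError):
            build_sections(cloud, 1.0, 2.0)


class TestAssignment:
    def test_single_pixel_single_element(self):
        mesh = tiny_mesh(np.array([[0.0, 0.0, 0.5]]))
        cloud = cloud_from_points([[1, 1, 1]], [Tissue.CALCIUM])
        assign_materials(mesh, cloud, None, far_cutoff=10.0)
        assert mesh.material[0] == Tissue.CALCIUM

    def test_exact_tie_resolves_to_lowest_pixel_index(self):
        mesh = tiny_mesh(np.array([[0.0, 0.0, 0.0]]))
        cloud = cloud_from_points([[1, 0, 0], [-1, 0, 0]],
                                  [Tissue.NECROTIC, Tissue.CALCIUM])
        assign_materials(mesh, cloud, None, far_cutoff=10.0)
        assert mesh.material[0] == Tissue.NECROTIC

    def test_far_centroid_falls_back_to_sleeve(self):
        mesh = tiny_mesh(np.array([[50.0, 0, 0]]))
        cloud = cloud_from_points([[0, 0, 0]], [Tissue.WALL])
        summary = assign_materials(mesh, cloud, None, far_cutoff=1.0)
        assert mesh.material[0] == Tissue.SLEEVE
        assert summary.n_far == 1

    def test_empty_cloud_rejected(self):
        mesh = tiny_mesh(np.array([[0.0, 0, 0]]))
        cloud = cloud_from_points(np.zeros((0, 3)), [])
        with pytest.raises(ValueError):
            assign_materials(mesh, cloud, None)

    def test_sectioned_equals_brute_force_on_random_cloud(self, rng):
        """Sectioned + escalation must agree with the exhaustive O(N*M)
        oracle on every element, not just most."""
        n_pix = 4000
        st = rng.uniform(0, 12, n_pix)
        pts = np.column_stack([rng.normal(0, 1.5, n_pix), rng.normal(0, 1.5, n_pix), st])
        labels = rng.choice([1, 2, 3, 4, 5], n_pix).astype(np.int16)
        cl = np.column_stack([np.zeros(25), np.zeros(25), np.linspace(0, 12, 25)])
        cloud = PixelCloud(points=pts, labels=labels, stations=st,
                           centerline_points=cl, centerline_stations=cl[:, 2])
        cents = np.column_stack([rng.normal(0, 1.2, 300), rng.normal(0, 1.2, 300),
                                 rng.uniform(0, 12, 300)])
        mesh = tiny_mesh(cents)
        idx = build_sections(cloud, section_length=3.0, overlap=0.7)
        assign_materials(mesh, cloud, idx, far_cutoff=50.0)
        expected = labels[brute_force_nearest(mesh.centroids(), pts)]
        assert np.array_equal(mesh.material, expected)

    def test_pixel_order_permutation_only_affects_exact_ties(self, rng):
        n_pix = 1000
        st = rng.uniform(0, 6, n_pix)
        pts = np.column_stack([rng.normal(0, 1, n_pix), rng.normal(0, 1, n_pix), st])
        labels = rng.choice([1, 4, 5], n_pix).astype(np.int16)
        cl = np.column_stack([np.zeros(10), np.zeros(10), np.linspace(0, 6, 10)])
        cents = np.column_stack([rng.normal(0, 1, 80), rng.normal(0, 1, 80),
                                 rng.uniform(0, 6, 80)])
        perm = rng.permutation(n_pix)
        results = []
        for order in (np.arange(n_pix), perm):
            cloud = PixelCloud(points=pts[order], labels=labels[order],
                               stations=st[order], centerline_points=cl,
                               centerline_stations=cl[:, 2])
            mesh = tiny_mesh(cents)
            assign_materials(mesh, cloud, build_sections(cloud, 3.0, 0.7),
                             far_cutoff=50.0)
            results.append(mesh.material.copy())
        assert np.array_equal(results[0], results[1])
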