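"""Image processing: classification, island removal, sleeve, contours,
branch-gap detection."""

import numpy as np
import pytest
from scipy import ndimage

from ivus2fe.labels import Tissue
from ivus2fe.phantom import Branch, PhantomSpec, generate_vh_stack
from ivus2fe.vh_image import (ColorMap, VHFrame, add_sleeve,
                              classify_pixels, detect_branch_gaps,
                              extract_contours, remove_islands)


def annulus_frame(size=200, r_in=40, r_out=60, label=Tissue.WALL) -> VHFrame:
    c = (size - 1) / 2
    yy, xx = np.indices((size, size))
    r = np.hypot(xx - c, yy - c)
    labels = np.where((r >= r_in) & (r < r_out), int(label), 0).astype(np.int16)
    return VHFrame(labels, px_scale=0.02)


class TestClassify:
    def test_reference_colors_map_to_their_labels(self):
        img = np.zeros((2, 3, 3), dtype=np.uint8)
        img[0, 0] = (255, 255, 255)   # calcium
        img[0, 1] = (0, 0, 0)         # background
        img[0, 2] = (255, 0, 0)       # necrotic
        img[1, 0] = (128, 128, 128)   # wall
        img[1, 1] = (0, 128, 0)       # fibrotic
        img[1, 2] = (144, 238, 144)   # fibrofatty
        f = classify_pixels(img)
        assert f.labels[0, 0] == Tissue.CALCIUM
        assert f.labels[0, 1] == Tissue.BACKGROUND
        assert f.labels[0, 2] == Tissue.NECROTIC
        assert f.labels[1, 0] == Tissue.WALL
        assert f.labels[1, 1] == Tissue.FIBROUS
        assert f.labels[1, 2] == Tissue.FIBROFATTY

    def test_pixels_beyond_tolerance_become_background(self):
        img = np.full((1, 1, 3), (60, 60, 60), dtype=np.uint8)  # far from all refs
        assert classify_pixels(img).labels[0, 0] == Tissue.BACKGROUND

    def test_noisy_colors_snap_to_nearest_reference(self):
        img = np.full((1, 1, 3), (245, 250, 248), dtype=np.uint8)
        assert classify_pixels(img).labels[0, 0] == Tissue.CALCIUM

    def test_non_rgb_input_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            classify_pixels(np.zeros((4, 4), dtype=np.uint8))

    def test_phantom_roundtrip_counts_equal_truth(self, phantom_small):
        _, stack = phantom_small
        for i, img in enumerate(stack.images):
            f = classify_pixels(img)
            counts = np.bincount(f.labels.ravel(), minlength=len(Tissue))
            assert np.array_equal(counts, stack.truth.pixel_counts[i])

    def test_duplicate_reference_colors_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            ColorMap(entries={1: ("a", (1, 2, 3)), 2: ("b", (1, 2, 3))})


class TestRemoveIslands:
    def test_clean_frame_unchanged(self):
        f = annulus_frame()
        out = remove_islands(f, min_area=20)
        assert np.array_equal(out.labels, f.labels)

    def test_small_island_removed_to_surrounding_label(self):
        f = annulus_frame()
        f.labels[10:12, 10:11] = Tissue.CALCIUM  # 2 px island in background
        out = remove_islands(f, min_area=5)
        assert (out.labels[:20, :20] == Tissue.BACKGROUND).all()
        # independent connected-component check: no tiny components remain
        for lbl in np.unique(out.labels):
            if lbl == 0:
                continue
            comp, n = ndimage.label(out.labels == lbl, structure=np.ones((3, 3)))
            assert np.bincount(comp.ravel())[1:].min() >= 5

    def test_island_inside_wall_takes_wall_label(self):
        f = annulus_frame()
        f.labels[100 - 50, 100] = Tissue.NECROTIC  # 1 px inside the wall band
        out = remove_islands(f, min_area=5)
        assert out.labels[100 - 50, 100] == Tissue.WALL

    def test_zero_min_area_is_identity(self):
        f = annulus_frame()
        f.labels[0, 0] = Tissue.CALCIUM
        out = remove_islands(f, min_area=0)
        assert np.array_equal(out.labels, f.labels)

    def test_negative_min_area_rejected(self):
        with pytest.raises(ValueError):
            remove_islands(annulus_frame(), min_area=-1)

    def test_no_new_labels_introduced(self, phantom_small):
        _, stack = phantom_small
        f = classify_pixels(stack.images[5])
        out = remove_islands(f, min_area=50)
        assert set(np.unique(out.labels)) <= set(np.unique(f.labels))


class TestSleeve:
    def test_dilation_radius_from_thickness_and_scale(self):
        # 0.2 mm at 0.02 mm/px -> 10 px
        f = annulus_frame(r_out=60)
        out = add_sleeve(f, 0.2)
        c = (f.labels.shape[0] - 1) / 2
        yy, xx = np.indices(f.labels.shape)
        r = np.hypot(xx - c, yy - c)
        sleeve_r = r[out.labels == Tissue.SLEEVE]
        assert sleeve_r.max() == pytest.approx(70, abs=1.5)
        assert sleeve_r.min() >= 59.0  # no sleeve inside the lumen

    def test_zero_thickness_identity(self):
        f = annulus_frame()
        out = add_sleeve(f, 0.0)
        assert np.array_equal(out.labels, f.labels)

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError):
            add_sleeve(annulus_frame(), -0.1)

    def test_tissue_labels_never_overwritten(self):
        f = annulus_frame()
        out = add_sleeve(f, 0.2)
        tissue = f.labels > 0
        assert np.array_equal(out.labels[tissue], f.labels[tissue])

    def test_sleeve_pixel_count_monotone_in_thickness(self):
        f = annulus_frame()
        counts = [
            (add_sleeve(f, t).labels == Tissue.SLEEVE).sum()
            for t in (0.0, 0.1, 0.2, 0.3)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert counts[-1] > counts[0]


class TestContours:
    def test_circle_radii_recovered(self):
        f = annulus_frame(r_in=40, r_out=60)
        e = extract_contours(add_sleeve(f, 0.0))
        lum_r = np.linalg.norm(e.lumen_ring(), axis=1)
        out_r = np.linalg.norm(e.outer_ring(), axis=1)
        assert np.allclose(lum_r, 40, atol=1.0)
        assert np.allclose(out_r, 59.5, atol=1.0)

    def test_polylines_closed_and_ccw(self):
        e = extract_contours(annulus_frame())
        assert np.array_equal(e.lumen[0], e.lumen[-1])
        assert np.array_equal(e.outer[0], e.outer[-1])
        # shoelace area positive = counter-clockwise
        for poly in (e.lumen[:-1], e.outer[:-1]):
            x, y = poly[:, 0], poly[:, 1]
            area = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
            assert area > 0

    def test_lumen_strictly_inside_outer(self, frames_small):
        for f in frames_small:
            e = extract_contours(f)
            lum_r = np.linalg.norm(e.lumen_ring(), axis=1)
            out_r = np.linalg.norm(e.outer_ring(), axis=1)
            assert (lum_r < out_r).all()

    def test_rotation_equivariance(self, phantom_small):
        _, stack = phantom_small
        f = classify_pixels(stack.images[3])
        e = extract_contours(f)
        rot = VHFrame(np.rot90(f.labels).copy(), px_scale=f.px_scale)
        e_rot = extract_contours(rot)
        # np.rot90 rotates +90 deg (CCW in x-right/y-up coords): contour
        # at angle k maps to angle k + 90 deg
        n = e.n_points
        shift = n // 4
        r_orig = np.linalg.norm(e.lumen_ring(), axis=1)
        r_rot = np.linalg.norm(e_rot.lumen_ring(), axis=1)
        assert np.allclose(np.roll(r_orig, shift), r_rot, atol=1.0)

    def test_empty_frame_rejected(self):
        f = VHFrame(np.zeros((50, 50), dtype=np.int16), px_scale=0.02)
        with pytest.raises(ValueError):
            extract_contours(f)


class TestBranchGaps:
    def test_intact_annulus_has_no_gap(self):
        assert detect_branch_gaps(annulus_frame()) == []

    def test_phantom_gap_span_recovered(self):
        spec = PhantomSpec(n_frames=4, image_size=250, lumen_radius=1.2,
                           wall_thickness=0.8,
                           branch=Branch(frames=(1, 2), center_deg=90.0, span_deg=40.0))
        stack = generate_vh_stack(spec)
        f = classify_pixels(stack.images[1])
        gaps = detect_branch_gaps(f)
        assert len(gaps) == 1
        a0, a1 = gaps[0]
        span = (a1 - a0) % 360.0
        assert span == pytest.approx(40.0, abs=2.0)
        mid = (a0 + span / 2.0) % 360.0
        assert mid == pytest.approx(90.0, abs=2.0)

    def test_two_disjoint_gaps_found_separately(self):
        f = annulus_frame()
        c = (f.labels.shape[0] - 1) / 2
        yy, xx = np.indices(f.labels.shape)
        theta = np.degrees(np.arctan2(c - yy, xx - c)) % 360.0
        f.labels[(theta >= 10) & (theta < 50)] = 0
        f.labels[(theta >= 180) & (theta < 230)] = 0
        gaps = detect_branch_gaps(f)
        assert len(gaps) == 2
        spans = sorted(((a1 - a0) % 360.0) for a0, a1 in gaps)
        assert spans[0] == pytest.approx(40.0, abs=3.0)
        assert spans[1] == pytest.approx(50.0, abs=3.0)
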