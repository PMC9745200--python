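"""Shared fixtures: small phantoms and their processed stages.

Session-scoped so the expensive reconstruction stages are built once and
shared across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest

from ivus2fe.centerline import compute_frames, load_centerline, place_contours
from ivus2fe.phantom import default_phantom, generate_vh_stack
from ivus2fe.surface_mesh import cap_ends, loft_tube
from ivus2fe.vh_image import add_sleeve, build_contour_set, classify_pixels


@pytest.fixture(scope="session")
def phantom_small():
    """12-frame curved phantom without a branch, with its stack."""
    spec = default_phantom(n_frames=12, image_size=300, seed=0)
    return spec, generate_vh_stack(spec)


@pytest.fixture(scope="session")
def phantom_branch():
    spec = default_phantom(n_frames=12, image_size=300, seed=0, branch=True)
    return spec, generate_vh_stack(spec)


@pytest.fixture(scope="session")
def frames_small(phantom_small):
    _, stack = phantom_small
    return [add_sleeve(classify_pixels(img, frame_index=i), 0.2)
            for i, img in enumerate(stack.images)]


@pytest.fixture(scope="session")
def frames_branch(phantom_branch):
    _, stack = phantom_branch
    return [add_sleeve(classify_pixels(img, frame_index=i), 0.2)
            for i, img in enumerate(stack.images)]


@pytest.fixture(scope="session")
def centerline_small(phantom_small):
    _, stack = phantom_small
    return compute_frames(load_centerline(stack.centerline_csv))


@pytest.fixture(scope="session")
def oriented_contours_small(frames_small, centerline_small):
    cs = build_contour_set(frames_small)
    return place_contours(cs, centerline_small, px_scale=0.02)


@pytest.fixture(scope="session")
def capped_tube(oriented_contours_small):
    """Closed first-pass surface of the unbranched phantom."""
    return cap_ends(loft_tube(oriented_contours_small))


@pytest.fixture(scope="session")
def branch_surface(frames_branch, phantom_branch):
    from ivus2fe.surface_mesh import build_branch

    _, stack = phantom_branch
    cs = build_contour_set(frames_branch)
    c = compute_frames(load_centerline(stack.centerline_csv))
    oc = place_contours(cs, c, px_scale=0.02)
    return build_branch(cap_ends(loft_tube(oc)))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
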