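"""Shared fixtures: hand-built contours and small phantoms."""

import numpy as np
import pytest

from kneecdi import (
    ContourSet,
    SliceContour,
    VoxelGeometry,
)


def straight_slice(
    slice_index=0,
    bone="femur",
    length=30.0,
    thickness=2.0,
    spacing=0.05,
    denuded=(),
):
    """Bone boundary along y=0, cartilage at y=thickness.

    ``denuded`` is a list of (x0, x1) intervals where the cartilage surface
    collapses onto the bone (thickness 0).
    """
    x = np.arange(0.0, length + spacing / 2, spacing)
    bone_poly = np.stack([x, np.zeros_like(x)], axis=1)
    t = np.full_like(x, thickness)
    for x0, x1 in denuded:
        t[(x >= x0) & (x <= x1)] = 0.0
    cart = np.stack([x, t], axis=1)
    return SliceContour(slice_index, bone, bone_poly, cart)


def stack_of(slices, side="left", n_slices=None, knee_id="toy",
             timepoint="baseline"):
    idx = [sc.slice_index for sc in slices]
    lo, hi = min(idx), max(idx)
    if n_slices is None:
        n_slices = max(hi + 1, 2)
    return ContourSet(
        knee_id=knee_id,
        timepoint=timepoint,
        side=side,
        geometry=VoxelGeometry(n_slices=n_slices),
        slices=slices,
        medial_slice=lo,
        lateral_slice=hi if hi != lo else lo + 1,
    )


@pytest.fixture
def parallel_stack():
    """Two-slice knee with flat 2 mm cartilage on both bones."""
    slices = []
    for i in (0, 1):
        for bone in ("femur", "tibia"):
            slices.append(straight_slice(i, bone))
    return stack_of(slices)
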