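"""Informative-location discovery from denuded-cartilage frequency maps.

The development logic behind the informative locations: project each
knee's denuded area (thickness == 0) onto the universal (u, v) map,
accumulate across knees into a per-bin frequency map, and place the
measurement sites in the region that is most frequently denuded.

Two placement layouts are offered.  ``grid`` (the default, matching the
9-per-bone pattern) spans the bounding box of the top-decile frequency
region with an evenly spaced square grid; ``peaks`` picks the highest-
frequency bins subject to a minimum separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .cdi import _thickness_profile
from .errors import NoDenudedRegionError, ValidationError
from .geometry import (
    BONES,
    BoneLabel,
    ContourSet,
    InformativeLocation,
    InformativeLocationSet,
    SurfaceCoordinate,
    arclength_parameterize,
    slice_for_u,
)

DEFAULT_GRID = (50, 50)


@dataclass
class DenudedFrequencyMap:
    """Per-bin counts of knees denuded at each (u, v) grid cell."""

    bone: BoneLabel
    counts: np.ndarray
    n_knees: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValidationError("counts must be a 2-D (u, v) grid")
        if self.n_knees < 1:
            raise ValidationError("map must aggregate at least one knee")
        if np.any(self.counts < 0) or np.any(self.counts > self.n_knees):
            raise ValidationError("bin counts must lie in [0, n_knees]")

    @property
    def frequency(self) -> np.ndarray:
        return self.counts / self.n_knees

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.counts.shape
        return (np.arange(nu) + 0.5) / nu, (np.arange(nv) + 0.5) / nv


def project_denuded(
    cs: ContourSet,
    grid_shape: tuple[int, int] = DEFAULT_GRID,
    threshold: float = 0.0,
) -> dict[BoneLabel, np.ndarray]:
    """Binary denuded mask over the (u, v) grid, per bone.

    A bin is denuded when the measured thickness at its centre is at or
    below ``threshold`` (default 0.0 mm: bone actually exposed).  Bins
    whose slice lacks a usable contour are left False.
    """
    nu, nv = grid_shape
    if nu < 1 or nv < 1:
        raise ValidationError("grid shape must be positive")
    u_centers = (np.arange(nu) + 0.5) / nu
    v_centers = (np.arange(nv) + 0.5) / nv
    masks: dict[BoneLabel, np.ndarray] = {}
    for bone in BONES:
        mask = np.zeros((nu, nv), dtype=bool)
        # group u-bins resolving to the same slice: one vectorized
        # thickness profile per distinct slice
        slice_of = np.array([slice_for_u(cs, u) for u in u_centers])
        for idx in np.unique(slice_of):
            sc = cs.contour_for(int(idx), bone)
            if sc is None or sc.boundary_only:
                continue
            amap = arclength_parameterize(sc.bone_boundary)
            t = _thickness_profile(sc, v_centers, amap)
            mask[slice_of == idx, :] = (t <= threshold + 1e-9)[None, :]
        masks[bone] = mask
    return masks


def accumulate_frequency(
    masks: Sequence[np.ndarray], bone: BoneLabel = "femur"
) -> DenudedFrequencyMap:
    """Stack per-knee binary masks into a denuded-frequency map."""
    if len(masks) == 0:
        raise ValidationError("no masks to accumulate")
    shape = np.shape(masks[0])
    for m in masks:
        if np.shape(m) != shape:
            raise ValidationError("all masks must share the grid shape")
    counts = np.sum([np.asarray(m, dtype=bool) for m in masks], axis=0)
    return DenudedFrequencyMap(bone=bone, counts=counts, n_knees=len(masks))


def build_frequency_maps(
    contour_sets: Iterable[ContourSet],
    grid_shape: tuple[int, int] = DEFAULT_GRID,
    threshold: float = 0.0,
) -> dict[BoneLabel, DenudedFrequencyMap]:
    """Project every knee and accumulate one frequency map per bone."""
    per_bone: dict[BoneLabel, list[np.ndarray]] = {b: [] for b in BONES}
    for cs in contour_sets:
        masks = project_denuded(cs, grid_shape=grid_shape, threshold=threshold)
        for b in BONES:
            per_bone[b].append(masks[b])
    return {b: accumulate_frequency(per_bone[b], bone=b) for b in BONES}


def _top_decile_bbox(freq: np.ndarray, centers_u, centers_v):
    """Bounding box (u0, u1, v0, v1) of bins within 10% of the peak."""
    peak = freq.max()
    iu, iv = np.nonzero(freq >= 0.9 * peak)
    return (
        centers_u[iu.min()],
        centers_u[iu.max()],
        centers_v[iv.min()],
        centers_v[iv.max()],
    )


def select_informative(
    fmap: DenudedFrequencyMap,
    n: int = 9,
    layout: Literal["grid", "peaks"] = "grid",
    min_separation: float = 0.05,
    name_prefix: str | None = None,
) -> InformativeLocationSet:
    """Place ``n`` measurement sites in the most frequently denuded region.

    ``grid``: a square grid (``n`` must be a perfect square) spanning the
    bounding box of the top-decile frequency region, sites at the centres
    of the equal subdivision (for n=9, the tercile midpoints).  ``peaks``:
    the ``n`` highest-frequency bins at least ``min_separation`` apart in
    (u, v), ties broken by lexicographic (u, v) order.  Both layouts are
    deterministic and invariant to rescaling all counts.
    """
    if n < 1:
        raise ValidationError("need at least one location")
    freq = fmap.frequency
    if freq.max() <= 0:
        raise NoDenudedRegionError(
            f"no denuded bins on the {fmap.bone} map ({fmap.n_knees} knees)"
        )
    cu, cv = fmap.bin_centers()
    prefix = name_prefix or f"{fmap.bone}_d"
    locs: list[InformativeLocation] = []

    if layout == "grid":
        k = int(round(np.sqrt(n)))
        if k * k != n:
            raise ValidationError("grid layout needs a square location count")
        u0, u1, v0, v1 = _top_decile_bbox(freq, cu, cv)
        m = 1
        for j in range(k):
            v = v0 + (j + 0.5) / k * (v1 - v0)
            for i in range(k):
                u = u0 + (i + 0.5) / k * (u1 - u0)
                locs.append(
                    InformativeLocation(
                        f"{prefix}{m}", fmap.bone, SurfaceCoordinate(u, v)
                    )
                )
                m += 1
    elif layout == "peaks":
        iu, iv = np.meshgrid(np.arange(len(cu)), np.arange(len(cv)), indexing="ij")
        flat = np.stack([iu.ravel(), iv.ravel()], axis=1)
        uv = np.stack([cu[flat[:, 0]], cv[flat[:, 1]]], axis=1)
        f = freq[flat[:, 0], flat[:, 1]]
        # descending frequency, ties by ascending (u, v)
        order = np.lexsort((uv[:, 1], uv[:, 0], -f))
        chosen: list[np.ndarray] = []
        for idx in order:
            if f[idx] <= 0:
                break
            p = uv[idx]
            if any(np.hypot(*(p - q)) < min_separation for q in chosen):
                continue
            chosen.append(p)
            if len(chosen) == n:
                break
        if len(chosen) < n:
            raise ValidationError(
                f"only {len(chosen)} denuded peaks available at "
                f"separation {min_separation}"
            )
        for m, p in enumerate(chosen, start=1):
            locs.append(
                InformativeLocation(
                    f"{prefix}{m}", fmap.bone,
                    SurfaceCoordinate(float(p[0]), float(p[1])),
                )
            )
    else:
        raise ValidationError(f"unknown layout {layout!r}")
    return InformativeLocationSet(locs, provenance="discovered")


def discover_locations(
    contour_sets: Iterable[ContourSet],
    n_per_bone: int = 9,
    layout: Literal["grid", "peaks"] = "grid",
    grid_shape: tuple[int, int] = DEFAULT_GRID,
    threshold: float = 0.0,
    min_separation: float = 0.05,
) -> InformativeLocationSet:
    """End-to-end discovery: cohort contours -> 9 + 9 informative locations."""
    fmaps = build_frequency_maps(contour_sets, grid_shape, threshold)
    locs: list[InformativeLocation] = []
    for bone in BONES:
        sub = select_informative(
            fmaps[bone], n=n_per_bone, layout=layout,
            min_separation=min_separation,
        )
        locs.extend(sub.locations)
    return InformativeLocationSet(locs, provenance="discovered")
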