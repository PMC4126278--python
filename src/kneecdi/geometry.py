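"""Universal 2-D joint-surface coordinate system over sagittal slice contours.

The articular surface of the medial femoral condyle or tibial plateau is
represented as a rectangle: ``u`` runs medial (0) to lateral (1) across the
sagittal slice stack, and ``v`` runs anterior (0) to posterior (1) as
normalized arc length along the bone--cartilage boundary within a slice.
One location table in (u, v) therefore serves every knee, regardless of
size, side, or acquisition direction.

Conventions
-----------
* ``u = 0`` is the most *medial* slice the reader indicated, ``u = 1`` the
  most lateral; left and right knees are normalized by the medial/lateral
  slice indices alone, so the same table applies to both sides.
* ``v = 0`` is the anterior endpoint of the stored bone boundary.  Suppliers
  must store boundary points anterior-first; :func:`check_orientation`
  flags slices whose stored order disagrees with their neighbours.
* Slice indices are 0-based internally; files carry explicit indices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
from shapely.geometry import LineString

from .errors import (
    DegenerateContourError,
    UnmeasurableLocationError,
    ValidationError,
)

BoneLabel = Literal["femur", "tibia"]
BONES: tuple[BoneLabel, BoneLabel] = ("femur", "tibia")


@dataclass(frozen=True)
class VoxelGeometry:
    """Acquisition geometry of the sagittal MR stack.

    Defaults are the OAI 3-D DESS protocol: 0.365 x 0.456 mm in-plane,
    0.7 mm slice thickness, no gap.
    """

    dx: float = 0.365
    dy: float = 0.456
    dz: float = 0.7
    n_slices: int = 160

    def __post_init__(self):
        if not (self.dx > 0 and self.dy > 0 and self.dz > 0):
            raise ValidationError("voxel resolutions must be positive")
        if self.n_slices < 2:
            raise ValidationError("need at least 2 sagittal slices")


@dataclass
class SliceContour:
    """Traced contours of one bone on one sagittal slice.

    ``bone_boundary`` is the bone--cartilage interface polyline, ordered
    anterior to posterior, in slice-plane millimetres.  ``cartilage_surface``
    is the outer cartilage surface; it may be ``None`` on boundary-only
    slices (loaded but flagged, thickness unmeasurable).
    """

    slice_index: int
    bone: BoneLabel
    bone_boundary: np.ndarray
    cartilage_surface: np.ndarray | None = None

    def __post_init__(self):
        self.bone_boundary = _as_polyline(self.bone_boundary, "bone_boundary")
        if self.cartilage_surface is not None:
            self.cartilage_surface = _as_polyline(
                self.cartilage_surface, "cartilage_surface"
            )

    @property
    def boundary_only(self) -> bool:
        return self.cartilage_surface is None

    def validate_simple(self) -> None:
        """Check both polylines are simple (non-self-intersecting)."""
        for name, poly in (
            ("bone_boundary", self.bone_boundary),
            ("cartilage_surface", self.cartilage_surface),
        ):
            if poly is None or len(poly) < 3:
                continue
            if not LineString(poly).is_simple:
                raise DegenerateContourError(
                    f"{name} on slice {self.slice_index} ({self.bone}) "
                    "is self-intersecting"
                )


def _as_polyline(pts, name: str) -> np.ndarray:
    arr = np.asarray(pts, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateContourError(
            f"{name} must be an (n>=2, 2) array of slice-plane mm points"
        )
    if not np.all(np.isfinite(arr)):
        raise DegenerateContourError(f"{name} contains non-finite coordinates")
    return arr


@dataclass
class ContourSet:
    """All traced contours for one knee at one timepoint."""

    knee_id: str
    timepoint: str
    side: Literal["left", "right"]
    geometry: VoxelGeometry
    slices: list[SliceContour]
    medial_slice: int
    lateral_slice: int

    def __post_init__(self):
        if self.timepoint not in ("baseline", "followup"):
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")
        if self.side not in ("left", "right"):
            raise ValidationError(f"unknown side {self.side!r}")
        if self.medial_slice == self.lateral_slice:
            raise ValidationError("medial_slice must differ from lateral_slice")
        lo = min(self.medial_slice, self.lateral_slice)
        hi = max(self.medial_slice, self.lateral_slice)
        for sc in self.slices:
            if not lo <= sc.slice_index <= hi:
                raise ValidationError(
                    f"slice index {sc.slice_index} outside the medial–lateral "
                    f"range [{lo}, {hi}]"
                )
        self._index: dict[tuple[int, str], SliceContour] = {}
        for sc in self.slices:
            key = (sc.slice_index, sc.bone)
            if key in self._index:
                raise ValidationError(
                    f"duplicate contour for slice {sc.slice_index} / {sc.bone}"
                )
            self._index[key] = sc

    def contour_for(self, slice_index: int, bone: BoneLabel) -> SliceContour | None:
        return self._index.get((slice_index, bone))

    def slice_indices(self, bone: BoneLabel) -> list[int]:
        return sorted(i for (i, b) in self._index if b == bone)


@dataclass(frozen=True)
class SurfaceCoordinate:
    """Position on the rectangular joint-surface map, both axes in [0, 1]."""

    u: float
    v: float

    def __post_init__(self):
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.v <= 1.0):
            raise ValidationError(f"(u, v)=({self.u}, {self.v}) outside [0,1]^2")


@dataclass(frozen=True)
class InformativeLocation:
    name: str
    bone: BoneLabel
    coord: SurfaceCoordinate


@dataclass
class InformativeLocationSet:
    """Named measurement sites on the universal map, per bone."""

    locations: list[InformativeLocation]
    provenance: Literal["default", "discovered", "user"] = "user"

    def __post_init__(self):
        names = [loc.name for loc in self.locations]
        if len(set(names)) != len(names):
            raise ValidationError("informative location names must be unique")

    def for_bone(self, bone: BoneLabel) -> list[InformativeLocation]:
        return [loc for loc in self.locations if loc.bone == bone]

    def __len__(self) -> int:
        return len(self.locations)


def default_informative_locations() -> InformativeLocationSet:
    """Illustrative default table: 9 femur + 9 tibia sites.

    A 3x3 grid per bone over the central weight-bearing region, where
    denuded cartilage is most frequent in medial knee OA.  These are
    illustrative defaults, not the coordinates used on real OAI knees;
    substitute exact coordinates via a user table when available.
    """
    locs: list[InformativeLocation] = []
    us = (0.3, 0.5, 0.7)
    vs = (0.35, 0.5, 0.65)
    for bone, prefix in (("femur", "F"), ("tibia", "T")):
        k = 1
        for v in vs:
            for u in us:
                locs.append(
                    InformativeLocation(
                        f"{prefix}{k}", bone, SurfaceCoordinate(u, v)
                    )
                )
                k += 1
    return InformativeLocationSet(locs, provenance="default")


# ---------------------------------------------------------------------------
# u -> slice
# ---------------------------------------------------------------------------

def slice_for_u(cs: ContourSet, u: float) -> int:
    """Map the medial–lateral coordinate ``u`` to the nearest slice index.

    ``u = 0`` is the medial-most slice, ``u = 1`` the lateral-most; the
    target is ``medial + u * (lateral - medial)`` rounded to the nearest
    integer slice.  A half-way tie goes to the slice *farther from the
    medial end*, a rule that is symmetric under mirroring the acquisition
    direction, so left and right knees resolve to the same anatomy.
    """
    if not 0.0 <= u <= 1.0:
        raise ValidationError(f"u={u} outside [0, 1]")
    span = cs.lateral_slice - cs.medial_slice
    # offset from the medial end in slices; ties round up (away from medial)
    k = math.floor(abs(span) * u + 0.5)
    return cs.medial_slice + int(math.copysign(k, span))


# ---------------------------------------------------------------------------
# v -> point on the bone boundary
# ---------------------------------------------------------------------------

@dataclass
class ArcLengthMap:
    """Arc-length parameterization of a polyline.

    Maps ``v`` in [0, 1] (0 = anterior endpoint) to a point in slice-plane
    mm by linear interpolation within segments.
    """

    points: np.ndarray
    cum: np.ndarray = field(repr=False)
    length: float

    def __call__(self, v) -> np.ndarray:
        v = np.asarray(v, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValidationError("v outside [0, 1]")
        s = v * self.length
        x = np.interp(s, self.cum, self.points[:, 0])
        y = np.interp(s, self.cum, self.points[:, 1])
        return np.stack([x, y], axis=-1)

    def tangent(self, v: float, h_mm: float = 0.2) -> np.ndarray:
        """Unit tangent at ``v`` by a symmetric arc-length difference.

        Averages the directions of the adjacent segments; ``h_mm`` is
        clipped so both probe points stay on the polyline.
        """
        h = min(h_mm, self.length / 4.0) / self.length
        a = self(max(0.0, v - h))
        b = self(min(1.0, v + h))
        d = b - a
        n = np.linalg.norm(d)
        if n == 0:
            raise DegenerateContourError("zero-length tangent probe")
        return d / n

    def project(self, point: np.ndarray) -> float:
        """Arc-length position (in [0,1]) of the nearest boundary point."""
        p = np.asarray(point, dtype=float)
        a = self.points[:-1]
        b = self.points[1:]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        denom[denom == 0] = 1.0
        t = np.clip(np.einsum("ij,ij->i", p - a, ab) / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d2 = np.einsum("ij,ij->i", proj - p, proj - p)
        i = int(np.argmin(d2))
        s = self.cum[i] + t[i] * (self.cum[i + 1] - self.cum[i])
        return float(s / self.length)


def arclength_parameterize(boundary: np.ndarray) -> ArcLengthMap:
    """Build the v -> point mapping for a bone-boundary polyline."""
    pts = _as_polyline(boundary, "boundary")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    length = float(cum[-1])
    if length <= 0:
        raise DegenerateContourError("boundary has zero total length")
    return ArcLengthMap(points=pts, cum=cum, length=length)


def resolve_location(
    cs: ContourSet,
    coord: SurfaceCoordinate,
    bone: BoneLabel,
    name: str = "",
) -> tuple[int, np.ndarray]:
    """Resolve a (u, v) site to (slice index, point on the bone boundary).

    Raises :class:`UnmeasurableLocationError` when the resolved slice has
    no contour for the bone (carrying knee and location identifiers so the
    caller can flag and continue).
    """
    idx = slice_for_u(cs, coord.u)
    sc = cs.contour_for(idx, bone)
    if sc is None:
        raise UnmeasurableLocationError(
            f"no {bone} contour on slice {idx} of knee {cs.knee_id}",
            knee_id=cs.knee_id,
            location=name,
        )
    amap = arclength_parameterize(sc.bone_boundary)
    return idx, amap(coord.v)


def check_orientation(cs: ContourSet, bone: BoneLabel) -> list[int]:
    """Flag slices whose stored point order disagrees with their neighbours.

    Suppliers contract to store boundaries anterior-first; a manually traced
    slice occasionally comes in reversed.  The anterior→posterior direction
    of each boundary (endpoint difference) is compared with the per-stack
    majority; indices of disagreeing slices are returned for review.
    """
    idxs = cs.slice_indices(bone)
    if not idxs:
        return []
    dirs = []
    for i in idxs:
        bb = cs.contour_for(i, bone).bone_boundary
        d = bb[-1] - bb[0]
        n = np.linalg.norm(d)
        dirs.append(d / n if n > 0 else np.zeros(2))
    dirs = np.asarray(dirs)
    mean_dir = dirs.mean(axis=0)
    if np.linalg.norm(mean_dir) == 0:
        return []
    agree = dirs @ mean_dir
    return [i for i, a in zip(idxs, agree) if a < 0]


def mirror_contour_set(cs: ContourSet) -> ContourSet:
    """Re-index a knee to the opposite-side slice convention.

    Slice indices are reflected about the stack centre and the side label
    flipped; in-plane coordinates are untouched.  Resolving the same (u, v)
    before and after yields the same physical points.
    """
    lo = min(cs.medial_slice, cs.lateral_slice)
    hi = max(cs.medial_slice, cs.lateral_slice)
    flip: Callable[[int], int] = lambda i: hi + lo - i
    slices = [
        SliceContour(
            slice_index=flip(sc.slice_index),
            bone=sc.bone,
            bone_boundary=sc.bone_boundary.copy(),
            cartilage_surface=None
            if sc.cartilage_surface is None
            else sc.cartilage_surface.copy(),
        )
        for sc in cs.slices
    ]
    return ContourSet(
        knee_id=cs.knee_id,
        timepoint=cs.timepoint,
        side="left" if cs.side == "right" else "right",
        geometry=cs.geometry,
        slices=slices,
        medial_slice=flip(cs.medial_slice),
        lateral_slice=flip(cs.lateral_slice),
    )
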