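"""Cartilage Damage Index: thickness, length, aggregation, change scores.

The CDI of a bone is the sum over its informative locations of

    thickness_i (mm) * cartilage length_i (mm) * voxel size (mm)

a volume proxy in mm^3.  Thickness is measured from the bone--cartilage
interface to the outer cartilage surface along the local outward boundary
normal; cartilage length is the anterior--posterior arc length of the bone
boundary that is still cartilage-covered on the location's slice.  Lower
CDI means more cartilage damage: denuded locations contribute zero.

"Voxel size" defaults to the slice thickness ``dz``; an in-plane-area
interpretation (``dx * dy``) is available for sensitivity analysis via
``voxel_mode="dxdy"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .errors import (
    DegenerateContourError,
    EmptyMeasurementError,
    UnmeasurableLocationError,
    ValidationError,
)
from .geometry import (
    BONES,
    ArcLengthMap,
    BoneLabel,
    ContourSet,
    InformativeLocationSet,
    SliceContour,
    VoxelGeometry,
    arclength_parameterize,
    slice_for_u,
)

#: default cap (mm) on the normal-ray search before falling back to
#: nearest-point distance
DEFAULT_SEARCH_CAP = 15.0
#: default step (mm) for sampling the boundary when measuring covered length
DEFAULT_LENGTH_STEP = 0.2
#: thickness below this is treated as denuded when measuring covered length
COVERAGE_EPS = 1e-6


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def _ray_polyline_first_hit(
    origins: np.ndarray,
    directions: np.ndarray,
    polyline: np.ndarray,
    cap: float,
) -> np.ndarray:
    """Distance along each ray to its first polyline crossing, NaN if none.

    Vectorized over rays x segments.  Origins lying on the polyline hit at
    distance 0 (the denuded case, where the cartilage surface has collapsed
    onto the bone boundary).
    """
    a = polyline[:-1]  # (m, 2)
    ab = polyline[1:] - a  # (m, 2)
    o = origins[:, None, :]  # (n, 1, 2)
    d = directions[:, None, :]  # (n, 1, 2)
    ao = a[None, :, :] - o  # (n, m, 2)
    # solve o + t*d = a + s*ab :  cross products of the 2x2 system
    denom = d[..., 0] * (-ab[None, :, 1]) - d[..., 1] * (-ab[None, :, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ao[..., 0] * (-ab[None, :, 1]) - ao[..., 1] * (-ab[None, :, 0])) / denom
        s = (d[..., 0] * ao[..., 1] - d[..., 1] * ao[..., 0]) / denom
    valid = (
        np.isfinite(t)
        & np.isfinite(s)
        & (s >= -1e-9)
        & (s <= 1 + 1e-9)
        & (t >= -1e-9)
        & (t <= cap)
    )
    t = np.where(valid, np.maximum(t, 0.0), np.inf)
    first = t.min(axis=1)
    return np.where(np.isfinite(first), first, np.nan)


def _nearest_points(
    points: np.ndarray, polyline: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest polyline point for each query point: (distances, projections)."""
    a = polyline[:-1]
    ab = polyline[1:] - a
    denom = np.einsum("ij,ij->i", ab, ab)
    denom = np.where(denom == 0, 1.0, denom)
    ap = points[:, None, :] - a[None, :, :]  # (n, m, 2)
    t = np.clip(np.einsum("nmj,mj->nm", ap, ab) / denom, 0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * ab[None, :, :]
    d = np.linalg.norm(points[:, None, :] - proj, axis=2)
    idx = d.argmin(axis=1)
    rows = np.arange(len(points))
    return d[rows, idx], proj[rows, idx]


def _thickness_profile(
    sc: SliceContour,
    vs: np.ndarray,
    amap: ArcLengthMap | None = None,
    search_cap: float = DEFAULT_SEARCH_CAP,
) -> np.ndarray:
    """Thickness at many arc positions ``vs`` along one slice's boundary."""
    if sc.cartilage_surface is None:
        raise DegenerateContourError(
            f"slice {sc.slice_index} ({sc.bone}) has no cartilage surface"
        )
    surf = sc.cartilage_surface
    if amap is None:
        amap = arclength_parameterize(sc.bone_boundary)
    vs = np.asarray(vs, dtype=float)
    pts = amap(vs)

    # outward normals from averaged adjacent-segment tangents
    h = min(0.2, amap.length / 4.0) / amap.length
    tan = amap(np.minimum(vs + h, 1.0)) - amap(np.maximum(vs - h, 0.0))
    norm = np.linalg.norm(tan, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tan /= norm
    normals = np.stack([-tan[:, 1], tan[:, 0]], axis=1)
    # orient each normal toward the cartilage side: toward the nearest
    # surface point (robust on long curved boundaries where a centroid
    # heuristic flips sign near the arc ends)
    near_d, near_p = _nearest_points(pts, surf)
    toward = near_p - pts
    dots = np.einsum("ij,ij->i", normals, toward)
    sign = np.where(dots >= 0, 1.0, -1.0)
    # coincident surface (denuded): direction is irrelevant, hit at 0
    sign[near_d < 1e-9] = 1.0
    normals *= sign[:, None]

    t = _ray_polyline_first_hit(pts, normals, surf, cap=search_cap)

    # footprint: arc interval of the boundary covered by the cartilage
    # surface (projections of its endpoints); outside it the bone is denuded
    s0 = amap.project(surf[0])
    s1 = amap.project(surf[-1])
    lo, hi = min(s0, s1), max(s0, s1)
    margin = 0.1 / amap.length  # 0.1 mm slack at the footprint edges
    outside = (vs < lo - margin) | (vs > hi + margin)

    # no normal crossing within the cap: fall back to nearest-point distance
    miss = np.isnan(t) & ~outside
    if np.any(miss):
        t[miss] = near_d[miss]
    t[outside] = 0.0
    return t


# ---------------------------------------------------------------------------
# public single-point / single-slice operations
# ---------------------------------------------------------------------------

def measure_thickness(
    sc: SliceContour,
    bone_point: np.ndarray,
    search_cap: float = DEFAULT_SEARCH_CAP,
) -> float:
    """Cartilage thickness (mm) at a point on the bone--cartilage boundary.

    The point must lie on (within ~1e-6 mm of) ``sc.bone_boundary``; its
    arc position is recovered by projection.  Returns 0.0 where the bone
    is denuded (the point lies outside the cartilage footprint, or the
    surface has collapsed onto the boundary).
    """
    amap = arclength_parameterize(sc.bone_boundary)
    v = amap.project(np.asarray(bone_point, dtype=float))
    return float(_thickness_profile(sc, np.array([v]), amap, search_cap)[0])


def measure_length(
    sc: SliceContour,
    step: float = DEFAULT_LENGTH_STEP,
    search_cap: float = DEFAULT_SEARCH_CAP,
    coverage_eps: float = COVERAGE_EPS,
) -> float:
    """Anterior--posterior cartilage length (mm) on one slice.

    Arc length of the portion of the bone boundary where measured thickness
    exceeds ``coverage_eps``, estimated by sampling the boundary every
    ``step`` mm and summing covered sample intervals.
    """
    if step <= 0:
        raise ValidationError("length sampling step must be positive")
    amap = arclength_parameterize(sc.bone_boundary)
    n = max(int(np.ceil(amap.length / step)) + 1, 2)
    vs = np.linspace(0.0, 1.0, n)
    t = _thickness_profile(sc, vs, amap, search_cap)
    covered = t > coverage_eps
    # each sample represents one interval of the uniform arc partition
    return float(covered.mean() * amap.length)


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

@dataclass
class ThicknessSample:
    """One informative-location measurement on one knee."""

    location: str
    bone: BoneLabel
    slice_index: int | None
    thickness: float  # t_i, mm; 0 when denuded
    cartilage_length: float  # L_i, mm, anterior–posterior covered extent
    bone_point: tuple[float, float] | None
    measurable: bool = True


@dataclass
class CDIResult:
    """Per-location samples and regional CDI aggregates for one knee."""

    knee_id: str
    timepoint: str
    samples: list[ThicknessSample]
    femur_cdi: float
    tibia_cdi: float
    tibiofemoral_cdi: float
    voxel_size: float
    height_m: float | None = None
    femur_cdi_adj: float | None = None
    tibia_cdi_adj: float | None = None
    tibiofemoral_cdi_adj: float | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def adjusted(self) -> bool:
        return self.height_m is not None

    def region(self, name: str, adjusted: bool = False) -> float:
        key = f"{name}_cdi" + ("_adj" if adjusted else "")
        val = getattr(self, key)
        if val is None:
            raise ValidationError(f"{key} not available (no height set)")
        return val


REGIONS = ("femur", "tibia", "tibiofemoral")


def compute_cdi(
    cs: ContourSet,
    locations: InformativeLocationSet,
    voxel_mode: Literal["dz", "dxdy"] = "dz",
    search_cap: float = DEFAULT_SEARCH_CAP,
    length_step: float = DEFAULT_LENGTH_STEP,
) -> CDIResult:
    """Measure all informative locations and aggregate the regional CDIs.

    Per bone, CDI = sum_i t_i * L_i * voxel, with voxel = dz (default) or
    dx*dy.  Unmeasurable locations (no contour on the resolved slice, or a
    boundary-only slice) contribute 0 and are flagged rather than aborting
    the knee; a bone with *no* measurable location raises
    :class:`EmptyMeasurementError`.
    """
    geom = cs.geometry
    voxel = geom.dz if voxel_mode == "dz" else geom.dx * geom.dy
    samples: list[ThicknessSample] = []
    flags: list[str] = []
    totals = {"femur": 0.0, "tibia": 0.0}
    measurable_count = {"femur": 0, "tibia": 0}
    bones_requested = {loc.bone for loc in locations.locations}

    # cache per (slice, bone): arc map + cartilage length
    cache: dict[tuple[int, str], tuple[ArcLengthMap, float]] = {}

    for loc in locations.locations:
        idx = slice_for_u(cs, loc.coord.u)
        sc = cs.contour_for(idx, loc.bone)
        if sc is None or sc.boundary_only:
            samples.append(
                ThicknessSample(loc.name, loc.bone, idx if sc else None,
                                0.0, 0.0, None, measurable=False)
            )
            flags.append(
                f"unmeasurable location {loc.name} ({loc.bone}) on knee "
                f"{cs.knee_id}: "
                + ("no contour" if sc is None else "boundary-only slice")
                + f" at slice {idx}"
            )
            continue
        key = (idx, loc.bone)
        if key not in cache:
            amap = arclength_parameterize(sc.bone_boundary)
            L = measure_length(sc, step=length_step, search_cap=search_cap)
            cache[key] = (amap, L)
        amap, L = cache[key]
        t = float(_thickness_profile(sc, np.array([loc.coord.v]), amap,
                                     search_cap)[0])
        pt = amap(loc.coord.v)
        samples.append(
            ThicknessSample(loc.name, loc.bone, idx, t, L,
                            (float(pt[0]), float(pt[1])))
        )
        totals[loc.bone] += t * L * voxel
        measurable_count[loc.bone] += 1

    for bone in BONES:
        if bone in bones_requested and measurable_count[bone] == 0:
            raise EmptyMeasurementError(
                f"every {bone} location unmeasurable on knee {cs.knee_id}"
            )

    return CDIResult(
        knee_id=cs.knee_id,
        timepoint=cs.timepoint,
        samples=samples,
        femur_cdi=totals["femur"],
        tibia_cdi=totals["tibia"],
        tibiofemoral_cdi=totals["femur"] + totals["tibia"],
        voxel_size=voxel,
        flags=flags,
    )


def height_adjust(result: CDIResult, height_m: float) -> CDIResult:
    """Divide each regional CDI by standing height (metres).

    Returns a new result carrying both raw and adjusted values; the input
    is untouched.
    """
    if not height_m > 0:
        raise ValidationError(f"height must be positive, got {height_m}")
    return replace(
        result,
        height_m=height_m,
        femur_cdi_adj=result.femur_cdi / height_m,
        tibia_cdi_adj=result.tibia_cdi / height_m,
        tibiofemoral_cdi_adj=result.tibiofemoral_cdi / height_m,
    )


@dataclass
class ChangeRecord:
    """Follow-up minus baseline CDI, per region, for one knee."""

    knee_id: str
    adjusted: bool
    baseline: dict[str, float]
    followup: dict[str, float]
    change: dict[str, float]


def change_score(baseline: CDIResult, followup: CDIResult) -> ChangeRecord:
    """Longitudinal change = follow-up minus baseline, componentwise.

    Both results must belong to the same knee and share adjustment state
    (both raw, or both height-adjusted).
    """
    if baseline.knee_id != followup.knee_id:
        raise ValidationError(
            f"knee mismatch: {baseline.knee_id!r} vs {followup.knee_id!r}"
        )
    if baseline.adjusted != followup.adjusted:
        raise ValidationError(
            "baseline and follow-up must share adjustment state"
        )
    adjusted = baseline.adjusted
    b = {r: baseline.region(r, adjusted) for r in REGIONS}
    f = {r: followup.region(r, adjusted) for r in REGIONS}
    return ChangeRecord(
        knee_id=baseline.knee_id,
        adjusted=adjusted,
        baseline=b,
        followup=f,
        change={r: f[r] - b[r] for r in REGIONS},
    )
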