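"""Synthetic knee phantoms with known ground-truth cartilage fields.

Real DESS images are access-controlled, so every stage of the pipeline is
exercised on stylized digital knees instead: the medial femoral condyle is
a circular-arc cylinder and the medial tibial plateau a shallow arc slab,
each swept across the sagittal stack.  Cartilage is an offset surface
``bone + t(u, v) * outward_normal`` whose thickness field

    t(u, v) = max(T0 - thinning - sum(defect depths at (u, v)), 0)

is known exactly everywhere, so the ground-truth CDI can be computed by
dense numerical integration and compared with the measurement pipeline.
Defects are hard discs in (u, v) space; a defect deeper than the local
thickness exposes bone (thickness clamps to 0), which is how denuded areas
arise.  Phantoms are emitted as contour sets — the pipeline's native
input — not as images: image segmentation is not the method under test.

Reader variability is simulated as i.i.d. normal jitter on every contour
point plus an occasional one-slice misidentification of the medial or
lateral endpoint.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import (
    BONES,
    BoneLabel,
    ContourSet,
    InformativeLocationSet,
    SliceContour,
    VoxelGeometry,
)

#: OAI DESS acquisition geometry; 31 slices at 0.7 mm span a ~21 mm medial
#: compartment, the stack width the phantoms emulate
DEFAULT_GEOMETRY = VoxelGeometry(dx=0.365, dy=0.456, dz=0.7, n_slices=31)


@dataclass(frozen=True)
class Defect:
    """A focal cartilage defect: a disc in (u, v) with uniform depth (mm)."""

    bone: BoneLabel
    u: float
    v: float
    radius: float
    depth: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValidationError("defect radius must be positive")
        if self.depth < 0:
            raise ValidationError("defect depth must be non-negative")


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one synthetic knee at one timepoint.

    ``femur_radius`` / ``tibia_radius`` are the sagittal curvature radii of
    the two bone surfaces (mm); ``*_halfangle`` the arc half-extents (rad),
    so the anterior–posterior boundary length is ``2 * halfangle * radius``.
    ``base_thickness`` maps bone -> healthy cartilage thickness T0 (mm).
    ``thinning`` is a uniform global loss (mm) applied before defects
    (used to carry longitudinal progression).
    """

    knee_id: str = "phantom"
    timepoint: str = "baseline"
    side: str = "left"
    geometry: VoxelGeometry = DEFAULT_GEOMETRY
    femur_radius: float = 22.0
    femur_halfangle: float = 0.70
    tibia_radius: float = 60.0
    tibia_halfangle: float = 0.24
    base_thickness: tuple[tuple[str, float], ...] = (("femur", 2.2), ("tibia", 2.0))
    defects: tuple[Defect, ...] = ()
    thinning: float = 0.0
    points_per_contour: int = 101
    seed: int = 0

    def __post_init__(self):
        if self.femur_radius <= 0 or self.tibia_radius <= 0:
            raise ValidationError("bone radii must be positive")
        if self.thinning < 0:
            raise ValidationError("thinning must be non-negative")
        if self.points_per_contour < 3:
            raise ValidationError("need at least 3 points per contour")

    @property
    def t0(self) -> dict[str, float]:
        return dict(self.base_thickness)

    def arc_length(self, bone: BoneLabel) -> float:
        if bone == "femur":
            return 2 * self.femur_halfangle * self.femur_radius
        return 2 * self.tibia_halfangle * self.tibia_radius


@dataclass
class PhantomTruth:
    """Queryable ground truth of a phantom's cartilage field."""

    spec: PhantomSpec

    def thickness(self, bone: BoneLabel, u, v) -> np.ndarray:
        """Exact cartilage thickness (mm) at map position (u, v)."""
        u = np.asarray(u, dtype=float)
        v = np.asarray(v, dtype=float)
        t = np.full(np.broadcast(u, v).shape, self.spec.t0[bone] - self.spec.thinning)
        for d in self.spec.defects:
            if d.bone != bone:
                continue
            inside = (u - d.u) ** 2 + (v - d.v) ** 2 <= d.radius**2
            t = t - np.where(inside, d.depth, 0.0)
        return np.maximum(t, 0.0)

    def length(self, bone: BoneLabel, u: float, n_fine: int = 2001) -> float:
        """Cartilage-covered boundary length (mm) at slice position u."""
        vs = np.linspace(0.0, 1.0, n_fine)
        covered = self.thickness(bone, u, vs) > 0
        return float(covered.mean() * self.spec.arc_length(bone))

    def cdi(
        self,
        locations: InformativeLocationSet,
        voxel: float | None = None,
        n_fine: int = 2001,
    ) -> dict[str, float]:
        """Ground-truth regional CDI: sum of t * L * voxel over locations."""
        if voxel is None:
            voxel = self.spec.geometry.dz
        totals = {"femur": 0.0, "tibia": 0.0}
        for loc in locations.locations:
            t = float(self.thickness(loc.bone, loc.coord.u, loc.coord.v))
            L = self.length(loc.bone, loc.coord.u, n_fine=n_fine)
            totals[loc.bone] += t * L * voxel
        totals["tibiofemoral"] = totals["femur"] + totals["tibia"]
        return totals

    def denuded_fraction(self, bone: BoneLabel, n_grid: int = 101) -> float:
        g = (np.arange(n_grid) + 0.5) / n_grid
        uu, vv = np.meshgrid(g, g, indexing="ij")
        return float((self.thickness(bone, uu, vv) <= 0).mean())


def _bone_arc(spec: PhantomSpec, bone: BoneLabel) -> tuple[np.ndarray, np.ndarray]:
    """(points, outward unit normals) of the bone boundary, anterior first."""
    if bone == "femur":
        radius, half = spec.femur_radius, spec.femur_halfangle
        center = np.array([40.0, 45.0])
    else:
        radius, half = spec.tibia_radius, spec.tibia_halfangle
        center = np.array([42.0, -45.0])
    phi = np.linspace(-half, half, spec.points_per_contour)
    if bone == "femur":
        # condyle: arc on the underside of the circle, cartilage below
        e = np.stack([np.sin(phi), -np.cos(phi)], axis=1)
    else:
        # plateau: shallow arc on top of a large circle, cartilage above
        e = np.stack([np.sin(phi), np.cos(phi)], axis=1)
    return center + radius * e, e


def generate_phantom(spec: PhantomSpec) -> tuple[ContourSet, PhantomTruth]:
    """Realize a phantom spec as a contour set plus its ground truth.

    The emitted bone boundary samples the analytic arc at uniform angular
    steps (anterior first); the cartilage surface is the outward offset by
    the local ground-truth thickness.  Deterministic: the same spec always
    yields identical contours.
    """
    geom = spec.geometry
    n = geom.n_slices
    truth = PhantomTruth(spec)
    if spec.side == "left":
        medial, lateral = 0, n - 1
    else:
        medial, lateral = n - 1, 0

    slices: list[SliceContour] = []
    vs = np.linspace(0.0, 1.0, spec.points_per_contour)
    for i in range(n):
        u = (i - medial) / (lateral - medial)
        for bone in BONES:
            pts, normals = _bone_arc(spec, bone)
            t = truth.thickness(bone, u, vs)
            cart = pts + t[:, None] * normals
            slices.append(
                SliceContour(
                    slice_index=i,
                    bone=bone,
                    bone_boundary=pts,
                    cartilage_surface=cart,
                )
            )
    cs = ContourSet(
        knee_id=spec.knee_id,
        timepoint=spec.timepoint,
        side=spec.side,  # type: ignore[arg-type]
        geometry=geom,
        slices=slices,
        medial_slice=medial,
        lateral_slice=lateral,
    )
    return cs, truth


def progress_phantom(
    spec: PhantomSpec,
    thinning_rate: float = 0.0,
    defect_growth: float = 0.0,
) -> PhantomSpec:
    """Follow-up spec: uniform thinning plus radial defect growth.

    Ground truth becomes ``max(baseline - thinning_rate, 0)`` pointwise
    (existing defects widen by ``defect_growth`` in map units), so the
    follow-up CDI can only be lower than baseline when rates are positive.
    """
    if thinning_rate < 0 or defect_growth < 0:
        raise ValidationError("progression rates must be non-negative")
    grown = tuple(
        dataclasses.replace(d, radius=d.radius + defect_growth)
        for d in spec.defects
    )
    return dataclasses.replace(
        spec,
        timepoint="followup",
        thinning=spec.thinning + thinning_rate,
        defects=grown,
    )


@dataclass(frozen=True)
class ReaderNoiseModel:
    """Simulated manual-tracing variability.

    ``jitter_sd``: isotropic normal jitter (mm) added independently to every
    contour point, for both polylines.  ``endpoint_misid_prob``: probability
    that the reader mis-identifies the most-medial or most-lateral slice by
    one slice.
    """

    jitter_sd: float = 0.05
    endpoint_misid_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.jitter_sd < 0:
            raise ValidationError("jitter sd must be non-negative")
        if not 0 <= self.endpoint_misid_prob <= 1:
            raise ValidationError("misidentification probability outside [0,1]")


def apply_reader_noise(cs: ContourSet, model: ReaderNoiseModel) -> ContourSet:
    """Return a jittered copy of a contour set; the original is untouched."""
    rng = np.random.default_rng(model.seed)
    medial, lateral = cs.medial_slice, cs.lateral_slice
    step = 1 if lateral > medial else -1
    if model.endpoint_misid_prob > 0:
        # an endpoint slip moves the endpoint one slice into the stack
        # (contours beyond the new endpoint are dropped, as a reader would)
        if rng.random() < model.endpoint_misid_prob:
            medial += step
        if rng.random() < model.endpoint_misid_prob:
            lateral -= step
        if medial == lateral:  # keep the set valid on tiny stacks
            medial, lateral = cs.medial_slice, cs.lateral_slice
    lo, hi = min(medial, lateral), max(medial, lateral)

    slices = []
    for sc in cs.slices:
        if not lo <= sc.slice_index <= hi:
            continue
        bb = sc.bone_boundary + rng.normal(0, model.jitter_sd, sc.bone_boundary.shape)
        cart = None
        if sc.cartilage_surface is not None:
            cart = sc.cartilage_surface + rng.normal(
                0, model.jitter_sd, sc.cartilage_surface.shape
            )
        slices.append(SliceContour(sc.slice_index, sc.bone, bb, cart))
    return ContourSet(
        knee_id=cs.knee_id,
        timepoint=cs.timepoint,
        side=cs.side,
        geometry=cs.geometry,
        slices=slices,
        medial_slice=medial,
        lateral_slice=lateral,
    )


def random_phantom_spec(
    seed: int,
    base_thickness: float | None = None,
    defects: Sequence[Defect] = (),
    **overrides,
) -> PhantomSpec:
    """A randomized but anatomically plausible phantom spec.

    Radii, arc extents, slice counts and (unless pinned) thicknesses are
    drawn from ranges typical of the medial compartment.  Used for
    ground-truth recovery sweeps.
    """
    rng = np.random.default_rng(seed)
    t_f = base_thickness if base_thickness is not None else rng.uniform(1.5, 2.8)
    t_t = base_thickness if base_thickness is not None else rng.uniform(1.5, 2.8)
    spec = PhantomSpec(
        knee_id=f"rand-{seed}",
        geometry=VoxelGeometry(
            dx=0.365, dy=0.456, dz=0.7, n_slices=int(rng.integers(21, 41))
        ),
        side=str(rng.choice(["left", "right"])),
        femur_radius=rng.uniform(18.0, 26.0),
        femur_halfangle=rng.uniform(0.55, 0.85),
        tibia_radius=rng.uniform(45.0, 75.0),
        tibia_halfangle=rng.uniform(0.18, 0.30),
        base_thickness=(("femur", t_f), ("tibia", t_t)),
        defects=tuple(defects),
        seed=seed,
    )
    return dataclasses.replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: JSN-like severity strata encoded as planted denuded-area fraction:
#: grade 0 none, 1 < 10 %, 2 ~ 10–30 %, 3 > 30 % of the map
_GRADE_DEFECT_RADIUS = {0: 0.0, 1: 0.15, 2: 0.27, 3: 0.38}
#: baseline JSN mixture of the emulated validation sample
DEFAULT_MIXTURE = (0.42, 0.30, 0.25, 0.03)
#: probability a knee in each stratum progresses over follow-up
_GRADE_PROG_PROB = (0.15, 0.25, 0.40, 0.55)


@dataclass
class CohortKnee:
    """One simulated knee: both timepoints plus truth and covariates."""

    knee_id: str
    grade: int
    spec_baseline: PhantomSpec
    spec_followup: PhantomSpec
    baseline: ContourSet
    followup: ContourSet
    truth_baseline: PhantomTruth
    truth_followup: PhantomTruth
    covariates: dict = field(default_factory=dict)


def generate_cohort(
    n_knees: int,
    mixture: Sequence[float] = DEFAULT_MIXTURE,
    seed: int = 0,
    defect_center: tuple[float, float] = (0.5, 0.5),
    defect_center_sd: float = 0.05,
    geometry: VoxelGeometry = DEFAULT_GEOMETRY,
) -> tuple[list[CohortKnee], pd.DataFrame]:
    """Simulate a severity-stratified cohort with 24-month follow-up.

    Each knee draws a JSN-like stratum from ``mixture``; higher strata get
    thinner baseline cartilage and a larger full-depth defect centred near
    ``defect_center`` in the weight-bearing region.  Progressors (stratum-
    dependent probability) thin faster and their defects grow.  Covariates
    (height, JSN/KL grades, JSW, HKA, progression flags) are generated
    consistently with the planted severity.  Fully reproducible from
    ``seed``.
    """
    if n_knees < 1:
        raise ValidationError("need at least one knee")
    mixture = np.asarray(mixture, dtype=float)
    if mixture.ndim != 1 or len(mixture) != 4 or np.any(mixture < 0):
        raise ValidationError("mixture must be 4 non-negative weights")
    if mixture.sum() <= 0:
        raise ValidationError("mixture weights must not all be zero")
    mixture = mixture / mixture.sum()

    rng = np.random.default_rng(seed)
    knees: list[CohortKnee] = []
    rows = []
    for j in range(n_knees):
        grade = int(rng.choice(4, p=mixture))
        t0_f = float(np.clip(rng.normal(2.4 - 0.25 * grade, 0.15), 0.8, 3.5))
        t0_t = float(np.clip(rng.normal(2.2 - 0.25 * grade, 0.15), 0.8, 3.5))
        defects: tuple[Defect, ...] = ()
        if grade > 0:
            cu = float(np.clip(rng.normal(defect_center[0], defect_center_sd), 0.05, 0.95))
            cv = float(np.clip(rng.normal(defect_center[1], defect_center_sd), 0.05, 0.95))
            r = _GRADE_DEFECT_RADIUS[grade] * float(rng.uniform(0.9, 1.1))
            depth = max(t0_f, t0_t) + 1.0  # full-depth: exposes bone
            defects = (
                Defect("femur", cu, cv, r, depth),
                Defect("tibia", cu, cv, r * 0.9, depth),
            )
        spec_b = PhantomSpec(
            knee_id=f"K{j:03d}",
            side="left" if rng.random() < 0.5 else "right",
            geometry=geometry,
            base_thickness=(("femur", t0_f), ("tibia", t0_t)),
            defects=defects,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        progressor = bool(rng.random() < _GRADE_PROG_PROB[grade])
        if progressor:
            thin = float(rng.uniform(0.10, 0.22))
            growth = float(rng.uniform(0.03, 0.07)) if defects else 0.0
        else:
            thin = float(rng.uniform(0.01, 0.06))
            growth = 0.0
        spec_f = progress_phantom(spec_b, thinning_rate=thin, defect_growth=growth)

        cs_b, truth_b = generate_phantom(spec_b)
        cs_f, truth_f = generate_phantom(spec_f)

        height = float(np.clip(rng.normal(1.69, 0.09), 1.40, 2.05))
        kl = int(np.clip(grade + 1 + (rng.random() < 0.2), 0, 4)) if grade > 0 \
            else int(rng.random() < 0.4)
        jsn_fu = min(grade + 1, 3) if progressor else grade
        kl_prog = progressor or (rng.random() < 0.10)
        kl_fu = min(kl + 1, 4) if kl_prog else kl
        jsw = float(np.clip(rng.normal(4.6 - 1.2 * grade, 0.4), 0.3, 7.0))
        jsw_change = float(rng.normal(-0.6 if progressor else -0.1, 0.15))
        hka = float(rng.normal(-0.5 - 1.6 * grade, 1.8))  # varus negative

        cov = dict(
            knee_id=spec_b.knee_id,
            height_m=height,
            jsn_grade=grade,
            jsn_grade_followup=jsn_fu,
            kl_grade=kl,
            kl_grade_followup=kl_fu,
            jsn_progression=jsn_fu != grade,
            kl_progression=kl_fu != kl,
            jsw_mm=jsw,
            jsw_change_mm=jsw_change,
            hka_deg=hka,
        )
        rows.append(cov)
        knees.append(
            CohortKnee(
                knee_id=spec_b.knee_id,
                grade=grade,
                spec_baseline=spec_b,
                spec_followup=spec_f,
                baseline=cs_b,
                followup=cs_f,
                truth_baseline=truth_b,
                truth_followup=truth_f,
                covariates=cov,
            )
        )
    return knees, pd.DataFrame(rows)
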