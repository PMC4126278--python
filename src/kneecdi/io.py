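"""File formats: contour-set JSON, location tables, tidy result tables.

Contour sets travel as JSON with explicit slice indices and millimetre
coordinates, so the medial/lateral and anterior/posterior conventions are
self-describing::

    {"knee_id": ..., "timepoint": "baseline", "side": "left",
     "geometry": {"dx": 0.365, "dy": 0.456, "dz": 0.7, "n_slices": 31},
     "medial_slice": 0, "lateral_slice": 30,
     "slices": [{"slice_index": 0, "bone": "femur",
                 "bone_boundary": [[x, y], ...],
                 "cartilage_surface": [[x, y], ...]}, ...]}

``cartilage_surface`` may be omitted on a slice (boundary-only: loaded
but flagged, thickness unmeasurable there).  Writing then reading a set
round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cdi import CDIResult, REGIONS
from .errors import SchemaError, ValidationError
from .geometry import (
    ContourSet,
    InformativeLocation,
    InformativeLocationSet,
    SliceContour,
    SurfaceCoordinate,
    VoxelGeometry,
)

_REQUIRED_TOP = (
    "knee_id",
    "timepoint",
    "side",
    "geometry",
    "medial_slice",
    "lateral_slice",
    "slices",
)
_REQUIRED_GEOM = ("dx", "dy", "dz", "n_slices")
_REQUIRED_SLICE = ("slice_index", "bone", "bone_boundary")


def read_contour_set(path: str | Path) -> ContourSet:
    """Load and validate a contour-set JSON file.

    Schema violations raise :class:`SchemaError` naming the offending
    field; invariant violations (e.g. ``medial_slice == lateral_slice``)
    raise :class:`ValidationError` from the domain types.
    """
    path = Path(path)
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    for key in _REQUIRED_TOP:
        if key not in doc:
            raise SchemaError(f"{path}: missing field {key!r}", field=key)
    g = doc["geometry"]
    for key in _REQUIRED_GEOM:
        if key not in g:
            raise SchemaError(
                f"{path}: geometry missing field {key!r}", field=f"geometry.{key}"
            )
    slices = []
    for k, s in enumerate(doc["slices"]):
        for key in _REQUIRED_SLICE:
            if key not in s:
                raise SchemaError(
                    f"{path}: slices[{k}] missing field {key!r}",
                    field=f"slices[{k}].{key}",
                )
        slices.append(
            SliceContour(
                slice_index=int(s["slice_index"]),
                bone=s["bone"],
                bone_boundary=np.asarray(s["bone_boundary"], dtype=float),
                cartilage_surface=(
                    np.asarray(s["cartilage_surface"], dtype=float)
                    if s.get("cartilage_surface") is not None
                    else None
                ),
            )
        )
    return ContourSet(
        knee_id=str(doc["knee_id"]),
        timepoint=doc["timepoint"],
        side=doc["side"],
        geometry=VoxelGeometry(
            dx=float(g["dx"]), dy=float(g["dy"]), dz=float(g["dz"]),
            n_slices=int(g["n_slices"]),
        ),
        slices=slices,
        medial_slice=int(doc["medial_slice"]),
        lateral_slice=int(doc["lateral_slice"]),
    )


def write_contour_set(cs: ContourSet, path: str | Path) -> None:
    """Write a contour set as schema JSON (coordinates in mm)."""
    doc = {
        "knee_id": cs.knee_id,
        "timepoint": cs.timepoint,
        "side": cs.side,
        "geometry": {
            "dx": cs.geometry.dx,
            "dy": cs.geometry.dy,
            "dz": cs.geometry.dz,
            "n_slices": cs.geometry.n_slices,
        },
        "medial_slice": cs.medial_slice,
        "lateral_slice": cs.lateral_slice,
        "slices": [
            {
                "slice_index": sc.slice_index,
                "bone": sc.bone,
                "bone_boundary": sc.bone_boundary.tolist(),
                **(
                    {"cartilage_surface": sc.cartilage_surface.tolist()}
                    if sc.cartilage_surface is not None
                    else {}
                ),
            }
            for sc in cs.slices
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_locations(path: str | Path) -> InformativeLocationSet:
    """Load an informative-location table from JSON."""
    with open(path) as fh:
        doc = json.load(fh)
    if "locations" not in doc:
        raise SchemaError(f"{path}: missing field 'locations'", field="locations")
    locs = []
    for k, row in enumerate(doc["locations"]):
        for key in ("name", "bone", "u", "v"):
            if key not in row:
                raise SchemaError(
                    f"{path}: locations[{k}] missing field {key!r}",
                    field=f"locations[{k}].{key}",
                )
        locs.append(
            InformativeLocation(
                str(row["name"]), row["bone"],
                SurfaceCoordinate(float(row["u"]), float(row["v"])),
            )
        )
    return InformativeLocationSet(locs, provenance=doc.get("provenance", "user"))


def write_locations(locs: InformativeLocationSet, path: str | Path) -> None:
    doc = {
        "provenance": locs.provenance,
        "locations": [
            {"name": l.name, "bone": l.bone, "u": l.coord.u, "v": l.coord.v}
            for l in locs.locations
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def results_table(results: list[CDIResult]) -> pd.DataFrame:
    """Tidy table: one row per knee-timepoint-region, 2-dp reporting."""
    if not results:
        raise ValidationError("no results to tabulate")
    rows = []
    for r in results:
        for region in REGIONS:
            rows.append(
                {
                    "knee_id": r.knee_id,
                    "timepoint": r.timepoint,
                    "region": region,
                    "cdi_mm3": round(r.region(region), 2),
                    "cdi_height_adjusted": (
                        round(r.region(region, adjusted=True), 2)
                        if r.adjusted
                        else np.nan
                    ),
                    "n_flagged_locations": len(r.flags),
                }
            )
    return pd.DataFrame(rows)


def write_results(
    results: list[CDIResult],
    csv_path: str | Path,
    samples_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the tidy CDI table (CSV) and per-location samples (JSON)."""
    table = results_table(results)
    table.to_csv(csv_path, index=False)
    if samples_path is not None:
        doc = [
            {
                "knee_id": r.knee_id,
                "timepoint": r.timepoint,
                "flags": r.flags,
                "samples": [
                    {
                        "location": s.location,
                        "bone": s.bone,
                        "slice_index": s.slice_index,
                        "thickness_mm": round(s.thickness, 4),
                        "cartilage_length_mm": round(s.cartilage_length, 4),
                        "measurable": s.measurable,
                    }
                    for s in r.samples
                ],
            }
            for r in results
        ]
        with open(samples_path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return table


@dataclass
class RunConfig:
    """Validated knobs for a measurement run."""

    voxel_mode: str = "dz"
    search_cap_mm: float = 15.0
    length_step_mm: float = 0.2
    ttest_variant: str = "welch"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.voxel_mode not in ("dz", "dxdy"):
            raise ValidationError(f"unknown voxel_mode {self.voxel_mode!r}")
        if self.search_cap_mm <= 0 or self.length_step_mm <= 0:
            raise ValidationError("search cap and length step must be positive")
        if self.ttest_variant not in ("welch", "pooled"):
            raise ValidationError(f"unknown t-test variant {self.ttest_variant!r}")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
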