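"""Typed error signals used across the package.

Undefined statistics and unmeasurable geometry raise these instead of
returning sentinel numbers, so callers can distinguish "the quantity does
not exist for this input" from "the computation failed".
"""


class KneeCDIError(Exception):
    """Base class for all package errors."""


class ValidationError(KneeCDIError):
    """An input violates a documented invariant."""


class DegenerateContourError(ValidationError):
    """A polyline is too short, zero-length, or self-intersecting."""


class SchemaError(ValidationError):
    """A file does not match the contour-set JSON schema.

    Carries the name of the offending field in ``field``.
    """

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class UnmeasurableLocationError(KneeCDIError):
    """An informative location cannot be resolved on this knee.

    Carries ``knee_id`` and ``location`` so pipelines can log and continue.
    """

    def __init__(self, message: str, knee_id: str = "", location: str = ""):
        super().__init__(message)
        self.knee_id = knee_id
        self.location = location


class EmptyMeasurementError(KneeCDIError):
    """Every informative location of a bone was unmeasurable."""


class UndefinedStatisticError(KneeCDIError):
    """A statistic is undefined for this sample (e.g. zero variance)."""


class NoDenudedRegionError(KneeCDIError):
    """A denuded-frequency map is all zero; no region to select from."""
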