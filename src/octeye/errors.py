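"""Exception hierarchy shared across the pipeline stages."""


class OcteyeError(Exception):
    """Base class for all octeye errors."""


class GeometryError(OcteyeError):
    """An eye geometry violates an anatomical invariant (surface ordering,
    non-positive thickness, iris outside its wing bounds, ...)."""


class ScheduleError(OcteyeError):
    """A time point falls outside an osmotic scenario's schedule."""


class TruncationError(OcteyeError):
    """The requested image is too shallow to contain the retina at its
    optical-path depth; rendering refuses rather than silently clipping."""


class DetectionError(OcteyeError):
    """Surface detection failed (no cornea found, empty image, ...)."""


class MeasurementError(OcteyeError):
    """A biometric parameter could not be computed from the available
    surfaces (missing trace at the AP axis, empty sampling window, ...)."""
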