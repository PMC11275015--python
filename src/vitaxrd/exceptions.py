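"""Exception hierarchy for the vitaxrd pipeline.

Every stage raises a subclass of :class:`VitaxrdError`, so callers can
distinguish pipeline failures from programming errors.
"""


class VitaxrdError(Exception):
    """Base class for all vitaxrd errors."""


class DomainError(VitaxrdError):
    """Input outside the mathematical domain of a mapping (e.g. r/D > 1)."""


# --- frame validation / centre finding -----------------------------------

class EmptyFrame(VitaxrdError):
    """Frame total counts below the emptiness floor."""


class NoDefinedCenter(VitaxrdError):
    """Beam-centre refinement did not converge to a defined centre."""


# --- calibration ----------------------------------------------------------

class NoRingsFound(VitaxrdError):
    """No calibrant rings detected in the radial profile."""


class AmbiguousOrderAssignment(VitaxrdError):
    """No diffraction-order assignment fits the detected rings."""


# --- reduction ------------------------------------------------------------

class ShapeMismatch(VitaxrdError):
    """Two frames have incompatible pixel dimensions."""


class GeometryMismatch(VitaxrdError):
    """Two frames were recorded at different nominal geometries."""


class CenterOutsideFrame(VitaxrdError):
    """Requested integration centre lies outside the detector."""


# --- harmonization --------------------------------------------------------

class UnknownGeometry(VitaxrdError):
    """Profile carries no recognised nominal geometry tag."""


class NoOverlap(VitaxrdError):
    """Profiles share no common q-range."""


class TooFewSamples(VitaxrdError):
    """Not enough samples for the requested statistic."""


# --- biomarkers -----------------------------------------------------------

class WindowOutsideRange(VitaxrdError):
    """Peak search window does not intersect the profile's q-range."""


class NoSamplesForLabel(VitaxrdError):
    """No samples carry the requested diagnosis label."""


# --- classification -------------------------------------------------------

class TooFewPatients(VitaxrdError):
    """Fewer than two patients in some class; cannot split."""


class SingleClassTrain(VitaxrdError):
    """Training set contains a single class."""


class SingleClassTest(VitaxrdError):
    """Test set contains a single class; ROC undefined."""


# --- workbench ------------------------------------------------------------

class PipelineError(VitaxrdError):
    """Stage failure with context about which stage and frame failed."""

    def __init__(self, stage: str, message: str, frame_id: str | None = None):
        self.stage = stage
        self.frame_id = frame_id
        ctx = f"[stage={stage}" + (f", frame={frame_id}" if frame_id else "") + "]"
        super().__init__(f"{ctx} {message}")
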