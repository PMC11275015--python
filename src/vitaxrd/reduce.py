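"""Frame validation, background subtraction, and azimuthal integration.

A 2D isotropic scattering pattern carries its information in the radial
direction only; averaging over azimuth around the beam centre turns each
frame into a 1D intensity-vs-radius profile, subsequently mapped to
momentum transfer q.  Intensity is reported as the *mean* counts per pixel
in each annulus, so profiles from different geometries are comparable;
``n_pixels`` preserves the bookkeeping needed to recover annulus sums.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._annulus import annular_stats
from .exceptions import (
    CenterOutsideFrame,
    EmptyFrame,
    GeometryMismatch,
    NoDefinedCenter,
    ShapeMismatch,
)
from .geometry import BeamGeometry, CenterEstimate, DetectorSpec, find_beam_center, pixel_to_q


@dataclass
class DetectorImage:
    """One diffractogram: a photon-count frame plus cohort metadata.

    ``counts`` is non-negative; integer for raw frames, float after
    background subtraction.  ``geometry`` is the nominal distance tag
    ("2cm" or "16cm"); ``label`` is the patient diagnosis.
    """

    counts: np.ndarray
    frame_id: str = ""
    patient_id: str = ""
    specimen_id: str = ""
    spot: int = 0
    geometry: str = ""
    label: str = "unknown"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2D array")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class PixelProfile:
    """Azimuthally averaged profile on a pixel-radius grid."""

    bin_index: np.ndarray      # annulus numbers with ≥1 member pixel
    radius_px: np.ndarray      # bin midpoints, (k + 0.5) * bin_width
    intensity: np.ndarray      # mean counts per pixel in the annulus
    n_pixels: np.ndarray
    sums: np.ndarray           # accumulated counts per annulus (exact)
    bin_width: float
    frame_id: str = ""


@dataclass
class RadialProfile:
    """1D intensity versus momentum transfer q (nm⁻¹)."""

    q: np.ndarray
    intensity: np.ndarray
    n_pixels: np.ndarray
    frame_id: str = ""
    geometry: str = ""
    mapping_mode: str = ""
    patient_id: str = ""
    label: str = "unknown"

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.n_pixels = np.asarray(self.n_pixels)
        if not (len(self.q) == len(self.intensity) == len(self.n_pixels)):
            raise ValueError("q, intensity, n_pixels must have equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.intensity))):
            raise ValueError("profile contains NaN/Inf")


@dataclass
class FrameValidation:
    keep: bool
    reason: str = ""
    center: CenterEstimate | None = None


def validate_frame(image: DetectorImage, min_total_counts: float = 100.0,
                   **center_kwargs) -> FrameValidation:
    """Apply the cleaning rule: drop frames that are empty or centre-less.

    Never raises; the drop reason is "empty" (counts below floor) or
    "no_center" (beam-centre search failed).  Kept frames carry the fitted
    centre so downstream stages reuse it.
    """
    try:
        est = find_beam_center(image, min_total_counts=min_total_counts, **center_kwargs)
    except EmptyFrame:
        return FrameValidation(False, "empty")
    except NoDefinedCenter:
        return FrameValidation(False, "no_center")
    return FrameValidation(True, "", est)


def subtract_background(image: DetectorImage, background: DetectorImage) -> DetectorImage:
    """Pixel-wise sample − empty-holder background, clipped at zero counts."""
    if image.counts.shape != background.counts.shape:
        raise ShapeMismatch(
            f"{image.counts.shape} vs {background.counts.shape}"
        )
    if image.geometry and background.geometry and image.geometry != background.geometry:
        raise GeometryMismatch(f"{image.geometry} vs {background.geometry}")
    corrected = np.clip(
        image.counts.astype(float) - background.counts.astype(float), 0.0, None
    )
    return replace(image, counts=corrected)


def azimuthal_integrate(
    image: DetectorImage,
    center: tuple[float, float],
    bin_width: float = 1.0,
    mask: np.ndarray | None = None,
) -> PixelProfile:
    """Average the frame over azimuth into 1-pixel-wide annuli.

    Pixels flagged True in ``mask`` (e.g. behind the beamstop) are excluded
    from both sums and counts; annuli with zero member pixels are dropped.
    """
    counts = image.counts
    n_rows, n_cols = counts.shape
    if not (0.0 <= center[0] <= n_rows and 0.0 <= center[1] <= n_cols):
        raise CenterOutsideFrame(f"center {center} outside {counts.shape}")
    sums, npix = annular_stats(counts, center, bin_width, mask)
    valid = npix > 0
    idx = np.nonzero(valid)[0]
    return PixelProfile(
        bin_index=idx,
        radius_px=(idx + 0.5) * bin_width,
        intensity=sums[valid] / npix[valid],
        n_pixels=npix[valid],
        sums=sums[valid],
        bin_width=bin_width,
        frame_id=image.frame_id,
    )


def to_q_profile(
    pixel_profile: PixelProfile,
    geometry: BeamGeometry,
    detector: DetectorSpec,
    patient_id: str = "",
    label: str = "unknown",
    geometry_tag: str = "",
) -> RadialProfile:
    """Map a pixel-radius profile onto momentum transfer.

    Each annulus is represented by its midpoint radius; intensities carry
    over unchanged.  Monotonicity of the mapping guarantees a strictly
    increasing q grid.
    """
    r_mm = pixel_profile.radius_px * detector.pixel_pitch_mm
    q = pixel_to_q(r_mm, geometry)
    return RadialProfile(
        q=q,
        intensity=pixel_profile.intensity,
        n_pixels=pixel_profile.n_pixels,
        frame_id=pixel_profile.frame_id,
        geometry=geometry_tag,
        mapping_mode=geometry.mapping_mode,
        patient_id=patient_id,
        label=label,
    )


def beamstop_mask(shape: tuple[int, int], center: tuple[float, float],
                  radius_px: float) -> np.ndarray:
    """Boolean mask (True = exclude) for pixels behind a central beamstop."""
    from ._annulus import pixel_radii

    return pixel_radii(shape, center) < radius_px
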