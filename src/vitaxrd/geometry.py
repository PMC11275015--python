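"""Detector geometry: beam-centre finding, distance calibration, pixel→q.

The momentum-transfer magnitude is q = (4π sin θ)/λ with 2θ the scattering
angle.  Two conventions relate the pixel-to-centre distance r to 2θ:

``paper_sin``
    sin 2θ = r/D — the convention stated by the study this pipeline
    reproduces; default everywhere.
``exact_tan``
    tan 2θ = r/D — the exact flat-detector relation, provided for
    comparison.

Both are strictly increasing in r and agree to first order at small angle.
One run must use a single mode end to end (simulation, calibration,
reduction); mixing modes shifts recovered peak positions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import find_peaks

from ._annulus import annular_stats, pixel_radii
from .exceptions import (
    AmbiguousOrderAssignment,
    DomainError,
    EmptyFrame,
    NoDefinedCenter,
    NoRingsFound,
)

MAPPING_MODES = ("paper_sin", "exact_tan")


@dataclass(frozen=True)
class DetectorSpec:
    """Pixelated photon-counting detector: square grid, square pixels."""

    n_rows: int = 256
    n_cols: int = 256
    pixel_pitch_mm: float = 0.055

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("detector must have at least one pixel")
        if self.pixel_pitch_mm <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


@dataclass(frozen=True)
class BeamGeometry:
    """Everything needed to map a pixel to momentum transfer.

    center_row/center_col are fractional pixel coordinates in the convention
    where pixel (i, j) has centre (i + 0.5, j + 0.5); distance_D_mm is the
    sample-to-detector distance; wavelength 0.154 nm is Cu Kα.
    """

    center_row: float
    center_col: float
    distance_D_mm: float
    wavelength_nm: float = 0.154
    mapping_mode: str = "paper_sin"

    def __post_init__(self):
        if self.distance_D_mm <= 0:
            raise ValueError("sample-to-detector distance must be positive")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        if self.mapping_mode not in MAPPING_MODES:
            raise ValueError(f"mapping_mode must be one of {MAPPING_MODES}")


@dataclass(frozen=True)
class CalibrantSpec:
    """Powder calibrant with known d-spacings (nm), largest first."""

    name: str
    d_spacings_nm: tuple[float, ...]

    def __post_init__(self):
        d = self.d_spacings_nm
        if len(d) < 1:
            raise ValueError("calibrant needs at least one d-spacing")
        if any(x <= 0 for x in d):
            raise ValueError("d-spacings must be positive")
        if any(d[i] <= d[i + 1] for i in range(len(d) - 1)):
            raise ValueError("d-spacings must be strictly decreasing")

    @property
    def q_orders(self) -> np.ndarray:
        """Ring positions 2π/d in nm⁻¹, ascending."""
        return 2.0 * np.pi / np.asarray(self.d_spacings_nm)


def load_agbh() -> CalibrantSpec:
    """Silver behenate: layered standard, d001 = 5.8380 nm, harmonic orders."""
    with resources.files("vitaxrd.data").joinpath("agbh.json").open() as fh:
        payload = json.load(fh)
    d001 = float(payload["d001_nm"])
    n = int(payload["n_orders"])
    return CalibrantSpec(payload["name"], tuple(d001 / k for k in range(1, n + 1)))


# --------------------------------------------------------------------------
# pixel <-> q mapping
# --------------------------------------------------------------------------

def q_from_d(d_nm):
    """Momentum transfer of a periodicity d: q = 2π/d (nm⁻¹)."""
    d = np.asarray(d_nm, dtype=float)
    if np.any(d <= 0):
        raise DomainError("d-spacing must be positive")
    out = 2.0 * np.pi / d
    return float(out) if np.isscalar(d_nm) else out


def pixel_to_q(r_mm, geometry: BeamGeometry):
    """Map radial distance on the detector (mm) to q (nm⁻¹)."""
    r = np.asarray(r_mm, dtype=float)
    if np.any(r < 0):
        raise DomainError("radius must be non-negative")
    ratio = r / geometry.distance_D_mm
    if geometry.mapping_mode == "paper_sin":
        if np.any(ratio > 1.0):
            raise DomainError("r/D > 1: sin 2θ = r/D undefined")
        two_theta = np.arcsin(ratio)
    else:
        two_theta = np.arctan(ratio)
    q = 4.0 * np.pi * np.sin(two_theta / 2.0) / geometry.wavelength_nm
    return float(q) if np.isscalar(r_mm) else q


def q_to_radius_mm(q_nm, geometry: BeamGeometry):
    """Inverse of :func:`pixel_to_q`: detector radius (mm) of a ring at q."""
    q = np.asarray(q_nm, dtype=float)
    if np.any(q < 0):
        raise DomainError("q must be non-negative")
    s = q * geometry.wavelength_nm / (4.0 * np.pi)
    if np.any(s > 1.0):
        raise DomainError("q beyond backscattering limit")
    two_theta = 2.0 * np.arcsin(s)
    if geometry.mapping_mode == "paper_sin":
        if np.any(two_theta > np.pi / 2):
            raise DomainError("2θ > 90°: not representable with sin 2θ = r/D")
        r = geometry.distance_D_mm * np.sin(two_theta)
    else:
        if np.any(two_theta >= np.pi / 2):
            raise DomainError("2θ ≥ 90°: beyond a flat detector")
        r = geometry.distance_D_mm * np.tan(two_theta)
    return float(r) if np.isscalar(q_nm) else r


def max_q(geometry: BeamGeometry, detector: DetectorSpec) -> float:
    """Largest q reachable on the detector (distance to the farthest corner)."""
    corners_r = [0.5, detector.n_rows - 0.5]
    corners_c = [0.5, detector.n_cols - 0.5]
    r_px = max(
        math.hypot(cr - geometry.center_row, cc - geometry.center_col)
        for cr in corners_r
        for cc in corners_c
    )
    return pixel_to_q(r_px * detector.pixel_pitch_mm, geometry)


# --------------------------------------------------------------------------
# beam-centre finding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CenterEstimate:
    row: float
    col: float
    quality: float  # R² of the radial (annulus-mean) model at the refined centre


def _counts_of(image) -> np.ndarray:
    return np.asarray(getattr(image, "counts", image), dtype=float)


def _marginal_symmetry_center(marginal: np.ndarray, min_halfspan: int = 24) -> float:
    """Mirror-symmetry point of a 1D marginal profile (pixel-centre coords).

    Scores every candidate position by the mean squared difference between
    the profile and its reflection over the largest in-bounds half-span,
    normalised by the window's variance so flat near-edge stretches cannot
    masquerade as symmetry points; smoothing suppresses Poisson noise.
    """
    m = uniform_filter(marginal.astype(float), size=5, mode="nearest")
    n = len(m)
    lo, hi = min_halfspan, n - min_halfspan
    if lo >= hi:
        return n / 2.0
    best_c, best_s = n / 2.0, np.inf
    for c in range(lo, hi):
        t = min(c, n - 1 - c)
        left = m[c - t : c + 1][::-1]
        right = m[c : c + t + 1]
        both = np.concatenate([left, right])
        var = float(both.var())
        if var <= 0:
            continue
        s = float(np.mean((left - right) ** 2)) / var
        if s < best_s:
            best_s, best_c = s, c
    return best_c + 0.5


def _global_coarse_center(counts: np.ndarray, factor: int = 4
                          ) -> tuple[float, float]:
    """Exhaustive coarse centre scan on a block-summed frame.

    Fallback for patterns whose marginals have false mirror points (e.g.
    many-ring calibrants, which are locally periodic): scores every ~4 px
    candidate over the whole frame by within-annulus variance of the
    downsampled image and returns the best, in full-resolution pixel
    coordinates.
    """
    n_rows, n_cols = counts.shape
    nr, nc = n_rows // factor, n_cols // factor
    small = counts[: nr * factor, : nc * factor].reshape(
        nr, factor, nc, factor).sum(axis=(1, 3))
    rows = np.arange(nr, dtype=float) + 0.5
    cols = np.arange(nc, dtype=float) + 0.5
    best = (np.inf, nr / 2.0, nc / 2.0)
    for cr in np.arange(2.0, nr - 2.0, 1.0):
        for cc in np.arange(2.0, nc - 2.0, 1.0):
            ssw, _ = _symmetry_score(small, rows, cols, cr, cc, float(max(nr, nc)))
            if ssw < best[0]:
                best = (ssw, cr, cc)
    return best[1] * factor, best[2] * factor


def _symmetry_score(sub: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                    cr: float, cc: float, max_r: float) -> tuple[float, float]:
    """(within-annulus SS, total SS) for a candidate centre over a crop."""
    r = np.hypot(rows[:, None] - cr, cols[None, :] - cc)
    bins = r.astype(np.intp).ravel()
    vals = sub.ravel()
    n = np.bincount(bins)
    s = np.bincount(bins, weights=vals)
    s2 = np.bincount(bins, weights=vals * vals)
    idx = np.arange(n.size)
    valid = (n >= 8) & (idx <= max_r)
    nv, sv, s2v = n[valid], s[valid], s2[valid]
    ss_within = float(np.sum(s2v - sv * sv / nv))
    n_tot = int(nv.sum())
    grand = sv.sum() / n_tot
    ss_total = float(s2v.sum() - n_tot * grand * grand)
    return ss_within, ss_total


def find_beam_center(
    image,
    min_total_counts: float = 100.0,
    window_half: int = 64,
    min_structure: float = 0.02,
) -> CenterEstimate:
    """Locate the beam centre of a (nearly) isotropic scattering frame.

    The intensity-weighted centroid of the whole frame seeds a
    coarse-to-fine grid search that minimises the within-annulus variance
    (an isotropic pattern is constant on annuli about the true centre);
    the coarse stage spans ±12 px to absorb centroid bias when the pattern
    is clipped by the detector edge.  Raises :class:`EmptyFrame` below the
    counts floor and :class:`NoDefinedCenter` when the coarse search hits
    its box boundary or the frame shows no radial structure (flat noise).
    """
    counts = _counts_of(image)
    total = counts.sum()
    if total < min_total_counts:
        raise EmptyFrame(f"total counts {total:.0f} < floor {min_total_counts:.0f}")

    n_rows, n_cols = counts.shape
    # Seed: an isotropic pattern's row marginal is symmetric about the true
    # centre row even when the detector clips the pattern in columns (the
    # column window is the same for every row), and vice versa — so each
    # coordinate is the mirror-symmetry point of the smoothed 1D marginal.
    seed = (_marginal_symmetry_center(counts.sum(axis=1)),
            _marginal_symmetry_center(counts.sum(axis=0)))

    def crop_around(center):
        rlo = max(0, int(round(center[0])) - window_half)
        rhi = min(n_rows, int(round(center[0])) + window_half)
        clo = max(0, int(round(center[1])) - window_half)
        chi = min(n_cols, int(round(center[1])) + window_half)
        sub = counts[rlo:rhi, clo:chi]
        rows = np.arange(rlo, rhi, dtype=float) + 0.5
        cols = np.arange(clo, chi, dtype=float) + 0.5
        return sub, rows, cols

    def best_over(crop, deltas, base):
        sub, rows, cols = crop
        results = []
        for dr in deltas:
            for dc in deltas:
                ssw, sst = _symmetry_score(sub, rows, cols,
                                           base[0] + dr, base[1] + dc,
                                           float(window_half))
                results.append((ssw, sst, dr, dc))
        results.sort(key=lambda t: t[0])
        return results[0]

    def attempt(start):
        crop = crop_around(start)
        coarse = np.arange(-6.0, 6.01, 2.0)
        ssw, sst, dr, dc = best_over(crop, coarse, start)
        if abs(dr) >= coarse[-1] or abs(dc) >= coarse[-1]:
            raise NoDefinedCenter("centre refinement hit the search-box boundary")
        base = (start[0] + dr, start[1] + dc)
        for deltas in (np.arange(-1.5, 1.51, 0.5),
                       np.arange(-0.375, 0.376, 0.125),
                       np.arange(-0.1, 0.101, 0.05)):
            ssw, sst, dr, dc = best_over(crop, deltas, base)
            base = (base[0] + dr, base[1] + dc)
        quality = 1.0 - ssw / sst if sst > 0 else 0.0
        if quality < min_structure:
            raise NoDefinedCenter(
                f"no radial structure (R²={quality:.4f} < {min_structure})"
            )
        return CenterEstimate(base[0], base[1], quality)

    try:
        return attempt(seed)
    except NoDefinedCenter:
        # marginal seed can lock onto a false mirror point of a locally
        # periodic (many-ring) pattern; retry from a global coarse scan
        return attempt(_global_coarse_center(counts))


# --------------------------------------------------------------------------
# sample-to-detector distance calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationResult:
    distance_mm: float
    residual: float           # rms(r − D·s) / rms(r) over assigned rings
    first_order: int          # diffraction order assigned to the innermost ring
    ring_radii_px: tuple[float, ...]


def _detect_ring_radii(profile: np.ndarray, counts: np.ndarray,
                       min_radius_px: float) -> np.ndarray:
    """Peak radii (px, sub-pixel) of a pixel-radius calibrant profile."""
    valid = counts > 0
    m = np.where(valid, profile, 0.0)
    scale = float(m.max() - np.median(m[valid])) if valid.any() else 0.0
    if scale <= 0:
        return np.empty(0)
    peaks, _ = find_peaks(m, prominence=0.05 * scale, distance=3)
    peaks = peaks[peaks >= min_radius_px]
    # the background apex at the beamstop edge mimics a ring; a real ring
    # never has a near-zero left flank
    peaks = [p for p in peaks
             if p < 3 or np.min(m[p - 3 : p]) > 0.02 * m[p]]
    radii = []
    for p in peaks:
        # parabolic sub-pixel refinement through the three points around the max
        if 0 < p < len(m) - 1:
            y0, y1, y2 = m[p - 1], m[p], m[p + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        radii.append(p + 0.5 + delta)  # bin p midpoint is p + 0.5
    return np.asarray(radii)


def calibrate_distance(
    calibrant_image,
    calibrant: CalibrantSpec,
    center: tuple[float, float],
    detector: DetectorSpec,
    wavelength_nm: float = 0.154,
    mapping_mode: str = "paper_sin",
    max_first_order: int = 5,
    rel_tol: float = 0.02,
    min_radius_px: float = 5.0,
) -> CalibrationResult:
    """Fit the sample-to-detector distance from a calibrant frame.

    Detects ring radii in the pixel-radius profile, tries assigning the
    innermost detected ring to diffraction orders 1..max_first_order
    (subsequent rings take consecutive orders), and keeps the assignment
    whose through-origin least-squares fit r = D·s(q_n) has the smallest
    relative residual; ties break toward the smaller first order.
    """
    counts = _counts_of(calibrant_image)
    sums, npix = annular_stats(counts, center, 1.0)
    with np.errstate(invalid="ignore"):
        profile = np.where(npix > 0, sums / np.maximum(npix, 1), 0.0)
    radii_px = _detect_ring_radii(profile, npix, min_radius_px)
    if radii_px.size == 0:
        raise NoRingsFound("no peaks in the calibrant radial profile")

    r_mm = radii_px * detector.pixel_pitch_mm
    q_orders = calibrant.q_orders
    sin_theta = q_orders * wavelength_nm / (4.0 * np.pi)
    two_theta = 2.0 * np.arcsin(np.clip(sin_theta, 0, 1))
    s_all = np.sin(two_theta) if mapping_mode == "paper_sin" else np.tan(two_theta)

    best = None
    for m0 in range(1, max_first_order + 1):
        hi = m0 - 1 + len(r_mm)
        if hi > len(s_all):
            break
        s = s_all[m0 - 1 : hi]
        if np.any(s <= 0):
            continue
        D = float(np.sum(r_mm * s) / np.sum(s * s))
        resid = float(np.sqrt(np.mean((r_mm - D * s) ** 2) / np.mean(r_mm**2)))
        if best is None or resid < best[0] - 1e-12:
            best = (resid, m0, D)
    if best is None:
        raise AmbiguousOrderAssignment("no feasible order assignment")
    resid, m0, D = best
    if resid > rel_tol:
        raise AmbiguousOrderAssignment(
            f"best assignment (first order {m0}) residual {resid:.3g} > {rel_tol}"
        )
    return CalibrationResult(D, resid, m0, tuple(float(x) for x in radii_px))
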