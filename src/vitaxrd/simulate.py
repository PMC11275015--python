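"""Synthetic Debye–Scherrer frames emulating a two-geometry tissue cohort.

The generator renders isotropic powder-diffraction patterns: a smooth
exponentially decaying amorphous background plus Gaussian rings in q, with
independent Poisson counting noise per pixel.  Cohort structure mirrors the
study design this pipeline targets: 107 patients (60 cancer / 47
non-cancer), two specimens per patient — one measured at a nominal 2 cm
(wide-angle) and one at 16 cm (small-angle) sample-to-detector distance —
and 10 spots per specimen.

Class-conditional ring templates encode the lipid biomarkers: non-cancer
tissue shows a strong triglyceride-packing ring at 1.5 nm⁻¹ (16 cm) and a
strong inter-fatty-acid ring at 13.9 nm⁻¹ (2 cm); cancer tissue suppresses
both while the water-structure ring at 20.2 nm⁻¹ gains relative weight.
A multiplicative log-normal patient effect on peak amplitudes makes the
classes overlap, so classification is non-trivial.

Per-frame random streams are derived from the root seed by stable hashing
of (patient, specimen, spot), so changing cohort composition does not
reshuffle unrelated frames.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._annulus import pixel_radii
from .geometry import (
    BeamGeometry,
    CalibrantSpec,
    DetectorSpec,
    max_q,
    pixel_to_q,
)
from .reduce import DetectorImage


# --------------------------------------------------------------------------
# ring model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RingPeak:
    """One isotropic diffraction ring: Gaussian in q."""

    q_center: float    # nm⁻¹
    width: float       # Gaussian sigma, nm⁻¹
    amplitude: float   # expected counts/pixel at the peak (before rescaling)

    def __post_init__(self):
        if self.q_center <= 0:
            raise ValueError("q_center must be positive")
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class RingModel:
    """Radial intensity model: Gaussian rings over a decaying background."""

    peaks: tuple[RingPeak, ...] = ()
    background_amplitude: float = 0.0
    background_scale: float = 1.0   # nm⁻¹ decay constant of exp(−q/scale)
    beamstop_radius: float = 3.0    # pixels zeroed around the beam centre

    def __post_init__(self):
        if self.background_amplitude < 0:
            raise ValueError("background amplitude must be non-negative")
        if self.background_scale <= 0:
            raise ValueError("background scale must be positive")


def radial_intensity(model: RingModel, q):
    """Expected intensity at momentum transfer q (counts, continuous).

    Background term A·exp(−q/s) plus the sum of Gaussian rings; smooth and
    non-negative everywhere.
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    out = np.zeros_like(q, dtype=float)
    if model.background_amplitude > 0:
        out += model.background_amplitude * np.exp(-q / model.background_scale)
    for p in model.peaks:
        out += p.amplitude * np.exp(-0.5 * ((q - p.q_center) / p.width) ** 2)
    return float(out) if out.ndim == 0 else out


def expected_image(model: RingModel, geometry: BeamGeometry,
                   detector: DetectorSpec) -> np.ndarray:
    """Noise-free expected counts per pixel, beamstop pixels zeroed."""
    r_px = pixel_radii(detector.shape, (geometry.center_row, geometry.center_col))
    q = pixel_to_q(r_px * detector.pixel_pitch_mm, geometry)
    mean = radial_intensity(model, q)
    mean[r_px < model.beamstop_radius] = 0.0
    return mean


def render_frame(
    model: RingModel,
    geometry: BeamGeometry,
    detector: DetectorSpec,
    photon_budget: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Render one Poisson-noisy frame.

    Each pixel is an independent Poisson draw with mean proportional to the
    radial model at that pixel's q.  With ``photon_budget`` the means are
    rescaled so the expected frame total equals the budget; ``None`` keeps
    the model's absolute amplitudes (used when composing tissue + holder
    components that must stay mutually calibrated).
    """
    rng = np.random.default_rng(rng)
    mean = expected_image(model, geometry, detector)
    if photon_budget is not None:
        if photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        total = mean.sum()
        if total > 0:
            mean = mean * (photon_budget / total)
    return rng.poisson(mean).astype(np.int64)


# --------------------------------------------------------------------------
# calibrant frames
# --------------------------------------------------------------------------

def calibrant_ring_model(
    calibrant: CalibrantSpec,
    geometry: BeamGeometry,
    detector: DetectorSpec,
    ring_amplitude: float = 1.0,
    ring_width_px: float = 1.5,
    background_amplitude: float = 0.5,
    beamstop_radius: float = 3.0,
) -> RingModel:
    """Narrow rings at every calibrant order visible inside the q-range.

    Ring widths are specified in detector pixels and converted to q through
    the local derivative dq/dr at each ring radius, so rings stay equally
    sharp across the frame.  The background term models the bright
    small-angle halo around the beamstop that anchors centre finding.
    """
    q_lim = max_q(geometry, detector)
    peaks = []
    dr = detector.pixel_pitch_mm
    for q_n in calibrant.q_orders:
        if q_n > q_lim:
            break
        from .geometry import q_to_radius_mm

        r_mm = q_to_radius_mm(q_n, geometry)
        dq_dr = (pixel_to_q(min(r_mm + dr, geometry.distance_D_mm * 0.999), geometry)
                 - pixel_to_q(max(r_mm - dr, 0.0), geometry)) / (2 * dr)
        sigma_q = max(ring_width_px * dr * abs(dq_dr), 1e-6)
        peaks.append(RingPeak(q_n, sigma_q, ring_amplitude))
    return RingModel(
        peaks=tuple(peaks),
        background_amplitude=background_amplitude,
        background_scale=max(q_lim / 4.0, 1e-6),
        beamstop_radius=beamstop_radius,
    )


def render_calibrant_frame(
    calibrant: CalibrantSpec,
    geometry: BeamGeometry,
    detector: DetectorSpec,
    rng: np.random.Generator | int | None = None,
    photon_budget: float = 2_000_000.0,
    **model_kwargs,
) -> np.ndarray:
    """Render a calibration-standard frame (background-only if no order fits)."""
    model = calibrant_ring_model(calibrant, geometry, detector, **model_kwargs)
    return render_frame(model, geometry, detector, photon_budget, rng)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

GEOMETRY_TAGS = ("2cm", "16cm")


def default_templates() -> dict[tuple[str, str], RingModel]:
    """Class-conditional ring templates per nominal geometry.

    Amplitudes are relative (frames are renormalised to the photon budget);
    what separates the classes is the peak-to-background *share*.  Widths:
    0.08 nm⁻¹ for the sharp small-angle ring, 1.0 nm⁻¹ for the broad
    wide-angle humps.
    """
    return {
        ("16cm", "non-cancer"): RingModel(
            peaks=(RingPeak(1.5, 0.08, 1.0),),
            background_amplitude=1.0, background_scale=1.0),
        ("16cm", "cancer"): RingModel(
            peaks=(RingPeak(1.5, 0.08, 0.15),),
            background_amplitude=1.0, background_scale=1.0),
        ("2cm", "non-cancer"): RingModel(
            peaks=(RingPeak(13.9, 1.0, 1.0), RingPeak(20.2, 1.0, 0.3)),
            background_amplitude=3.0, background_scale=5.0),
        ("2cm", "cancer"): RingModel(
            peaks=(RingPeak(13.9, 1.0, 0.25), RingPeak(20.2, 1.0, 0.8)),
            background_amplitude=3.0, background_scale=5.0),
    }


def default_holder_background() -> dict[str, RingModel]:
    """Empty-holder (mylar + aluminium) scattering: smooth decay, no rings."""
    return {
        "2cm": RingModel(background_amplitude=1.0, background_scale=8.0),
        "16cm": RingModel(background_amplitude=1.0, background_scale=1.5),
    }


@dataclass
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults reproduce the target study's scale: 107 patients with a
    60/107 cancer fraction, two specimens each (one per geometry), ten
    spots per specimen.  ``patient_effect_sd`` is the sd (log scale) of the
    multiplicative log-normal perturbation applied to template peak
    amplitudes per patient.
    """

    n_patients: int = 107
    fraction_cancer: float = 60 / 107
    specimens_per_patient: int = 2
    spots_per_specimen: int = 10
    specimen_geometries: tuple[str, ...] = ("2cm", "16cm")
    nominal_distance_mm: dict = field(
        default_factory=lambda: {"2cm": 20.0, "16cm": 160.0})
    distance_jitter_frac: float = 0.02
    beam_centers: dict = field(
        default_factory=lambda: {"2cm": (128.0, 52.0), "16cm": (128.0, 128.0)})
    center_jitter_sd: float = 1.0
    patient_effect_sd: float = 0.5
    photon_budget: float = 2_000_000.0
    holder_fraction: float = 0.1
    templates: dict = field(default_factory=default_templates)
    holder_background: dict = field(default_factory=default_holder_background)
    mapping_mode: str = "paper_sin"
    detector: DetectorSpec = field(default_factory=DetectorSpec)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.fraction_cancer <= 1.0):
            raise ValueError("fraction_cancer must be in [0, 1]")
        if min(self.n_patients, self.specimens_per_patient,
               self.spots_per_specimen) < 1:
            raise ValueError("counts must be at least 1")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive")
        if not (0.0 <= self.holder_fraction < 1.0):
            raise ValueError("holder_fraction must be in [0, 1)")


@dataclass
class CohortData:
    """Everything a downstream run needs: frames plus truth."""

    frames: list
    manifest: pd.DataFrame
    backgrounds: dict          # geometry tag -> DetectorImage
    calibrants: dict           # geometry tag -> DetectorImage
    geometries: dict           # geometry tag -> true BeamGeometry (base centre)
    detector: DetectorSpec
    config: CohortConfig


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-entity random stream via stable hashing."""
    key = zlib.crc32("/".join(tokens).encode())
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))


def _scaled_model(model: RingModel, factors: np.ndarray | None,
                  target_total: float, geometry: BeamGeometry,
                  detector: DetectorSpec, beamstop_radius: float) -> np.ndarray:
    """Expected image of ``model`` (amplitudes × factors) scaled to a total."""
    peaks = model.peaks
    if factors is not None:
        peaks = tuple(replace(p, amplitude=p.amplitude * f)
                      for p, f in zip(peaks, factors))
    m = replace(model, peaks=peaks, beamstop_radius=beamstop_radius)
    img = expected_image(m, geometry, detector)
    total = img.sum()
    return img * (target_total / total) if total > 0 else img


def simulate_cohort(config: CohortConfig,
                    calibrant: CalibrantSpec | None = None) -> CohortData:
    """Render the full synthetic cohort, deterministically from the seed.

    Per patient, one log-normal factor per template peak perturbs the class
    amplitudes; each spot is then an independent Poisson rendering.  Sample
    frames are the sum of the tissue component (scaled to
    (1 − holder_fraction)·photon_budget) and a fixed empty-holder component
    (holder_fraction·photon_budget); the per-geometry background frame
    renders the holder component alone, so subtraction is unbiased.
    """
    if calibrant is None:
        from .geometry import load_agbh

        calibrant = load_agbh()
    det = config.detector
    rng_dist = _stream(config.seed, "distance")
    geometries: dict[str, BeamGeometry] = {}
    for tag in sorted(set(config.specimen_geometries)):
        d0 = config.nominal_distance_mm[tag]
        d_true = d0 * (1.0 + config.distance_jitter_frac *
                       rng_dist.uniform(-1.0, 1.0))
        cr, cc = config.beam_centers[tag]
        geometries[tag] = BeamGeometry(cr, cc, d_true,
                                       mapping_mode=config.mapping_mode)
        # sanity: the class templates must scatter into the visible q-range
        q_lim = max_q(geometries[tag], det)
        for (g, lab), tmpl in config.templates.items():
            if g != tag or not tmpl.peaks:
                continue
            inside = [p for p in tmpl.peaks if p.q_center <= q_lim]
            if not inside:
                raise ValueError(
                    f"template ({g}, {lab}): no peak inside q-range (max {q_lim:.2f})")
            if len(inside) < len(tmpl.peaks):
                warnings.warn(
                    f"template ({g}, {lab}): some peaks beyond q_max={q_lim:.2f}",
                    stacklevel=2)

    n_cancer = int(round(config.n_patients * config.fraction_cancer))
    patients = [f"P{i:03d}" for i in range(config.n_patients)]
    labels = {p: ("cancer" if i < n_cancer else "non-cancer")
              for i, p in enumerate(patients)}

    beamstop = {tag: config.templates[(tag, "cancer")].beamstop_radius
                if (tag, "cancer") in config.templates else 3.0
                for tag in geometries}

    frames: list[DetectorImage] = []
    rows = []
    for pid in patients:
        label = labels[pid]
        for s_idx in range(config.specimens_per_patient):
            sid = f"S{s_idx}"
            tag = config.specimen_geometries[s_idx % len(config.specimen_geometries)]
            geom = geometries[tag]
            tmpl = config.templates[(tag, label)]
            rng_pat = _stream(config.seed, "patient", pid, tag)
            factors = np.exp(rng_pat.normal(0.0, config.patient_effect_sd,
                                            size=len(tmpl.peaks)))
            for spot in range(config.spots_per_specimen):
                rng_f = _stream(config.seed, "frame", pid, sid, str(spot))
                jitter = rng_f.normal(0.0, config.center_jitter_sd, size=2)
                geom_f = replace(geom,
                                 center_row=geom.center_row + jitter[0],
                                 center_col=geom.center_col + jitter[1])
                tissue = _scaled_model(
                    tmpl, factors, (1 - config.holder_fraction) * config.photon_budget,
                    geom_f, det, tmpl.beamstop_radius)
                holder = _scaled_model(
                    config.holder_background[tag], None,
                    config.holder_fraction * config.photon_budget,
                    geom_f, det, tmpl.beamstop_radius)
                counts = rng_f.poisson(tissue + holder).astype(np.int64)
                fid = f"{pid}_{sid}_{spot:02d}_{tag}"
                frames.append(DetectorImage(
                    counts, frame_id=fid, patient_id=pid, specimen_id=sid,
                    spot=spot, geometry=tag, label=label))
                rows.append({
                    "frame_id": fid, "patient_id": pid, "specimen_id": sid,
                    "spot": spot, "geometry_cm": int(tag.removesuffix("cm")),
                    "label": label,
                    "truth_distance_mm": geom.distance_D_mm,
                    "truth_center_row": geom_f.center_row,
                    "truth_center_col": geom_f.center_col,
                    "truth_peaks": ";".join(
                        f"{p.q_center:g}:{p.amplitude * f:.6g}"
                        for p, f in zip(tmpl.peaks, factors)),
                })

    backgrounds, calibrants = {}, {}
    for tag, geom in geometries.items():
        rng_b = _stream(config.seed, "background", tag)
        holder = _scaled_model(config.holder_background[tag], None,
                               config.holder_fraction * config.photon_budget,
                               geom, det, beamstop[tag])
        backgrounds[tag] = DetectorImage(
            rng_b.poisson(holder).astype(np.int64),
            frame_id=f"background_{tag}", geometry=tag)
        rng_c = _stream(config.seed, "calibrant", tag)
        cal_counts = render_calibrant_frame(
            calibrant, geom, det, rng=rng_c,
            photon_budget=config.photon_budget,
            beamstop_radius=beamstop[tag])
        calibrants[tag] = DetectorImage(
            cal_counts, frame_id=f"calibrant_{tag}", geometry=tag)

    manifest = pd.DataFrame(rows)
    if manifest["frame_id"].duplicated().any():
        raise RuntimeError("duplicate frame ids in manifest")
    return CohortData(frames, manifest, backgrounds, calibrants,
                      geometries, det, config)
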