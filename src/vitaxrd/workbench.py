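"""Pipeline orchestration and file I/O.

Ties the stages into the reproducible chain
``simulate → calibrate → reduce → harmonize → classify → report``, both
in memory (the functions below, used by tests and scripts) and on disk
(TIFF frames, CSV profiles/matrices/metrics, JSON summaries, a SHA-256
manifest of every artifact).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import biomarkers as bm
from .classify import ClassifierConfig, evaluate_cluster
from .exceptions import PipelineError
from .geometry import (
    BeamGeometry,
    CalibrationResult,
    DetectorSpec,
    calibrate_distance,
    find_beam_center,
    load_agbh,
)
from .harmonize import (
    HarmonizedMatrix,
    assign_cluster,
    remove_outliers,
    trim_and_resample,
)
from .reduce import (
    DetectorImage,
    RadialProfile,
    azimuthal_integrate,
    beamstop_mask,
    subtract_background,
    to_q_profile,
    validate_frame,
)
from .simulate import CohortConfig, CohortData, simulate_cohort

log = logging.getLogger("vitaxrd")


@dataclass
class RunConfig:
    """Everything a full run needs besides the output directory."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cut_fraction: float = 0.045
    n_grid_points: int = 50
    z_threshold: float = 3.0
    n_realizations: int = 200
    train_fraction: float = 0.6
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scaler_mode: str = "train_only"
    bin_width_px: float = 1.0
    min_total_counts: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.cut_fraction < 0.5):
            raise ValueError("cut_fraction must be in [0, 0.5)")
        if self.n_grid_points < 2:
            raise ValueError("n_grid_points must be ≥ 2")

    @classmethod
    def from_json(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        cohort_kw = payload.pop("cohort", {})
        clf_kw = payload.pop("classifier", {})
        cfg = cls(
            cohort=CohortConfig(**cohort_kw),
            classifier=ClassifierConfig(**clf_kw),
            **payload,
        )
        if seed is not None:
            cfg = replace(cfg, seed=seed,
                          cohort=replace(cfg.cohort, seed=seed))
        return cfg

    def config_hash(self) -> str:
        def jsonable(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return {str(k): jsonable(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [jsonable(v) for v in o]
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (str, int, float, bool)) or o is None:
                return o
            return str(o)

        blob = json.dumps(jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# in-memory pipeline
# --------------------------------------------------------------------------

def calibrate_cohort(cohort: CohortData, calibrant=None
                     ) -> dict[str, tuple[CalibrationResult, tuple[float, float]]]:
    """Beam centre + sample-to-detector distance per geometry tag."""
    if calibrant is None:
        calibrant = load_agbh()
    out = {}
    for tag, frame in cohort.calibrants.items():
        est = find_beam_center(frame)
        cal = calibrate_distance(
            frame, calibrant, (est.row, est.col), cohort.detector,
            wavelength_nm=cohort.geometries[tag].wavelength_nm,
            mapping_mode=cohort.config.mapping_mode,
        )
        out[tag] = (cal, (est.row, est.col))
    return out


def reduce_cohort(
    cohort: CohortData,
    calibrations: dict | None = None,
    bin_width: float = 1.0,
    min_total_counts: float = 100.0,
    beamstop_pad: float = 1.0,
) -> tuple[list[RadialProfile], list[tuple[str, str]]]:
    """Validate, background-subtract and integrate every frame.

    Returns the q-profiles of kept frames and a (frame_id, reason) log of
    dropped ones.  Uses the calibrated distance when given, else the true
    simulation geometry; the integration centre is always the per-frame
    fitted centre.
    """
    if calibrations is None:
        calibrations = calibrate_cohort(cohort)
    profiles, dropped = [], []
    beamstop_r = {tag: cohort.config.templates[(tag, "cancer")].beamstop_radius
                  for tag in cohort.geometries}
    for frame in cohort.frames:
        v = validate_frame(frame, min_total_counts=min_total_counts)
        if not v.keep:
            dropped.append((frame.frame_id, v.reason))
            continue
        center = (v.center.row, v.center.col)
        corrected = subtract_background(frame, cohort.backgrounds[frame.geometry])
        mask = beamstop_mask(corrected.counts.shape, center,
                             beamstop_r[frame.geometry] + beamstop_pad)
        pix = azimuthal_integrate(corrected, center, bin_width, mask)
        cal, _ = calibrations[frame.geometry]
        geom = replace(cohort.geometries[frame.geometry],
                       center_row=center[0], center_col=center[1],
                       distance_D_mm=cal.distance_mm)
        profiles.append(to_q_profile(pix, geom, cohort.detector,
                                     patient_id=frame.patient_id,
                                     label=frame.label,
                                     geometry_tag=frame.geometry))
    return profiles, dropped


def build_matrices(
    profiles: list[RadialProfile],
    cut_fraction: float = 0.045,
    n_points: int = 50,
    z_threshold: float = 3.0,
) -> dict[str, HarmonizedMatrix]:
    """Cluster by geometry, trim/resample to the common grid, drop outliers."""
    clusters: dict[str, list[RadialProfile]] = {}
    for p in profiles:
        clusters.setdefault(assign_cluster(p), []).append(p)
    out = {}
    for tag, members in sorted(clusters.items()):
        matrix = trim_and_resample(members, tag, cut_fraction, n_points)
        if matrix.n_samples >= 3:
            matrix, _ = remove_outliers(matrix, z_threshold)
        out[tag] = matrix
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute every stage in order, writing the report bundle to disk.

    Idempotent given identical (config, seed); every artifact is listed
    with its SHA-256 digest in ``sha256_manifest.json``.  Stage failures
    surface as :class:`PipelineError` tagged with the stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out / "run.log")
    log.info("run start: seed=%d config=%s", config.seed, config.config_hash())

    try:
        cohort = simulate_cohort(replace(config.cohort, seed=config.seed))
        write_cohort(cohort, out / "frames")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate", str(e)) from e

    try:
        calibrations = calibrate_cohort(cohort)
        cal_payload = {
            tag: {"distance_mm": cal.distance_mm, "residual": cal.residual,
                  "first_order": cal.first_order,
                  "center": list(center)}
            for tag, (cal, center) in calibrations.items()
        }
        _write_json(out / "calibration.json", cal_payload)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("calibrate", str(e)) from e

    try:
        profiles, dropped = reduce_cohort(
            cohort, calibrations, config.bin_width_px, config.min_total_counts)
        for tag in cohort.geometries:
            rows = []
            for p in profiles:
                if p.geometry != tag:
                    continue
                for qv, iv, nv in zip(p.q, p.intensity, p.n_pixels):
                    rows.append((p.frame_id, qv, iv, int(nv)))
            pd.DataFrame(rows, columns=["frame_id", "q_nm_inv", "intensity",
                                        "n_pixels"]).to_csv(
                out / f"profiles_{tag}.csv", index=False)
        _write_json(out / "dropped_frames.json",
                    [{"frame_id": f, "reason": r} for f, r in dropped])
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError("reduce", str(e)) from e

    try:
        matrices = build_matrices(profiles, config.cut_fraction,
                                  config.n_grid_points, config.z_threshold)
        for tag, m in matrices.items():
            write_matrix_csv(m, out / f"harmonized_{tag}.csv")
        _write_json(out / "exclusions.json", {
            tag: [{"sample_id": r.sample_id, "max_abs_z": r.max_abs_z,
                   "columns": list(r.columns)} for r in m.exclusion_log]
            for tag, m in matrices.items()})
    except Exception as e:  # noqa: BLE001
        raise PipelineError("harmonize", str(e)) from e

    try:
        marker_payload = {}
        for tag, m in matrices.items():
            rows = {}
            for label in ("cancer", "non-cancer"):
                avg = bm.class_average(m, label)
                pd.DataFrame({"q_nm_inv": avg.q, "intensity": avg.intensity}
                             ).to_csv(out / f"class_average_{tag}_{label}.csv",
                                      index=False)
                meas = {}
                for peak in bm.DEFAULT_PANEL:
                    w_lo = peak.q_center - peak.half_window
                    w_hi = peak.q_center + peak.half_window
                    if w_lo < avg.q[0] or w_hi > avg.q[-1]:
                        continue
                    pm = bm.measure_peak(avg, peak)
                    meas[peak.name] = {
                        "center": pm.center, "height": pm.height,
                        "significance": pm.significance,
                        "suppressed": bm.is_peak_suppressed(pm)}
                rows[label] = meas
            marker_payload[tag] = rows
        _write_json(out / "biomarkers.json", marker_payload)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("biomarkers", str(e)) from e

    try:
        summary_payload = {}
        for tag, m in matrices.items():
            results, summary, grid, mean_tpr = evaluate_cluster(
                m, config.n_realizations, config.train_fraction,
                config.classifier, config.seed, config.scaler_mode)
            pd.DataFrame({
                "realization": [r.realization for r in results],
                "auc": [r.auc for r in results],
                "sensitivity": [r.sensitivity for r in results],
                "specificity": [r.specificity for r in results],
                "threshold": [r.threshold for r in results],
            }).to_csv(out / f"metrics_{tag}.csv", index=False)
            best = results[summary.best_realization]
            worst = results[summary.worst_realization]
            pd.DataFrame({
                "fpr": grid,
                "mean_tpr": mean_tpr,
                "best_tpr": np.interp(grid, best.fpr, best.tpr),
                "worst_tpr": np.interp(grid, worst.fpr, worst.tpr),
            }).to_csv(out / f"roc_{tag}.csv", index=False)
            summary_payload[tag] = {
                "metrics": summary.metrics,
                "best_realization": summary.best_realization,
                "worst_realization": summary.worst_realization,
                "n_realizations": summary.n_realizations,
                "n_samples": m.n_samples,
            }
        _write_json(out / "summary.json", {
            "seed": config.seed, "config_hash": config.config_hash(),
            "clusters": summary_payload})
    except Exception as e:  # noqa: BLE001
        raise PipelineError("classify", str(e)) from e

    try:
        digest = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name not in ("sha256_manifest.json", "run.log")
        }
        _write_json(out / "sha256_manifest.json", digest)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("report", str(e)) from e
    log.info("run complete: %d profiles, %d dropped", len(profiles), len(dropped))
    return {"matrices": matrices, "summary": summary_payload,
            "dropped": dropped, "calibration": cal_payload}


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

def write_cohort(cohort: CohortData, frames_dir: str | Path) -> None:
    """Frames as single-channel 32-bit integer TIFFs plus the CSV manifest."""
    d = Path(frames_dir)
    d.mkdir(parents=True, exist_ok=True)
    for frame in cohort.frames:
        tifffile.imwrite(d / f"{frame.frame_id}.tiff",
                         frame.counts.astype(np.int32))
    for tag, frame in cohort.backgrounds.items():
        tifffile.imwrite(d / f"background_{tag}.tiff",
                         frame.counts.astype(np.int32))
    for tag, frame in cohort.calibrants.items():
        tifffile.imwrite(d / f"calibrant_{tag}.tiff",
                         frame.counts.astype(np.int32))
    cohort.manifest.to_csv(d / "manifest.csv", index=False)


def read_cohort(frames_dir: str | Path, config: CohortConfig | None = None
                ) -> CohortData:
    """Rehydrate a cohort written by :func:`write_cohort`."""
    d = Path(frames_dir)
    manifest = pd.read_csv(d / "manifest.csv")
    config = config or CohortConfig()
    frames = []
    for row in manifest.itertuples():
        tag = f"{row.geometry_cm}cm"
        frames.append(DetectorImage(
            tifffile.imread(d / f"{row.frame_id}.tiff"),
            frame_id=row.frame_id, patient_id=row.patient_id,
            specimen_id=row.specimen_id, spot=int(row.spot),
            geometry=tag, label=row.label))
    tags = sorted({f.geometry for f in frames})
    backgrounds = {t: DetectorImage(tifffile.imread(d / f"background_{t}.tiff"),
                                    frame_id=f"background_{t}", geometry=t)
                   for t in tags}
    missing = [t for t in tags if not (d / f"calibrant_{t}.tiff").exists()]
    if missing:
        raise PipelineError("calibrate", f"missing calibrant frame(s): {missing}")
    calibrants = {t: DetectorImage(tifffile.imread(d / f"calibrant_{t}.tiff"),
                                   frame_id=f"calibrant_{t}", geometry=t)
                  for t in tags}
    det = config.detector
    geometries = {}
    for t in tags:
        truth = manifest.loc[manifest.geometry_cm == int(t.removesuffix("cm")),
                             "truth_distance_mm"]
        d_mm = float(truth.iloc[0]) if len(truth) else config.nominal_distance_mm[t]
        cr, cc = config.beam_centers.get(t, (det.n_rows / 2, det.n_cols / 2))
        geometries[t] = BeamGeometry(cr, cc, d_mm, mapping_mode=config.mapping_mode)
    return CohortData(frames, manifest, backgrounds, calibrants, geometries,
                      det, config)


def write_matrix_csv(matrix: HarmonizedMatrix, path: str | Path) -> None:
    cols = [f"q={q:.12g}" for q in matrix.q_grid]
    df = pd.DataFrame(matrix.X, columns=cols)
    df.insert(0, "frame_id", matrix.frame_ids)
    df.insert(1, "patient_id", matrix.patient_ids)
    df.insert(2, "label", matrix.labels)
    df.to_csv(path, index=False)


def read_matrix_csv(path: str | Path, cluster: str) -> HarmonizedMatrix:
    df = pd.read_csv(path)
    qcols = [c for c in df.columns if c.startswith("q=")]
    return HarmonizedMatrix(
        cluster=cluster,
        q_grid=np.array([float(c[2:]) for c in qcols]),
        X=df[qcols].to_numpy(float),
        labels=df["label"].tolist(),
        patient_ids=df["patient_id"].tolist(),
        frame_ids=df["frame_id"].tolist(),
    )


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _setup_logging(logfile: Path) -> None:
    if not any(isinstance(h, logging.FileHandler)
               and getattr(h, "_vitaxrd", "") == str(logfile)
               for h in log.handlers):
        h = logging.FileHandler(logfile)
        h._vitaxrd = str(logfile)
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
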