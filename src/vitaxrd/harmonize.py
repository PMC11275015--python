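"""Profile harmonization: clustering, trimming/resampling, outliers, scaling.

Profiles from the two sample-to-detector distances live on different q
grids, so each geometry forms its own cluster.  Within a cluster the
common range is the intersection of member ranges with 4.5% of its span
cut from each end; every profile is then linearly interpolated onto a
50-point equally spaced grid.  Outliers are removed by per-column
z-scores in a single pass, and features are standardized either on the
whole cluster (mirroring a pre-split normalisation) or on training rows
only (leakage-free; the default for reported benchmarks).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import NoOverlap, TooFewSamples, UnknownGeometry
from .reduce import RadialProfile

CLUSTER_OF_GEOMETRY = {"2cm": "cluster_2cm", "16cm": "cluster_16cm"}


def assign_cluster(profile: RadialProfile) -> str:
    """Deterministic geometry → cluster tag mapping."""
    try:
        return CLUSTER_OF_GEOMETRY[profile.geometry]
    except KeyError:
        raise UnknownGeometry(
            f"profile {profile.frame_id!r} has geometry {profile.geometry!r}"
        ) from None


@dataclass
class ExclusionRecord:
    sample_id: str
    max_abs_z: float
    columns: tuple[int, ...]   # columns where |z| exceeded the threshold


@dataclass
class HarmonizedMatrix:
    """Per-cluster feature matrix: n_samples × len(q_grid) intensities."""

    cluster: str
    q_grid: np.ndarray
    X: np.ndarray
    labels: list[str]
    patient_ids: list[str]
    frame_ids: list[str]
    scaler_mean: np.ndarray | None = None
    scaler_sd: np.ndarray | None = None
    exclusion_log: list = field(default_factory=list)

    def __post_init__(self):
        self.q_grid = np.asarray(self.q_grid, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] != len(self.q_grid):
            raise ValueError("X must be n_samples × len(q_grid)")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("matrix contains NaN/Inf")
        n = self.X.shape[0]
        if not (len(self.labels) == len(self.patient_ids) == len(self.frame_ids) == n):
            raise ValueError("metadata length mismatch")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]


def trim_and_resample(
    profiles: list[RadialProfile],
    cluster: str,
    cut_fraction: float = 0.045,
    n_points: int = 50,
) -> HarmonizedMatrix:
    """Resample profiles onto a common grid over the trimmed shared range.

    The shared range is the intersection of member q-ranges;
    ``cut_fraction`` of its *span* is removed from each end and the target
    grid is ``n_points`` equally spaced values across what remains.  Linear
    interpolation is exact for affine profiles and never extrapolates.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    if not (0.0 <= cut_fraction < 0.5):
        raise ValueError("cut_fraction must be in [0, 0.5)")
    lo = max(float(p.q[0]) for p in profiles)
    hi = min(float(p.q[-1]) for p in profiles)
    if hi <= lo:
        raise NoOverlap(f"profiles share no q-range (intersection [{lo}, {hi}])")
    cut = cut_fraction * (hi - lo)
    grid = np.linspace(lo + cut, hi - cut, n_points)
    X = np.empty((len(profiles), n_points))
    for i, p in enumerate(profiles):
        X[i] = np.interp(grid, p.q, p.intensity)
    return HarmonizedMatrix(
        cluster=cluster,
        q_grid=grid,
        X=X,
        labels=[p.label for p in profiles],
        patient_ids=[p.patient_id for p in profiles],
        frame_ids=[p.frame_id for p in profiles],
    )


def remove_outliers(matrix: HarmonizedMatrix, z_threshold: float = 3.0
                    ) -> tuple[HarmonizedMatrix, list[ExclusionRecord]]:
    """Drop samples whose largest per-column |z| exceeds the threshold.

    z-scores use the within-cluster column mean and population sd
    (zero-variance columns count as z = 0).  Single pass: scores are not
    recomputed after removal.
    """
    if matrix.n_samples < 3:
        raise TooFewSamples(f"{matrix.n_samples} samples < 3")
    mu = matrix.X.mean(axis=0)
    sd = matrix.X.std(axis=0)
    safe = np.where(sd > 0, sd, 1.0)
    z = (matrix.X - mu) / safe
    z[:, sd == 0] = 0.0
    absz = np.abs(z)
    flagged = absz.max(axis=1) > z_threshold
    log = [
        ExclusionRecord(
            sample_id=matrix.frame_ids[i],
            max_abs_z=float(absz[i].max()),
            columns=tuple(np.nonzero(absz[i] > z_threshold)[0]),
        )
        for i in np.nonzero(flagged)[0]
    ]
    keep = ~flagged
    filtered = HarmonizedMatrix(
        cluster=matrix.cluster,
        q_grid=matrix.q_grid,
        X=matrix.X[keep],
        labels=[l for l, k in zip(matrix.labels, keep) if k],
        patient_ids=[p for p, k in zip(matrix.patient_ids, keep) if k],
        frame_ids=[f for f, k in zip(matrix.frame_ids, keep) if k],
        exclusion_log=list(matrix.exclusion_log) + log,
    )
    return filtered, log


def standardize(matrix: HarmonizedMatrix,
                fit_on: np.ndarray | list[int] | None = None) -> HarmonizedMatrix:
    """Column-wise (x − mean)/sd using stats from ``fit_on`` rows.

    ``fit_on=None`` fits on all rows.  Zero-variance columns pass through
    unchanged (sd recorded as 1).  All rows are transformed with the fitted
    stats, so held-out rows never influence them.
    """
    idx = np.arange(matrix.n_samples) if fit_on is None else np.asarray(fit_on)
    if idx.size == 0:
        raise ValueError("fit_on must be non-empty")
    mu = matrix.X[idx].mean(axis=0)
    sd = matrix.X[idx].std(axis=0)
    constant = sd == 0
    mu = np.where(constant, 0.0, mu)
    sd = np.where(constant, 1.0, sd)
    return replace(matrix, X=(matrix.X - mu) / sd, scaler_mean=mu, scaler_sd=sd)


def apply_scaler(X: np.ndarray, mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Transform rows with previously fitted stats."""
    return (np.asarray(X, dtype=float) - mean) / sd
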