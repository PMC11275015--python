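import numpy as np
import pytest

import vitaxrd as vx
from vitaxrd.workbench import build_matrices, calibrate_cohort, reduce_cohort


@pytest.fixture(scope="session")
def detector():
    return vx.DetectorSpec()


@pytest.fixture(scope="session")
def geom16():
    return vx.BeamGeometry(128.0, 128.0, 160.0)


@pytest.fixture(scope="session")
def geom2():
    return vx.BeamGeometry(128.0, 52.0, 20.0)


@pytest.fixture(scope="session")
def ring16():
    return vx.RingModel(peaks=(vx.RingPeak(1.5, 0.08, 1.0),),
                        background_amplitude=1.0, background_scale=1.0)


@pytest.fixture(scope="session")
def frame16(ring16, geom16, detector):
    counts = vx.render_frame(ring16, geom16, detector, 2e6, rng=0)
    return vx.DetectorImage(counts, frame_id="f16", geometry="16cm")


@pytest.fixture(scope="session")
def mini_processed():
    """Small processed cohort shared by reduction/harmonization tests."""
    cfg = vx.CohortConfig(n_patients=12, fraction_cancer=0.5,
                          spots_per_specimen=2, seed=11)
    cohort = vx.simulate_cohort(cfg)
    calibrations = calibrate_cohort(cohort)
    profiles, dropped = reduce_cohort(cohort, calibrations)
    matrices = build_matrices(profiles)
    return {"cohort": cohort, "calibrations": calibrations,
            "profiles": profiles, "dropped": dropped, "matrices": matrices}


@pytest.fixture(scope="session")
def bench_processed():
    """Benchmark cohort at the study's class structure, used by the
    end-to-end discrimination and peak-recovery checks."""
    cfg = vx.CohortConfig(n_patients=40, spots_per_specimen=4, seed=7)
    cohort = vx.simulate_cohort(cfg)
    calibrations = calibrate_cohort(cohort)
    profiles, dropped = reduce_cohort(cohort, calibrations)
    matrices = build_matrices(profiles)
    return {"cohort": cohort, "calibrations": calibrations,
            "profiles": profiles, "dropped": dropped, "matrices": matrices}


def brute_force_annuli(counts, center, bin_width=1.0, mask=None):
    """Independent per-pixel accumulator oracle for azimuthal integration."""
    counts = np.asarray(counts, dtype=float)
    n_rows, n_cols = counts.shape
    sums = {}
    npix = {}
    for i in range(n_rows):
        for j in range(n_cols):
            if mask is not None and mask[i, j]:
                continue
            r = np.hypot(i + 0.5 - center[0], j + 0.5 - center[1])
            b = int(np.floor(r / bin_width))
            sums[b] = sums.get(b, 0.0) + counts[i, j]
            npix[b] = npix.get(b, 0) + 1
    n_bins = max(sums) + 1 if sums else 0
    s = np.zeros(n_bins)
    n = np.zeros(n_bins, dtype=int)
    for b in sums:
        s[b] = sums[b]
        n[b] = npix[b]
    return s, n
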