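# vitaxrd

X-ray scattering pipeline for breast-tissue classification: from raw 2D
photon-count diffraction frames to patient-grouped random-forest performance
metrics, with a synthetic cohort generator so every stage is testable without
measured data.

## The problem

Small- and wide-angle X-ray scattering (SAXS/WAXS) of breast tissue probes
structural periodicities of the lipid-rich extracellular matrix. Three
diffraction features act as structural biomarkers, located at momentum
transfer q = 4π sin θ / λ (related to real-space spacing d by q = 2π/d):

| q (nm⁻¹) | origin | behaviour in cancer |
|---|---|---|
| 1.5  | regular triglyceride packing | suppressed |
| 13.9 | inter-fatty-acid distance | suppressed, often below 3 σ_background |
| 20.2 | O–O distance of tetrahedral water | relatively enhanced |

Measuring a cohort at two sample-to-detector distances (2 cm for the
wide-angle peaks, 16 cm for the small-angle peak) gives two q-range
"clusters" of 1D scattering profiles that a classifier can separate into
cancer / non-cancer — provided evaluation is honest about patients: all
frames of a patient must stay on one side of every train/test split.

## What the package does

- **simulate** — renders isotropic Debye–Scherrer frames (Gaussian rings in
  q over a decaying amorphous background, Poisson counting noise, beam-centre
  jitter, log-normal per-patient amplitude effects) for a configurable
  cohort: by default 107 patients × 2 specimens (one per geometry) × 10
  spots, 60/107 cancer; plus per-geometry empty-holder background frames and
  silver-behenate (AgBH, d₀₀₁ = 5.8380 nm) calibrant frames.
- **geometry** — beam-centre finding (marginal-symmetry seed + annular
  variance refinement), sample-to-detector distance calibration from AgBH
  ring radii, and the pixel→q mapping in two conventions (`paper_sin`:
  sin 2θ = r/D; `exact_tan`: tan 2θ = r/D).
- **reduce** — frame cleaning (drop empty / centre-less frames), empty-holder
  background subtraction, azimuthal integration into 1-pixel annuli, q
  conversion.
- **harmonize** — per-geometry clustering, 4.5% range trim, linear resampling
  onto a common 50-point q-grid, single-pass z-score outlier removal,
  column standardization (train-only or cluster-wide).
- **biomarkers** — local-baseline peak fitting of the three biomarkers and
  the k·σ_background suppression test; class-average curves.
- **classify** — stratified patient-disjoint 60/40 splits repeated 200
  times, a 100-tree depth-10 random forest scoring frames by the fraction of
  trees voting cancer, ROC with the operating point closest to the ideal
  corner (0, 1), and min/max/mean aggregation of AUC, sensitivity and
  specificity across realizations.
- **workbench / CLI** — `vitaxrd simulate | calibrate | reduce | harmonize |
  classify | report | run-all`, with TIFF frames, CSV profiles/matrices,
  JSON summaries and a SHA-256 manifest per run.

## Worked example

```python
import vitaxrd as vx
from vitaxrd.workbench import calibrate_cohort, reduce_cohort, build_matrices
from vitaxrd.biomarkers import class_average, measure_peak, PANEL_BY_NAME

cfg = vx.CohortConfig(n_patients=20, spots_per_specimen=3, seed=42)
cohort = vx.simulate_cohort(cfg)
calibrations = calibrate_cohort(cohort)
profiles, dropped = reduce_cohort(cohort, calibrations)
matrices = build_matrices(profiles)

m16 = matrices["cluster_16cm"]
for label in ("non-cancer", "cancer"):
    pm = measure_peak(class_average(m16, label), PANEL_BY_NAME["triglyceride"])
    print(f"triglyceride peak ({label}): q = {pm.center:.3f} nm^-1, "
          f"height/sigma_bg = {pm.significance:.1f}")

_, summary, _, _ = vx.evaluate_cluster(m16, n_realizations=20, seed=42)
a = summary.metrics["auc"]
print(f"16 cm cluster AUC over 20 patient-grouped splits: "
      f"mean {a['mean']:.3f}, min {a['min']:.3f}, max {a['max']:.3f}")
```

prints

```
triglyceride peak (non-cancer): q = 1.500 nm^-1, height/sigma_bg = 82.7
triglyceride peak (cancer): q = 1.500 nm^-1, height/sigma_bg = 13.4
16 cm cluster AUC over 20 patient-grouped splits: mean 0.976, min 0.917, max 1.000
```

The class-average triglyceride peak sits exactly at its simulated position;
its significance drops roughly sixfold in the cancer class; and the
patient-grouped random forest separates the classes nearly perfectly at
these noise settings, while label permutation (see
`evaluate_cluster(..., permute_labels=True)`) returns chance-level AUC.

The same pipeline runs from the shell:

```bash
vitaxrd run-all --out runs/demo --seed 42
vitaxrd report --run-dir runs/demo
```

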