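# Methods

## Forward model of a diffractogram

A diffractogram is a 256 × 256 array of photon counts from a pixelated
detector (55 µm pitch) at distance D behind the sample, illuminated at
λ = 0.154 nm (Cu Kα). The scattering pattern is assumed isotropic, so the
expected intensity at a pixel depends only on its momentum transfer

    q = 4π sin θ / λ,

with the scattering angle 2θ obtained from the pixel's distance r to the
beam centre. Two conventions are implemented and must be used consistently
within a run:

- `paper_sin` (default): sin 2θ = r/D. This is the convention the pipeline
  is designed to reproduce; it is exact for a detector curved around the
  sample and approximate for a flat one.
- `exact_tan`: tan 2θ = r/D, the exact flat-detector relation.

They agree to first order at small angle (within 0.01% at r/D = 0.01) and
diverge at wide angle; because simulation, calibration and reduction all
share one mode, recovered peak positions are internally consistent in
either mode (verified by a round-trip test in both).

The radial intensity model is a smooth amorphous background plus Gaussian
rings:

    I(q) = A_bg · exp(−q/s) + Σ_k A_k · exp(−(q − q_k)² / 2σ_k²).

Pixel counts are independent Poisson draws from this model scaled so the
expected frame total equals the photon budget; a central disk (default
radius 3 px) is zeroed to model the beamstop.

### Default cohort conditions

The generator's defaults emulate the study design the pipeline targets:
107 patients (60 cancer / 47 non-cancer), two specimens per patient — one
measured at a nominal 2 cm, one at 16 cm — and 10 spots per specimen
(2140 frames). Class-conditional templates encode the biomarkers
(amplitudes are relative; frames are renormalised to the photon budget, so
classes differ in peak-to-background *share*):

| geometry | class | peaks (q, σ, A) | background (A, s) |
|---|---|---|---|
| 16 cm | non-cancer | (1.5, 0.08, 1.0) | (1.0, 1.0) |
| 16 cm | cancer | (1.5, 0.08, 0.15) | (1.0, 1.0) |
| 2 cm | non-cancer | (13.9, 1.0, 1.0), (20.2, 1.0, 0.3) | (3.0, 5.0) |
| 2 cm | cancer | (13.9, 1.0, 0.25), (20.2, 1.0, 0.8) | (3.0, 5.0) |

Widths are 0.08 nm⁻¹ for the sharp small-angle ring and 1.0 nm⁻¹ for the
broad wide-angle humps; no published amplitudes or widths exist for these
curves, so the values are stand-ins chosen to look like broad WAXS humps
over a decaying background, exposed in `CohortConfig` and never asserted
as measured values.

Patient heterogeneity is a multiplicative log-normal effect (sd 0.5 on the
log scale) drawn once per patient per peak, which makes class
distributions overlap and occasionally produces genuinely extreme patients
— an intended feature: the z-score outlier filter may legitimately remove
such a patient. Beam-centre jitter is Gaussian with sd 1 px per frame. The
per-frame photon budget is 2 × 10⁶ counts, of which 10% is empty-holder
(mylar + aluminium) scattering; the background frame renders exactly that
holder component, so subtraction is unbiased in expectation.

Beam-centre geometry: the 16 cm beam is centred on the detector; the 2 cm
beam sits far off-centre (row 128, col 52). With a 256 × 55 µm detector a
centred 2 cm beam tops out near q ≈ 21 nm⁻¹, leaving the 20.2 nm⁻¹ water
peak at the trimmed edge of the usable range; offsetting the centre toward
one edge — standard practice for wide-angle work on small detectors —
extends coverage to q ≈ 29 nm⁻¹ and places all wide-angle biomarkers
comfortably inside the harmonized grid.

Randomness: every frame's stream is derived from the root seed by stable
hashing of (patient, specimen, spot), so adding patients or spots never
reshuffles existing frames, and identical (config, seed) reproduce output
byte for byte.

### What the generator does *not* emulate

No detector point-spread, polarization or mirror-divergence effects, no
anisotropic (textured) patterns, no collagen features, no dose or
dead-time effects, and patient heterogeneity is a single multiplicative
factor per peak rather than correlated biochemical variation. Passing
tests therefore demonstrate that the *analysis chain* is correct and
leakage-free under the stated statistical structure — not that real
tissue achieves any particular AUC.

## Beam-centre finding

Two stages. The seed exploits a property of isotropic patterns: the row
marginal Σ_cols I is exactly mirror-symmetric about the true centre row
even when the detector clips the pattern in columns (and vice versa), so
each coordinate is found as the best mirror point of the smoothed 1D
marginal, scored by variance-normalised mean squared asymmetry. The seed
is then refined by a coarse-to-fine grid search (±6 px down to 0.05 px
steps) minimising the within-annulus variance of a 128 px window. Locally
periodic patterns (many-ring calibrants) can fool the marginal seed with
false mirror points; in that case a global coarse scan of the 4×4
block-summed frame reseeds the search.

Failure modes map to the cleaning rule: frames with fewer than 100 total
counts are "empty"; frames where the coarse search hits its box boundary
or where the radial model explains less than R² = 0.02 of the windowed
variance (flat noise) have "no defined centre". Both thresholds are
configurable.

## Distance calibration

AgBH rings sit at q_n = 2πn/d₀₀₁ with d₀₀₁ = 5.8380 nm (standard calibrant
literature value, stored in `data/agbh.json`, overridable). Ring radii are
detected as prominence-filtered peaks of the pixel-radius profile with
parabolic sub-pixel refinement; a peak whose left flank falls to near zero
is rejected as the background apex at the beamstop edge. The innermost
detected ring is tentatively assigned order m = 1…5 (consecutive orders
thereafter), each assignment is fit through the origin, r = D·s(q_n) with
s = sin 2θ or tan 2θ per mode, and the assignment with the smallest
relative residual wins (ties to smaller m; residual above 2% raises an
ambiguity error). Simulated round trips recover D to ~0.02% at 160 mm and
20 mm in both modes.

## Reduction

Pixel (i, j) has centre (i + 0.5, j + 0.5); annulus k collects pixels with
floor(r/w) = k at bin width w = 1 px, giving ~130–240 raw bins — well
above the 50-point target grid. Background subtraction (clipped at zero)
precedes integration because subtracting frames is exact while subtracting
profiles is only approximate when centres differ. Per-annulus intensity is
the *mean* counts per pixel, so profiles are comparable across geometries;
`n_pixels` and exact accumulated sums are kept so Σ intensity·n equals the
unmasked pixel total to machine precision. Beamstop pixels are excluded by
a mask (radius + 1 px) around the fitted centre. The q value of a bin is
the mapped midpoint radius.

## Harmonization

Per cluster (geometry), the common range is the intersection of member
q-ranges with 4.5% of the span cut from each end; profiles are linearly
interpolated onto 50 equally spaced points (exact for affine profiles;
error ≤ h²·max|I″|/8 otherwise, tested on a quadratic; extrapolation never
occurs by construction). Outlier removal is a single pass over the
resampled matrix — profile-level z-scores are only well defined on a
common grid — excluding any sample whose largest per-column |z| exceeds 3
(population sd; zero-variance columns count as z = 0). Standardization
fits per-column mean/sd either on training rows of each realization
(`train_only`, default for every reported number — leakage-free) or once
on the whole cluster (`cluster_wide`, mirroring a pre-split normalisation;
kept as a fidelity option). Zero-variance columns pass through unchanged
with sd recorded as 1.

## Biomarker quantification

Search windows are ±0.3 nm⁻¹ around 1.5 nm⁻¹ and ±2 nm⁻¹ around 13.9 and
20.2 nm⁻¹ (only nominal centres are standard; the widths are this
package's choice). The local baseline is the straight line through the
window's edge samples, making the height invariant to any affine-in-q
additive term; the centre is refined by a parabola through the three
points around the argmax and clamped (with a flag) at the window edges.
σ_background is the sd of baseline residuals in one-half-window flanks on
each side (outer thirds of the window when the flanks leave the profile).
A peak is "suppressed" when height/σ_background < k, default k = 3,
strict inequality. Biomarker measurements are reported alongside
classification but are not fed to the classifier, which sees full
profiles.

## Classification and evaluation

Splits are stratified at the patient level: within each class, patients
are shuffled and the first round(0.6·n) go to training, so every frame of
a patient stays on one side (disjointness is asserted on every
realization). The classifier is a random forest — 100 trees, depth 10,
bootstrap per tree, √(n_features) feature subsampling — and the score of
a test frame is the fraction of trees voting cancer. (A "learning rate"
is sometimes quoted for random forests in this context; it has no meaning
for the algorithm and is ignored.) The ROC sweeps all distinct score
thresholds; AUC is trapezoidal (equal to the Mann–Whitney concordant-pair
statistic, verified to 1e−9); the operating point minimises the Euclidean
distance to the ideal corner (0, 1), ties resolving to the higher
threshold, and sensitivity/specificity are recomputed from the confusion
matrix at that threshold. Aggregation reports min/max/mean per metric,
identifies best/worst realizations by AUC, and averages ROC curves
vertically (mean tpr on a fixed 101-point fpr grid — the averaging scheme
is this package's choice). Evaluation is per diffractogram; a
patient-level aggregation (mean score per patient) is provided but off by
default. Per-realization RF seeds derive from the root seed and the
realization index, so any single realization is reproducible alone.

The label-permutation control permutes the patient→label map per
realization before splitting, preserving the grouping structure; with ~16
test patients per realization the null AUC has an sd of roughly 0.15, so
its mean over 20 realizations sits within a few hundredths of 0.5.

## Problem sizes used in tests and the acceptance script

Full-scale runs (107 × 2 × 10) work but are unnecessary for verifying the
pipeline's properties; the test suite and `scripts/acceptance.py` use a
desk-scale rendition of the same design — 40 patients × 2 specimens × 4
spots (320 frames), 20 split realizations per cluster — plus a 51-patient
single-spot cohort for the outlier-filter check and the full 107-patient
manifest for split hygiene. These sizes are stated here as the package's
chosen benchmark conditions.

## Known limitations

- The `paper_sin` mapping is kept as the default for fidelity even though
  a flat detector obeys tan 2θ = r/D; at the 2 cm geometry's widest angles
  the two differ by several percent in q.
- Calibration assumes detected calibrant rings are consecutive orders; a
  frame where an intermediate order is invisible would mis-assign.
- The outlier filter is single-pass by design; heavy-tailed patient
  effects can legitimately flag real (non-artifact) samples.
- σ_background estimation assumes flat-ish flanks; strongly curved
  backgrounds inflate it and make the suppression test conservative.
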