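# Methods

## Problem and scope

Dominant intraprostatic lesion (DIL) contours drawn separately on T2-weighted
(T2W), ADC and Ktrans images of the same patient differ, and the size of that
disagreement determines whether a single sequence suffices for defining a
radiotherapy boost volume. The package measures the disagreement in two
complementary ways: volumetric contour agreement (Dice, Jaccard, HD95, MDA)
and voxel-wise rank correlation of the underlying parametric maps inside a
common sampling region, then aggregates both over a cohort. A synthetic
cohort generator provides inputs with known ground truth; nothing in the
analysis path depends on the generator.

## Grid model and resampling

Grids are axis-aligned with 0-based voxel indices; the physical coordinate
of index (i, j, k) is the *center* of that voxel, `origin + index · spacing`,
in mm. Non-axis-aligned NIfTI affines (off-diagonal magnitude > 1e-6) and
axis flips are rejected rather than reinterpreted: the analysis assumes
co-registered axis-aligned grids, and silently accepting rotations is a
classic source of coordinate bugs.

Resampling maps each reference voxel center through a given rigid transform
(`p_moving = R p_ref + t`, extrinsic x-y-z Euler angles) into the moving
volume and interpolates there (linear by default; out-of-support points get
a configurable fill value, default 0). The transform is *applied*, never
estimated — the intended data are already co-registered, and registration
estimation is out of scope. Masks are resampled by linearly interpolating
the 0/1 field and thresholding at 0.5 (majority rule). Coordinates within
1e-9 voxel of a grid point are snapped before interpolation so that
identity resampling is bit-exact.

## Agreement metrics

Conventions, fixed because tools in this space differ on each of them:

* **Boundary**: centers of true voxels with ≥ 1 false or out-of-grid face
  neighbour (6-connectivity); the grid edge counts as exposure.
* **Distances**: Euclidean nearest-neighbour distances in physical mm
  between the two boundary point sets, both directions (KD-tree; verified
  against an all-pairs brute-force oracle to 1e-9 mm in the tests).
* **HD95 / MDA**: computed on the *pooled* bidirectional multiset
  (A→B together with B→A), making both symmetric by construction. The
  percentile linearly interpolates between closest order statistics
  (pooled {0×9, 10} at q = 95 → 5.5 mm pins the convention); q = 100 equals
  the classical symmetric Hausdorff distance. MDA is the pooled mean —
  hence HD95 ≥ MDA is *not* guaranteed, while HD100 ≥ MDA always is.
* **Empty masks**: both empty → undefined (error); exactly one empty →
  Dice = Jaccard = 0, distance metrics undefined.

## Voxel-wise correlation

The Boolean sum volume (BSV) is the union of the contours from all three
sequences and is always built from all three masks, even when a single pair
is correlated — this keeps the number of sampled voxels identical across
pairs. Spearman's ρ is the Pearson correlation of fractional ranks
(average ranks for ties, divided by n; normalisation cancels in ρ).
A map constant inside the BSV gives a flagged undefined result, never a
silent 0; downstream, flagged rows are excluded from cohort averages with
the exclusion surfaced in the row counts. Spearman rather than Pearson
because only a monotone relationship between sequences is assumed. Voxels
are treated as exchangeable observations; no spatial autocorrelation
correction is applied.

## Cohort aggregation

All SDs are sample SDs (n−1); strata with n < 2 report SD as NaN. Zones are
stored four-way (AFS/CZ/PZ/TZ) and displayed as AFS, Peripheral, and pooled
Cent/Tran plus Total; Gleason grade groups 4 and 5 are pooled at ingest and
never reported separately. Patients with an uninformative Ktrans map are
dropped from Ktrans-involved pairs only (T2-Ktrans and ADC-Ktrans), with n
reported per row. The ADC-Ktrans pair is computed and reported as extended
output even where the two-pair table layout is mirrored. Composition
percentages are computed over patients with known labels; unlabeled counts
are reported in their own row.

## Synthetic cohort: the stated world

Defaults encode the study conditions the pipeline is meant to exercise:
90 patients; native grids T2W 0.5 × 0.5 × 3.0 mm (the reference), ADC
2.0 × 2.0 × 3.0 mm, Ktrans 1.5 × 1.5 × 3.0 mm over a shared 48 × 48 × 42 mm
field of view; lesion volumes lognormal with mean 2.14 mL and SD 2.1 mL
(clipped to [0.25, 8] mL so the lesion fits the grid); zone weights
0.352/0.056/0.324/0.254 renormalised to sum to 1; grade-group weights
0.303/0.394/0.172/0.131; 19/90 patients with uninformative Ktrans
(realised as an exact count per cohort, randomly assigned); b-values
50/400/800 s/mm²; Spearman targets 0.20 (T2-ADC), 0.13 (T2-Ktrans) and
0.15 (ADC-Ktrans, a value chosen once between the other two since no
reference value exists for that pair).

**Lesions** are voxelized ellipsoids with mild random axis anisotropy
(ratios U(0.75, 1.3)) rescaled to the drawn volume, centered with ±2 mm
jitter. **Contours** are smooth random boundary displacements of the base
lesion: the mask is re-thresholded as `signed_distance ≤ g`, with g a
Gaussian random field of pointwise SD equal to the scale (mm) and 4 mm
correlation length. Scale 0 reproduces the base exactly; expected Dice
decreases monotonically in scale (Monte-Carlo calibrated by
`calibrate_perturbation`, seeded). Default per-sequence scales 0.75 / 1.25 /
2.25 mm (T2W / ADC / Ktrans) were chosen a priori from a surface-area
estimate to land in the observed Dice regime (~0.6–0.85) and were not
adjusted afterwards; the second observer redraws at 2.5 mm. A perturbation
that empties a small lesion raises an error at the primitive level; cohort
generation redraws such contours (≤ 20 attempts), as an observer would.

**Parametric maps.** Within-patient coupling uses a trivariate Gaussian
copula with pairwise latent parameter r = 2·sin(π·ρ_s/6), which yields
Spearman ρ_s exactly for continuous marginals; the latent matrix is nudged
to the nearest usable PSD matrix if needed. Marginals (lesion/background):
T2W truncated-normal 300 ± 60 / 450 ± 80 a.u. (hypointense lesion); ADC
truncated-normal 990 ± 150 / 1500 ± 200 ×10⁻⁶ mm²/s (stored in mm²/s;
reported ×10⁻⁶); Ktrans exponential mean 4 / 1 min⁻¹ (internally consistent
with reported tumour values, which are themselves high relative to the
wider literature — no physiological realism is claimed). Latent fields are
white noise smoothed by a 3 mm Gaussian kernel and renormalised by the
exact kernel L2 norm, so the pointwise marginal stays standard normal and
the cross-correlation is preserved; 3 mm ≥ the coarsest native spacing,
which keeps the native↔reference linear resampling essentially
rank-transparent (measured paired delivered−true ρ ≈ −0.001 ± 0.003).

The coupled region is the BSV **dilated by one coarse native voxel**
(2 mm in-plane, one slice axially). Without the margin, linear resampling
mixes independent background values into BSV-edge voxels and biases the
delivered in-BSV Spearman low by up to ~0.08 for the doubly-resampled
ADC-Ktrans pair. Outside the coupled region, values are independent draws
from the background marginals (smoothed the same way). The standalone
`generate_correlated_pair` keeps the strict inside-BSV/outside-BSV
contract.

**ADC delivery.** The delivered ADC map is not the truth: the true field is
resampled to the native DWI grid, monoexponential signals
S(b) = s₀·exp(−b·ADC) receive additive Gaussian noise (default SD 1% of
s₀ = 1000), and ADC is refit per voxel as the negative OLS slope of
(b, log S). Non-positive noisy signals are excluded from that voxel's fit
and flagged; negative slopes are clipped to 0 and flagged. Additive
Gaussian (not Rician) noise is a simplification, adequate at the simulated
SNR; a limitation at low signal levels. **Uninformative Ktrans** cases have
their coupled-region values redrawn from the background distribution, so
lesion and background are statistically indistinguishable and downstream ρ
is ≈ 0; the case is flagged `ktrans_usable = False`.

Determinism: a `SeedSequence` per cohort spawns one child per patient plus
one for the unusable-case assignment; regeneration is byte-identical,
including written NIfTI files (uncompressed `.nii`, float32 volumes, uint8
masks).

## What a green test does and does not establish

The generator produces spatially smooth copula fields, ellipsoidal lesions
and exchangeable voxels. It does not emulate scanner physics (bias fields,
distortion, coil profiles), anatomy (zonal structure, benign hyperplasia
mimics), or observer psychology (systematic window/level biases). Green
recovery tests therefore establish that the *pipeline* is correct and
calibrated — not that any particular clinical cohort statistic is
reproduced. Cohort statistics from real observers on real images (e.g. the
magnitude of interobserver Dice differences) remain outside what synthetic
data can validate. Per-patient in-BSV ρ estimates have large spread
(SD ≈ 0.26 at the default smoothing, a few dozen effective samples per
lesion), so single-cohort means carry sampling error ≈ 0.03 at n = 90;
recovery tests use 3·SE bands computed from the cohort itself.

## Numerical choices

* Percentile: linear interpolation between closest order statistics.
* Mask-resampling threshold: 0.5.
* SD denominator: n−1 everywhere; single observations report SD 0 (voxel
  statistics) or NaN (cohort strata), as documented per function.
* Axis-alignment tolerance: 1e-6 on affine off-diagonals; grid-snap
  tolerance 1e-9 voxel.
* ADC fit: closed-form OLS slope on log-signals, vectorised; exact in the
  noiseless case to floating-point round-off.
* Ties: average ranks (makes Pearson-of-ranks equal textbook Spearman).
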