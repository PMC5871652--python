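# Methods

## Signal model and estimator

The forward model is the two-compartment IVIM decay
S(b)/S(0) = f·exp(−b·D\*) + (1−f)·exp(−b·D). Three tissue scenarios are
built in, all with D = 0.7 × 10⁻³ mm²/s and D\*/D ratios of 10 (brain,
low perfusion), 20 (kidney, medium) and 70 (liver, high). The segmented
estimator fits ln S linearly over the nonzero fit b-values and converts
slope and intercept to D and f = 1 − S(int)/S(0). Design choices that
matter downstream:

- **The measured (noisy) b = 0 signal is the denominator of f.** S(0) is
  an observed quantity, so its noise propagates into f. This is what makes
  f's dispersion larger than D's, and it contributes a small *positive*
  noise-induced bias in f (E[1/S(0)] > 1/E[S(0)]) that partially offsets
  the negative intrinsic bias at high SNR windows.
- **No clamping.** Negative D or f, or f > 1, are kept; censoring them
  would distort every bias and CoV estimate. Only non-positive signals
  (where the log is undefined) invalidate a fit; invalid fits are dropped
  from the moments and their count is reported. The handling of
  noise-corrupted non-positive signals is a package decision — at the
  studied SNR levels the event is vanishingly rare (it only matters in
  stress tests at SNR ≈ 10).
- **"Scheme [X,1000]" means three acquisitions {0, X, 1000}** fitted on
  the pair {X, 1000}. The fitter nevertheless accepts any ≥ 2 nonzero
  points (ordinary least squares in log space) for multi-b in-vivo data;
  on two points OLS reduces exactly to the closed-form line, which a
  property test asserts to machine precision.
- Units: D and D\* are mm²/s internally everywhere; rendered tables and
  map filenames use the conventional ×10⁻³ mm²/s scale.

## Noise simulation

Noise-free signals are generated on the ten-point grid 0, 200, …, 1000
s/mm²; iid zero-mean Gaussian noise (an adequate approximation to Rician
magnitude noise at SNR ≥ 40) is added to *every* point including b = 0;
fitting then uses the scheme's subset. The noise SD is calibrated per
(tissue, f) curve.

Two calibrations are implemented and recorded in all outputs:

- `rms_db` (default): σ = RMS(ten-point curve) / 10^(SNR/20). This is the
  decibel-style convention of communications-engineering noise routines,
  where the reference amplitude is the RMS of the whole transmitted
  signal. Under it, SNR 40 on the brain f = 0.1 curve gives σ ≈ 0.0067.
- `b0_linear`: σ = S(0)/SNR = 1/SNR, the naive amplitude-ratio reading
  (σ = 0.025 at SNR 40), retained as a configurable alternative.

The two readings differ by roughly a factor of four at these SNR levels
and are mutually irreconcilable with a single narrative: a √NSA ladder
(SNR 40→55→80 as averages 1→2→4) describes amplitude ratios, while the
dispersion behaviour this package targets follows the dB-style
calibration. `rms_db` is the default because it is the calibration under
which the estimator's reproducibility matches the reference behaviour of
the three-b-value protocol (f CoV ≈ 12% at SNR 40 with [300,1000], ≈ 2%
at SNR 55); the alternative yields several-fold larger dispersion.

Monte-Carlo defaults: N = 1000 iterations per cell, f grid 0.06–0.30 in
steps of 0.02 (13 values). Seeding: one root seed per batch, split into
an independent child stream per true f; within a stream, iteration i is
row i of a single (N × 10) draw, so any batch and any per-f subset is
bit-for-bit reproducible. The full 3-model × 8-scheme × 3-SNR study is
~2.8 million two-point fits and runs in well under a minute on one CPU.

## Error statistics and recommendation

Per (parameter, true f): relative bias mean(xᵢ−X)/X, relative error
√(mean((xᵢ−X)²))/X, and CoV 100·SD/mean. All use the population (÷N) SD,
matching the moment definitions; with population moments the identity
relerr² = bias² + (SD/X)² is exact, and a test asserts it. Grid
aggregation is the arithmetic mean ± population SD over the 13 f values —
the "value ± value" convention of the reported tables. The overall error
is the simple sum σ_{D+f} = σ_D + σ_f per f, aggregated the same way.

Recommendation: per (model, SNR), the argmin of the grid-mean overall
error. Because candidate schemes are evaluated on independent noise
draws, schemes whose overall errors differ by less than the Monte-Carlo
standard error of the difference (delta-method SE of the RMS statistic,
combined across the grid) are reported together as a tie set. At SNR 40
for the brain model, [400,1000] and [500,1000] are such a statistical tie
at N = 1000; kidney and liver have clear argmins. Schemes whose grid-mean
f relative error is below 10% are listed separately as a second,
threshold-based criterion. Optima need not be monotone across SNR — the
report shows whatever the computed argmin is.

## Synthetic cohort

The generator emulates a healthy-volunteer brain study: 16 subjects, 4
with a second acquisition, b = {0, 300, 500, 1000} s/mm², nominal SNR 45
at b = 1000. Geometry is a 48×48×3 DWI slab with a ring-shaped cortical
grey-matter region (soft-edged probabilistic mask and a stricter
partial-volume mask generated at 96×96×3, the structural resolution) —
no anatomical realism is attempted, because the downstream statistics
need only a contiguous ROI with a boundary.

Parameter hierarchy: subject-mean D ~ N(0.85 × 10⁻³, 0.04 × 10⁻³) mm²/s
and f ~ N(0.15, 0.015); voxel truths are truncated normals around the
subject means (voxel SDs 0.08 × 10⁻³ mm²/s and 0.04; truncation
f ∈ (0.01, 0.6), D > 0.1 × 10⁻³ mm²/s). The cohort means were chosen
once so that the segmented fit — with its known intrinsic bias at
D\*/D = 10 — lands in the observed grey-matter range for both fitted
schemes (f ≈ 0.12–0.14, D ≈ 0.86–0.88 × 10⁻³ mm²/s). D\* is tied to D
voxelwise by the fixed ratio 10 since no voxelwise D\* distribution is
available to emulate; within-subject voxel SDs are set to make histogram
widths plausible rather than matched to any measurement. Unlike the
simulation arm, noise here is a single SD per subject, constant across
b-values, equal to the cohort-mean grey-matter signal at b = 1000 divided
by the nominal SNR (the convention used for acquired data).

What passing cohort tests show — and what they do not: the pipeline
reproduces the *signs and orderings* of the in-vivo effects (higher f and
lower D with [500,1000] than [300,1000], negative Bland–Altman f bias
growing with true f, wCV(f) > wCV(D), positive between-scheme
correlation). The printed in-vivo magnitudes (cohort means, r values, BA
biases, wCV percentages) depend on real anatomy, physiological noise and
unknown ROI placement and are not reproducible from a synthetic slab;
they are treated as qualitative patterns only.

## Voxelwise pipeline

Masks are bilinearly resampled (slicewise; slice counts must match) to
the DWI grid and binarised at T = 0.7; the PVE path first keeps only
voxels with partial-volume value exactly 1. Histograms share one layout
across subjects and schemes: bin count = ⌊√(maximum ROI voxel count in
the cohort)⌋, range [0, cohort-wide maximum value]; cohort histograms are
unweighted averages of subject histograms. Repeatability uses the
root-mean-square within-subject CV over paired ROI means, two 4×4-voxel
ROIs per measurement pair placed on the middle slice at the grey-matter
centroid ± an offset (default: the mean in-plane radius of the masked
voxels, which lands on the ring; configurable, since no canonical ROI
coordinates exist). Inside a pair the sample SD (÷(n−1), n = 2) is used —
the standard repeatability convention — whereas the simulation-arm CoV
uses the population SD per its definition; the difference is deliberate.
Mask comparisons report mean, median and 10th/90th percentiles per mask
plus a Welch t-test p-value; p-values are reported, never used as
decision gates.

## Numerical notes and limitations

- Two-point fits are algebraically exact; no iterative optimisation or
  initialisation exists anywhere in the estimator.
- The delta-method SE used for tie detection is first-order and treats
  D- and f-error as additive (conservative, since they are positively
  correlated within a batch).
- Degenerate inputs: equal signals at both fit points give D = 0
  (returned as-is); empty masks give empty maps; an all-invalid f-cell
  would make the grid aggregate NaN (never observed at SNR ≥ 40).
- Rician magnitude bias, multi-coil noise statistics, spatial noise
  correlation, motion, distortion and registration error are all out of
  scope; free-D\* (full bi-exponential), kurtosis and tri-exponential
  models are not implemented.
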