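# ivim3b — rapid three-b-value IVIM analysis

`ivim3b` is a simulation and analysis toolkit for intravoxel incoherent
motion (IVIM) diffusion-weighted MRI with a minimal, clinic-friendly
acquisition: three b-values — 0, one intermediate value, and 1000 s/mm².
It is aimed at MR physicists and image-analysis researchers who want to
know *which* intermediate b-value to acquire for a given tissue and image
quality, and what bias and variability to expect in the resulting
diffusion coefficient and perfusion-fraction maps.

## The model and estimator

The IVIM model attributes the diffusion-weighted signal to tissue water
diffusion and capillary-network pseudo-diffusion:

    S(b)/S(0) = f · exp(−b·D*) + (1 − f) · exp(−b·D)

with diffusion coefficient *D* (mm²/s), pseudo-diffusion coefficient *D\**
and perfusion fraction *f*. The **segmented (constrained) fit** assumes the
perfusion compartment is fully attenuated at high b, fits

    S(b)/S(0) = exp(−b·D)

log-linearly over the high-b measurements (an exact line through two
points for the three-b-value protocol), and takes

    D = −slope,   f = 1 − S(int)/S(0)

where S(int) is the fit's extrapolated intercept at b = 0. This avoids the
notoriously unstable joint estimation of *D\**, at the cost of an intrinsic
bias — negative in *f*, positive in *D* — whenever perfusion signal
survives at the lower fit b-value. The package quantifies that
bias/variance trade-off by Monte-Carlo simulation over three canonical
tissue scenarios (brain D\*/D = 10, kidney 20, liver 70; D = 0.7 × 10⁻³
mm²/s), eight candidate schemes [200,1000] … [900,1000], SNR levels
40/55/80, and a true-f grid 0.06–0.30, and recommends the scheme with the
smallest overall relative error σ_{D+f} = σ_D + σ_f.

A synthetic grey-matter cohort generator (16 subjects, 4 rescanned, b =
{0, 300, 500, 1000}, SNR ≈ 45 at b = 1000) plus a voxelwise pipeline
(mask resampling, histograms, Pearson correlation, Bland–Altman,
within-subject CV) make the full in-vivo-style analysis runnable without
any imaging data; the same pipeline reads real 4-D NIfTI DWI + FSL-style
bval files + tissue masks.

## Worked example

```python
import ivim3b as iv

# Monte-Carlo for the brain scenario, scheme [500,1000], SNR 40
batch = iv.run_monte_carlo(iv.BRAIN, iv.AcquisitionScheme.two_point(500),
                           iv.NoiseSpec(snr=40), seed=1)
summ = iv.summarize_batch(batch)
print(f"f bias   {100 * summ['f'].bias_grid[0]:.1f}%")
print(f"f relerr {100 * summ['f'].relerr_grid[0]:.1f}%")
print(f"D bias   {100 * summ['D'].bias_grid[0]:.1f}%")
```

prints (seed 1):

```
f bias   -8.2%
f relerr 18.9%
D bias   2.6%
```

i.e. at SNR 40 the [500,1000] protocol underestimates the perfusion
fraction by ~9% of its true value with a ~19% RMS relative error, while
the diffusion coefficient is overestimated by under 3%. The same
experiment from the shell, with the full Table-style report:

```bash
ivim3b simulate --seed 1 --out-dir out/        # full 3×8×3 study
ivim3b recommend --seed 1 --out-dir out/       # optimal scheme per tissue/SNR
ivim3b synth-cohort --seed 1 --out-dir cohort/ # synthetic volunteer NIfTIs
ivim3b cohort-stats --seed 1 --out-dir stats/  # in-vivo-style statistics
```

At SNR 40 the recommended schemes are [500,1000] for brain, [300,1000]
for kidney and [200,1000] for liver: the low-perfusion brain needs a
higher fit window to escape the intrinsic bias, while the highly perfused
liver benefits from the lower-noise wide window.

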