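"""Synthetic grey-matter cohort generator.

Produces volunteer-study stand-ins so the voxelwise pipeline is fully
testable without any imaging data: per-subject grey-matter (GM) voxel
populations with known ground-truth IVIM parameters, three-b-value DWI
signals at realistic SNR, probabilistic and partial-volume (PVE) tissue
masks on a higher-resolution structural grid, and repeat acquisitions for
a subset of subjects.

The geometry is deliberately simple — a 2-D multi-slice slab with a
ring-shaped cortical GM region around a white-matter-like core — because
the downstream statistics only need a contiguous region with a soft
boundary, not anatomical realism.  Ground truth per voxel is drawn from
truncated normals around subject means, which are themselves drawn from
cohort-level distributions; the pseudo-diffusion coefficient is tied to
the diffusion coefficient by a fixed ratio (default 10, the low-perfusion
regime of cortical tissue).

Unlike the simulation arm, the in-vivo-style SNR here is defined at
b = 1000 (the NEMA-style convention for acquired data): the per-point
noise SD, constant across b-values for a subject, is the cohort-mean GM
signal at b = 1000 divided by the nominal SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import stats as sps

from .core import TissueModel, ivim_signal

__all__ = ["CohortSpec", "SyntheticSubject", "SyntheticCohort",
           "sample_subject", "generate_cohort"]


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for the synthetic volunteer cohort.

    Defaults emulate a healthy young-adult brain cohort: 16 subjects, four
    of them scanned twice, acquired at b = {0, 300, 500, 1000} s/mm^2 with
    SNR ~ 45 at b = 1000.  Cohort-mean GM truth (D = 0.85e-3 mm^2/s,
    f = 0.15) is chosen so that the segmented fit — which carries a known
    negative intrinsic bias in f and positive bias in D at D*/D = 10 —
    lands in the observed grey-matter range for both fitted schemes.
    """

    n_subjects: int = 16
    n_repeat_subjects: int = 4
    shape: tuple[int, int, int] = (48, 48, 3)      # DWI grid
    mask_shape: tuple[int, int, int] = (96, 96, 3)  # structural (T1) grid
    gm_D_mean: float = 0.85e-3      # cohort mean of subject-mean D, mm^2/s
    gm_D_sd: float = 0.04e-3        # between-subject SD of mean D
    gm_f_mean: float = 0.15         # cohort mean of subject-mean f
    gm_f_sd: float = 0.015          # between-subject SD of mean f
    voxel_D_sd: float = 0.08e-3     # within-subject voxelwise SD of D
    voxel_f_sd: float = 0.04        # within-subject voxelwise SD of f
    ratio: float = 10.0             # D*/D per voxel
    b_values: tuple[float, ...] = (0.0, 300.0, 500.0, 1000.0)
    snr: float = 45.0               # empirical SNR at b=1000
    wm_D: float = 0.72e-3           # background (white-matter-like) D
    wm_f: float = 0.03              # background f
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeat_subjects > self.n_subjects:
            raise ValueError("cannot have more repeat subjects than subjects")
        for name in ("gm_D_sd", "gm_f_sd", "voxel_D_sd", "voxel_f_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.gm_f_mean < 1:
            raise ValueError("gm_f_mean must lie in (0, 1)")
        if 0.0 not in self.b_values:
            raise ValueError("b_values must include 0")


@dataclass
class SyntheticSubject:
    """One synthetic volunteer: truth maps, signals, masks, optional repeat."""

    subject_id: str
    truth_D: np.ndarray          # (x, y, z), NaN outside the head
    truth_f: np.ndarray
    dwi: np.ndarray              # (x, y, z, n_b)
    gm_mask: np.ndarray          # probabilistic GM map on the structural grid
    pve_mask: np.ndarray         # partial-volume GM map on the structural grid
    b_values: tuple[float, ...]
    noise_sigma: float
    repeat_dwi: np.ndarray | None = None

    @property
    def has_repeat(self) -> bool:
        return self.repeat_dwi is not None


def _ring_profile(shape_xy: tuple[int, int], r_in: float, r_out: float,
                  soft: float) -> np.ndarray:
    """Radially symmetric ring membership in [0, 1] with soft edges.

    ``soft`` is the transition width (in voxels of the given grid) over
    which membership ramps linearly from 0 to 1 at both ring boundaries.
    """
    nx, ny = shape_xy
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    r = np.hypot(x[:, None], y[None, :])
    inner = np.clip((r - r_in) / soft + 0.5, 0.0, 1.0)
    outer = np.clip((r_out - r) / soft + 0.5, 0.0, 1.0)
    return inner * outer


def _truncnorm(rng: np.random.Generator, mean, sd: float,
               lo: float, hi: float, size=None) -> np.ndarray:
    """Truncated-normal draw; degenerates to the clipped mean when sd = 0."""
    if sd == 0:
        out = np.broadcast_to(np.clip(mean, lo, hi), size or np.shape(mean))
        return np.array(out, dtype=float)
    a = (lo - np.asarray(mean)) / sd
    b = (hi - np.asarray(mean)) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size,
                             random_state=rng)


def sample_subject(spec: CohortSpec, rng: np.random.Generator,
                   subject_id: str = "sub-01",
                   with_repeat: bool = False) -> SyntheticSubject:
    """Draw one subject: truth maps, masks, and noisy DWI signal(s).

    Subject-mean D and f come from the cohort distributions; voxel truths
    are truncated normals around the subject means (f in (0.01, 0.6),
    D > 0.1e-3 mm^2/s).  Signals follow the bi-exponential forward model
    voxelwise; iid Gaussian noise of constant SD across b-values is added
    to every volume including b = 0, scaled so the empirical SNR at
    b = 1000 in GM is approximately ``spec.snr``.
    """
    nx, ny, nz = spec.shape
    mx, my, mz = spec.mask_shape
    if mz != nz:
        raise ValueError("mask and DWI grids must share the slice count")

    # geometry, in units of the DWI grid; scaled up for the structural grid
    r_in, r_out = 0.18 * nx, 0.38 * nx
    head_r = 0.46 * nx

    # structural-grid masks (shared across slices; soft boundary ~1.5 voxel)
    scale = mx / nx
    prob2d = _ring_profile((mx, my), r_in * scale, r_out * scale, 1.5 * scale)
    pve2d = _ring_profile((mx, my), r_in * scale, r_out * scale, 3.0)
    gm_mask = np.repeat(prob2d[:, :, None], mz, axis=2)
    pve_mask = np.repeat(pve2d[:, :, None], mz, axis=2)

    # DWI-grid region labels
    ring = _ring_profile((nx, ny), r_in, r_out, 1.5)
    x = np.arange(nx) - (nx - 1) / 2.0
    y = np.arange(ny) - (ny - 1) / 2.0
    head2d = np.hypot(x[:, None], y[None, :]) <= head_r
    gm_vox2d = ring >= 0.5
    head = np.repeat(head2d[:, :, None], nz, axis=2)
    gm_vox = np.repeat(gm_vox2d[:, :, None], nz, axis=2)

    # subject means, then voxel truths
    D_s = float(_truncnorm(rng, spec.gm_D_mean, spec.gm_D_sd, 0.1e-3, 3e-3))
    f_s = float(_truncnorm(rng, spec.gm_f_mean, spec.gm_f_sd, 0.01, 0.6))

    truth_D = np.full(spec.shape, np.nan)
    truth_f = np.full(spec.shape, np.nan)
    n_gm = int(gm_vox.sum())
    n_bg = int((head & ~gm_vox).sum())
    truth_D[gm_vox] = _truncnorm(rng, D_s, spec.voxel_D_sd, 0.1e-3, 3e-3,
                                 size=n_gm)
    truth_f[gm_vox] = _truncnorm(rng, f_s, spec.voxel_f_sd, 0.01, 0.6,
                                 size=n_gm)
    truth_D[head & ~gm_vox] = _truncnorm(rng, spec.wm_D, spec.voxel_D_sd,
                                         0.1e-3, 3e-3, size=n_bg)
    truth_f[head & ~gm_vox] = _truncnorm(rng, spec.wm_f, 0.01, 0.001, 0.6,
                                         size=n_bg)

    # forward signals (normalised to S(0)=1 in tissue; air stays 0)
    b = np.asarray(spec.b_values)
    dwi = np.zeros((*spec.shape, b.size))
    D_star = spec.ratio * truth_D[head]
    for j, bb in enumerate(b):
        sig = (truth_f[head] * np.exp(-bb * D_star)
               + (1.0 - truth_f[head]) * np.exp(-bb * truth_D[head]))
        vol = np.zeros(spec.shape)
        vol[head] = sig
        dwi[..., j] = vol

    # constant-across-b noise, SNR defined at b=1000 over GM
    j1000 = int(np.flatnonzero(b == 1000.0)[0])
    sigma = float(np.mean(dwi[..., j1000][gm_vox]) / spec.snr)

    def _noisy() -> np.ndarray:
        return dwi + rng.normal(0.0, sigma, size=dwi.shape)

    return SyntheticSubject(
        subject_id=subject_id,
        truth_D=truth_D,
        truth_f=truth_f,
        dwi=_noisy(),
        gm_mask=gm_mask,
        pve_mask=pve_mask,
        b_values=tuple(float(bb) for bb in b),
        noise_sigma=sigma,
        repeat_dwi=_noisy() if with_repeat else None,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort plus the spec that produced it."""

    spec: CohortSpec
    subjects: list[SyntheticSubject]

    @property
    def repeat_subjects(self) -> list[SyntheticSubject]:
        return [s for s in self.subjects if s.has_repeat]

    def save(self, out_dir: str | Path) -> None:
        """Write the cohort as NIfTI volumes + FSL-style bval text + JSON.

        Per subject: ``<id>_dwi.nii`` (4-D), ``<id>_dwi_repeat.nii`` when
        present, ``<id>_gm.nii`` and ``<id>_pve.nii`` masks, ``<id>.bval``,
        and a truth sidecar ``<id>_truth.nii`` (two-volume D, f).
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        aff = np.eye(4)
        for s in self.subjects:
            nib.save(nib.Nifti1Image(s.dwi.astype(np.float32), aff),
                     out / f"{s.subject_id}_dwi.nii")
            if s.repeat_dwi is not None:
                nib.save(nib.Nifti1Image(s.repeat_dwi.astype(np.float32), aff),
                         out / f"{s.subject_id}_dwi_repeat.nii")
            nib.save(nib.Nifti1Image(s.gm_mask.astype(np.float32), aff),
                     out / f"{s.subject_id}_gm.nii")
            nib.save(nib.Nifti1Image(s.pve_mask.astype(np.float32), aff),
                     out / f"{s.subject_id}_pve.nii")
            truth = np.stack([s.truth_D, s.truth_f], axis=-1)
            nib.save(nib.Nifti1Image(truth.astype(np.float32), aff),
                     out / f"{s.subject_id}_truth.nii")
            (out / f"{s.subject_id}.bval").write_text(
                " ".join(f"{b:g}" for b in s.b_values) + "\n"
            )
        meta = asdict(self.spec)
        meta["subject_ids"] = [s.subject_id for s in self.subjects]
        meta["repeat_ids"] = [s.subject_id for s in self.repeat_subjects]
        (out / "cohort.json").write_text(json.dumps(meta, indent=2))


def generate_cohort(spec: CohortSpec,
                    seed: int | None = None) -> SyntheticCohort:
    """Generate the full cohort; the first ``n_repeat_subjects`` get repeats.

    Deterministic under the seed (``spec.seed`` unless overridden): one
    child random stream per subject.
    """
    root = spec.seed if seed is None else seed
    streams = np.random.SeedSequence(root).spawn(spec.n_subjects)
    subjects = [
        sample_subject(
            spec,
            np.random.default_rng(ss),
            subject_id=f"sub-{i + 1:02d}",
            with_repeat=i < spec.n_repeat_subjects,
        )
        for i, ss in enumerate(streams)
    ]
    return SyntheticCohort(spec=spec, subjects=subjects)
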