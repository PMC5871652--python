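"""Voxelwise segmented fitting and cohort statistics.

Applies the segmented IVIM estimator per voxel on multi-b DWI volumes and
computes the study-level statistics used for in-vivo grey-matter analysis:
mask resampling and thresholding, ROI extraction, fixed-bin histograms,
between-scheme correlation and Bland-Altman agreement, scan-rescan
within-subject coefficient of variation (wCV, root-mean-square method), and
probabilistic-vs-partial-volume mask comparison.

Works identically on synthetic cohorts (:mod:`ivim3b.cohort`) and on real
4-D NIfTI DWI volumes with an FSL-style b-value text file and tissue masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

from .core import AcquisitionScheme, fit_signal_matrix
from .cohort import SyntheticCohort, SyntheticSubject

__all__ = [
    "ParameterMap",
    "HistogramSpec",
    "RepeatabilityResult",
    "load_dwi",
    "read_bvals",
    "fit_voxelwise",
    "resample_mask",
    "roi_histogram",
    "bland_altman",
    "pearson_r",
    "extract_roi_values",
    "within_subject_cv",
    "mask_comparison",
    "analyze_cohort",
]

MASK_THRESHOLD = 0.7  # binarisation threshold after bilinear resampling


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------


def load_dwi(path: str | Path) -> np.ndarray:
    """Read a 4-D DWI NIfTI volume as a float array (x, y, z, b)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected 4-D DWI volume, got shape {data.shape}")
    return data


def read_bvals(path: str | Path) -> np.ndarray:
    """Read an FSL-dialect b-value text file (whitespace-separated)."""
    return np.array(Path(path).read_text().split(), dtype=float)


# ---------------------------------------------------------------------------
# Voxelwise fitting
# ---------------------------------------------------------------------------


@dataclass
class ParameterMap:
    """Voxelwise D (mm^2/s) and f estimates plus validity flags.

    Voxels outside the mask, and masked voxels whose fit failed in the log
    domain, hold NaN; ``valid`` is True only where a finite fit exists.
    """

    D: np.ndarray
    f: np.ndarray
    valid: np.ndarray
    scheme: str

    def values(self, parameter: str, mask: np.ndarray | None = None) -> np.ndarray:
        """Valid estimates of 'D' or 'f', optionally under a further mask."""
        arr = {"D": self.D, "f": self.f}[parameter]
        sel = self.valid if mask is None else (self.valid & mask.astype(bool))
        return arr[sel]


def fit_voxelwise(dwi: np.ndarray, b_values, mask: np.ndarray,
                  scheme: AcquisitionScheme) -> ParameterMap:
    """Segmented fit per masked voxel of a 4-D DWI volume.

    The volume must contain b = 0 and every fit b-value of ``scheme``;
    other acquired b-values are ignored.
    """
    b_values = np.asarray(b_values, dtype=float)
    if dwi.shape[-1] != b_values.size:
        raise ValueError("last DWI axis must match the b-value list")
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.shape[:-1]:
        raise ValueError("mask grid does not match the DWI grid")

    needed = (0.0,) + tuple(scheme.fit_bvalues)
    idx = []
    for b in needed:
        hit = np.flatnonzero(b_values == b)
        if hit.size == 0:
            raise ValueError(f"required b-value {b:g} missing from volume")
        idx.append(int(hit[0]))

    D = np.full(mask.shape, np.nan)
    f = np.full(mask.shape, np.nan)
    valid = np.zeros(mask.shape, dtype=bool)
    if mask.any():
        vox = dwi[mask]  # (n_vox, n_b)
        D_v, f_v, _, ok = fit_signal_matrix(
            vox[:, idx[0]], vox[:, idx[1:]], np.asarray(scheme.fit_bvalues)
        )
        D[mask], f[mask] = D_v, f_v
        valid[mask] = ok
    return ParameterMap(D=D, f=f, valid=valid, scheme=scheme.name)


# ---------------------------------------------------------------------------
# Mask handling
# ---------------------------------------------------------------------------


def resample_mask(mask: np.ndarray, target_shape: tuple[int, ...],
                  threshold: float = MASK_THRESHOLD,
                  pve: bool = False) -> np.ndarray:
    """Resample a tissue map to the DWI grid and binarise it.

    Probabilistic path: bilinear (slicewise) interpolation to
    ``target_shape`` followed by ``value >= threshold``.  PVE path: only
    voxels with partial-volume value exactly 1 are kept *before*
    resampling, then the same interpolation and threshold are applied.
    Grids must represent the same physical extent and share the slice
    count; only in-plane resolution may differ.
    """
    mask = np.asarray(mask, dtype=float)
    if mask.ndim != len(target_shape):
        raise ValueError("mask and target dimensionality differ")
    if mask.ndim == 3 and mask.shape[2] != target_shape[2]:
        raise ValueError("slice counts differ; only in-plane resampling "
                         "is supported")
    if pve:
        mask = (mask == 1.0).astype(float)
    if mask.shape == tuple(target_shape):
        out = mask
    else:
        zoom = [t / s for t, s in zip(target_shape, mask.shape)]
        if mask.ndim == 3:
            zoom[2] = 1.0
        out = ndimage.zoom(mask, zoom, order=1, grid_mode=True,
                           mode="grid-constant")
        # guard against off-by-one from rounding inside zoom
        out = out[tuple(slice(0, t) for t in target_shape)]
    return out >= threshold


# ---------------------------------------------------------------------------
# Histograms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HistogramSpec:
    """Fixed-bin histogram layout shared by every subject and scheme.

    The bin count is the square root of the maximum ROI voxel count across
    the cohort (floored); the range always starts at zero and ends at the
    cohort-wide maximum value, so counts are comparable across subjects.
    """

    n_bins: int
    vmax: float

    @classmethod
    def from_cohort(cls, max_count: int, vmax: float) -> "HistogramSpec":
        if max_count < 1 or vmax <= 0:
            raise ValueError("need a positive voxel count and maximum value")
        return cls(n_bins=int(math.floor(math.sqrt(max_count))), vmax=vmax)

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, self.vmax, self.n_bins + 1)


def roi_histogram(values, spec: HistogramSpec) -> np.ndarray:
    """Histogram counts of ROI values under a fixed bin layout."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("values must be non-empty")
    counts, _ = np.histogram(values, bins=spec.edges)
    return counts


# ---------------------------------------------------------------------------
# Agreement and repeatability statistics
# ---------------------------------------------------------------------------


def bland_altman(values_a, values_b) -> dict[str, float]:
    """Bland-Altman agreement of paired measurements.

    Returns the mean difference (bias) and the 95% limits of agreement
    (bias +/- 1.96 SD of the differences).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired inputs must have equal length")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return {"bias": bias, "loa_low": bias - 1.96 * sd,
            "loa_high": bias + 1.96 * sd, "sd": sd}


def pearson_r(values_a, values_b) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3:
        raise ValueError("need at least three pairs")
    r, p = sps.pearsonr(a, b)
    return float(r), float(p)


@dataclass(frozen=True)
class RepeatabilityResult:
    """Within-subject CV of one parameter under one scheme."""

    parameter: str
    scheme: str
    wcv_percent: float
    n_pairs: int


def extract_roi_values(pmap: ParameterMap, gm_mask: np.ndarray,
                       parameter: str, roi_size: int = 4,
                       offset: float | None = None) -> list[np.ndarray]:
    """Values in two ``roi_size`` x ``roi_size`` ROIs on the middle slice.

    ROI centres sit on the grey-matter region at the mask centroid shifted
    left/right by ``offset`` voxels (default: the mean in-plane radius of
    the masked voxels, which lands on a ring-shaped cortex).
    """
    gm = np.asarray(gm_mask, dtype=bool)
    z = gm.shape[2] // 2 if gm.ndim == 3 else None
    plane = gm[:, :, z] if z is not None else gm
    xs, ys = np.nonzero(plane)
    if xs.size == 0:
        raise ValueError("empty grey-matter mask")
    cx, cy = xs.mean(), ys.mean()
    if offset is None:
        offset = float(np.hypot(xs - cx, ys - cy).mean())
    half = roi_size // 2
    rois = []
    for sign in (+1, -1):
        x0 = int(round(cx + sign * offset)) - half
        y0 = int(round(cy)) - half
        sl = (slice(x0, x0 + roi_size), slice(y0, y0 + roi_size))
        arr = {"D": pmap.D, "f": pmap.f}[parameter]
        block = arr[sl + (z,)] if z is not None else arr[sl]
        rois.append(block[np.isfinite(block)])
    return rois


def within_subject_cv(pairs) -> float:
    """Root-mean-square within-subject CV (%) over measurement pairs.

    ``pairs`` is an (n, 2) array of repeated ROI-mean measurements.  Each
    pair contributes (SD/mean)^2 with the sample SD (ddof=1, the standard
    repeatability convention for n = 2); the wCV is 100 * sqrt of the mean
    of those terms.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 1:
        raise ValueError("pairs must be an (n, 2) array with n >= 1")
    sd = arr.std(axis=1, ddof=1)
    mean = arr.mean(axis=1)
    if np.any(mean == 0):
        raise ValueError("pair mean of zero; wCV undefined")
    return float(100.0 * np.sqrt(np.mean((sd / mean) ** 2)))


def mask_comparison(pmap: ParameterMap, prob_mask: np.ndarray,
                    pve_mask: np.ndarray,
                    threshold: float = MASK_THRESHOLD) -> pd.DataFrame:
    """Summary statistics of D and f under probabilistic vs PVE masks.

    Both masks are resampled to the map grid (the PVE path keeps only
    fully-grey-matter voxels before resampling).  Reports mean, median,
    10th and 90th percentiles per parameter per mask, plus a Welch t-test
    p-value for the difference of means (reported, never gated on).
    """
    target = pmap.D.shape
    m_prob = resample_mask(prob_mask, target, threshold=threshold)
    m_pve = resample_mask(pve_mask, target, threshold=threshold, pve=True)
    rows = []
    for param in ("D", "f"):
        vals = {"probabilistic": pmap.values(param, m_prob),
                "pve": pmap.values(param, m_pve)}
        _, p_val = sps.ttest_ind(vals["probabilistic"], vals["pve"],
                                 equal_var=False)
        for mask_name, v in vals.items():
            rows.append({
                "parameter": param,
                "mask": mask_name,
                "n_voxels": int(v.size),
                "mean": float(np.mean(v)),
                "median": float(np.median(v)),
                "p10": float(np.percentile(v, 10)),
                "p90": float(np.percentile(v, 90)),
                "p_diff_means": float(p_val),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort-level orchestration
# ---------------------------------------------------------------------------


def _subject_gm_mask(subject: SyntheticSubject) -> np.ndarray:
    return resample_mask(subject.gm_mask, subject.truth_D.shape)


def analyze_cohort(cohort: SyntheticCohort,
                   b_lows: tuple[float, float] = (300.0, 500.0)
                   ) -> dict[str, object]:
    """Full in-vivo-style analysis of a (synthetic) cohort.

    Fits every subject with the two-point schemes ``[b_low, 1000]`` for each
    requested ``b_low``, then computes per-subject GM means, between-scheme
    Pearson correlation and Bland-Altman agreement, shared-bin average
    histograms, and the scan-rescan wCV from the repeat subjects.
    """
    schemes = {bl: AcquisitionScheme.two_point(bl) for bl in b_lows}
    rows = []
    maps: dict[tuple[str, float], ParameterMap] = {}
    gm_masks: dict[str, np.ndarray] = {}
    for s in cohort.subjects:
        gm = _subject_gm_mask(s)
        gm_masks[s.subject_id] = gm
        for bl, scheme in schemes.items():
            pm = fit_voxelwise(s.dwi, s.b_values, gm, scheme)
            maps[(s.subject_id, bl)] = pm
            rows.append({
                "subject": s.subject_id,
                "scheme": scheme.name,
                "b_low": bl,
                "mean_D": float(np.nanmean(pm.values("D"))),
                "mean_f": float(np.nanmean(pm.values("f"))),
                "n_voxels": int(pm.valid.sum()),
            })
    subject_means = pd.DataFrame(rows)

    bl_a, bl_b = b_lows
    wide = subject_means.pivot(index="subject", columns="b_low",
                               values=["mean_D", "mean_f"])
    corr = {
        param: pearson_r(wide[(f"mean_{param}", bl_a)],
                         wide[(f"mean_{param}", bl_b)])
        for param in ("D", "f")
    }
    ba = {
        param: bland_altman(wide[(f"mean_{param}", bl_a)],
                            wide[(f"mean_{param}", bl_b)])
        for param in ("D", "f")
    }

    # shared histogram layout: sqrt of the max ROI voxel count, range [0, max]
    max_count = int(subject_means["n_voxels"].max())
    histograms: dict[tuple[str, float], np.ndarray] = {}
    hist_specs: dict[str, HistogramSpec] = {}
    for param in ("D", "f"):
        vmax = max(float(np.max(maps[(s.subject_id, bl)].values(param)))
                   for s in cohort.subjects for bl in b_lows)
        spec = HistogramSpec.from_cohort(max_count, vmax)
        hist_specs[param] = spec
        for bl in b_lows:
            counts = np.mean(
                [roi_histogram(maps[(s.subject_id, bl)].values(param), spec)
                 for s in cohort.subjects], axis=0)
            histograms[(param, bl)] = counts

    # wCV from repeat subjects: two 4x4 ROIs per measurement pair
    wcv_rows = []
    for bl, scheme in schemes.items():
        for param in ("D", "f"):
            pairs = []
            for s in cohort.repeat_subjects:
                gm = gm_masks[s.subject_id]
                pm1 = maps[(s.subject_id, bl)]
                pm2 = fit_voxelwise(s.repeat_dwi, s.b_values, gm, scheme)
                rois1 = extract_roi_values(pm1, gm, param)
                rois2 = extract_roi_values(pm2, gm, param)
                for r1, r2 in zip(rois1, rois2):
                    pairs.append([float(np.mean(r1)), float(np.mean(r2))])
            if pairs:
                wcv_rows.append(RepeatabilityResult(
                    parameter=param, scheme=scheme.name,
                    wcv_percent=within_subject_cv(np.asarray(pairs)),
                    n_pairs=len(pairs)))

    return {
        "subject_means": subject_means,
        "pearson": corr,
        "bland_altman": ba,
        "histograms": histograms,
        "histogram_specs": hist_specs,
        "wcv": wcv_rows,
        "maps": maps,
    }
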