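"""Bias, error and reproducibility statistics, and scheme recommendation.

All statistics are computed per (parameter, true f) over the Monte-Carlo
iterations, then aggregated over the f grid as mean +/- SD:

* relative bias      mean(x_i - X) / X
* relative error     sqrt(mean((x_i - X)^2)) / X     (RMS, not on means)
* CoV (%)            100 * SD(x_i) / mean(x_i)
* overall error      sigma_{D+f} = sigma_D + sigma_f

Population SD (divide by N) is used throughout, matching the definitions
above; at N = 1000 the distinction from the sample SD is negligible.
Invalid fits are excluded from all moments and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AcquisitionScheme, TissueModel
from .noise import MonteCarloBatch, NoiseSpec

__all__ = [
    "ErrorSummary",
    "Recommendation",
    "relative_bias",
    "relative_error",
    "coefficient_of_variation",
    "overall_error",
    "aggregate_over_grid",
    "summarize_batch",
    "error_table",
    "recommend_scheme",
]


def relative_bias(estimates, truth: float) -> float:
    """Mean signed deviation of the estimates, normalised by the truth."""
    x = np.asarray(estimates, dtype=float)
    if truth == 0:
        raise ValueError("truth must be nonzero")
    return float(np.mean(x - truth) / truth)


def relative_error(estimates, truth: float) -> float:
    """RMS distance of the estimates from the truth, normalised by it."""
    x = np.asarray(estimates, dtype=float)
    if truth == 0:
        raise ValueError("truth must be nonzero")
    return float(np.sqrt(np.mean((x - truth) ** 2)) / truth)


def coefficient_of_variation(estimates) -> float:
    """Population SD over mean of the estimates, in percent."""
    x = np.asarray(estimates, dtype=float)
    m = np.mean(x)
    if m == 0:
        raise ValueError("mean of estimates is zero; CoV undefined")
    return float(100.0 * np.std(x) / m)


def overall_error(err_D: float, err_f: float) -> float:
    """Combined relative error sigma_{D+f} = sigma_D + sigma_f."""
    return err_D + err_f


def aggregate_over_grid(per_f_values) -> tuple[float, float]:
    """Mean and population SD of a per-f statistic over the f grid."""
    x = np.asarray(per_f_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two f-grid points to aggregate")
    return float(np.mean(x)), float(np.std(x))


@dataclass
class ErrorSummary:
    """Per-f and grid-aggregated statistics for one parameter of one batch."""

    model: str
    scheme: str
    snr: float
    parameter: str  # 'D' or 'f'
    f_grid: np.ndarray
    per_f_bias: np.ndarray
    per_f_relerr: np.ndarray
    per_f_cov: np.ndarray
    n_invalid: np.ndarray

    @property
    def bias_grid(self) -> tuple[float, float]:
        return aggregate_over_grid(self.per_f_bias)

    @property
    def relerr_grid(self) -> tuple[float, float]:
        return aggregate_over_grid(self.per_f_relerr)

    @property
    def cov_grid(self) -> tuple[float, float]:
        return aggregate_over_grid(self.per_f_cov)


def summarize_batch(batch: MonteCarloBatch) -> dict[str, ErrorSummary]:
    """Per-f bias/relative-error/CoV for D and f of one Monte-Carlo batch.

    The truth for D is the tissue model's D at every f; the truth for f is
    the grid value itself.
    """
    out: dict[str, ErrorSummary] = {}
    for param in ("D", "f"):
        bias, relerr, cov = [], [], []
        for f_true in batch.f_grid:
            est = batch.estimates(float(f_true), param)
            truth = batch.model.D if param == "D" else float(f_true)
            bias.append(relative_bias(est, truth))
            relerr.append(relative_error(est, truth))
            cov.append(coefficient_of_variation(est))
        out[param] = ErrorSummary(
            model=batch.model.name,
            scheme=batch.scheme.name,
            snr=batch.noise.snr,
            parameter=param,
            f_grid=batch.f_grid,
            per_f_bias=np.array(bias),
            per_f_relerr=np.array(relerr),
            per_f_cov=np.array(cov),
            n_invalid=batch.n_invalid,
        )
    return out


def _relerr_se(estimates: np.ndarray, truth: float) -> float:
    """Monte-Carlo standard error of the per-f relative error (delta method)."""
    e2 = (np.asarray(estimates, float) - truth) ** 2
    m = np.mean(e2)
    if m == 0:
        return 0.0
    var_m = np.var(e2) / e2.size
    return float(np.sqrt(var_m) / (2.0 * np.sqrt(m)) / abs(truth))


def error_table(batches: list[MonteCarloBatch]) -> pd.DataFrame:
    """Grid-aggregated error table, one row per (model, scheme, snr).

    Columns include the grid mean +/- SD of the D and f relative errors and
    of the overall error, plus a delta-method Monte-Carlo standard error of
    the grid-mean overall error (used for recommendation tie-breaking).
    """
    rows = []
    for batch in batches:
        summ = summarize_batch(batch)
        per_overall = summ["D"].per_f_relerr + summ["f"].per_f_relerr
        se_per_f = []
        for f_true in batch.f_grid:
            se_D = _relerr_se(batch.estimates(float(f_true), "D"), batch.model.D)
            se_f = _relerr_se(batch.estimates(float(f_true), "f"), float(f_true))
            se_per_f.append(se_D + se_f)
        se_grid = float(np.sqrt(np.sum(np.square(se_per_f))) / len(se_per_f))
        ov_mean, ov_sd = aggregate_over_grid(per_overall)
        rows.append(
            {
                "model": batch.model.name,
                "scheme": batch.scheme.name,
                "snr": batch.noise.snr,
                "calibration": batch.noise.calibration,
                "bias_D_mean": summ["D"].bias_grid[0],
                "bias_D_sd": summ["D"].bias_grid[1],
                "bias_f_mean": summ["f"].bias_grid[0],
                "bias_f_sd": summ["f"].bias_grid[1],
                "relerr_D_mean": summ["D"].relerr_grid[0],
                "relerr_D_sd": summ["D"].relerr_grid[1],
                "relerr_f_mean": summ["f"].relerr_grid[0],
                "relerr_f_sd": summ["f"].relerr_grid[1],
                "cov_D_mean": summ["D"].cov_grid[0],
                "cov_f_mean": summ["f"].cov_grid[0],
                "overall_mean": ov_mean,
                "overall_sd": ov_sd,
                "overall_se": se_grid,
                "n_invalid_total": int(batch.n_invalid.sum()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class Recommendation:
    """Recommended scheme(s) for one (model, SNR) cell.

    ``chosen_schemes`` holds the argmin of the grid-mean overall error plus
    any scheme whose overall error is within one Monte-Carlo standard error
    of the difference from that minimum (statistical ties are reported as
    ranges rather than broken arbitrarily).  ``below_10pct`` lists every
    scheme whose grid-mean f relative error is under 10%.
    """

    model: str
    snr: float
    chosen_schemes: list[str]
    best_scheme: str
    best_overall: float
    below_10pct: list[str]
    table: pd.DataFrame


def recommend_scheme(table: pd.DataFrame, model: str,
                     snr: float) -> Recommendation:
    """Pick the optimal b-value scheme(s) for one (model, SNR) cell."""
    sub = table[(table["model"] == model) & (table["snr"] == snr)]
    if sub.empty:
        raise ValueError(f"no rows for model={model!r}, snr={snr}")
    sub = sub.reset_index(drop=True)
    i_best = int(sub["overall_mean"].idxmin())
    best = sub.loc[i_best]
    ties = []
    for _, row in sub.iterrows():
        diff = row["overall_mean"] - best["overall_mean"]
        se_diff = float(np.hypot(row["overall_se"], best["overall_se"]))
        if diff < se_diff:
            ties.append(row["scheme"])
    below = sub.loc[sub["relerr_f_mean"] < 0.10, "scheme"].tolist()
    return Recommendation(
        model=model,
        snr=snr,
        chosen_schemes=ties,
        best_scheme=str(best["scheme"]),
        best_overall=float(best["overall_mean"]),
        below_10pct=below,
        table=sub,
    )
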