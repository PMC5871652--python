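"""Forward IVIM signal model and the segmented (constrained) estimator.

The intravoxel incoherent motion (IVIM) model describes the diffusion-weighted
MR signal in tissue as a bi-exponential decay

    S(b)/S(0) = f * exp(-b * D*) + (1 - f) * exp(-b * D)

where ``D`` is the tissue diffusion coefficient (mm^2/s), ``D*`` the
pseudo-diffusion coefficient attributed to capillary perfusion, and ``f`` the
perfusion fraction.  The segmented (constrained) estimator assumes the
perfusion compartment is fully attenuated at high b-values, fits

    S(b)/S(0) = exp(-b * D)

log-linearly over the high-b measurements, and recovers the perfusion
fraction from the offset of the extrapolated intercept S(int) to the
measured b=0 signal:

    f = 1 - S(int) / S(0)

Estimates are deliberately *not* clamped to physical ranges: bias and
variability statistics downstream must see the raw estimator output.  Only
non-positive signals (which break the log transform) mark a fit invalid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "TissueModel",
    "AcquisitionScheme",
    "SignalCurve",
    "FitResult",
    "BRAIN",
    "KIDNEY",
    "LIVER",
    "TISSUE_MODELS",
    "ivim_signal",
    "segmented_fit",
    "two_point_fit",
    "fit_signal_matrix",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TissueModel:
    """Ground-truth diffusion/perfusion scenario.

    Parameters
    ----------
    name
        Human-readable label (e.g. ``"brain"``).
    D
        Tissue diffusion coefficient in mm^2/s.
    D_star
        Pseudo-diffusion coefficient in mm^2/s; must exceed ``D``.
    """

    name: str
    D: float
    D_star: float

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.D_star <= self.D:
            raise ValueError(
                f"D* ({self.D_star}) must exceed D ({self.D}); "
                "the perfusion compartment decays faster than tissue water"
            )

    @property
    def ratio(self) -> float:
        """Pseudo-diffusion to diffusion ratio D*/D (dimensionless)."""
        return self.D_star / self.D


#: Canonical low-perfusion scenario (grey matter); D*/D = 10.
BRAIN = TissueModel("brain", D=0.7e-3, D_star=7e-3)
#: Canonical medium-perfusion scenario; D*/D = 20.
KIDNEY = TissueModel("kidney", D=0.7e-3, D_star=14e-3)
#: Canonical high-perfusion scenario; D*/D = 70.
LIVER = TissueModel("liver", D=0.7e-3, D_star=49e-3)

TISSUE_MODELS = {m.name: m for m in (BRAIN, KIDNEY, LIVER)}


@dataclass(frozen=True)
class AcquisitionScheme:
    """An ordered b-value list with the subset used by the segmented fit.

    ``fit_bvalues`` are the nonzero b-values entering the log-linear fit;
    the common rapid protocol uses exactly two, written ``[b_low, b_high]``.
    """

    b_values: tuple[float, ...]
    fit_bvalues: tuple[float, ...]

    def __post_init__(self) -> None:
        bv = tuple(float(b) for b in self.b_values)
        fb = tuple(float(b) for b in self.fit_bvalues)
        object.__setattr__(self, "b_values", bv)
        object.__setattr__(self, "fit_bvalues", fb)
        if 0.0 not in bv:
            raise ValueError("b_values must contain b=0 (normalisation point)")
        if len(fb) < 2:
            raise ValueError("at least two nonzero fit b-values are required")
        if any(b <= 0 for b in fb):
            raise ValueError("fit b-values must be positive")
        if len(set(fb)) != len(fb):
            raise ValueError("fit b-values must be distinct")
        missing = set(fb) - set(bv)
        if missing:
            raise ValueError(f"fit b-values {sorted(missing)} not in b_values")

    @classmethod
    def two_point(cls, b_low: float, b_high: float = 1000.0) -> "AcquisitionScheme":
        """Three-acquisition protocol {0, b_low, b_high} fitted on the pair."""
        if not 0 < b_low < b_high:
            raise ValueError("need 0 < b_low < b_high")
        return cls(b_values=(0.0, b_low, b_high), fit_bvalues=(b_low, b_high))

    @property
    def fit_pair(self) -> tuple[float, float]:
        """(b_low, b_high): the extreme fit b-values."""
        return (min(self.fit_bvalues), max(self.fit_bvalues))

    @property
    def name(self) -> str:
        lo, hi = self.fit_pair
        return f"[{lo:g},{hi:g}]"


@dataclass
class SignalCurve:
    """Normalised signal S(b)/S(0) sampled on a b-value grid."""

    b_values: np.ndarray
    signals: np.ndarray
    truth: tuple[TissueModel, float] | None = None

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.b_values.shape != self.signals.shape:
            raise ValueError("b_values and signals must have equal length")

    def at(self, b: float) -> float:
        idx = np.flatnonzero(self.b_values == b)
        if idx.size == 0:
            raise KeyError(f"no measurement at b={b}")
        return float(self.signals[idx[0]])


@dataclass(frozen=True)
class FitResult:
    """Segmented-fit output for one signal curve.

    ``valid`` is False when a required signal was non-positive (log-domain
    failure); such results carry NaN estimates and are excluded from
    summary statistics, with their count reported alongside.
    """

    D_est: float
    f_est: float
    S_int: float
    valid: bool = True


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------


def ivim_signal(model: TissueModel, f, b):
    """Bi-exponential IVIM signal ``f e^{-bD*} + (1-f) e^{-bD}``.

    Accepts scalar or array ``f`` and ``b`` (broadcast together); returns the
    normalised signal S(b)/S(0), which lies in (0, 1] for b >= 0.
    """
    f = np.asarray(f, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("perfusion fraction f must lie in [0, 1]")
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    out = f * np.exp(-b * model.D_star) + (1.0 - f) * np.exp(-b * model.D)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Segmented (constrained) fit
# ---------------------------------------------------------------------------


def two_point_fit(S0: float, S_low: float, S_high: float,
                  b_low: float, b_high: float) -> FitResult:
    """Closed-form segmented fit through exactly two high-b points.

    D  = ln(S(b_low)/S(b_high)) / (b_high - b_low)
    S(int) = exp of the line ln S extrapolated to b=0
    f  = 1 - S(int)/S(0)  with the *measured* S(0) in the denominator.
    """
    if S0 <= 0 or S_low <= 0 or S_high <= 0:
        return FitResult(math.nan, math.nan, math.nan, valid=False)
    span = b_high - b_low
    D_est = math.log(S_low / S_high) / span
    # intercept of the log-linear fit at b=0
    ln_int = (b_high * math.log(S_low) - b_low * math.log(S_high)) / span
    S_int = math.exp(ln_int)
    f_est = 1.0 - S_int / S0
    return FitResult(D_est=D_est, f_est=f_est, S_int=S_int, valid=True)


def fit_signal_matrix(S0: np.ndarray, S_fit: np.ndarray,
                      b_fit: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised log-linear segmented fit.

    Parameters
    ----------
    S0
        Measured b=0 signals, shape ``(n,)``.
    S_fit
        Signals at the fit b-values, shape ``(n, k)`` with ``k >= 2``.
    b_fit
        The ``k`` nonzero fit b-values.

    Returns
    -------
    (D_est, f_est, S_int, valid) arrays of shape ``(n,)``.  Rows with any
    non-positive required signal are flagged invalid and carry NaN.

    Notes
    -----
    Ordinary least squares of ln S on b; with ``k == 2`` this is the exact
    line through the two points, identical to the closed-form solution.
    """
    S0 = np.asarray(S0, dtype=float)
    S_fit = np.asarray(S_fit, dtype=float)
    b_fit = np.asarray(b_fit, dtype=float)
    if S_fit.ndim != 2 or S_fit.shape[1] != b_fit.size:
        raise ValueError("S_fit must be (n, k) matching b_fit of length k")

    valid = (S0 > 0) & np.all(S_fit > 0, axis=1)
    n = S0.shape[0]
    D_est = np.full(n, np.nan)
    f_est = np.full(n, np.nan)
    S_int = np.full(n, np.nan)
    if valid.any():
        lnS = np.log(S_fit[valid])
        b_c = b_fit - b_fit.mean()
        slope = (lnS * b_c).sum(axis=1) / (b_c ** 2).sum()
        intercept = lnS.mean(axis=1) - slope * b_fit.mean()
        D_est[valid] = -slope
        S_int[valid] = np.exp(intercept)
        f_est[valid] = 1.0 - S_int[valid] / S0[valid]
    return D_est, f_est, S_int, valid


def segmented_fit(curve: SignalCurve, scheme: AcquisitionScheme) -> FitResult:
    """Segmented IVIM fit of one signal curve under ``scheme``.

    Fits ln S linearly over the scheme's nonzero fit b-values (exact
    two-point line when the pair has two members, ordinary least squares
    otherwise), then ``D_est = -slope``, ``S_int = exp(intercept)`` and
    ``f_est = 1 - S_int / S(0)`` with the measured S(0).

    Estimates are returned unclamped: noise may legitimately drive
    ``D_est <= 0`` or ``f_est`` outside [0, 1].  Only non-positive input
    signals (log failure) yield an invalid result.
    """
    S0 = curve.at(0.0)
    S_fit = np.array([curve.at(b) for b in scheme.fit_bvalues])
    D, f, S_int, valid = fit_signal_matrix(
        np.array([S0]), S_fit[None, :], np.asarray(scheme.fit_bvalues)
    )
    return FitResult(float(D[0]), float(f[0]), float(S_int[0]), bool(valid[0]))
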