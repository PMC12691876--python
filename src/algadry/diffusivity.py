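"""Fick-slab moisture diffusion: forward model, slope method, Arrhenius fit.

The slab solution of Fick's second law gives, for a half-thickness L and
uniform initial moisture,

    MR(t) = (8/pi^2) * sum_{n>=1} 1/(2n-1)^2 * exp(-(2n-1)^2 pi^2 D_eff t / 4 L^2)

For long times the first term dominates and ln(MR) is linear in t with
slope -pi^2 D_eff / (4 L^2); the slope method regresses ln(MR) on time
(in seconds) and reads D_eff off that slope.  Temperature dependence is
summarized by an Arrhenius law D_eff = D_0 exp(-E_a / R T).

The gas constant defaults to 8.3123 J/mol/K to keep arithmetic traceable
to the engineering sources this package follows; pass ``gas_constant=8.314``
for the CODATA value (the difference is far below estimation error).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .errors import InsufficientDataError, NoDryingError, ValidationError
from .types import MoistureRatioCurve

GAS_CONSTANT_J_MOL_K = 8.3123

__all__ = [
    "DiffusivityEstimate",
    "ArrheniusFit",
    "fick_mr",
    "estimate_deff_slope",
    "arrhenius_fit",
]


@dataclass
class DiffusivityEstimate:
    """Effective moisture diffusivity at one air temperature."""

    temp_C: float
    d_eff_m2_s: float
    slope_per_s: float
    intercept: float
    r2: float
    half_thickness_m: float
    n_points_used: int
    mr_window: tuple


@dataclass
class ArrheniusFit:
    """Arrhenius parameters for D_eff across temperatures."""

    d0_m2_s: float
    ea_J_mol: float
    r2: float
    slope_K: float  # -(regression slope of ln D_eff vs 1/T); E_a = slope_K * R
    gas_constant: float = GAS_CONSTANT_J_MOL_K


def fick_mr(d_eff: float, half_thickness_m: float, t_s, n_terms: int = 200) -> np.ndarray:
    """Series solution MR(t) for a slab of half-thickness L (times in seconds)."""
    if d_eff <= 0 or half_thickness_m <= 0:
        raise ValidationError("d_eff and half_thickness_m must be > 0")
    if n_terms < 1:
        raise ValidationError("n_terms must be >= 1")
    t = np.atleast_1d(np.asarray(t_s, dtype=float))
    if np.any(t < 0):
        raise ValidationError("times must be >= 0")
    odd = 2.0 * np.arange(1, n_terms + 1) - 1.0  # 1, 3, 5, ...
    decay = np.pi**2 * d_eff / (4.0 * half_thickness_m**2)
    terms = np.exp(-np.outer(t, odd**2) * decay) / odd**2
    mr = (8.0 / np.pi**2) * terms.sum(axis=1)
    mr = np.clip(mr, 0.0, 1.0 + 1e-9)
    return mr if np.ndim(t_s) else float(mr[0])


def estimate_deff_slope(
    curve: MoistureRatioCurve,
    half_thickness_m: float = 0.001,
    mr_window: tuple = (0.95, 0.05),
    temp_C: float = float("nan"),
) -> DiffusivityEstimate:
    """Slope-method estimate of D_eff from ln(MR) regressed on time.

    Only points with mr_min <= MR <= mr_max enter the regression: very
    early points deviate from one-term log-linearity and near-zero MR makes
    log-noise explode.  Times are converted to seconds internally, so the
    returned D_eff is in m²/s regardless of the curve's unit tag.
    """
    if half_thickness_m <= 0:
        raise ValidationError("half_thickness_m must be > 0")
    mr_max, mr_min = mr_window
    if not mr_max > mr_min >= 0:
        raise ValidationError(f"invalid mr_window {mr_window!r}: need max > min >= 0")
    t_s = curve.times_in("s")
    mr = curve.mr
    mask = (mr > 0) & (mr >= mr_min) & (mr <= mr_max)
    n_used = int(mask.sum())
    if n_used < 3:
        raise InsufficientDataError(
            f"slope method needs >= 3 points inside MR window {mr_window}, got {n_used}"
        )
    fit = linregress(t_s[mask], np.log(mr[mask]))
    if fit.slope >= 0:
        raise NoDryingError("ln(MR) slope is nonnegative: no net drying in window")
    d_eff = -fit.slope * 4.0 * half_thickness_m**2 / np.pi**2
    return DiffusivityEstimate(
        temp_C=float(temp_C),
        d_eff_m2_s=float(d_eff),
        slope_per_s=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        half_thickness_m=float(half_thickness_m),
        n_points_used=n_used,
        mr_window=(float(mr_max), float(mr_min)),
    )


def arrhenius_fit(
    estimates: list,
    gas_constant: float = GAS_CONSTANT_J_MOL_K,
) -> ArrheniusFit:
    """Least squares of ln(D_eff) on 1/T across >= 2 distinct temperatures.

    Accepts DiffusivityEstimate objects or (temp_C, d_eff) pairs.
    """
    temps, deffs = [], []
    for item in estimates:
        if isinstance(item, DiffusivityEstimate):
            temps.append(item.temp_C)
            deffs.append(item.d_eff_m2_s)
        else:
            t, d = item
            temps.append(float(t))
            deffs.append(float(d))
    temps = np.asarray(temps)
    deffs = np.asarray(deffs)
    if temps.size < 2:
        raise InsufficientDataError("Arrhenius fit needs >= 2 temperatures")
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures in Arrhenius fit")
    if np.any(deffs <= 0):
        raise ValidationError("all d_eff values must be > 0")
    inv_T = 1.0 / (temps + 273.15)
    fit = linregress(inv_T, np.log(deffs))
    slope_K = -float(fit.slope)
    return ArrheniusFit(
        d0_m2_s=float(np.exp(fit.intercept)),
        ea_J_mol=slope_K * gas_constant,
        r2=float(fit.rvalue**2),
        slope_K=slope_K,
        gas_constant=gas_constant,
    )
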