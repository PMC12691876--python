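"""Spectrophotometric calculators for pigments and antioxidant capacity.

Total carotenoids (CT) and fucoxanthin (FC) come from five-wavelength
absorbance combinations (all turbidity-corrected against A750):

    alpha = A480 - A750
    beta  = (A631 - A750) + (A582 - A750) - 0.297 (A665 - A750)
    gamma = A665 - A750

    CT = 4 alpha                       (µg/mL)
    FC = 7.69 alpha - 5.55 beta - 0.377 gamma   (µg/mL)

DPPH radical-scavenging activity is the percent drop of the control
absorbance at 517 nm.  Linear calibration (absorbance on concentration)
supports gallic-acid / quercetin standard curves for TPC / TFC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .errors import InsufficientDataError, ValidationError
from .types import AssaySample

__all__ = [
    "PigmentResult",
    "CalibrationLine",
    "carotenoid_total",
    "fucoxanthin",
    "fucoxanthin_share",
    "dpph_inhibition",
    "linear_calibration",
]


@dataclass
class PigmentResult:
    """Derived pigment quantities for one absorbance quintuple."""

    alpha: float
    beta: float
    gamma: float
    ct: float
    fc: float
    fc_share_pct: float | None  # None when CT <= 0


def _abc(sample: AssaySample):
    alpha = sample.a480 - sample.a750
    gamma = sample.a665 - sample.a750
    beta = (sample.a631 - sample.a750) + (sample.a582 - sample.a750) - 0.297 * gamma
    return alpha, beta, gamma


def carotenoid_total(sample: AssaySample) -> float:
    """Total carotenoids CT = 4·alpha (µg/mL); negative values are flagged."""
    ct = 4.0 * _abc(sample)[0]
    if ct < 0:
        warnings.warn(f"negative CT = {ct:.4f}: check blank/baseline", stacklevel=2)
    return ct


def fucoxanthin(sample: AssaySample) -> PigmentResult:
    """Fucoxanthin FC with its intermediate (alpha, beta, gamma) triple."""
    alpha, beta, gamma = _abc(sample)
    ct = 4.0 * alpha
    fc = 7.69 * alpha - 5.55 * beta - 0.377 * gamma
    if fc < 0:
        warnings.warn(f"negative FC = {fc:.4f}: check blank/baseline", stacklevel=2)
    share = 100.0 * fc / ct if ct > 0 else None
    return PigmentResult(alpha=alpha, beta=beta, gamma=gamma, ct=ct, fc=fc, fc_share_pct=share)


def fucoxanthin_share(fc: float, ct: float) -> float:
    """Fucoxanthin as a percentage of total carotenoids, 100·FC/CT."""
    if ct <= 0:
        raise ValidationError(f"share undefined for CT = {ct} <= 0")
    return 100.0 * fc / ct


def dpph_inhibition(abs_control: float, abs_sample: float) -> float:
    """DPPH inhibition (%) = 100·(A_control − A_sample)/A_control."""
    if abs_control <= 0:
        raise ValidationError("control absorbance must be > 0")
    pct = 100.0 * (abs_control - abs_sample) / abs_control
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"DPPH inhibition {pct:.2f}% outside [0, 100]", stacklevel=2)
    return pct


@dataclass
class CalibrationLine:
    """Ordinary least-squares standard curve, absorbance on concentration."""

    slope: float
    intercept: float
    r2: float
    conc_min: float
    conc_max: float

    def predict(self, absorbance: float) -> float:
        """Invert the line: concentration for a measured absorbance."""
        conc = (absorbance - self.intercept) / self.slope
        if not self.conc_min <= conc <= self.conc_max:
            warnings.warn(
                f"predicted concentration {conc:.4g} extrapolates beyond the "
                f"standard range [{self.conc_min:.4g}, {self.conc_max:.4g}]",
                stacklevel=2,
            )
        return conc


def linear_calibration(concentrations, absorbances) -> CalibrationLine:
    """Fit a standard curve from >= 3 standards at distinct concentrations."""
    conc = np.asarray(concentrations, dtype=float)
    absb = np.asarray(absorbances, dtype=float)
    if conc.size != absb.size:
        raise ValidationError("concentration and absorbance lengths differ")
    if conc.size < 3:
        raise InsufficientDataError("calibration needs >= 3 standards")
    if np.unique(conc).size < 2:
        raise ValidationError("standards must span distinct concentrations")
    fit = linregress(conc, absb)
    if fit.slope == 0:
        raise ValidationError("degenerate calibration: zero slope")
    return CalibrationLine(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        conc_min=float(conc.min()),
        conc_max=float(conc.max()),
    )
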