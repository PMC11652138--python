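"""Absolute calcium calibration for ratiometric Fura-2 imaging.

Converts background- and autofluorescence-corrected 340/380 nm excitation
ratios R into absolute Ca2+ concentrations via the ratiometric calibration

    [Ca2+] = K_eff * (R - R_min) / (R_max - R)

where the effective dissociation constant folds the indicator's in-cell
dissociation constant K_D together with an ROI- or compartment-specific
correction factor alpha that accounts for the unequal excitation and
collection efficiency of the Ca-bound and Ca-free dye forms:

    K_eff = K_D * (R_max + alpha) / (R_min + alpha)

R_min and R_max are the ratios at zero and saturating Ca2+, measured in situ
by ionomycin permeabilisation with EGTA-buffered (depletion) and 2 mM Ca2+
(saturation) media.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import CalciumTrace, RatioTrace

__all__ = [
    "CalibrationParams",
    "compute_keff",
    "ratio_to_concentration",
    "concentration_to_ratio",
    "estimate_rmin_rmax",
    "calibrate_trace",
    "CalibrationError",
    "FURA2_KD_NM",
]

#: In-cell dissociation constant of Fura-2, nM.
FURA2_KD_NM = 228.0


class CalibrationError(ValueError):
    """Inconsistent or incomplete calibration parameters."""


def compute_keff(k_d: float, r_max: float, r_min: float, alpha: float) -> float:
    """Effective dissociation constant K_eff = K_D (R_max + a)/(R_min + a), nM.

    Strictly decreasing in alpha when R_max > R_min; tends to K_D as
    alpha grows without bound, and to K_D * R_max / R_min at alpha = 0.
    """
    if k_d <= 0:
        raise CalibrationError("K_D must be positive")
    if r_min + alpha == 0:
        raise CalibrationError("R_min + alpha = 0: division by zero")
    return k_d * (r_max + alpha) / (r_min + alpha)


@dataclass(frozen=True)
class CalibrationParams:
    """Complete calibration: K_D, in-situ R_min/R_max, correction alpha.

    ``ceiling`` bounds the reportable concentration (nM): noisy pixels with
    R at or above R_max are clipped there and flagged rather than raising.
    """

    k_d: float = FURA2_KD_NM
    r_min: float = 0.5
    r_max: float = 6.0
    alpha: float = 1.0
    ceiling: float = 10_000.0  # nM (10 uM)

    def __post_init__(self) -> None:
        if self.k_d <= 0:
            raise CalibrationError("K_D must be positive")
        if not (0 < self.r_min < self.r_max):
            raise CalibrationError("require 0 < R_min < R_max")
        if self.alpha < 0:
            raise CalibrationError("alpha must be non-negative")
        if self.ceiling <= 0:
            raise CalibrationError("ceiling must be positive")

    @property
    def k_eff(self) -> float:
        """Effective dissociation constant, nM."""
        return compute_keff(self.k_d, self.r_max, self.r_min, self.alpha)

    def with_alpha(self, alpha: float) -> "CalibrationParams":
        return replace(self, alpha=alpha)


def ratio_to_concentration(
    ratio: np.ndarray | float,
    calib: CalibrationParams,
    return_flags: bool = False,
):
    """Convert 340/380 ratios to [Ca2+] in nM.

    Out-of-range ratios are made total rather than fatal: R <= R_min maps to
    0 nM and R >= R_max (or any R whose concentration would exceed the
    ceiling) maps to ``calib.ceiling``; such elements are flagged when
    ``return_flags`` is true.
    """
    r = np.asarray(ratio, dtype=float)
    scalar = r.ndim == 0
    r = np.atleast_1d(r)
    keff = calib.k_eff

    below = r < calib.r_min
    with np.errstate(divide="ignore", invalid="ignore"):
        conc = keff * (r - calib.r_min) / (calib.r_max - r)
    above = (r >= calib.r_max) | (conc > calib.ceiling)
    conc = np.where(below, 0.0, conc)
    conc = np.where(above, calib.ceiling, conc)
    flags = below | above | ~np.isfinite(np.atleast_1d(np.asarray(ratio, float)))

    if scalar:
        conc, flags = float(conc[0]), bool(flags[0])
    if return_flags:
        return conc, flags
    return conc


def concentration_to_ratio(
    concentration: np.ndarray | float, calib: CalibrationParams
) -> np.ndarray | float:
    """Forward model: [Ca2+] (nM) to the 340/380 ratio it would produce.

    Algebraic inverse of :func:`ratio_to_concentration`:
    R = (c R_max + K_eff R_min) / (c + K_eff), mapping 0 -> R_min and
    infinity -> R_max.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    keff = calib.k_eff
    r = (c * calib.r_max + keff * calib.r_min) / (c + keff)
    return float(r) if r.ndim == 0 else r


def estimate_rmin_rmax(
    saturation_trace: RatioTrace,
    depletion_trace: RatioTrace,
    plateau_fraction: float = 0.2,
) -> tuple[float, float]:
    """Estimate (R_max, R_min) from ionomycin saturation/depletion recordings.

    Each trace is averaged over its final ``plateau_fraction`` of valid
    frames, where the ratio has settled at the saturated (2 mM Ca2+) or
    depleted (EGTA) plateau.
    """
    if not (0 < plateau_fraction <= 1):
        raise ValueError("plateau_fraction must lie in (0, 1]")

    def plateau_mean(trace: RatioTrace) -> float:
        r = np.asarray(trace.ratio, float)[np.asarray(trace.valid, bool)]
        if r.size == 0:
            raise CalibrationError("no valid frames in calibration trace")
        n = max(1, int(round(plateau_fraction * r.size)))
        return float(np.mean(r[-n:]))

    r_max = plateau_mean(saturation_trace)
    r_min = plateau_mean(depletion_trace)
    if r_min >= r_max:
        raise CalibrationError(
            f"estimated R_min ({r_min:.3g}) >= R_max ({r_max:.3g}): "
            "saturation/depletion traces inconsistent (swapped inputs?)"
        )
    return r_max, r_min


def calibrate_trace(trace: RatioTrace, calib: CalibrationParams) -> CalciumTrace:
    """Element-wise conversion of a ratio trace to absolute [Ca2+] (nM).

    Frames flagged invalid on input (e.g. corrected F380 <= 0) stay invalid;
    out-of-range ratios are clipped and additionally flagged.
    """
    conc, flags = ratio_to_concentration(trace.ratio, calib, return_flags=True)
    valid = np.asarray(trace.valid, bool) & ~np.atleast_1d(flags)
    return CalciumTrace(
        time=np.asarray(trace.time, float),
        concentration=np.atleast_1d(conc),
        valid=valid,
        compartment=trace.compartment,
    )
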