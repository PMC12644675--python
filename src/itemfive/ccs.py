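"""Travelling-wave ion mobility CCS calibration and drift-peak statistics.

Calibration follows the standard travelling-wave procedure: measured drift
times are dead-time corrected, published calibrant cross sections are
reduced by charge and reduced mass, and a power law (log-log fit) or a
straight line relates corrected drift time to corrected cross section.
Analyte drift times are then converted back to nitrogen CCS values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import GAS_MASSES

__all__ = [
    "CalibrantEntry",
    "CCSCalibration",
    "MobilityRecord",
    "corrected_drift_time",
    "corrected_ccs",
    "fit_calibration",
    "apply_calibration",
    "drift_peak_stats",
]

N2_MASS = GAS_MASSES["nitrogen"]


@dataclass(frozen=True)
class CalibrantEntry:
    """One calibrant ion: published CCS (A^2) and measured drift time (ms)."""

    name: str
    charge: int
    neutral_mass: float
    published_ccs: float
    drift_time: float

    def __post_init__(self):
        if min(self.charge, self.neutral_mass, self.published_ccs,
               self.drift_time) <= 0:
            raise ValueError("calibrant fields must all be positive")


def corrected_drift_time(td: float, mz: float, edc_coefficient: float) -> float:
    """Dead-time corrected drift time t' = td - EDC * sqrt(mz) / 1000 (ms).

    The enhanced-duty-cycle (EDC) delay coefficient is instrument specific.
    """
    td = np.asarray(td, dtype=float)
    if np.any(td <= 0):
        raise ValueError("drift time must be > 0")
    t_prime = td - edc_coefficient * np.sqrt(mz) / 1000.0
    if np.any(t_prime <= 0):
        raise ValueError("corrected drift time <= 0; check EDC coefficient")
    return float(t_prime) if np.ndim(t_prime) == 0 else t_prime


def reduced_mass(neutral_mass: float, gas_mass: float = N2_MASS) -> float:
    return neutral_mass * gas_mass / (neutral_mass + gas_mass)


def corrected_ccs(ccs: float, z: int, neutral_mass: float,
                  gas_mass: float = N2_MASS) -> float:
    """Charge/reduced-mass normalized cross section: CCS' = CCS sqrt(mu) / z."""
    if min(z, neutral_mass, gas_mass) <= 0:
        raise ValueError("z, neutral_mass and gas_mass must be positive")
    return ccs * np.sqrt(reduced_mass(neutral_mass, gas_mass)) / z


@dataclass
class CCSCalibration:
    """Fitted drift-time to cross-section relation.

    log-log mode: ln CCS' = ln_intercept + exponent * ln t' (power law);
    linear mode: CCS' = ln_intercept + exponent * t' (slope/intercept reuse
    the same fields).
    """

    edc_coefficient: float
    ln_intercept: float
    exponent: float
    fit_mode: str
    r_squared: float
    t_prime_range: tuple[float, float]

    def evaluate(self, t_prime):
        t_prime = np.asarray(t_prime, dtype=float)
        if self.fit_mode == "log-log":
            out = np.exp(self.ln_intercept + self.exponent * np.log(t_prime))
        else:
            out = self.ln_intercept + self.exponent * t_prime
        return float(out) if out.ndim == 0 else out


def fit_calibration(
    calibrants: list[CalibrantEntry],
    mode: str = "log-log",
    edc_coefficient: float = 0.0,
    gas_mass: float = N2_MASS,
) -> CCSCalibration:
    """Fit corrected CCS against corrected drift time over the calibrants."""
    if mode not in ("log-log", "linear"):
        raise ValueError(f"unknown fit mode {mode!r}")
    if len(calibrants) < 2:
        raise ValueError("need at least 2 calibrants")
    t_prime = np.array([
        corrected_drift_time(c.drift_time,
                             (c.neutral_mass + c.charge * 1.00728) / c.charge,
                             edc_coefficient)
        for c in calibrants])
    ccs_prime = np.array([
        corrected_ccs(c.published_ccs, c.charge, c.neutral_mass, gas_mass)
        for c in calibrants])
    if np.unique(t_prime).size < 2:
        raise ValueError("calibrant drift times are degenerate")
    if mode == "log-log":
        res = stats.linregress(np.log(t_prime), np.log(ccs_prime))
    else:
        res = stats.linregress(t_prime, ccs_prime)
    return CCSCalibration(
        edc_coefficient=edc_coefficient,
        ln_intercept=res.intercept,
        exponent=res.slope,
        fit_mode=mode,
        r_squared=res.rvalue**2,
        t_prime_range=(float(t_prime.min()), float(t_prime.max())),
    )


def apply_calibration(
    cal: CCSCalibration,
    td: float,
    mz: float,
    z: int,
    neutral_mass: float,
    gas_mass: float = N2_MASS,
) -> float:
    """Convert an analyte drift time to a CCS value (A^2).

    Evaluates the fitted relation at the corrected drift time and inverts the
    charge/reduced-mass normalization.  Extrapolation beyond the calibrated
    drift-time range warns but proceeds.
    """
    import warnings

    t_prime = corrected_drift_time(td, mz, cal.edc_coefficient)
    lo, hi = cal.t_prime_range
    if not lo <= t_prime <= hi:
        warnings.warn(
            f"corrected drift time {t_prime:.3g} ms outside calibrated range "
            f"[{lo:.3g}, {hi:.3g}] ms; extrapolating", stacklevel=2)
    ccs_prime = cal.evaluate(t_prime)
    return ccs_prime * z / np.sqrt(reduced_mass(neutral_mass, gas_mass))


@dataclass
class MobilityRecord:
    """Per-analyte mobility summary (one row of a drift-time/CCS table)."""

    analyte: str
    charge: int
    neutral_mass: float
    drift_time_mean: float
    drift_time_sd: float
    fwhm: float
    ccs: float
    ccs_sd: float


def drift_peak_stats(drift_times, intensities) -> tuple[float, float, float]:
    """Centroid, sd and FWHM of an arrival-time profile.

    The centroid and sd are intensity weighted; the FWHM interpolates the
    half-maximum crossings linearly.  A single nonzero bin reports the grid
    spacing as its FWHM (documented convention for unresolved peaks).
    """
    t = np.asarray(drift_times, dtype=float)
    w = np.asarray(intensities, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 profile points")
    if np.any(w < 0):
        raise ValueError("intensities must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no centroid")
    order = np.argsort(t)
    t, w = t[order], w[order]
    mean = float(np.average(t, weights=w))
    sd = float(np.sqrt(np.average((t - mean) ** 2, weights=w)))

    half = w.max() / 2.0
    above = np.nonzero(w >= half)[0]
    first, last = above[0], above[-1]
    bin_width = float(np.median(np.diff(t))) if t.size > 1 else 0.0
    if (w > 0).sum() == 1:
        return mean, sd, bin_width
    # left crossing
    if first == 0:
        left = t[0]
    else:
        i = first
        left = t[i - 1] + (half - w[i - 1]) / (w[i] - w[i - 1]) * (t[i] - t[i - 1])
    if last == t.size - 1:
        right = t[-1]
    else:
        i = last
        right = t[i] + (w[i] - half) / (w[i] - w[i + 1]) * (t[i + 1] - t[i])
    fwhm = right - left
    if fwhm <= 0:
        fwhm = bin_width
    return mean, sd, float(fwhm)
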