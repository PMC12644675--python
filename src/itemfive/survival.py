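"""Survival-yield curves and Boltzmann sigmoid fitting.

The survival yield (SY) is the normalized fraction of the intact complex
(educt) ion among all monitored educt + product signals at a given collision
voltage difference.  Replicate-averaged SY(dCV) curves are sigmoidal and are
fitted with the four-parameter Boltzmann function

    y(x) = A2 + (A1 - A2) / (1 + exp((x - x0) / dx)),

whose midpoint x0 is the half-dissociation voltage (dCV50).  The analytic
tangent at the midpoint, slope (A2 - A1)/(4 dx), linearizes the transition
region for the downstream kinetic treatment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .spectra import NormalizedIntensities

__all__ = [
    "SurvivalYieldCurve",
    "BoltzmannFit",
    "TangentLine",
    "boltzmann",
    "assemble_curve",
    "fit_boltzmann",
    "tangent_at_midpoint",
    "sample_tangent",
]


def boltzmann(x, a1, a2, x0, dx):
    """Boltzmann sigmoid; decays from plateau ``a1`` to ``a2`` for a1 > a2.

    Evaluated through the logistic function for overflow-free behaviour at
    steep slopes (small dx).
    """
    from scipy.special import expit

    x = np.asarray(x, dtype=float)
    return a2 + (a1 - a2) * expit(-(x - x0) / dx)


@dataclass
class SurvivalYieldCurve:
    """Replicate-averaged educt fraction vs collision voltage difference."""

    analyte: str
    delta_cv: np.ndarray
    sy_mean: np.ndarray
    sy_sd: np.ndarray
    n_replicates: int

    def __post_init__(self):
        self.delta_cv = np.asarray(self.delta_cv, dtype=float)
        self.sy_mean = np.asarray(self.sy_mean, dtype=float)
        self.sy_sd = np.asarray(self.sy_sd, dtype=float)
        if not (self.delta_cv.shape == self.sy_mean.shape == self.sy_sd.shape):
            raise ValueError("delta_cv, sy_mean and sy_sd must align")
        if np.any(np.diff(self.delta_cv) <= 0):
            raise ValueError("delta_cv must be strictly increasing")
        if np.any((self.sy_mean < 0) | (self.sy_mean > 100)):
            raise ValueError("survival yields must lie in [0, 100] percent")

    def __len__(self) -> int:
        return self.delta_cv.size


@dataclass
class BoltzmannFit:
    a1: float
    a2: float
    x0: float
    dx: float
    r_squared: float

    def __call__(self, x):
        return boltzmann(x, self.a1, self.a2, self.x0, self.dx)

    @property
    def dcv50(self) -> float:
        return self.x0


@dataclass
class TangentLine:
    """Line tangent to a Boltzmann curve at its midpoint (anchor_x = x0)."""

    slope: float
    intercept: float
    anchor_x: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def assemble_curve(
    normalized: list[NormalizedIntensities],
    educt_label: str = "trimer",
    analyte: str = "",
) -> SurvivalYieldCurve:
    """Average the educt fraction across replicates on a shared dCV schedule.

    Every replicate must cover the identical schedule; otherwise the error
    lists each missing (replicate, dCV) pair.
    """
    by_rep: dict[str, dict[float, float]] = {}
    for item in normalized:
        if educt_label not in item.fractions:
            raise KeyError(f"educt label {educt_label!r} missing at "
                           f"dCV={item.delta_cv}")
        by_rep.setdefault(item.replicate_id, {})[item.delta_cv] = \
            item.fractions[educt_label]
    schedule = sorted({dcv for rep in by_rep.values() for dcv in rep})
    if len(schedule) < 3:
        raise ValueError("need at least 3 distinct dCV values")
    missing = [(rep_id, dcv) for rep_id, rep in by_rep.items()
               for dcv in schedule if dcv not in rep]
    if missing:
        raise ValueError(f"replicate schedules are not aligned; missing: {missing}")
    matrix = np.array([[by_rep[rep_id][dcv] for dcv in schedule]
                       for rep_id in sorted(by_rep)])
    # ddof=0: population sd over the recorded replicates, 0 for n=1
    return SurvivalYieldCurve(
        analyte=analyte,
        delta_cv=np.array(schedule),
        sy_mean=matrix.mean(axis=0),
        sy_sd=matrix.std(axis=0, ddof=0),
        n_replicates=matrix.shape[0],
    )


class BoltzmannFitError(RuntimeError):
    """Fit failure; carries the initializer that was used."""

    def __init__(self, message: str, init: dict):
        super().__init__(f"{message}; initial guess: {init}")
        self.init = init


def fit_boltzmann(
    curve: SurvivalYieldCurve,
    pin_plateaus: bool = False,
    weighted: bool = False,
) -> BoltzmannFit:
    """Least-squares Boltzmann fit of a survival-yield curve.

    Initialization: A1 = max(sy), A2 = min(sy), x0 at the point closest to the
    half height, dx = dCV range / 10.  Plateaus are free by default
    (``pin_plateaus=True`` fixes them at 100/0); ``weighted=True`` weights by
    the replicate standard deviations where nonzero.
    """
    x, y = curve.delta_cv, curve.sy_mean
    if len(curve) < 4:
        raise ValueError("need at least 4 points to fit a 4-parameter sigmoid")
    if np.all(np.diff(y) >= 0) and y[-1] > y[0]:
        warnings.warn("survival yield increases with dCV; educt should decay",
                      stacklevel=2)
    a1_init, a2_init = float(y.max()), float(y.min())
    half = 0.5 * (a1_init + a2_init)
    # midpoint guess: interpolate the half-height crossing of the decay;
    # fall back to the point nearest half height for non-crossing data
    x0_init = float(x[np.argmin(np.abs(y - half))])
    below = np.nonzero(y < half)[0]
    if below.size and below[0] > 0:
        i = below[0]
        x0_init = float(x[i - 1] + (y[i - 1] - half)
                        * (x[i] - x[i - 1]) / (y[i - 1] - y[i]))
    dx_init = float(np.ptp(x)) / 10.0 or 1.0
    init = dict(a1=a1_init, a2=a2_init, x0=x0_init, dx=dx_init)

    model = Model(boltzmann)
    fit_kw = {}
    if weighted:
        sd = np.where(curve.sy_sd > 0, curve.sy_sd, np.nan)
        fallback = np.nanmean(sd) if np.any(np.isfinite(sd)) else 1.0
        fit_kw["weights"] = 1.0 / np.where(np.isfinite(sd), sd, fallback)

    result = None
    for dx_try in (dx_init, dx_init / 5.0, 2.0 * dx_init):
        params = model.make_params(**{**init, "dx": dx_try})
        params["dx"].set(min=1e-6)
        if pin_plateaus:
            params["a1"].set(value=100.0, vary=False)
            params["a2"].set(value=0.0, vary=False)
        attempt = model.fit(y, params, x=x, **fit_kw)
        if result is None or attempt.chisqr < result.chisqr:
            result = attempt
    if result is None or not result.success:
        raise BoltzmannFitError("Boltzmann fit did not converge", init)
    best = result.best_values
    residuals = y - boltzmann(x, **best)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(residuals**2)) / ss_tot if ss_tot > 0 else 1.0
    return BoltzmannFit(a1=best["a1"], a2=best["a2"], x0=best["x0"],
                        dx=best["dx"], r_squared=r2)


def tangent_at_midpoint(fit: BoltzmannFit) -> TangentLine:
    """Analytic tangent of the fitted sigmoid at its midpoint.

    At x0 the curve passes through (A1 + A2)/2 with slope (A2 - A1)/(4 dx).
    """
    slope = (fit.a2 - fit.a1) / (4.0 * fit.dx)
    value = 0.5 * (fit.a1 + fit.a2)
    return TangentLine(slope=slope, intercept=value - slope * fit.x0,
                       anchor_x=fit.x0)


def sample_tangent(
    fit: BoltzmannFit,
    line: TangentLine | None = None,
    n_points: int = 5,
    sy_bounds: tuple[float, float] = (10.0, 90.0),
) -> np.ndarray:
    """Evenly spaced (dCV, SY) points on the midpoint tangent.

    Points span the dCV interval where the linear SY lies within
    ``sy_bounds`` (percent, bounds included).  The bounds keep every sampled
    SY strictly inside (0, 100) so the downstream logarithms stay finite.
    """
    if line is None:
        line = tangent_at_midpoint(fit)
    low, high = sy_bounds
    if not (0.0 < low < high < 100.0):
        raise ValueError("sy_bounds must satisfy 0 < low < high < 100")
    if n_points < 2:
        raise ValueError("need at least 2 tangent points")
    lo_plateau, hi_plateau = min(fit.a1, fit.a2), max(fit.a1, fit.a2)
    if high > hi_plateau or low < lo_plateau:
        raise ValueError(
            f"sy_bounds {sy_bounds} outside the tangent's plateau range "
            f"({lo_plateau:.3g}, {hi_plateau:.3g})")
    if line.slope == 0:
        raise ValueError("tangent slope is zero; cannot invert for dCV")
    sy = np.linspace(high, low, n_points)  # descending along increasing dCV
    dcv = (sy - line.intercept) / line.slope
    order = np.argsort(dcv)
    return np.column_stack([dcv[order], sy[order]])
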