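"""Apparent kinetics and pseudo-thermodynamics of gas-phase dissociation.

The collision voltage difference (dCV) is mapped to an effective collision
temperature through the centre-of-mass collision energy,

    T_coll = T_amb + z e dCV * m_gas / (m_gas + m_ion) / (dof_factor * k_B),

where ``dof_factor`` is the effective number of internal degrees of freedom
over which the deposited energy is partitioned.  Survival yields on the
Boltzmann-curve tangent convert to dimensionless apparent rate constants,
k# = -ln(SY) / residence_factor (a quasi-first-order decay over a fixed,
dimensionless residence interval).  Arrhenius plots (ln k# vs 1/T) and
Ellingham diagrams (Eyring free energy vs T) are fitted linearly and
extrapolated to ambient temperature, yielding the "m0g" quantities: the mean
charge state with zero external energy contribution in the gas phase.

Both instrument-dependent constants (``dof_factor``, ``residence_factor``)
are explicit configuration; :func:`calibrate_conditions` solves them from a
published reference (dH#, T dS#) pair so results can be put on the scale of
an existing data set.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats

from .constants import (
    BOLTZMANN,
    ELEMENTARY_CHARGE,
    GAS_CONSTANT,
    GAS_MASSES,
    PLANCK,
)
from .survival import BoltzmannFit, sample_tangent

__all__ = [
    "CollisionConditions",
    "ArrheniusFit",
    "EllinghamFit",
    "ThermoKineticResult",
    "dcv_to_temperature",
    "rate_from_survival",
    "free_energy_from_rate",
    "fit_arrhenius",
    "fit_ellingham",
    "extrapolate_ambient",
    "analyze_boltzmann_fit",
    "calibrate_conditions",
]


@dataclass(frozen=True)
class CollisionConditions:
    """Physical setting of a collision-cell dissociation experiment.

    Parameters
    ----------
    charge:
        Precursor charge state z (protons).
    ion_mass:
        Neutral n-mer mass in u.
    gas:
        Collision gas name (``argon``, ``nitrogen``, ``helium``) or None
        when ``gas_mass`` is given directly.
    T_amb:
        Ambient temperature in K used as the zero-energy baseline and the
        extrapolation target.
    dof_factor:
        Effective degrees-of-freedom divisor of the centre-of-mass energy.
    residence_factor:
        Dimensionless normalization of the decay interval entering
        k# = -ln(SY) / residence_factor.
    """

    charge: int = 5
    ion_mass: float = 9238.73
    gas: str | None = "argon"
    gas_mass: float | None = None
    T_amb: float = 298.15
    dof_factor: float = 1.5
    residence_factor: float = 1.0
    e: float = ELEMENTARY_CHARGE
    k_B: float = BOLTZMANN
    h: float = PLANCK
    R: float = GAS_CONSTANT

    def __post_init__(self):
        if self.charge < 1 or self.ion_mass <= 0 or self.T_amb <= 0:
            raise ValueError("charge, ion_mass and T_amb must be positive")
        if self.dof_factor <= 0 or self.residence_factor <= 0:
            raise ValueError("dof_factor and residence_factor must be positive")
        if self.gas_mass is None and self.gas is None:
            raise ValueError("either gas or gas_mass is required")

    @property
    def collision_gas_mass(self) -> float:
        if self.gas_mass is not None:
            return self.gas_mass
        try:
            return GAS_MASSES[self.gas]
        except KeyError:
            raise ValueError(f"unknown collision gas {self.gas!r}") from None

    @property
    def kelvin_per_volt(self) -> float:
        """Slope of the dCV -> T_coll map in K/V."""
        m_gas = self.collision_gas_mass
        com_fraction = m_gas / (m_gas + self.ion_mass)
        return self.charge * self.e * com_fraction / (self.dof_factor * self.k_B)


def dcv_to_temperature(delta_cv, cond: CollisionConditions):
    """Effective collision temperature (K); affine and increasing in dCV."""
    delta_cv = np.asarray(delta_cv, dtype=float)
    if np.any(delta_cv < 0):
        raise ValueError("delta_cv must be >= 0")
    out = cond.T_amb + cond.kelvin_per_volt * delta_cv
    return float(out) if out.ndim == 0 else out


def rate_from_survival(sy, residence_factor: float = 1.0):
    """Dimensionless apparent rate constant from a survival-yield fraction.

    k# = -ln(SY) / residence_factor for SY in (0, 1]; SY must be clipped
    away from 0 upstream (tangent sampling bounds guarantee this).
    """
    sy = np.asarray(sy, dtype=float)
    if np.any(sy <= 0) or np.any(sy > 1):
        raise ValueError("survival yield must lie in (0, 1]")
    out = -np.log(sy) / residence_factor
    return float(out) if out.ndim == 0 else out


def free_energy_from_rate(k_sharp, T, cond: CollisionConditions):
    """Eyring-form activation free energy in kJ/mol.

    dG#(T) = -R T ln(k# h / (k_B T)).
    """
    k_sharp = np.asarray(k_sharp, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(k_sharp <= 0):
        raise ValueError("rate constant must be > 0 (infinite barrier at 0)")
    if np.any(T <= 0):
        raise ValueError("temperature must be > 0")
    out = -cond.R * T * np.log(k_sharp * cond.h / (cond.k_B * T)) / 1e3
    return float(out) if out.ndim == 0 else out


@dataclass
class ArrheniusFit:
    """ln k# = ln A - E_a / (R T); E_a in kJ/mol."""

    ln_a: float
    e_a: float
    r_squared: float

    def ln_k(self, T):
        return self.ln_a - self.e_a * 1e3 / (GAS_CONSTANT * np.asarray(T, float))


@dataclass
class EllinghamFit:
    """dG#(T) = dH# - T dS#; dH# in kJ/mol, dS# in kJ/(mol K)."""

    dh: float
    ds: float
    r_squared: float

    def dg(self, T):
        return self.dh - np.asarray(T, float) * self.ds


def _linfit(x: np.ndarray, y: np.ndarray):
    if np.unique(x).size < 2:
        raise ValueError("need at least two distinct abscissa values")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_arrhenius(temperatures, rates) -> ArrheniusFit:
    """Least squares of ln k# against 1/T."""
    T = np.asarray(temperatures, dtype=float)
    k = np.asarray(rates, dtype=float)
    if T.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(k <= 0):
        raise ValueError("rates must be positive")
    slope, intercept, r2 = _linfit(1.0 / T, np.log(k))
    return ArrheniusFit(ln_a=intercept, e_a=-slope * GAS_CONSTANT / 1e3,
                        r_squared=r2)


def fit_ellingham(temperatures, free_energies) -> EllinghamFit:
    """Least squares of dG# (kJ/mol) against T; intercept dH#, slope -dS#."""
    T = np.asarray(temperatures, dtype=float)
    dG = np.asarray(free_energies, dtype=float)
    if T.size < 2:
        raise ValueError("need at least 2 points")
    slope, intercept, r2 = _linfit(T, dG)
    return EllinghamFit(dh=intercept, ds=-slope, r_squared=r2)


@dataclass
class ThermoKineticResult:
    """Ambient-temperature ("m0g") extrapolation of one analyte."""

    k_m0g: float
    kd_m0g: float
    dg_m0g: float   # kJ/mol
    dh_m0g: float   # kJ/mol
    tds_m0g: float  # kJ/mol


def extrapolate_ambient(arr: ArrheniusFit, ell: EllinghamFit,
                        cond: CollisionConditions) -> ThermoKineticResult:
    """Evaluate both linear fits at T_amb.

    dG# = dH# - T_amb dS# holds exactly by construction; the equilibrium-type
    constant follows from the Boltzmann form KD# = exp(-dG#/(R T_amb)).
    """
    T0 = cond.T_amb
    dh = ell.dh
    tds = T0 * ell.ds
    dg = dh - tds
    k0 = float(np.exp(arr.ln_k(T0)))
    kd = float(np.exp(-dg * 1e3 / (cond.R * T0)))
    return ThermoKineticResult(k_m0g=k0, kd_m0g=kd, dg_m0g=dg, dh_m0g=dh,
                               tds_m0g=tds)


@dataclass
class ThermoKineticAnalysis:
    """Full per-analyte record: tangent points, both fits, extrapolation."""

    points: np.ndarray  # columns: dCV, SY %, T_coll, k#, dG# (kJ/mol)
    arrhenius: ArrheniusFit
    ellingham: EllinghamFit
    result: ThermoKineticResult


def analyze_boltzmann_fit(
    fit: BoltzmannFit,
    cond: CollisionConditions,
    n_points: int = 5,
    sy_bounds: tuple[float, float] = (10.0, 90.0),
) -> ThermoKineticAnalysis:
    """Tangent sampling -> temperatures -> rates -> both diagrams -> m0g.

    This is the per-analyte core of the dissociation analysis: points on the
    midpoint tangent of the fitted survival-yield sigmoid are transformed to
    (T_coll, k#, dG#) triples, fitted as Arrhenius and Ellingham lines, and
    extrapolated to ambient temperature.
    """
    pts = sample_tangent(fit, n_points=n_points, sy_bounds=sy_bounds)
    dcv, sy = pts[:, 0], pts[:, 1]
    T = dcv_to_temperature(dcv, cond)
    k = rate_from_survival(sy / 100.0, cond.residence_factor)
    dG = free_energy_from_rate(k, T, cond)
    arr = fit_arrhenius(T, k)
    ell = fit_ellingham(T, dG)
    result = extrapolate_ambient(arr, ell, cond)
    table = np.column_stack([dcv, sy, T, k, dG])
    return ThermoKineticAnalysis(points=table, arrhenius=arr, ellingham=ell,
                                 result=result)


def calibrate_conditions(
    fit: BoltzmannFit,
    cond: CollisionConditions,
    reference_dh: float,
    reference_tds: float,
    n_points: int = 5,
    sy_bounds: tuple[float, float] = (10.0, 90.0),
) -> CollisionConditions:
    """Solve (dof_factor, residence_factor) from a published reference row.

    Given a reference analyte's Boltzmann fit and its published activation
    enthalpy dH# and entropy term T_amb dS# (kJ/mol), find the two
    instrument-dependent constants that make this pipeline reproduce the
    pair.  The solved conditions then transfer to the other analytes of the
    same experiment series (same instrument, gas and charge state, their own
    ion masses).

    The system can have several isolated roots; among them the returned one
    maximizes internal consistency between the two extrapolation routes,
    i.e. minimizes the gap between the Arrhenius-extrapolated ln k#(T_amb)
    and the Eyring value ln(k_B T_amb / h) - dG#/(R T_amb).

    Raises ``RuntimeError`` when no physical solution exists, e.g. when the
    sigmoid is too steep for the requested reference values.
    """

    def conditions_for(p):
        return replace(cond, dof_factor=float(p[0]),
                       residence_factor=float(np.exp(p[1])))

    def residual(p):
        if p[0] <= 0:
            return [1e6, 1e6]
        res = analyze_boltzmann_fit(fit, conditions_for(p),
                                    n_points, sy_bounds).result
        return [res.dh_m0g - reference_dh, res.tds_m0g - reference_tds]

    roots = []
    for dof0 in (3.0, 10.0, 30.0, 100.0, 300.0):
        for ln_tau0 in (-40.0, -30.0, -20.0, -10.0, -3.0):
            sol, info, ier, _ = optimize.fsolve(
                residual, [dof0, ln_tau0], full_output=True)
            if ier != 1 or sol[0] <= 0:
                continue
            if max(abs(r) for r in residual(sol)) > 1e-6:
                continue
            if any(abs(sol[0] - r[0]) < 1e-3 * max(1.0, r[0]) for r in roots):
                continue
            roots.append(sol)
    if not roots:
        raise RuntimeError(
            "no (dof_factor, residence_factor) pair reproduces the reference "
            f"(dH={reference_dh}, TdS={reference_tds}) for this fit")

    def eyring_gap(p):
        trial = conditions_for(p)
        res = analyze_boltzmann_fit(fit, trial, n_points, sy_bounds).result
        ln_k_eyring = (np.log(trial.k_B * trial.T_amb / trial.h)
                       - res.dg_m0g * 1e3 / (trial.R * trial.T_amb))
        return abs(np.log(res.k_m0g) - ln_k_eyring)

    best = min(roots, key=eyring_gap)
    return conditions_for(best)
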