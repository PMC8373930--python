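"""Two-state folding thermodynamics.

The model combines the Gibbs-Helmholtz temperature dependence of the folding
free energy with the linear extrapolation method (LEM) for chemical
denaturation:

    dG_f(T, D) = dH_m * (1 - T/T_m)
               + dC_p * (T - T_m - T * ln(T/T_m))
               + m * D

with the *folding* sign convention throughout (dG_f < 0 for a stable protein,
dH_m < 0 for a cooperative folder, m > 0 so that denaturant destabilises).
T_m is the melting temperature at zero denaturant, dH_m the folding enthalpy
at T_m, dC_p the folding heat-capacity change, and m the denaturant m-value.

All temperatures are Kelvin, energies kJ/mol, denaturant concentrations molar.
Condition fields may be numpy arrays; every operation broadcasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .exceptions import InvalidConditionError, InvalidParameterError, NoTransitionError

#: Gas constant, kJ mol^-1 K^-1.
R_GAS = 0.008314

ArrayLike = Union[float, np.ndarray]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of one variant (folding sign convention).

    Attributes
    ----------
    t_m : float
        Melting temperature at zero denaturant, K.
    dh_m : float
        Folding enthalpy at ``t_m``, kJ/mol (negative for a cooperative folder).
    dcp : float
        Folding heat-capacity change, kJ/(mol K).
    m_value : float
        Denaturant m-value, kJ/(mol M); must be positive.
    """

    t_m: float
    dh_m: float
    dcp: float
    m_value: float

    def __post_init__(self) -> None:
        if not self.t_m > 0:
            raise InvalidParameterError(f"t_m must be positive Kelvin, got {self.t_m}")
        if not self.m_value > 0:
            raise InvalidParameterError(f"m_value must be positive, got {self.m_value}")


@dataclass(frozen=True)
class Condition:
    """A measurement condition: temperature (K) and denaturant concentration (M).

    Both fields accept scalars or numpy arrays (broadcastable).
    """

    temperature: ArrayLike
    denaturant: ArrayLike = 0.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.temperature) <= 0):
            raise InvalidConditionError("temperature must be positive Kelvin")
        if np.any(np.asarray(self.denaturant) < 0):
            raise InvalidConditionError("denaturant concentration must be >= 0 M")


def gibbs_free_energy(params: ThermoParams, cond: Condition) -> ArrayLike:
    """Folding free energy dG_f(T, D) in kJ/mol.

    Zero exactly at (T = t_m, D = 0); linear in denaturant with slope
    ``params.m_value``.
    """
    t = np.asarray(cond.temperature, dtype=float)
    d = cond.denaturant
    tm, dh, dcp, m = params.t_m, params.dh_m, params.dcp, params.m_value
    dg = dh * (1.0 - t / tm) + dcp * (t - tm - t * np.log(t / tm)) + m * d
    return dg if dg.ndim else float(dg)


def fraction_unfolded(params: ThermoParams, cond: Condition) -> ArrayLike:
    """Equilibrium fraction of unfolded molecules, in (0, 1).

    Two-state logistic link: f_U = 1 / (1 + exp(-dG_f / (R T))); equals 0.5
    where dG_f = 0 and increases monotonically with denaturant.
    """
    dg = gibbs_free_energy(params, cond)
    t = np.asarray(cond.temperature, dtype=float)
    fu = expit(np.asarray(dg) / (R_GAS * t))
    return fu if fu.ndim else float(fu)


def midpoint_denaturant(params: ThermoParams, temperature: float) -> float:
    """Denaturant midpoint [D]50% at ``temperature``: -dG_f(T, 0) / m.

    May be negative for variants that are unfolded in water at T (reported
    as-is).
    """
    dg0 = gibbs_free_energy(params, Condition(temperature, 0.0))
    return -dg0 / params.m_value


def max_stability_temperature(params: ThermoParams) -> float:
    """Temperature of maximum stability, where d(dG_f)/dT = 0.

    From -dH_m/T_m - dC_p ln(T/T_m) = 0; below it dG_f rises again towards
    cold denaturation. Falls back to 0 K when dC_p = 0 (no curvature).
    """
    if params.dcp == 0.0:
        return 0.0
    return params.t_m * math.exp(-params.dh_m / (params.t_m * params.dcp))


def melting_temperature_at(
    params: ThermoParams,
    denaturant: float = 0.0,
    bracket: tuple[float, float] = (250.0, 400.0),
) -> float:
    """Apparent (heat-denaturation) melting temperature at a denaturant level.

    Root of dG_f(T, D) = 0 in T above the stability maximum; equals ``t_m``
    at D = 0 and decreases with D for positive m. Raises
    :class:`NoTransitionError` if dG_f has no sign change between the
    stability maximum and the upper bracket edge (e.g. the protein is
    unfolded at all temperatures at this denaturant concentration).
    """
    if denaturant == 0.0:
        return params.t_m

    def f(t: float) -> float:
        return gibbs_free_energy(params, Condition(t, denaturant))

    lo = max(bracket[0], max_stability_temperature(params))
    hi = bracket[1]
    if lo >= hi or f(lo) > 0 or f(hi) < 0:
        raise NoTransitionError(
            f"dG_f(T, D={denaturant}) has no heat-denaturation root in "
            f"[{lo:.1f}, {hi:.1f}] K"
        )
    root = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return float(root)
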