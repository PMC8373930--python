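"""Map folded/unfolded populations to the measured fluorescence signal.

The observed signal is a population-weighted mix of two state baselines,

    F(T, D) = B_N(T, D) * (1 - f_U) + B_U(T, D) * f_U,

where each baseline is affine in temperature and denaturant:

    B_X(T, D) = intercept_X + t_slope_X * (T - 273.15 K) + d_slope_X * D.

Temperature slopes act on the Celsius scale (intercepts are the signal at
0 degC, 0 M), which keeps intercepts on the same order as the measured signal
for typical 15-95 degC ramps. ``normalize_signal`` inverts fitted baselines to
a degree-of-unfolding scale for direct comparison across variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateBaselineError
from .thermo import ArrayLike, Condition, ThermoParams, fraction_unfolded

#: Temperature offset so baseline slopes act per degC with intercepts at 0 degC.
T_REF = 273.15


@dataclass(frozen=True)
class BaselineParams:
    """Affine native (pre-transition) and unfolded (post-transition) baselines.

    Units: intercepts in signal units (at 0 degC, 0 M); temperature slopes in
    signal units per K; denaturant slopes in signal units per M.
    """

    native_intercept: float
    native_t_slope: float
    native_d_slope: float
    unfolded_intercept: float
    unfolded_t_slope: float
    unfolded_d_slope: float

    def native(self, cond: Condition) -> ArrayLike:
        """Native-state baseline B_N at a condition."""
        return (
            self.native_intercept
            + self.native_t_slope * (np.asarray(cond.temperature) - T_REF)
            + self.native_d_slope * np.asarray(cond.denaturant)
        )

    def unfolded(self, cond: Condition) -> ArrayLike:
        """Unfolded-state baseline B_U at a condition."""
        return (
            self.unfolded_intercept
            + self.unfolded_t_slope * (np.asarray(cond.temperature) - T_REF)
            + self.unfolded_d_slope * np.asarray(cond.denaturant)
        )


def predicted_signal(
    thermo: ThermoParams, baselines: BaselineParams, cond: Condition
) -> ArrayLike:
    """Noise-free predicted fluorescence signal at a condition.

    Bounded between the two baselines; equals their average at the transition
    midpoint. This single forward model is shared by the simulator and the
    global fitter.
    """
    fu = fraction_unfolded(thermo, cond)
    out = baselines.native(cond) * (1.0 - fu) + baselines.unfolded(cond) * fu
    arr = np.asarray(out)
    return arr if arr.ndim else float(arr)


def normalize_signal(
    signal: ArrayLike,
    baselines: BaselineParams,
    cond: Condition,
    min_separation: float = 1e-8,
) -> ArrayLike:
    """Invert fitted baselines: signal -> degree of unfolding.

    Returns (B_N - F) / (B_N - B_U); the exact inverse of
    :func:`predicted_signal` composed with the two-state populations. Values
    may slightly exceed [0, 1] for noisy data and are not clipped.

    Raises :class:`DegenerateBaselineError` where |B_N - B_U| falls below
    ``min_separation``.
    """
    bn = np.asarray(baselines.native(cond), dtype=float)
    bu = np.asarray(baselines.unfolded(cond), dtype=float)
    sep = bn - bu
    if np.any(np.abs(sep) < min_separation):
        raise DegenerateBaselineError(
            f"baseline separation below {min_separation} signal units"
        )
    out = (bn - np.asarray(signal, dtype=float)) / sep
    return out if out.ndim else float(out)
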