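"""Global weighted least-squares estimation of unfolding thermodynamics.

All series of a variant (across denaturant levels and replicates) enter one
objective: shared thermodynamic parameters, per-replicate baselines. Joint
multi-variant fits additionally share (or fix) selected thermodynamic
parameters across variants -- in practice the denaturant m-value, which is
expected to be invariant when the change in solvent-exposed surface area on
unfolding is unchanged.

Estimation is unweighted nonlinear least squares (trust-region reflective via
lmfit/scipy) with seeded multi-start restarts to guard against baseline /
transition swaps. The parameter covariance is (J^T J)^-1 * sigma_hat^2 with
sigma_hat^2 = SSR/dof; derived quantities (dG_f(T), [D]50%(T), apparent T_m(D))
get first-order (delta-method) standard errors from the full covariance.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Union

import lmfit
import numpy as np
from scipy.signal import savgol_filter

from .cycles import StabilityRecord
from .dataset import MaskWindow, UnfoldingDataset, apply_masks
from .exceptions import (
    CovarianceUnavailableError,
    DegenerateFitError,
    EmptyInputError,
    InvalidParameterError,
    NoTransitionError,
)
from .observation import T_REF, BaselineParams, predicted_signal
from .thermo import (
    Condition,
    ThermoParams,
    gibbs_free_energy,
    melting_temperature_at,
    midpoint_denaturant,
)

THERMO_NAMES = ("t_m", "dh_m", "dcp", "m_value")
BASELINE_NAMES = (
    "native_intercept",
    "native_t_slope",
    "native_d_slope",
    "unfolded_intercept",
    "unfolded_t_slope",
    "unfolded_d_slope",
)

#: Loose physical bounds keeping the optimiser in the folding-sign regime.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "t_m": (273.0, 420.0),
    "dh_m": (-1500.0, -1.0),
    "dcp": (-30.0, 1.0),
    "m_value": (0.05, 40.0),
}

#: Generic initial values when the data give no better information.
DEFAULT_THERMO_INIT = {"dh_m": -300.0, "dcp": -4.0, "m_value": 8.0}


@dataclass
class FitOptions:
    """Options controlling a global fit.

    ``fixed_parameters`` maps thermodynamic names (e.g. ``"m_value"``) to
    values held constant; ``shared_parameters`` names parameters estimated
    once across all variants of a joint fit. The two sets must be disjoint.
    """

    fixed_parameters: dict[str, float] = field(default_factory=dict)
    shared_parameters: tuple[str, ...] = ()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12
    max_iterations: int = 500
    seed: int = 0
    n_starts: int = 5
    baseline_d_slopes: bool = True
    mask_windows: tuple[MaskWindow, ...] = ()

    def __post_init__(self) -> None:
        overlap = set(self.fixed_parameters) & set(self.shared_parameters)
        if overlap:
            raise InvalidParameterError(
                f"parameters cannot be both fixed and shared: {sorted(overlap)}"
            )
        for name in list(self.fixed_parameters) + list(self.shared_parameters):
            if name not in THERMO_NAMES:
                raise InvalidParameterError(f"unknown thermodynamic parameter {name!r}")


@dataclass
class FitResult:
    """Fitted parameters with uncertainties for one variant."""

    variant_label: str
    thermo: ThermoParams
    baselines: list[BaselineParams]
    standard_errors: dict[str, float]
    covariance: Optional[np.ndarray]
    var_names: list[str]
    thermo_param_names: dict[str, str]
    residual_sd: float
    dof: int
    converged: bool
    n_series: int
    n_points: int


# ---------------------------------------------------------------------------
# Initial guesses
# ---------------------------------------------------------------------------


def _fit_line(temp_k: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(temp_k - T_REF, signal, 1)
    return float(intercept), float(slope)


def _detect_transition(temp: np.ndarray, signal: np.ndarray) -> None:
    """Raise :class:`NoTransitionError` if the series is consistent with a line."""
    coeffs = np.polyfit(temp, signal, 1)
    resid = signal - np.polyval(coeffs, temp)
    # Robust noise level from second differences (kills linear trend).
    noise = float(np.median(np.abs(np.diff(signal, 2)))) / (0.6745 * np.sqrt(6.0))
    scale = max(1.0, float(np.max(np.abs(signal))))
    if np.max(np.abs(resid)) <= max(5.0 * noise, 1e-9 * scale):
        raise NoTransitionError("no detectable transition (flat derivative)")


def initial_guess(dataset: UnfoldingDataset) -> tuple[ThermoParams, BaselineParams]:
    """Data-driven starting values for a global fit.

    T_m comes from the extremal smoothed dF/dT on the lowest-denaturant
    series; baselines from straight-line fits to the first and last 15% of
    that series (its ends are the only ones guaranteed native / unfolded
    across the whole denaturant grid); dH_m, dC_p and m start at generic
    cooperative-folder values.
    """
    low = min(dataset.series, key=lambda s: s.denaturant)
    temp = low.temperature[low.mask]
    sig = low.signal[low.mask]
    _detect_transition(temp, sig)

    window = min(15, len(sig) - (1 - len(sig) % 2))
    smoothed = savgol_filter(sig, window, 3) if window >= 5 else sig
    deriv = np.gradient(smoothed, temp)
    dev = deriv - np.median(deriv)
    t_m_guess = float(temp[int(np.argmax(np.abs(dev)))])

    k = max(3, int(0.15 * len(sig)))
    n_int, n_slope = _fit_line(temp[:k], sig[:k])
    u_int, u_slope = _fit_line(temp[-k:], sig[-k:])
    thermo = ThermoParams(
        t_m=t_m_guess,
        dh_m=DEFAULT_THERMO_INIT["dh_m"],
        dcp=DEFAULT_THERMO_INIT["dcp"],
        m_value=DEFAULT_THERMO_INIT["m_value"],
    )
    baselines = BaselineParams(n_int, n_slope, 0.0, u_int, u_slope, 0.0)
    return thermo, baselines


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------


def _thermo_pname(gi: int, name: str, shared: set[str]) -> str:
    return f"shared_{name}" if name in shared else f"g{gi}_{name}"


def _baseline_pname(gi: int, ri: int, name: str) -> str:
    return f"g{gi}_r{ri}_{name}"


def _build_parameters(
    groups: Sequence[tuple[str, list[UnfoldingDataset]]],
    guesses: Sequence[tuple[ThermoParams, BaselineParams]],
    options: FitOptions,
) -> lmfit.Parameters:
    shared = set(options.shared_parameters)
    bounds = {**DEFAULT_BOUNDS, **options.bounds}
    params = lmfit.Parameters()

    for name in options.shared_parameters:
        vals = [getattr(g[0], name) for g in guesses]
        lo, hi = bounds[name]
        params.add(f"shared_{name}", value=float(np.mean(vals)), min=lo, max=hi)

    for gi, (label, dsets) in enumerate(groups):
        thermo_guess, base_guess = guesses[gi]
        for name in THERMO_NAMES:
            if name in shared:
                continue
            lo, hi = bounds[name]
            params.add(
                f"g{gi}_{name}",
                value=float(np.clip(getattr(thermo_guess, name), lo, hi)),
                min=lo,
                max=hi,
            )
        for ri, _ in enumerate(dsets):
            for bname in BASELINE_NAMES:
                vary = options.baseline_d_slopes or not bname.endswith("d_slope")
                params.add(
                    _baseline_pname(gi, ri, bname),
                    value=float(getattr(base_guess, bname)),
                    vary=vary,
                )

    for name, value in options.fixed_parameters.items():
        for pname in {_thermo_pname(gi, name, shared) for gi in range(len(groups))}:
            params[pname].set(value=float(value), vary=False, min=-np.inf, max=np.inf)
    return params


def _unpack_thermo(params: lmfit.Parameters, gi: int, shared: set[str]) -> ThermoParams:
    return ThermoParams(
        *[params[_thermo_pname(gi, n, shared)].value for n in THERMO_NAMES]
    )


def _unpack_baselines(params: lmfit.Parameters, gi: int, ri: int) -> BaselineParams:
    return BaselineParams(
        *[params[_baseline_pname(gi, ri, n)].value for n in BASELINE_NAMES]
    )


def _residual(
    params: lmfit.Parameters,
    groups: Sequence[tuple[str, list[UnfoldingDataset]]],
    shared: set[str],
) -> np.ndarray:
    out = []
    for gi, (_, dsets) in enumerate(groups):
        thermo = _unpack_thermo(params, gi, shared)
        for ri, ds in enumerate(dsets):
            base = _unpack_baselines(params, gi, ri)
            for s in ds.series:
                pred = predicted_signal(
                    thermo, base, Condition(s.temperature, s.denaturant)
                )
                out.append((np.asarray(pred) - s.signal)[s.mask])
    return np.concatenate(out)


def _jitter(
    params: lmfit.Parameters, rng: np.random.Generator, amplitude: float
) -> lmfit.Parameters:
    jittered = params.copy()
    for name, p in jittered.items():
        if not p.vary:
            continue
        if name.endswith("_t_m"):
            p.value += rng.normal(0.0, 2.0)
        elif name.endswith(("_dh_m", "_dcp", "_m_value")):
            p.value *= 1.0 + rng.normal(0.0, 0.05)
        elif name.endswith("intercept"):
            p.value += rng.normal(0.0, 0.03 * amplitude)
        else:  # baseline slopes
            p.value += rng.normal(0.0, 0.1 * (abs(p.value) + 0.1))
        p.value = float(np.clip(p.value, p.min, p.max))
    return jittered


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _minimize(
    groups: Sequence[tuple[str, list[UnfoldingDataset]]],
    options: FitOptions,
) -> tuple[lmfit.minimizer.MinimizerResult, set[str]]:
    shared = set(options.shared_parameters)
    guesses = [initial_guess(dsets[0]) for _, dsets in groups]
    params0 = _build_parameters(groups, guesses, options)
    amp = float(
        np.mean(
            [
                abs(g[1].native_intercept - g[1].unfolded_intercept) or 100.0
                for g in guesses
            ]
        )
    )
    rng = np.random.default_rng(options.seed)
    fit_kws = dict(
        ftol=options.ftol,
        xtol=options.xtol,
        gtol=options.gtol,
        max_nfev=options.max_iterations * (len(params0) + 1),
    )
    best = None
    for start in range(max(1, options.n_starts)):
        p0 = params0 if start == 0 else _jitter(params0, rng, amp)
        result = lmfit.minimize(
            _residual,
            p0,
            args=(groups, shared),
            method="least_squares",
            nan_policy="raise",
            **fit_kws,
        )
        if best is None or result.chisqr < best.chisqr:
            best = result
    if best.covar is None:
        raise DegenerateFitError(
            "singular Jacobian: baselines or transition unidentifiable"
        )
    return best, shared


def _results_from(
    minres: lmfit.minimizer.MinimizerResult,
    groups: Sequence[tuple[str, list[UnfoldingDataset]]],
    shared: set[str],
) -> list[FitResult]:
    params = minres.params
    dof = minres.nfree
    residual_sd = float(np.sqrt(minres.chisqr / dof))
    stderr = {name: params[name].stderr for name in minres.var_names}
    results = []
    for gi, (label, dsets) in enumerate(groups):
        thermo = _unpack_thermo(params, gi, shared)
        baselines = [_unpack_baselines(params, gi, ri) for ri in range(len(dsets))]
        pname_map = {n: _thermo_pname(gi, n, shared) for n in THERMO_NAMES}
        ses = {
            n: float(stderr.get(pname_map[n]) or 0.0)
            if params[pname_map[n]].vary
            else 0.0
            for n in THERMO_NAMES
        }
        results.append(
            FitResult(
                variant_label=label,
                thermo=thermo,
                baselines=baselines,
                standard_errors=ses,
                covariance=minres.covar,
                var_names=list(minres.var_names),
                thermo_param_names=pname_map,
                residual_sd=residual_sd,
                dof=dof,
                converged=bool(minres.success),
                n_series=sum(len(ds.series) for ds in dsets),
                n_points=sum(ds.n_points for ds in dsets),
            )
        )
    return results


def _as_dataset_list(
    datasets: Union[UnfoldingDataset, Iterable[UnfoldingDataset]],
) -> list[UnfoldingDataset]:
    if isinstance(datasets, UnfoldingDataset):
        return [datasets]
    return list(datasets)


def fit_variant(
    datasets: Union[UnfoldingDataset, Iterable[UnfoldingDataset]],
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Globally fit all series (and replicates) of one variant.

    ``datasets`` is one :class:`UnfoldingDataset` or an iterable of replicate
    datasets sharing a variant label; thermodynamic parameters are shared
    across replicates, baselines are per replicate.
    """
    options = options or FitOptions()
    dsets = _as_dataset_list(datasets)
    if not dsets:
        raise EmptyInputError("no datasets to fit")
    labels = {ds.variant_label for ds in dsets}
    if len(labels) > 1:
        raise InvalidParameterError(
            f"fit_variant got multiple variants {sorted(labels)}; use fit_joint"
        )
    if options.mask_windows:
        dsets = [apply_masks(ds, options.mask_windows) for ds in dsets]
    groups = [(dsets[0].variant_label, dsets)]
    minres, shared = _minimize(groups, options)
    return _results_from(minres, groups, shared)[0]


def fit_joint(
    datasets: Iterable[UnfoldingDataset],
    options: Optional[FitOptions] = None,
) -> list[FitResult]:
    """Jointly fit several variants with shared (or fixed) parameters.

    Datasets are grouped by ``variant_label`` (replicates of a variant share
    its thermodynamic parameters). If the options neither share nor fix the
    m-value, it is shared by default -- a single m estimated across all
    variants. Returns one :class:`FitResult` per variant, in first-appearance
    order; each carries the full joint covariance.
    """
    options = options or FitOptions()
    dsets = _as_dataset_list(datasets)
    if not dsets:
        raise EmptyInputError("no datasets to fit")
    if options.mask_windows:
        dsets = [apply_masks(ds, options.mask_windows) for ds in dsets]
    if not options.shared_parameters and "m_value" not in options.fixed_parameters:
        options = dataclasses.replace(options, shared_parameters=("m_value",))

    order: list[str] = []
    by_label: dict[str, list[UnfoldingDataset]] = {}
    for ds in dsets:
        if ds.variant_label not in by_label:
            order.append(ds.variant_label)
            by_label[ds.variant_label] = []
        by_label[ds.variant_label].append(ds)
    groups = [(label, by_label[label]) for label in order]
    minres, shared = _minimize(groups, options)
    return _results_from(minres, groups, shared)


def average_m(fits: Iterable[Union[FitResult, float]]) -> float:
    """Arithmetic mean m-value over fits (or raw m-values)."""
    values = [
        f.thermo.m_value if isinstance(f, FitResult) else float(f) for f in fits
    ]
    if not values:
        raise EmptyInputError("average_m needs at least one value")
    return float(np.mean(values))


# ---------------------------------------------------------------------------
# Derived quantities and delta-method errors
# ---------------------------------------------------------------------------

_QUANTITIES: dict[str, Callable[..., float]] = {
    "dg": lambda tp, temperature=298.0, denaturant=0.0: float(
        gibbs_free_energy(tp, Condition(temperature, denaturant))
    ),
    "d50": lambda tp, temperature=298.0: midpoint_denaturant(tp, temperature),
    "tm_app": lambda tp, denaturant=0.0: melting_temperature_at(tp, denaturant),
}

_GRAD_STEPS = {"t_m": 1e-3, "dh_m": 1e-2, "dcp": 1e-4, "m_value": 1e-4}


def derived_quantity(
    fit: FitResult,
    quantity: Union[str, Callable[[ThermoParams], float]],
    **kwargs: float,
) -> tuple[float, float]:
    """Value and delta-method standard error of a derived quantity.

    ``quantity`` is ``"dg"`` (kwargs: temperature, denaturant), ``"d50"``
    (temperature), ``"tm_app"`` (denaturant), or any callable mapping
    :class:`ThermoParams` to a float. The error uses the analytic-free
    central-difference gradient with the full fit covariance.
    """
    if fit.covariance is None:
        raise CovarianceUnavailableError("fit carries no covariance")
    func = _QUANTITIES[quantity] if isinstance(quantity, str) else quantity

    def evaluate(tp: ThermoParams) -> float:
        return float(func(tp, **kwargs)) if kwargs else float(func(tp))

    value = evaluate(fit.thermo)
    grad = np.zeros(len(fit.var_names))
    for name in THERMO_NAMES:
        pname = fit.thermo_param_names[name]
        if pname not in fit.var_names:
            continue  # fixed parameter: no uncertainty contribution
        h = _GRAD_STEPS[name]
        hi = dataclasses.replace(fit.thermo, **{name: getattr(fit.thermo, name) + h})
        lo = dataclasses.replace(fit.thermo, **{name: getattr(fit.thermo, name) - h})
        grad[fit.var_names.index(pname)] = (evaluate(hi) - evaluate(lo)) / (2 * h)
    variance = float(grad @ fit.covariance @ grad)
    return value, float(np.sqrt(max(variance, 0.0)))


def derived_quantity_error(
    fit: FitResult,
    quantity: Union[str, Callable[[ThermoParams], float]],
    **kwargs: float,
) -> float:
    """Delta-method standard error of a derived quantity (see :func:`derived_quantity`)."""
    return derived_quantity(fit, quantity, **kwargs)[1]


def stability_record(
    fit: FitResult,
    temperature: float = 298.0,
    source: str = "free-fit",
) -> StabilityRecord:
    """A variant's dG_f at the reference temperature, with propagated error."""
    dg, se = derived_quantity(fit, "dg", temperature=temperature, denaturant=0.0)
    return StabilityRecord(
        variant_label=fit.variant_label,
        dg=dg,
        se=se,
        source=source,
        reference_temperature=temperature,
    )
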