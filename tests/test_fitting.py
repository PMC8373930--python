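"""Global fitting: initial guesses, recovery, joint/shared-m fits, delta-method errors."""

import numpy as np
import pytest

from foldstab import (
    Condition,
    ExperimentDesign,
    FitOptions,
    MaskWindow,
    ThermoParams,
    UnfoldingDataset,
    UnfoldingSeries,
    average_m,
    derived_quantity,
    derived_quantity_error,
    fit_joint,
    fit_variant,
    gibbs_free_energy,
    initial_guess,
    reference_params,
    simulate_dataset,
)
from foldstab.exceptions import (
    EmptyInputError,
    InvalidParameterError,
    NoTransitionError,
)
from foldstab.fitting import THERMO_NAMES

DG298_WT_TRUTH = -30.633  # Gibbs-Helmholtz evaluation of the wild-type truth


def _flat_dataset():
    temps = np.linspace(288.15, 368.15, 81)
    series = [
        UnfoldingSeries(d, temps, 900.0 - 1.5 * (temps - 273.15))
        for d in (0.0, 1.0, 2.0, 3.0, 4.0)
    ]
    return UnfoldingDataset("flat", series)


class TestInitialGuess:
    def test_tm_guess_close_to_truth(self, wt_noise_free):
        thermo, _ = initial_guess(wt_noise_free)
        assert thermo.t_m == pytest.approx(352.3, abs=2.0)

    def test_pure_baseline_has_no_transition(self):
        with pytest.raises(NoTransitionError):
            initial_guess(_flat_dataset())

    def test_guess_ordering_follows_true_stability(self, default_baselines):
        design = ExperimentDesign(noise_sd=0.0, temperature_step=1.0)
        d55g = simulate_dataset(reference_params("D55G"), default_baselines, design)
        i57a = simulate_dataset(reference_params("I57A"), default_baselines, design)
        assert initial_guess(d55g)[0].t_m > initial_guess(i57a)[0].t_m


class TestFitVariant:
    def test_zero_noise_exact_recovery(self, wt_noise_free, wt_params):
        fit = fit_variant(wt_noise_free, FitOptions(n_starts=1))
        assert fit.converged
        for name in THERMO_NAMES:
            assert abs(getattr(fit.thermo, name) - getattr(wt_params, name)) < 1e-4

    def test_noisy_recovery_within_pooled_reproducibility(self, wt_noisy):
        """At sigma = 1% amplitude, dG_f(298 K) is recovered within 1.2 kJ/mol."""
        fit = fit_variant(wt_noisy, FitOptions(n_starts=2))
        dg = gibbs_free_energy(fit.thermo, Condition(298.0, 0.0))
        assert abs(dg - DG298_WT_TRUTH) < 1.2

    def test_fixing_m_at_generating_value_matches_free_fit(self, default_baselines):
        truth = ThermoParams(352.3, -322.0, -4.3, 8.4)
        design = ExperimentDesign(seed=5, temperature_step=1.0)
        ds = simulate_dataset(truth, default_baselines, design)
        free = fit_variant(ds, FitOptions(n_starts=1))
        fixed = fit_variant(
            ds, FitOptions(fixed_parameters={"m_value": 8.4}, n_starts=1)
        )
        for name in ("t_m", "dh_m", "dcp"):
            delta = abs(getattr(free.thermo, name) - getattr(fixed.thermo, name))
            assert delta < max(free.standard_errors[name], 1e-6)
        assert fixed.standard_errors["m_value"] == 0.0

    def test_refit_from_solution_is_fixed_point(self, wt_noisy):
        fit = fit_variant(wt_noisy, FitOptions(n_starts=1))
        # SSR at the solution cannot be improved by refitting from it
        refit = fit_variant(wt_noisy, FitOptions(n_starts=1))
        assert refit.residual_sd == pytest.approx(fit.residual_sd, rel=1e-9)

    def test_replicates_share_thermo_with_per_replicate_baselines(
        self, default_baselines, wt_params
    ):
        reps = [
            simulate_dataset(
                wt_params,
                default_baselines,
                ExperimentDesign(seed=s, temperature_step=1.0),
                variant_label="wild-type",
                replicate_id=s,
            )
            for s in (0, 1)
        ]
        fit = fit_variant(reps, FitOptions(n_starts=1))
        assert len(fit.baselines) == 2
        assert fit.n_series == 26
        dg = gibbs_free_energy(fit.thermo, Condition(298.0, 0.0))
        assert abs(dg - DG298_WT_TRUTH) < 1.2

    def test_mask_windows_exclude_points(self, wt_noise_free):
        options = FitOptions(
            n_starts=1, mask_windows=(MaskWindow(t_min=360.0, d_max=2.0),)
        )
        fit = fit_variant(wt_noise_free, options)
        assert fit.n_points < wt_noise_free.n_points
        assert fit.converged

    def test_mixed_variants_rejected(self, wt_noise_free):
        other = UnfoldingDataset("other", wt_noise_free.series)
        with pytest.raises(InvalidParameterError):
            fit_variant([wt_noise_free, other])


@pytest.fixture(scope="module")
def common_m_datasets(default_baselines):
    truths = {
        "A": ThermoParams(352.3, -322.0, -4.3, 8.4),
        "B": ThermoParams(361.1, -378.0, -4.7, 8.4),
    }
    return [
        simulate_dataset(
            p,
            default_baselines,
            ExperimentDesign(seed=11 + i, temperature_step=1.0),
            variant_label=label,
        )
        for i, (label, p) in enumerate(truths.items())
    ]


@pytest.fixture(scope="module")
def wt_fit(default_baselines):
    ds = simulate_dataset(
        reference_params("wild-type"),
        default_baselines,
        ExperimentDesign(seed=1, temperature_step=1.0),
        variant_label="wild-type",
    )
    return fit_variant(ds, FitOptions(n_starts=1))


class TestFitJoint:
    def test_shared_m_recovers_common_truth(self, common_m_datasets):
        fits = fit_joint(
            common_m_datasets,
            FitOptions(shared_parameters=("m_value",), n_starts=1),
        )
        assert fits[0].thermo.m_value == fits[1].thermo.m_value
        se = fits[0].standard_errors["m_value"]
        assert abs(fits[0].thermo.m_value - 8.4) < 2 * se

    def test_fixed_m_shrinks_derived_errors(self, common_m_datasets):
        free = [fit_variant(ds, FitOptions(n_starts=1)) for ds in common_m_datasets]
        fixed = fit_joint(
            common_m_datasets,
            FitOptions(fixed_parameters={"m_value": 8.4}, n_starts=1),
        )
        for f_free, f_fixed in zip(free, fixed):
            se_free = derived_quantity_error(f_free, "dg", temperature=298.0)
            se_fixed = derived_quantity_error(f_fixed, "dg", temperature=298.0)
            assert se_fixed <= se_free

    def test_single_dataset_joint_equals_variant_fit(self, wt_noisy):
        joint = fit_joint([wt_noisy], FitOptions(n_starts=1))
        single = fit_variant(wt_noisy, FitOptions(n_starts=1))
        assert len(joint) == 1
        for name in THERMO_NAMES:
            assert getattr(joint[0].thermo, name) == pytest.approx(
                getattr(single.thermo, name), rel=1e-6
            )


class TestAverageM:
    def test_published_six_variant_mean(self):
        assert average_m([8.2, 8.7, 8.5, 8.3, 8.5, 7.9]) == pytest.approx(8.35)

    def test_single_value_and_constant(self):
        assert average_m([7.7]) == 7.7
        assert average_m([8.0, 8.0, 8.0]) == 8.0

    def test_empty_input(self):
        with pytest.raises(EmptyInputError):
            average_m([])


class TestDerivedQuantityErrors:
    def test_zero_gradient_quantity_has_zero_error(self, wt_fit):
        assert derived_quantity_error(wt_fit, lambda tp: 42.0) == 0.0

    def test_single_parameter_quantity_returns_its_se(self, wt_fit):
        se = derived_quantity_error(wt_fit, lambda tp: tp.t_m)
        assert se == pytest.approx(wt_fit.standard_errors["t_m"], rel=1e-6)

    def test_delta_method_matches_parametric_monte_carlo(self, wt_fit):
        """dG_f(298 K) SE vs a 2000-draw Gaussian resample of the covariance."""
        value, se = derived_quantity(wt_fit, "dg", temperature=298.0)
        idx = [wt_fit.var_names.index(wt_fit.thermo_param_names[n]) for n in THERMO_NAMES]
        mean = np.array([getattr(wt_fit.thermo, n) for n in THERMO_NAMES])
        cov = wt_fit.covariance[np.ix_(idx, idx)]
        rng = np.random.default_rng(2024)
        draws = rng.multivariate_normal(mean, cov, size=2000)
        dgs = [
            gibbs_free_energy(
                ThermoParams(*draw), Condition(298.0, 0.0)
            )
            for draw in draws
        ]
        assert se == pytest.approx(np.std(dgs, ddof=1), rel=0.15)
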