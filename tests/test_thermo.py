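"""Closed-form two-state thermodynamics against independent numerical oracles."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import bisect

from foldstab import (
    Condition,
    ThermoParams,
    fraction_unfolded,
    gibbs_free_energy,
    melting_temperature_at,
    midpoint_denaturant,
)
from foldstab.exceptions import (
    InvalidConditionError,
    InvalidParameterError,
    NoTransitionError,
)

from .conftest import random_params


def gibbs_oracle(p: ThermoParams, t: float, d: float) -> float:
    """van 't Hoff integration oracle: d(dG/T)/dT = -dH(T)/T^2 with
    dH(T) = dH_m + dC_p (T - T_m), integrated from T_m where dG = 0."""
    integral, _ = quad(
        lambda x: -(p.dh_m + p.dcp * (x - p.t_m)) / x**2, p.t_m, t, limit=200
    )
    return t * integral + p.m_value * d


class TestGibbsFreeEnergy:
    @pytest.mark.parametrize(
        "params, expected",
        [
            (ThermoParams(352.3, -322.0, -4.3, 8.2), -30.633),  # wild-type truth
            (ThermoParams(333.1, -269.0, -5.4, 11.6), -17.989),  # I57A truth
        ],
    )
    def test_known_stabilities_at_298K(self, params, expected):
        dg = gibbs_free_energy(params, Condition(298.0, 0.0))
        assert dg == pytest.approx(expected, abs=5e-3)
        assert dg == pytest.approx(gibbs_oracle(params, 298.0, 0.0), abs=1e-6)

    def test_zero_at_melting_temperature(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            p = random_params(rng)
            assert gibbs_free_energy(p, Condition(p.t_m, 0.0)) == 0.0

    def test_agrees_with_vant_hoff_integration_on_grid(self, wt_params):
        for t in np.linspace(280.0, 370.0, 7):
            for d in (0.0, 2.5, 5.0):
                assert gibbs_free_energy(wt_params, Condition(t, d)) == pytest.approx(
                    gibbs_oracle(wt_params, t, d), abs=1e-6
                )

    def test_linear_in_denaturant_with_slope_m(self, wt_params):
        h = 1e-6
        for d in (0.0, 1.0, 4.0):
            fd = (
                gibbs_free_energy(wt_params, Condition(310.0, d + h))
                - gibbs_free_energy(wt_params, Condition(310.0, d))
            ) / h
            assert fd == pytest.approx(wt_params.m_value, rel=1e-6)

    def test_rejects_nonpositive_temperature(self, wt_params):
        with pytest.raises(InvalidConditionError):
            gibbs_free_energy(wt_params, Condition(-1.0, 0.0))

    def test_rejects_negative_denaturant(self):
        with pytest.raises(InvalidConditionError):
            Condition(298.0, -0.1)


class TestFractionUnfolded:
    def test_half_unfolded_where_dg_vanishes(self, wt_params):
        assert fraction_unfolded(wt_params, Condition(wt_params.t_m, 0.0)) == 0.5
        d50 = midpoint_denaturant(wt_params, 310.0)
        assert fraction_unfolded(wt_params, Condition(310.0, d50)) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_wild_type_barely_unfolded_in_water(self, wt_params):
        # 1/(1+exp(30.633/(R*298)))
        fu = fraction_unfolded(wt_params, Condition(298.0, 0.0))
        assert fu == pytest.approx(4.27e-6, rel=0.02)

    def test_bounded_and_monotone_in_denaturant(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_params(rng)
            d = np.linspace(0.0, 7.0, 30)
            fu = fraction_unfolded(p, Condition(np.full_like(d, 320.0), d))
            assert np.all((fu > 0) & (fu < 1))
            assert np.all(np.diff(fu) > 0)

    def test_logistic_asymptotes(self, wt_params):
        # deep native / fully denatured limits
        assert fraction_unfolded(wt_params, Condition(288.0, 0.0)) < 1e-5
        assert fraction_unfolded(wt_params, Condition(368.0, 7.0)) > 1 - 1e-9


class TestMidpointsAndApparentTm:
    @pytest.mark.parametrize(
        "dg, m, expected",
        [(-30.5, 8.2, 3.7), (-17.9, 11.6, 1.5), (-38.4, 8.5, 4.5)],
    )
    def test_published_midpoints_from_dg_over_m(self, dg, m, expected):
        # [D]50% = -dG_f / m on the published (dG, m) pairs
        assert -dg / m == pytest.approx(expected, abs=0.05)

    def test_midpoint_zeroes_free_energy(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = random_params(rng)
            d50 = midpoint_denaturant(p, 300.0)
            assert gibbs_free_energy(p, Condition(300.0, max(d50, 0.0))) == pytest.approx(
                0.0 if d50 >= 0 else p.m_value * (-d50), abs=1e-9
            )

    def test_rejects_nonpositive_m_value(self):
        with pytest.raises(InvalidParameterError):
            ThermoParams(352.3, -322.0, -4.3, 0.0)

    def test_apparent_tm_at_zero_denaturant_is_tm(self, wt_params):
        assert melting_temperature_at(wt_params, 0.0) == wt_params.t_m

    def test_apparent_tm_matches_bisection_oracle(self, wt_params):
        root = bisect(
            lambda t: gibbs_free_energy(wt_params, Condition(t, 2.0)),
            250.0,
            400.0,
            xtol=1e-4,
        )
        assert melting_temperature_at(wt_params, 2.0) == pytest.approx(root, abs=2e-4)
        assert abs(
            gibbs_free_energy(
                wt_params, Condition(melting_temperature_at(wt_params, 2.0), 2.0)
            )
        ) < 1e-9

    def test_apparent_tm_strictly_decreasing_in_denaturant(self, wt_params):
        tms = [melting_temperature_at(wt_params, d) for d in (0.0, 1.0, 2.0, 3.0)]
        assert np.all(np.diff(tms) < 0)

    def test_no_transition_outside_bracket(self, wt_params):
        with pytest.raises(NoTransitionError):
            melting_temperature_at(wt_params, 2.0, bracket=(250.0, 260.0))

    def test_midpoint_and_apparent_tm_mutually_consistent(self):
        from foldstab.thermo import max_stability_temperature

        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(20):
            p = random_params(rng)
            lo = max(300.0, max_stability_temperature(p) + 2.0)
            if lo >= p.t_m - 1.0:
                continue
            t = float(rng.uniform(lo, p.t_m - 1.0))
            d50 = midpoint_denaturant(p, t)
            if d50 <= 0:
                continue
            assert melting_temperature_at(p, d50) == pytest.approx(t, abs=1e-6)
            checked += 1
        assert checked >= 5
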