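"""Kinetic building blocks and the structure of the assembled vector field."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from metaflex import (
    STATE_VARS,
    FluxSet,
    GlycogenCapError,
    MetabolicState,
    ModelInputError,
    compute_fluxes,
    insulin_production_erf,
    insulin_production_quadratic,
    meal_sources,
    rhs,
    rhs_direct,
    saturation_functions,
)
from metaflex.model import HEALTHY_SENSITIVITY


def erf_series(x: float, terms: int = 40) -> float:
    """Maclaurin-series oracle for erf, independent of scipy."""
    total = 0.0
    for n in range(terms):
        total += (-1) ** n * x ** (2 * n + 1) / (math.factorial(n) * (2 * n + 1))
    return 2.0 / math.sqrt(math.pi) * total


class TestInsulinProduction:
    def test_erf_symmetry_point_and_limit(self, params):
        p = replace(params, k_1=1.0, k_2=1.0)
        assert insulin_production_erf(p.v, p) == pytest.approx(p.k_1)
        assert insulin_production_erf(1e6, p) == pytest.approx(p.k_1 + p.k_2)
        # bounded on both sides
        assert insulin_production_erf(0.0, p) >= p.k_1 - p.k_2 - 1e-12

    def test_erf_against_series_oracle(self, params):
        p = replace(params, k_1=1.0, k_2=1.0)
        value = insulin_production_erf(p.v + p.c, p)
        assert value == pytest.approx(1.0 + erf_series(1.0), rel=1e-12)

    def test_quadratic_values_and_monotonicity(self, params):
        p = replace(params, k_IG=2.0, k_I2=3.0)
        assert insulin_production_quadratic(0.0, p) == 0.0
        assert insulin_production_quadratic(1.0, p) == pytest.approx(5.0)
        assert insulin_production_quadratic(2.0, p) > insulin_production_quadratic(1.0, p)

    @pytest.mark.parametrize("bad", [float("nan"), float("inf")])
    def test_non_finite_glucose_rejected(self, params, bad):
        with pytest.raises(ModelInputError):
            insulin_production_quadratic(bad, params)
        with pytest.raises(ModelInputError):
            insulin_production_erf(bad, params)

    def test_nonpositive_erf_width_rejected(self, params):
        with pytest.raises(ModelInputError):
            insulin_production_erf(1.0, replace(params, c=0.0))


class TestMealSources:
    def test_zero_at_meal_time(self, params):
        assert meal_sources(0.0, params) == (0.0, 0.0)

    def test_total_delivery_matches_quadrature_oracle(self, params):
        for which, B, theta in [(0, params.B_G, params.theta_G),
                                (1, params.B_T, params.theta_T)]:
            total, _ = quad(lambda t: meal_sources(t, params)[which], 0.0, 20.0 * B,
                            limit=200)
            assert total == pytest.approx(params.F * theta, rel=1e-6)

    def test_peak_location_and_height_against_grid_oracle(self, params):
        t = np.linspace(0.0, 6.0, 600001)
        F_G, _ = meal_sources(t, params)
        i = np.argmax(F_G)
        assert t[i] == pytest.approx(params.B_G, abs=1e-4)
        expected_height = params.F * params.theta_G / params.B_G * math.exp(-0.5)
        assert F_G[i] == pytest.approx(expected_height, rel=1e-8)

    def test_invalid_delay_rejected(self, params):
        with pytest.raises(ModelInputError):
            meal_sources(1.0, replace(params, B_G=0.0))


class TestSaturationFunctions:
    def test_boundary_values(self, params):
        f1, f2, f3 = saturation_functions(0.0, 0.0, params)
        assert (f1, f3) == (0.0, 0.0)
        _, f2_cap, _ = saturation_functions(params.Y_max, 1.0, params)
        assert f2_cap == 0.0
        f1_half, _, _ = saturation_functions(params.Y_0, 1.0, params)
        assert f1_half == pytest.approx(0.5)

    def test_ranges_and_monotonicity(self, params):
        grid = np.linspace(0.0, params.Y_max, 50)
        f1s = [saturation_functions(y, 1.0, params)[0] for y in grid]
        f2s = [saturation_functions(y, 1.0, params)[1] for y in grid]
        assert all(0.0 <= v < 1.0 for v in f1s + f2s)
        assert np.all(np.diff(f1s) > 0) and np.all(np.diff(f2s) < 0)

    def test_cap_breach_is_domain_error(self, params):
        with pytest.raises(GlycogenCapError):
            saturation_functions(params.Y_max + 0.01, 1.0, params)


def random_states(rng, n, high=3.0):
    states = rng.uniform(0.0, high, size=(n, len(STATE_VARS)))
    states[:, STATE_VARS.index("Y_L")] = rng.uniform(0.0, 2.9, size=n)
    return states


class TestFluxAssembly:
    def test_insulin_gated_fluxes_vanish_without_insulin(self, params):
        state = MetabolicState.from_array(
            [0.0] + [1.0] * (len(STATE_VARS) - 1)  # I = 0
        )
        f = compute_fluxes(state, 0.0, params)
        assert f.hepatic_glucose_uptake == 0.0
        assert f.lipogenesis == 0.0
        assert f.hepatic_tag_synthesis == 0.0
        assert f.muscle_glucose_oxidation == 0.0

    def test_negative_state_rejected(self, params):
        bad = np.ones(len(STATE_VARS))
        bad[1] = -0.5
        with pytest.raises(ModelInputError):
            compute_fluxes(bad, 0.0, params)

    def test_all_fluxes_nonnegative_at_random_states(self, params, rng):
        for y in random_states(rng, 50):
            fluxes = compute_fluxes(y, rng.uniform(0.0, 6.0), params)
            assert all(v >= 0.0 for v in fluxes.to_dict().values())

    def test_assembled_rhs_matches_direct_transcription(self, params, rng):
        """Flux-based assembly against an independent term-by-term transcription."""
        worst = 0.0
        for y in random_states(rng, 100):
            t = rng.uniform(0.0, 6.0)
            worst = max(worst, float(np.max(np.abs(
                rhs(y, t, params) - rhs_direct(y, t, params)
            ))))
        assert worst < 1e-12

    def test_transport_fluxes_shared_antisymmetrically(self, params, rng):
        """Every transport term enters donor and acceptor with opposite sign.

        Checked through conservation combinations: multiplying each equation
        by its volume factor and summing connected compartments must cancel
        the shared fluxes exactly, leaving only external sources/sinks.
        """
        a, e = params.alpha, params.eta
        idx = {name: i for i, name in enumerate(STATE_VARS)}
        for y in random_states(rng, 100):
            t = rng.uniform(0.0, 6.0)
            f = compute_fluxes(y, t, params)
            d = rhs(y, t, params)
            combos = [
                # plasma glucose + hepatic glycogen: k_L/beta_G*f1 terms cancel
                (a * d[idx["G_b"]] + e * d[idx["Y_L"]]
                 - (f.hepatic_gluconeogenesis - f.body_glucose_sink
                    - f.muscle_glucose_uptake - f.lipogenesis
                    + f.meal_glucose_input)),
                # plasma glucose + muscle glucose: muscle uptake cancels
                (a * d[idx["G_b"]] + d[idx["G_m"]]
                 - (f.hepatic_glucose_output + f.hepatic_gluconeogenesis
                    - f.body_glucose_sink - f.hepatic_glucose_uptake
                    - f.lipogenesis + f.meal_glucose_input
                    - f.muscle_glucose_oxidation - f.muscle_glycogen_synthesis
                    + f.muscle_glycogenolysis)),
                # plasma TAG + hepatic TAG: hepatic TAG export cancels
                (a * d[idx["T_b"]] + e * d[idx["T_L"]]
                 - (f.hepatic_tag_synthesis - f.muscle_tag_uptake
                    - f.adipose_tag_uptake + f.meal_tag_input)),
                # plasma FFA + hepatic FFA: k_BL/k_LB exchange cancels
                (a * d[idx["A_b"]] + e * d[idx["A_L"]]
                 - (f.adipose_ffa_output - f.muscle_ffa_uptake + f.lipogenesis
                    - f.hepatic_ffa_oxidation - f.hepatic_tag_synthesis)),
                # muscle glucose + glycogen: glycogen cycling cancels
                (d[idx["G_m"]] + d[idx["Y_m"]]
                 - (f.muscle_glucose_uptake - f.muscle_glucose_oxidation)),
                # muscle FFA + TAG: TAG cycling cancels
                (d[idx["A_m"]] + d[idx["T_m"]]
                 - (f.muscle_tag_uptake + f.muscle_ffa_uptake
                    - f.muscle_ffa_oxidation)),
            ]
            assert max(abs(c) for c in combos) < 1e-12

    def test_muscle_glycogen_terms_antisymmetric(self, params, rng):
        """dY_m is exactly minus the glycogen part of dG_m."""
        for y in random_states(rng, 20):
            f = compute_fluxes(y, 0.0, params)
            d = rhs(y, 0.0, params)
            assert d[STATE_VARS.index("Y_m")] == pytest.approx(
                f.muscle_glycogen_synthesis - f.muscle_glycogenolysis, abs=1e-14
            )

    def test_hepatic_glycogen_balance_shared_with_plasma(self, params, rng):
        for y in random_states(rng, 20):
            f = compute_fluxes(y, 0.0, params)
            d = rhs(y, 0.0, params)
            assert params.eta * d[STATE_VARS.index("Y_L")] == pytest.approx(
                f.hepatic_glucose_uptake - f.hepatic_glucose_output, abs=1e-14
            )


class TestMonotoneSensitivity:
    """Finite-difference monotonicity of fluxes in the sensitivity factors."""

    def _flux(self, params, name, **sens_kwargs):
        from metaflex import SensitivityFactors

        state = MetabolicState.from_array([1.5] + [1.0] * 11)  # I = 1.5 > 0
        f = compute_fluxes(state, 0.0, params, SensitivityFactors(**sens_kwargs))
        return getattr(f, name)

    def test_muscle_glucose_uptake_increases_with_sigma_G(self, params):
        lo = self._flux(params, "muscle_glucose_uptake", sigma_G=0.2)
        hi = self._flux(params, "muscle_glucose_uptake", sigma_G=0.9)
        assert hi > lo

    def test_adipose_ffa_output_decreases_with_sigma_A(self, params):
        lo_sens = self._flux(params, "adipose_ffa_output", sigma_A=0.1)
        hi_sens = self._flux(params, "adipose_ffa_output", sigma_A=0.9)
        assert lo_sens > hi_sens  # weaker suppression releases more FFA

    def test_hepatic_glucose_output_increases_with_sigma_L_reduction(self, params):
        lo_sens = self._flux(params, "hepatic_glucose_output", sigma_L=0.06)
        hi_sens = self._flux(params, "hepatic_glucose_output", sigma_L=1.0)
        assert lo_sens > hi_sens


from metaflex import healthy_parameters as _healthy_parameters  # noqa: E402

_PARAMS = _healthy_parameters()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.0, 3.0), min_size=12, max_size=12))
def test_rhs_finite_for_admissible_states(y):
    """The vector field is finite for every bounded non-negative state."""
    y = np.asarray(y)
    y[STATE_VARS.index("Y_L")] = min(y[STATE_VARS.index("Y_L")], _PARAMS.Y_max)
    assert np.all(np.isfinite(rhs(y, 0.5, _PARAMS)))


def test_fluxset_field_count_is_stable():
    """The named-flux surface covers every arrow plus the marker turnover."""
    assert len(FluxSet.__dataclass_fields__) == 27
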