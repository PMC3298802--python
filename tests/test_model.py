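"""Structural model: spec construction, rate matrix, steady state, units."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from ldopapop import defaults as D
from ldopapop.model import (
    ConfigurationError,
    DomainError,
    build_ode_system,
    full_model,
    metabolite_model,
    parent_model,
    plasma_model,
    steady_state,
)
from ldopapop.units import UnitError, convert_units


class TestSpec:
    def test_fully_symmetric_model_frees_single_brain_parameter_set(self):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        free = set(spec.free_parameter_names)
        assert {"V4", "Q4", "k40", "Kin"} <= free
        assert free.isdisjoint({"V5", "Q5", "k50"})
        # each constraint removes exactly one free parameter
        for k in range(4):
            spec_k = parent_model(constraints=("Q5", "V5", "k50")[:k])
            assert len(spec_k.parameter_names) - len(spec_k.free_parameter_names) == k

    def test_observation_mapping_unique_per_hemisphere(self):
        spec = full_model()
        assert spec.observation_compartment("ecf_LDOPA", "control") == "ecf_control"
        assert spec.observation_compartment("dial_DOPAC", "diseased") == "dopac_diseased"
        assert spec.error_model("plasma_LDOPA") == "proportional"
        assert spec.error_model("dial_HVA") == "additive"

    def test_missing_parameter_names_symbol(self):
        spec = plasma_model()
        params = {k: D.PARENT_THETA[k] for k in spec.parameter_names if k != "Q3"}
        with pytest.raises(ConfigurationError, match="Q3"):
            build_ode_system(spec, params)

    def test_negative_parameter_rejected(self):
        spec = plasma_model()
        params = {k: D.PARENT_THETA[k] for k in spec.parameter_names}
        params["Cl"] = -1.0
        with pytest.raises(DomainError, match="Cl"):
            build_ode_system(spec, params)
        params["Cl"] = 30.0
        params["V1"] = 0.0
        with pytest.raises(DomainError, match="V1"):
            build_ode_system(spec, params)


class TestRateMatrix:
    def test_closed_subsystem_columns_sum_to_zero(self, parent_theta):
        # no elimination, no endogenous input: pure mass exchange
        params = dict(parent_theta, Cl=0.0, k40=0.0, Kin=0.0)
        sys_ = build_ode_system(parent_model(constraints=("Q5", "V5", "k50")), params)
        np.testing.assert_allclose(sys_.A.sum(axis=0), 0.0, atol=1e-12)
        assert not np.any(sys_.b_endo)

    def test_symmetry_tie_copies_control_values(self, parent_theta):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        sys_ = build_ode_system(spec, parent_theta)
        p = dict(zip(spec.parameter_names, sys_.params))
        assert p["V5"] == p["V4"] and p["Q5"] == p["Q4"] and p["k50"] == p["k40"]


class TestSteadyState:
    def test_no_input_gives_zero_baseline(self, parent_theta):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        sys_ = build_ode_system(spec, dict(parent_theta, Kin=0.0))
        ss = steady_state(sys_)
        assert all(v["amount"] == 0.0 for v in ss.values())

    def test_baseline_matches_long_time_integration(self):
        # bottom-row symmetric model: k40 = 0.175 1/min, V4 = 13300 mL
        theta = dict(D.PARENT_THETA, Q4=22.4)
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        sys_ = build_ode_system(spec, theta)
        ss = steady_state(sys_)
        sol = solve_ivp(
            lambda t, x: sys_.A @ x + sys_.b_endo,
            (0.0, 1e5),
            np.zeros(spec.n_compartments),
            rtol=1e-10, atol=1e-12,
        )
        amounts = np.array([ss[c]["amount"] for c in spec.compartments])
        np.testing.assert_allclose(sol.y[:, -1], amounts, rtol=1e-6)
        # ECF baseline is within a few % of the single-compartment formula
        approx = theta["Kin"] / (theta["k40"] * theta["V4"])
        assert ss["ecf_control"]["concentration"] == pytest.approx(approx, rel=0.01)

    def test_plasma_baseline_far_below_quantification(self, parent_theta):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        ss = steady_state(build_ode_system(spec, parent_theta))
        assert 0 < ss["plasma"]["concentration"] < 0.01  # LLQ is 1 ng/mL

    def test_metabolite_baseline_linear_in_formation_constant(self):
        theta = {**D.PARENT_THETA, **D.METABOLITE_THETA[("DOPAC", "control")]}
        spec = metabolite_model("DOPAC", "control")
        base = steady_state(build_ode_system(spec, theta))["dopac_control"]["concentration"]
        doubled = steady_state(
            build_ode_system(spec, dict(theta, k46=2 * theta["k46"]))
        )["dopac_control"]["concentration"]
        assert doubled == pytest.approx(2 * base, rel=1e-10)

    def test_input_without_elimination_has_no_steady_state(self, parent_theta):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        sys_ = build_ode_system(spec, dict(parent_theta, Cl=0.0, k40=0.0))
        with pytest.raises(DomainError, match="steady state"):
            steady_state(sys_)


class TestConfigRoundTrip:
    def test_yaml_round_trip_rebuilds_spec_and_values(self, tmp_path):
        from ldopapop.config import load_model_config, save_model_config

        spec = parent_model(constraints=("Q5", "k50"))
        theta = {k: D.PARENT_THETA[k] for k in spec.free_parameter_names if k in D.PARENT_THETA}
        theta["V5"] = 12000.0
        path = tmp_path / "model.yaml"
        save_model_config(path, spec, theta=theta, omega2=dict(D.PARENT_OMEGA2),
                          sigma={"plasma_LDOPA": 0.087})
        spec2, theta2 = load_model_config(path)
        assert spec2 == spec
        assert theta2 == theta

    def test_config_marks_iiv_parameters_and_units(self):
        from ldopapop.config import spec_to_config

        spec = parent_model(constraints=("Q5", "V5", "k50"))
        cfg = spec_to_config(spec, theta=D.PARENT_THETA, omega2=D.PARENT_OMEGA2)
        assert cfg["parameters"]["Cl"]["iiv"] is True
        assert cfg["parameters"]["Q4"]["iiv"] is False
        assert cfg["parameters"]["Cl"]["unit"] == "mL/min"
        assert "1/min" in cfg["parameters"]["Kin"]["unit"]
        assert cfg["model"]["constraints"] == ["Q5", "V5", "k50"]


class TestUnits:
    def test_ldopa_mass_to_molar(self):
        assert convert_units(1.0, "L-DOPA", "ng/mL", "pmol/mL") == pytest.approx(1000.0 / 197.19)

    @pytest.mark.parametrize("analyte", ["L-DOPA", "DOPAC", "HVA", "dopamine"])
    def test_identity_and_round_trip(self, analyte):
        assert convert_units(2.5, analyte, "ng/mL", "ng/mL") == 2.5
        out = convert_units(
            convert_units(2.5, analyte, "ng/mL", "pmol/mL"), analyte, "pmol/mL", "ng/mL"
        )
        assert out == pytest.approx(2.5, rel=1e-12)

    def test_dose_conversion_needs_weight(self):
        assert convert_units(25.0, "L-DOPA", "mg/kg", "ng", body_weight_kg=0.288) == pytest.approx(7.2e6)
        with pytest.raises(UnitError):
            convert_units(25.0, "L-DOPA", "mg/kg", "ng")

    def test_unknown_inputs_rejected(self):
        with pytest.raises(UnitError):
            convert_units(1.0, "serotonin", "ng/mL", "pmol/mL")
        with pytest.raises(UnitError):
            convert_units(1.0, "L-DOPA", "ng/mL", "mol/L")

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_round_trip_property(self, value):
        back = convert_units(
            convert_units(value, "HVA", "pmol/mL", "ng/mL"), "HVA", "ng/mL", "pmol/mL"
        )
        assert back == pytest.approx(value, rel=1e-12)
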