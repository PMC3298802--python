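"""Synthetic-trial generator: determinism, IIV, error models, retrodialysis."""

import numpy as np
import pandas as pd
import pytest

from ldopapop import defaults as D
from ldopapop.model import parent_model, plasma_model
from ldopapop.simulate import (
    StudyDesign,
    draw_population,
    metabolite_study,
    parent_study,
    plasma_study,
    simulate_observations,
    simulate_retrodialysis,
    simulate_trial,
)


def _plasma_theta():
    spec = plasma_model()
    return {k: D.PARENT_THETA[k] for k in spec.parameter_names}


class TestDrawPopulation:
    def test_same_seed_reproduces_population(self):
        design = parent_study()
        a = draw_population(design, D.PARENT_THETA, D.PARENT_OMEGA2, seed=7)
        b = draw_population(design, D.PARENT_THETA, D.PARENT_OMEGA2, seed=7)
        for s, t in zip(a, b):
            assert s.params == t.params and s.body_weight == t.body_weight
            assert s.responder == t.responder and s.recovery == t.recovery
        c = draw_population(design, D.PARENT_THETA, D.PARENT_OMEGA2, seed=8)
        assert any(s.params != t.params for s, t in zip(a, c))

    def test_zero_variability_yields_typical_values(self):
        subs = draw_population(parent_study(), D.PARENT_THETA, {"Cl": 0.0}, seed=1)
        assert all(s.params["Cl"] == D.PARENT_THETA["Cl"] for s in subs)

    def test_log_clearance_variance_matches_omega2(self):
        """omega^2_Cl = 0.26: sample variance of log Cl over 10^4 subjects."""
        design = StudyDesign(groups={25.0: 10_000}, control_ecf={}, diseased_ecf={})
        subs = draw_population(design, D.PARENT_THETA, {"Cl": 0.26}, seed=3)
        logs = np.log([s.params["Cl"] for s in subs])
        assert np.var(logs, ddof=1) == pytest.approx(0.26, rel=0.05)
        assert np.mean(logs) == pytest.approx(np.log(30.0), abs=0.02)

    def test_missing_omega_for_flagged_parameter_raises(self):
        with pytest.raises(KeyError):
            draw_population(parent_study(), D.PARENT_THETA, {"nonexistent": 0.1}, seed=0)

    def test_responder_fraction_converges(self):
        design = StudyDesign(groups={25.0: 5_000})
        subs = draw_population(design, D.PARENT_THETA, {}, seed=5)
        frac = np.mean([s.responder for s in subs])
        assert frac == pytest.approx(12.0 / 17.0, abs=0.02)
        for s in subs[:200]:
            assert (s.th_percent < 40.0) == s.responder

    def test_printed_cohort_sizes(self):
        subs = draw_population(parent_study(), D.PARENT_THETA, {}, seed=2)
        assert len(subs) == 12
        assert sum("control" in s.hemispheres for s in subs) == 12
        assert sum("diseased" in s.hemispheres for s in subs) == 7
        assert all(s.responder for s in subs if "diseased" in s.hemispheres)


class TestSimulateObservations:
    def test_zero_noise_full_recovery_reproduces_interval_averages(self):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        design = parent_study()
        subs = draw_population(design, D.PARENT_THETA, {}, seed=4)
        s = subs[0]
        s = type(s)(**{**s.__dict__, "recovery": 1.0})
        sigma = {k: 0.0 for k in ("plasma_LDOPA", "ecf_LDOPA")}
        filled = simulate_observations(s, spec, design, sigma, rng=0)
        from ldopapop.model import build_ode_system
        from ldopapop.solver import solve_trajectory

        sys_ = build_ode_system(spec, s.params)
        wins = np.asarray(list(design.baseline_windows) + list(design.post_windows))
        traj = solve_trajectory(sys_, list(s.dose_events), np.asarray(design.plasma_times), windows=wins)
        obs = filled.observations
        ecf = obs[(obs.DVID == "ecf_LDOPA") & (obs.HEMI == "control")]
        np.testing.assert_allclose(
            ecf.DV.to_numpy(),
            traj.window_averages[:, spec.comp_index("ecf_control")],
            rtol=1e-12,
        )
        plasma = obs[obs.DVID == "plasma_LDOPA"]
        np.testing.assert_allclose(
            plasma.DV.to_numpy(), traj.compartment("plasma"), rtol=1e-12
        )

    def test_proportional_error_cv_matches_sigma(self):
        """sigma = 0.087 -> empirical CV of replicate observations ~ 8.7%."""
        spec = plasma_model()
        design = plasma_study()
        theta = _plasma_theta()
        subs = draw_population(design, theta, {}, seed=9)
        s = subs[0]
        vals = []
        rngs = np.random.SeedSequence(77).spawn(2000)
        for child in rngs:
            filled = simulate_observations(
                s, spec, design, {"plasma_LDOPA": 0.087}, rng=np.random.default_rng(child)
            )
            row = filled.observations
            vals.append(row[row.TIME == 20.0].DV.iloc[0])
        vals = np.asarray(vals)
        cv = vals.std(ddof=1) / vals.mean()
        assert cv == pytest.approx(0.087, rel=0.05)

    def test_interval_average_of_constant_equals_point_value(self):
        # undosed subject: the ECF stays at baseline, so window = point value
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        design = parent_study()
        subs = draw_population(design, D.PARENT_THETA, {}, seed=10)
        s = subs[0]
        s = type(s)(**{**s.__dict__, "dose_events": (), "recovery": 1.0})
        filled = simulate_observations(s, spec, design, {k: 0.0 for k in ("plasma_LDOPA", "ecf_LDOPA")}, rng=1)
        obs = filled.observations
        ecf = obs[(obs.DVID == "ecf_LDOPA") & (obs.HEMI == "control")]
        assert ecf.DV.nunique() == 1

    def test_plasma_predose_flagged_below_loq(self):
        spec = plasma_model()
        design = plasma_study()
        theta = _plasma_theta()
        subs = simulate_trial(design, spec, theta, {}, seed=12)
        for s in subs:
            obs = s.observations
            pre = obs[(obs.DVID == "plasma_LDOPA") & (obs.TIME < 0)]
            assert pre.BLQ.all()  # endogenous plasma L-DOPA is below 1 ng/mL

    def test_additive_error_clamped_at_zero(self):
        design = metabolite_study("control", analytes=("DOPAC",))
        from ldopapop.model import metabolite_model

        spec = metabolite_model("DOPAC", "control")
        theta = {**D.PARENT_THETA, **D.METABOLITE_THETA[("DOPAC", "control")]}
        subs = draw_population(design, theta, {}, seed=13)
        sigma = {"plasma_LDOPA": 0.0, "ecf_LDOPA": 0.0, ("dial_DOPAC", "control"): 5.0}
        filled = simulate_observations(subs[0], spec, design, sigma, rng=2)
        dv = filled.observations.query("DVID == 'dial_DOPAC'").DV
        assert (dv >= 0).all() and (dv == 0).any()


class TestRetrodialysis:
    def test_zero_noise_reports_true_loss(self):
        design = parent_study()
        s = draw_population(design, D.PARENT_THETA, {}, seed=6)[0]
        s = type(s)(**{**s.__dict__, "recovery": 0.30})
        fr = simulate_retrodialysis(s, perfusate_conc=100.0, n_fractions=6, rng=0, noise_sd=0.0)
        np.testing.assert_allclose(fr.LOSS, 0.30)
        np.testing.assert_allclose(fr.DV, 70.0)

    def test_zero_loss_returns_perfusate(self):
        s = draw_population(parent_study(), D.PARENT_THETA, {}, seed=6)[0]
        s = type(s)(**{**s.__dict__, "recovery": 1e-12})
        fr = simulate_retrodialysis(s, 100.0, 6, rng=0, noise_sd=0.0)
        np.testing.assert_allclose(fr.DV, 100.0, rtol=1e-9)

    def test_mean_loss_unbiased_over_many_fractions(self):
        s = draw_population(parent_study(), D.PARENT_THETA, {}, seed=6)[0]
        s = type(s)(**{**s.__dict__, "recovery": 0.30})
        losses = []
        for child in np.random.SeedSequence(99).spawn(2000):
            fr = simulate_retrodialysis(s, 100.0, 6, rng=np.random.default_rng(child), noise_sd=0.05)
            losses.append(fr.LOSS.mean())
        # SE of the grand mean ~ 0.05*0.7/sqrt(6*2000)
        assert np.mean(losses) == pytest.approx(0.30, abs=0.002)

    def test_input_validation(self):
        s = draw_population(parent_study(), D.PARENT_THETA, {}, seed=6)[0]
        with pytest.raises(ValueError):
            simulate_retrodialysis(s, -1.0, 6)
        with pytest.raises(ValueError):
            simulate_retrodialysis(s, 10.0, 0)


class TestTrialAssembly:
    def test_trial_is_deterministic_given_seed(self):
        spec = parent_model(constraints=("Q5", "V5", "k50"))
        a = simulate_trial(parent_study(), spec, D.PARENT_THETA, D.PARENT_OMEGA2, seed=21, retrodialysis=True)
        b = simulate_trial(parent_study(), spec, D.PARENT_THETA, D.PARENT_OMEGA2, seed=21, retrodialysis=True)
        for s, t in zip(a, b):
            pd.testing.assert_frame_equal(s.observations, t.observations)

    def test_design_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            StudyDesign(groups={10.0: 2}, plasma_times=(5.0, 5.0))
        with pytest.raises(ValueError, match="midpoint"):
            StudyDesign(groups={10.0: 2}, dialysate_mode="nearest")
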