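"""Estimation engine: objective oracles, LRT, fit behaviour, invariances."""

import numpy as np
import pandas as pd
import pytest

from ldopapop import defaults as D
from ldopapop.estimate import (
    ParameterSet,
    PopData,
    fit,
    laplace_objective,
    lrt_compare,
    lrt_threshold,
)
from ldopapop.model import build_ode_system, parent_model, plasma_model
from ldopapop.simulate import StudyDesign, plasma_study, simulate_trial
from ldopapop.solver import solve_trajectory


def _plasma_theta(peripherals=2):
    spec = plasma_model(peripherals)
    return {k: D.PARENT_THETA[k] for k in spec.parameter_names}


def _plasma_data(seed=1, omega2=None, peripherals=2, groups=None):
    spec = plasma_model(peripherals)
    theta = _plasma_theta(peripherals)
    design = plasma_study() if groups is None else StudyDesign(
        groups=groups, control_ecf={}, diseased_ecf={})
    subs = simulate_trial(design, spec, theta, omega2 or {"Cl": 0.26}, seed=seed)
    return PopData.from_subjects(subs, spec, dvids=["plasma_LDOPA"]), theta, subs


class TestLRT:
    def test_single_parameter_threshold_is_10_8(self):
        assert lrt_threshold(1) == pytest.approx(10.8, abs=0.05)

    def test_two_parameter_threshold_matches_chi_square(self):
        # chi2.ppf(0.999, 2) = 13.8155...
        assert lrt_threshold(2) == pytest.approx(13.816, abs=0.01)

    def test_identical_fits_not_significant(self):
        res = lrt_compare(100.0, 100.0, df=1)
        assert res.delta_mvof == 0.0 and not res.significant and res.warning is None

    def test_drop_meeting_threshold_is_significant(self):
        assert lrt_compare(100.0, 111.0, df=1).significant
        assert not lrt_compare(100.0, 110.0, df=1).significant

    def test_reduced_better_than_full_warns(self):
        res = lrt_compare(100.0, 95.0, df=1)
        assert res.warning is not None and not res.significant


class TestObjectiveOracles:
    def test_zero_iiv_equals_naive_pooled_loglik(self):
        data, theta, subs = _plasma_data(seed=5, omega2={})
        params = ParameterSet(theta=theta, omega2={}, sigma={"plasma_LDOPA": 0.087})
        mvof = laplace_objective(data, params)
        # independent pooled -2 log L from per-subject trajectories
        spec = plasma_model()
        total = 0.0
        for s in subs:
            sys_ = build_ode_system(spec, {k: theta[k] for k in spec.parameter_names})
            obs = s.observations
            obs = obs[(obs.DVID == "plasma_LDOPA") & (~obs.BLQ)]
            t = obs.TIME.to_numpy()
            traj = solve_trajectory(sys_, list(s.dose_events), np.sort(t))
            f = np.interp(t, traj.times, traj.compartment("plasma"))
            var = (0.087 * f) ** 2
            r = obs.DV.to_numpy() - f
            total += np.sum(np.log(2 * np.pi * var) + r * r / var)
        assert mvof == pytest.approx(total, abs=1e-6)

    def test_laplace_matches_gauss_hermite_quadrature(self):
        """Single subject, one-compartment model, IIV on Cl: adaptive
        quadrature over eta is the exact marginal likelihood oracle."""
        spec = plasma_model(peripherals=0)
        theta = {"Cl": 30.0, "V1": 98.0}
        design = StudyDesign(groups={25.0: 1}, control_ecf={}, diseased_ecf={})
        omega2, sigma = 0.26, 0.087
        subs = simulate_trial(design, spec, theta, {"Cl": omega2}, seed=8)
        data = PopData.from_subjects(subs, spec, dvids=["plasma_LDOPA"])
        params = ParameterSet(theta=theta, omega2={"Cl": omega2}, sigma={"plasma_LDOPA": sigma})
        mvof = laplace_objective(data, params)

        s = subs[0]
        obs = s.observations
        obs = obs[(obs.DVID == "plasma_LDOPA") & (~obs.BLQ)]
        t = np.sort(obs.TIME.to_numpy())
        y = obs.sort_values("TIME").DV.to_numpy()

        from scipy.integrate import quad
        from scipy.optimize import minimize_scalar

        def h(eta):
            """-2 log [p(y | eta) p(eta)] for scalar eta."""
            sys_ = build_ode_system(spec, dict(theta, Cl=theta["Cl"] * np.exp(eta)))
            f = solve_trajectory(sys_, list(s.dose_events), t).compartment("plasma")
            if not np.all(f > 1e-100):
                return np.inf
            var = (sigma * f) ** 2
            return (np.sum(np.log(2 * np.pi * var) + (y - f) ** 2 / var)
                    + np.log(2 * np.pi * omega2) + eta**2 / omega2)

        # adaptive quadrature of the (sharply peaked) marginal integrand
        mode = minimize_scalar(h, bounds=(-4, 4), method="bounded",
                               options=dict(xatol=1e-10)).x
        h0 = h(mode)
        integral, err = quad(lambda e: np.exp(-(h(e) - h0) / 2.0), -4, 4,
                             points=[mode], limit=200)
        assert err < 1e-5 * integral
        oracle = h0 - 2.0 * np.log(integral)
        assert mvof == pytest.approx(oracle, abs=0.1)

    def test_disconnected_compartment_leaves_objective_unchanged(self):
        """A brain branch with zero exchange is non-informative for plasma data."""
        data3, theta, subs = _plasma_data(seed=9)
        params = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        base = laplace_objective(data3, params)
        spec5 = parent_model(hemispheres=("control",))
        data5 = PopData.from_subjects(subs, spec5, dvids=["plasma_LDOPA"])
        theta5 = dict(theta, V4=13300.0, Q4=0.0, k40=0.175, Kin=5.8)
        params5 = ParameterSet(theta=theta5, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        assert laplace_objective(data5, params5) == pytest.approx(base, abs=1e-6)

    def test_objective_invariant_to_subject_order(self):
        data, theta, subs = _plasma_data(seed=10)
        params = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        a = laplace_objective(data, params)
        data_r = PopData.from_subjects(subs[::-1], plasma_model(), dvids=["plasma_LDOPA"])
        b = laplace_objective(data_r, params)
        assert a == pytest.approx(b, abs=1e-8)


class TestFit:
    def test_noise_free_data_recover_truth(self):
        """With (nearly) no residual noise the generating values are the optimum."""
        spec = plasma_model(peripherals=0)
        theta = {"Cl": 30.0, "V1": 98.0}
        design = StudyDesign(groups={10.0: 2, 25.0: 2, 50.0: 2}, control_ecf={}, diseased_ecf={})
        subs = simulate_trial(design, spec, theta, {}, sigma={"plasma_LDOPA": 1e-4}, seed=3)
        data = PopData.from_subjects(subs, spec, dvids=["plasma_LDOPA"])
        init = ParameterSet(theta={"Cl": 40.0, "V1": 80.0}, omega2={},
                            sigma={"plasma_LDOPA": 1e-3})
        res = fit(data, init, n_starts=1, maxiter=120, compute_se=False)
        assert res.estimates["Cl"] == pytest.approx(30.0, rel=1e-3)
        assert res.estimates["V1"] == pytest.approx(98.0, rel=1e-3)

    def test_fit_is_reproducible_bit_for_bit(self):
        data, theta, _ = _plasma_data(seed=12)
        init = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        r1 = fit(data, init, n_starts=1, maxiter=25, compute_se=False)
        r2 = fit(data, init, n_starts=1, maxiter=25, compute_se=False)
        assert r1.mvof == r2.mvof
        assert r1.estimates == r2.estimates

    def test_wald_intervals_and_cv_reported(self):
        data, theta, _ = _plasma_data(seed=13)
        init = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        res = fit(data, init, n_starts=1, maxiter=80, compute_se=True)
        assert res.hessian_pd
        for name in res.names:
            lo, hi = res.ci95[name]
            assert lo < res.estimates[name] < hi
            se = res.se[name]
            assert res.cv_percent[name] == pytest.approx(100 * se / res.estimates[name])
        table = res.report_table()
        assert set(table.columns) >= {"parameter", "estimate", "cv_percent", "lower", "upper"}

    def test_profile_likelihood_agrees_with_wald_bound(self):
        """MVOF rises by ~3.84 when a parameter is pinned at its 95% bound."""
        data, theta, _ = _plasma_data(seed=14, groups={10.0: 7, 25.0: 7, 50.0: 6})
        init = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        free = fit(data, init, n_starts=1, maxiter=150, compute_se=True)
        for bound in free.ci95["V1"]:
            init_fixed = ParameterSet(theta=dict(free.parameters.theta, V1=bound),
                                      omega2=free.parameters.omega2, sigma=free.parameters.sigma)
            fixed = fit(data, init_fixed,
                        free_theta=[n for n in free.spec.free_parameter_names if n != "V1"],
                        n_starts=1, maxiter=150, compute_se=False)
            delta = fixed.mvof - free.mvof
            assert delta == pytest.approx(3.84, rel=0.25)

    def test_residual_table_diagnostics_are_calibrated(self):
        from ldopapop.estimate import residual_table

        data, theta, _ = _plasma_data(seed=16)
        init = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        res = fit(data, init, n_starts=1, maxiter=80, compute_se=False)
        table = residual_table(res, data)
        assert len(table) == data.n_obs
        assert np.isfinite(table[["PRED", "IPRED", "WRES", "IWRES"]].to_numpy()).all()
        # individual weighted residuals are roughly standard normal
        assert 0.6 < table["IWRES"].std() < 1.4
        assert abs(table["IWRES"].mean()) < 0.3
        # individual predictions fit no worse than population predictions
        assert (table["RES"].abs().mean()
                <= (table["DV"] - table["PRED"]).abs().mean() + 1e-12)

    def test_empirical_bayes_estimates_track_true_etas(self):
        data, theta, subs = _plasma_data(seed=15)
        init = ParameterSet(theta=theta, omega2={"Cl": 0.26}, sigma={"plasma_LDOPA": 0.087})
        res = fit(data, init, n_starts=1, maxiter=80, compute_se=False)
        true_eta = np.array([s.eta["Cl"] for s in subs])
        ebe = res.eta["Cl"].to_numpy()
        assert np.corrcoef(true_eta, ebe)[0, 1] > 0.9
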