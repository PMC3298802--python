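"""Shared oracles and scenario builders for the test suite."""

import numpy as np
import pandas as pd
from scipy.linalg import expm

from ldopapop import defaults as D
from ldopapop.estimate import ParameterSet, PopData, fit, lrt_compare
from ldopapop.model import parent_model
from ldopapop.simulate import parent_study, simulate_trial
from ldopapop.solver import steady_state_vector

#: brain-side L-DOPA parameters estimated in the hemisphere-symmetry checks
BRAIN_PARAMS = ("V4", "Q4", "k40", "V5", "Q5", "k50", "Kin")


def full_theta():
    """Typical values covering the complete nine-compartment system."""
    theta = dict(D.PARENT_THETA)
    for block in D.METABOLITE_THETA.values():
        for k, v in block.items():
            theta.setdefault(k, v)
    theta.setdefault("V5", theta["V4"])
    theta.setdefault("Q5", theta["Q4"])
    theta.setdefault("k50", theta["k40"])
    return theta


def expm_oracle(system, doses, t_grid):
    """Independent per-interval augmented-matrix-exponential evaluation."""
    n = system.A.shape[0]
    x = steady_state_vector(system.A[None], system.b_endo[None])[0]
    x0 = x.copy()
    switch = sorted({d.start for d in doses} | {d.end for d in doses})
    t_now = min(switch) if switch else 0.0
    stops = sorted(set(switch) | {float(t) for t in t_grid if t > t_now})
    states = {}
    for t_next in stops:
        rate = sum(d.rate for d in doses if d.start <= t_now and t_next <= d.end)
        M = np.zeros((n + 1, n + 1))
        M[:n, :n] = system.A
        M[:n, n] = system.b_endo + rate * system.dose_vec
        z = expm(M * (t_next - t_now)) @ np.concatenate([x, [1.0]])
        x = z[:n]
        states[t_next] = x.copy()
        t_now = t_next
    out = np.empty((len(t_grid), n))
    for i, t in enumerate(t_grid):
        out[i] = states[float(t)] if t > (min(switch) if switch else np.inf) else x0
    return out


def hemisphere_symmetry_lrt(seed, k50_factor, maxiter=80):
    """Unconstrained vs k50=k40-constrained fit on one simulated trial.

    ECF data from both hemispheres, plasma disposition pinned at truth,
    no IIV: the comparison isolates the hemisphere-asymmetry question.
    Returns the likelihood-ratio decision record.
    """
    truth = dict(D.PARENT_THETA)
    truth["V5"], truth["Q5"] = truth["V4"], truth["Q4"]
    truth["k50"] = truth["k40"] * k50_factor
    subs = simulate_trial(parent_study(), parent_model(), truth, {}, seed=seed)
    init = ParameterSet(theta=dict(truth), omega2={}, sigma={"ecf_LDOPA": 0.17})
    fits = {}
    for name, constraints in (("full", ()), ("reduced", ("k50",))):
        spec = parent_model(constraints=constraints)
        free = [p for p in BRAIN_PARAMS if p not in spec.tied_parameters]
        data = PopData.from_subjects(subs, spec, dvids=["ecf_LDOPA"])
        fits[name] = fit(data, init, free_theta=free, n_starts=1,
                         maxiter=maxiter, compute_se=False)
    return lrt_compare(fits["full"], fits["reduced"], df=1)
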