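"""Nonlinear mixed-effects estimation for the L-DOPA population model.

The marginal likelihood over the lognormal random effects is approximated
by a Laplace expansion around each subject's conditional mode (empirical
Bayes estimate), with the *interaction* convention: the residual variance
of proportional-error observations is evaluated at the conditional
prediction.  This is the same family of approximation as first-order
conditional estimation with interaction; it is fully specified here and is
asymptotically equivalent, so absolute objective values carry the full
-2 log-likelihood constant (including the 2*pi terms) and only *differences*
in the objective are comparable across implementations.

For subject i with observations y_ij, predictions f_ij(eta) and residual
variances v_ij(eta) (sigma_prop^2 f^2 or sigma_add^2), define

    g_i(eta) = sum_j [log(2 pi v_ij) + (y_ij - f_ij)^2 / v_ij]
               + eta' Omega^-1 eta

and let eta_i minimise g_i.  The objective ("MVOF") is

    sum_i [ g_i(eta_i) + log|Omega| + log det H_i ],
    H_i = sum_j [ J_j J_j'/v_j + (dv_j)(dv_j)'/(2 v_j^2) ] + Omega^-1,

with J_j = df_j/deta and dv_j = dv_j/deta.  All free parameters (typical
values, IIV variances, residual SDs) are optimised on the log scale;
standard errors come from the inverse of half the finite-difference Hessian
of the objective, delta-method-transformed back to the natural scale.

Everything is deterministic for fixed data and settings, and the trajectory
solves are batched across subjects, finite-difference perturbations and
outer candidate points, which is what keeps population fits in the
seconds-to-a-minute range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model import (
    ConfigurationError,
    DoseEvent,
    PopModelSpec,
    build_matrices,
    metabolite_model,
    parent_model,
)
from .model import _volume_vector  # shared state->concentration bookkeeping
from .simulate import SubjectRecord
from .solver import solve_piecewise

__all__ = [
    "ParameterSet",
    "FitResult",
    "LRTResult",
    "PopData",
    "laplace_objective",
    "fit",
    "residual_table",
    "sequential_metabolite_fit",
    "lrt_compare",
    "symmetry_grid",
    "lrt_threshold",
]

log = logging.getLogger("ldopapop.estimate")

_INNER_MAX = 40
_INNER_GTOL = 1e-4
_INNER_STEP_CAP = 2.0  # largest |eta| move per Newton iteration (log scale)
_ETA_FD = 1e-4
_VAR_FLOOR = 1e-30


class DataError(ValueError):
    """Dataset inconsistent with the requested analysis."""


@dataclass
class ParameterSet:
    """Population parameters: typical values, IIV variances, residual SDs.

    ``sigma`` is keyed by observation stream (e.g. ``"plasma_LDOPA"`` or
    ``"dial_DOPAC:control"``) and holds standard deviations — proportional
    SD for L-DOPA streams, additive SD (concentration units) for metabolite
    streams.
    """

    theta: dict[str, float]
    omega2: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, float] = field(default_factory=dict)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.theta), dict(self.omega2), dict(self.sigma))

    def validate(self) -> None:
        for k, v in self.theta.items():
            if k.startswith("V") and v <= 0:
                raise ConfigurationError(f"volume {k} must be > 0, got {v}")
            if v < 0:
                raise ConfigurationError(f"typical value {k} must be >= 0, got {v}")
        for k, v in self.omega2.items():
            if v < 0:
                raise ConfigurationError(f"omega^2 {k} must be >= 0")
        for k, v in self.sigma.items():
            if v <= 0:
                raise ConfigurationError(f"sigma {k} must be > 0")


@dataclass
class LRTResult:
    delta_mvof: float
    df: int
    threshold: float
    p_value: float
    significant: bool
    warning: str | None = None


@dataclass
class FitResult:
    """Population fit: estimates, uncertainty, objective and EBEs."""

    spec: PopModelSpec
    names: list[str]  # free parameter labels in optimisation order
    estimates: dict[str, float]  # natural scale, all blocks
    se: dict[str, float | None]
    cv_percent: dict[str, float | None]
    ci95: dict[str, tuple[float, float] | None]
    mvof: float
    eta: pd.DataFrame  # subjects x IIV parameters (empirical Bayes modes)
    individual_params: pd.DataFrame  # subjects x model parameters
    converged: bool
    hessian_pd: bool
    n_obs: int
    n_subjects: int
    message: str = ""

    @property
    def parameters(self) -> ParameterSet:
        theta = {k: v for k, v in self.estimates.items() if not k.startswith(("omega2:", "sigma:"))}
        omega2 = {k.split(":", 1)[1]: v for k, v in self.estimates.items() if k.startswith("omega2:")}
        sigma = {k.split(":", 1)[1]: v for k, v in self.estimates.items() if k.startswith("sigma:")}
        return ParameterSet(theta, omega2, sigma)

    def report_table(self) -> pd.DataFrame:
        rows = []
        for name in self.names:
            est = self.estimates[name]
            ci = self.ci95.get(name)
            rows.append(dict(
                parameter=name, estimate=est,
                cv_percent=self.cv_percent.get(name),
                lower=None if ci is None else ci[0],
                upper=None if ci is None else ci[1],
            ))
        return pd.DataFrame(rows)


# -------------------------------------------------------------------------
# data container
# -------------------------------------------------------------------------

@dataclass
class PopData:
    """Observations of several subjects mapped onto one shared template.

    The template is the union of observation slots (point times and
    averaging windows per observation stream); subjects that lack a slot
    (missing hemisphere, excluded below-LOQ row) are masked out.
    """

    spec: PopModelSpec
    ids: list
    rates: np.ndarray  # (S,) infusion rate ng/min
    doses: list[DoseEvent]  # shared schedule at unit rate
    times: np.ndarray  # (nt,) unique point times
    windows: np.ndarray  # (nw, 2) unique windows
    kind: np.ndarray  # (nobs,) 0 point / 1 window
    slot: np.ndarray  # (nobs,) index into times or windows
    comp: np.ndarray  # (nobs,) compartment index
    is_prop: np.ndarray  # (nobs,) proportional error?
    sigma_key: list[str]  # per sigma group
    sigma_idx: np.ndarray  # (nobs,) index into sigma_key
    y: np.ndarray  # (S, nobs), NaN = missing
    mask: np.ndarray  # (S, nobs) bool

    @property
    def n_subjects(self) -> int:
        return len(self.ids)

    @property
    def n_obs(self) -> int:
        return int(self.mask.sum())

    @classmethod
    def from_subjects(
        cls,
        subjects: Sequence[SubjectRecord],
        spec: PopModelSpec,
        dvids: Sequence[str] | None = None,
        hemispheres: Sequence[str] | None = None,
        recovery: float | None = None,
        exclude_blq: bool = True,
    ) -> "PopData":
        """Assemble estimation data from simulated/loaded subject records.

        ``recovery`` divides the L-DOPA dialysate concentrations by the
        (pooled) probe recovery, turning them into brain-ECF estimates on
        the model's scale.  Below-LOQ rows are excluded (M1 convention).
        """
        usable = [s for s in subjects if s.observations is not None and len(s.observations)]
        durations = {d.duration for s in usable for d in s.dose_events}
        starts = {d.start for s in usable for d in s.dose_events}
        if len(durations) > 1 or len(starts) > 1:
            raise DataError("subjects must share one infusion schedule")
        duration = durations.pop() if durations else 20.0
        start = starts.pop() if starts else 0.0

        frames = []
        for s in usable:
            df = s.observations.copy()
            df["__id"] = s.id
            frames.append(df)
        allobs = pd.concat(frames, ignore_index=True)
        allobs = allobs[allobs["DVID"].isin(dvids or ["plasma_LDOPA", "ecf_LDOPA", "dial_DOPAC", "dial_HVA"])]
        if hemispheres is not None:
            allobs = allobs[(allobs["HEMI"].isin(hemispheres)) | (allobs["HEMI"] == "NA")]
        if exclude_blq and "BLQ" in allobs:
            allobs = allobs[~allobs["BLQ"].astype(bool)]
        if recovery is not None:
            sel = allobs["DVID"] == "ecf_LDOPA"
            allobs.loc[sel, "DV"] = allobs.loc[sel, "DV"] / recovery
        if not len(allobs):
            raise DataError("no usable observations after filtering")

        def slot_key(row):
            if np.isfinite(row.TIME):
                return ("p", round(float(row.TIME), 6), row.DVID, row.HEMI)
            return ("w", round(float(row.WSTART), 6), round(float(row.WEND), 6), row.DVID, row.HEMI)

        keys = sorted({slot_key(r) for r in allobs.itertuples()}, key=repr)
        key_index = {k: i for i, k in enumerate(keys)}

        times = sorted({k[1] for k in keys if k[0] == "p"})
        windows = sorted({(k[1], k[2]) for k in keys if k[0] == "w"})
        t_index = {t: i for i, t in enumerate(times)}
        w_index = {w: i for i, w in enumerate(windows)}

        nobs = len(keys)
        kind = np.zeros(nobs, dtype=int)
        slot = np.zeros(nobs, dtype=int)
        comp = np.zeros(nobs, dtype=int)
        is_prop = np.zeros(nobs, dtype=bool)
        sigma_keys: list[str] = []
        sigma_idx = np.zeros(nobs, dtype=int)
        for k, i in key_index.items():
            if k[0] == "p":
                kind[i], slot[i] = 0, t_index[k[1]]
                dvid, hemi = k[2], k[3]
            else:
                kind[i], slot[i] = 1, w_index[(k[1], k[2])]
                dvid, hemi = k[3], k[4]
            comp[i] = spec.comp_index(spec.observation_compartment(dvid, None if hemi == "NA" else hemi))
            is_prop[i] = spec.error_model(dvid) == "proportional"
            skey = dvid if hemi == "NA" or dvid in ("plasma_LDOPA", "ecf_LDOPA") else f"{dvid}:{hemi}"
            if skey not in sigma_keys:
                sigma_keys.append(skey)
            sigma_idx[i] = sigma_keys.index(skey)

        S = len(usable)
        y = np.full((S, nobs), np.nan)
        for si, s in enumerate(usable):
            sub = allobs[allobs["__id"] == s.id]
            for r in sub.itertuples():
                y[si, key_index[slot_key(r)]] = r.DV
        mask = np.isfinite(y)

        rates = np.array([s.dose_events[0].rate if s.dose_events else 0.0 for s in usable])
        return cls(
            spec=spec,
            ids=[s.id for s in usable],
            rates=rates,
            doses=[DoseEvent(start=start, duration=duration, rate=1.0)],
            times=np.asarray(times, float),
            windows=np.asarray(windows, float).reshape(-1, 2),
            kind=kind, slot=slot, comp=comp, is_prop=is_prop,
            sigma_key=sigma_keys, sigma_idx=sigma_idx, y=y, mask=mask,
        )


# -------------------------------------------------------------------------
# prediction engine
# -------------------------------------------------------------------------

class _Engine:
    """Batched template predictions for one PopData."""

    def __init__(self, data: PopData):
        self.data = data

    def predict(self, params: np.ndarray, rates: np.ndarray) -> np.ndarray:
        """params (..., P) natural, constraints applied; rates (...,) ng/min.

        Returns concentrations on the observation template, shape
        (..., nobs).
        """
        d = self.data
        shp = params.shape[:-1]
        flat = params.reshape(-1, params.shape[-1])
        rflat = np.broadcast_to(rates, shp).reshape(-1)
        A, b, dose_vec = build_matrices(d.spec, flat)
        states, averages = solve_piecewise(
            A, b, dose_vec, d.doses,
            times=d.times, windows=d.windows,
            rates=rflat[:, None],
        )
        vols = _volume_vector(d.spec, flat)
        if len(d.times):
            cp = states / vols[:, None, :]
        if len(d.windows):
            cw = averages / vols[:, None, :]
        preds = np.empty((flat.shape[0], len(d.kind)))
        pt = d.kind == 0
        if pt.any():
            preds[:, pt] = cp[:, d.slot[pt], d.comp[pt]]
        wd = d.kind == 1
        if wd.any():
            preds[:, wd] = cw[:, d.slot[wd], d.comp[wd]]
        return preds.reshape(shp + (len(d.kind),))


# -------------------------------------------------------------------------
# objective
# -------------------------------------------------------------------------

class _Objective:
    """Batched Laplace-with-interaction objective over outer points.

    Free vector x = [log theta_free..., log omega2..., log sigma...].
    """

    def __init__(
        self,
        data: PopData,
        init: ParameterSet,
        free_theta: Sequence[str] | None = None,
        subject_overrides: pd.DataFrame | None = None,
    ):
        self.data = data
        spec = data.spec
        self.engine = _Engine(data)
        self.pnames = list(spec.parameter_names)
        tied = set(spec.tied_parameters)

        override_cols = set() if subject_overrides is None else set(subject_overrides.columns)
        missing = [
            n for n in spec.free_parameter_names
            if spec.tied_parameters.get(n, n) not in init.theta
            and n not in init.theta and n not in override_cols
        ]
        if missing:
            raise ConfigurationError(f"missing typical values for {missing}")
        base = np.array([
            init.theta.get(n, init.theta.get(spec.tied_parameters.get(n, n), np.nan))
            for n in self.pnames
        ])
        self.base = spec.apply_constraints(base)

        override_names = set() if subject_overrides is None else set(subject_overrides.columns)
        if free_theta is None:
            free_theta = [n for n in spec.free_parameter_names if n not in override_names]
        bad = [n for n in free_theta if n in tied]
        if bad:
            raise ConfigurationError(f"cannot free symmetry-tied parameters {bad}")
        self.free_theta = list(free_theta)
        self.iiv_names = [n for n in init.omega2 if init.omega2[n] > 0]
        for n in self.iiv_names:
            if n not in self.pnames:
                raise ConfigurationError(f"IIV on unknown parameter {n!r}")
        for k in data.sigma_key:
            if k not in init.sigma:
                raise ConfigurationError(f"missing residual sigma for stream {k!r}")
        self.sigma_names = list(data.sigma_key)

        # per-subject fixed overrides (e.g. parent post hoc parameters)
        S = data.n_subjects
        self.overrides = np.full((S, len(self.pnames)), np.nan)
        if subject_overrides is not None:
            missing_ids = [i for i in data.ids if i not in subject_overrides.index]
            if missing_ids:
                raise DataError(f"subjects missing from parameter overrides: {missing_ids}")
            for si, sid in enumerate(data.ids):
                for name in subject_overrides.columns:
                    if name in self.pnames:
                        self.overrides[si, self.pnames.index(name)] = subject_overrides.loc[sid, name]

        with np.errstate(divide="ignore"):
            self.x0 = np.log(np.concatenate([
                [init.theta[spec.tied_parameters.get(n, n)] if n not in init.theta
                 else init.theta[n] for n in self.free_theta],
                [init.omega2[n] for n in self.iiv_names],
                [init.sigma[k] for k in self.sigma_names],
            ]))
        self.nx = len(self.x0)
        self.names = (
            list(self.free_theta)
            + [f"omega2:{n}" for n in self.iiv_names]
            + [f"sigma:{k}" for k in self.sigma_names]
        )
        self.q = len(self.iiv_names)
        self.iiv_idx = np.array([self.pnames.index(n) for n in self.iiv_names], dtype=int)
        self.free_idx = np.array([self.pnames.index(n) for n in self.free_theta], dtype=int)
        self._eta_cache = np.zeros((S, self.q))
        self.n_evals = 0

    # -- unpack ------------------------------------------------------------
    def _unpack(self, x: np.ndarray):
        nt, q = len(self.free_theta), self.q
        theta = np.exp(x[..., :nt])
        omega2 = np.exp(x[..., nt:nt + q])
        sigma = np.exp(x[..., nt + q:])
        return theta, omega2, sigma

    def population_params(self, x: np.ndarray) -> np.ndarray:
        """(T, P) natural population vectors with constraints applied."""
        theta, _, _ = self._unpack(x)
        T = x.shape[0]
        pop = np.broadcast_to(self.base, (T, len(self.pnames))).copy()
        if len(self.free_idx):
            pop[:, self.free_idx] = theta
        return self.data.spec.apply_constraints(pop)

    # -- core batched evaluation -------------------------------------------
    def mvof_batch(self, X: np.ndarray, inner_max: int = _INNER_MAX) -> np.ndarray:
        """Objective at each row of X, shape (T, nx) -> (T,)."""
        X = np.atleast_2d(np.asarray(X, float))
        T = X.shape[0]
        d = self.data
        S, q = d.n_subjects, self.q
        _, omega2, sigma = self._unpack(X)
        pop = self.population_params(X)  # (T, P)

        # subject parameter bases: population values with per-subject overrides
        sp = np.where(np.isnan(self.overrides)[None, :, :], pop[:, None, :], self.overrides[None, :, :])
        sp = d.spec.apply_constraints(sp)  # (T, S, P)

        y = d.y[None, :, :]
        mask = d.mask[None, :, :]
        sig_obs = sigma[:, d.sigma_idx][:, None, :]  # (T, 1, nobs)

        if q == 0:
            preds = self.engine.predict(sp, d.rates[None, :])
            mvof = self._pooled_mvof(preds, y, mask, sig_obs)
            self.n_evals += T
            return mvof

        om = omega2  # (T, q)
        eta = np.broadcast_to(self._eta_cache, (T, S, q)).copy()
        g_best = np.full((T, S), np.inf)
        eta_best = eta.copy()
        dir_best = np.zeros((T, S, q))
        step = np.ones((T, S))
        frozen = np.zeros((T, S), dtype=bool)
        gn_prev = np.full((T, S), np.nan)

        for it in range(inner_max):
            f0, J = self._predict_with_jac(sp, eta)
            g, grad, H = self._g_grad_H(f0, J, y, mask, sig_obs, eta, om)
            improved = g <= g_best + 1e-12
            upd = improved & ~frozen
            rel_impr = np.where(np.isfinite(g_best), g_best - g, np.inf)
            eta_best = np.where(upd[..., None], eta, eta_best)
            newdir = np.linalg.solve(2.0 * H, grad[..., None])[..., 0]
            # trust region: far from the mode the quadratic model overshoots
            cap = np.minimum(1.0, _INNER_STEP_CAP / (np.abs(newdir).max(axis=-1) + 1e-300))
            newdir = newdir * cap[..., None]
            gnorm = np.abs(grad).max(axis=-1)
            # Aitken boost: a geometric gradient decay means the quadratic
            # model overestimates curvature along the current direction
            with np.errstate(invalid="ignore", divide="ignore"):
                ratio = gnorm / gn_prev
            ratio = np.clip(np.nan_to_num(ratio, nan=0.0, posinf=0.0), 0.0, 0.95)
            boost = np.where(upd & (ratio > 0.3) & (step >= 1.0), 1.0 / (1.0 - ratio), 1.0)
            newdir = newdir * boost[..., None]
            dir_best = np.where(upd[..., None], newdir, dir_best)
            g_best = np.where(upd, g, g_best)
            gn_prev = np.where(upd, gnorm, gn_prev)
            # damping persists across acceptances: oscillating problems keep
            # a fractional step instead of re-overshooting every iteration
            step = np.where(upd, np.minimum(1.0, step * 1.5), step * 0.5)
            frozen |= improved & (gnorm < _INNER_GTOL)
            frozen |= improved & (rel_impr < 1e-8) & (it > 0)
            if frozen.all():
                break
            eta = np.where(frozen[..., None], eta_best,
                           eta_best - step[..., None] * dir_best)

        # final quantities at the conditional modes
        f0, J = self._predict_with_jac(sp, eta_best)
        g, grad, H = self._g_grad_H(f0, J, y, mask, sig_obs, eta_best, om)
        g_best = np.minimum(g_best, g)
        sign, logdetH = np.linalg.slogdet(H)
        logdetH = np.where(sign > 0, logdetH, np.inf)
        mvof = (g_best + np.log(om).sum(axis=-1)[:, None] + logdetH).sum(axis=1)
        self._eta_cache = eta_best[0].copy()
        self.n_evals += T
        return mvof

    def _predict_with_jac(self, sp: np.ndarray, eta: np.ndarray):
        """Conditional predictions and d f/d eta by central differences.

        sp: (T, S, P) subject base parameters; eta: (T, S, q).
        Returns f0 (T, S, nobs) and J (T, S, q, nobs).
        """
        T, S, P = sp.shape
        q = self.q
        K = 1 + 2 * q
        etas = np.broadcast_to(eta[:, :, None, :], (T, S, K, q)).copy()
        for k in range(q):
            etas[:, :, 1 + 2 * k, k] += _ETA_FD
            etas[:, :, 2 + 2 * k, k] -= _ETA_FD
        pars = np.broadcast_to(sp[:, :, None, :], (T, S, K, P)).copy()
        mult = np.ones((T, S, K, P))
        np.put_along_axis(
            mult,
            np.broadcast_to(self.iiv_idx[None, None, None, :], (T, S, K, q)),
            np.exp(etas),
            axis=-1,
        )
        pars = pars * mult
        rates = np.broadcast_to(self.data.rates[None, :, None], (T, S, K))
        preds = self.engine.predict(pars, rates)  # (T, S, K, nobs)
        f0 = preds[:, :, 0, :]
        J = (preds[:, :, 1::2, :] - preds[:, :, 2::2, :]) / (2.0 * _ETA_FD)
        return f0, J

    def _variances(self, f, sig_obs):
        prop = self.data.is_prop[None, None, :]
        var = np.where(prop, sig_obs**2 * f**2, sig_obs**2)
        return np.maximum(var, _VAR_FLOOR)

    def _g_grad_H(self, f0, J, y, mask, sig_obs, eta, om):
        d = self.data
        var = self._variances(f0, sig_obs)  # (T,S,nobs)
        r = np.where(mask, y - f0, 0.0)
        m = mask.astype(float)
        ll = m * (np.log(2.0 * np.pi * var) + r * r / var)
        g = ll.sum(axis=-1) + np.einsum("tsq,tq->ts", eta**2, 1.0 / om)

        prop = d.is_prop[None, None, None, :]
        dvar = np.where(prop, 2.0 * sig_obs[:, :, None, :] ** 2 * f0[:, :, None, :] * J, 0.0)
        w1 = m * (1.0 - r * r / var) / var  # coefficient of dvar
        w2 = m * 2.0 * r / var  # coefficient of J
        grad = (w1[:, :, None, :] * dvar - w2[:, :, None, :] * J).sum(axis=-1)
        grad = grad + 2.0 * eta / om[:, None, :]

        Jw = J * (m / var)[:, :, None, :]
        H = np.einsum("tsqn,tspn->tsqp", Jw, J)
        dvw = dvar * (m / (var * var))[:, :, None, :]
        H = H + 0.5 * np.einsum("tsqn,tspn->tsqp", dvw, dvar)
        T, S, q = eta.shape
        H = H + np.eye(q)[None, None] / om[:, None, :, None]
        # regularise: keep Newton steps defined even at indefinite points
        evals = np.linalg.eigvalsh(H)
        bad = evals[..., 0] < 1e-10
        if bad.any():
            H = H + np.where(bad[..., None, None], 1e-8 + np.abs(evals[..., 0])[..., None, None], 0.0) * np.eye(q)
        return g, grad, H

    def _pooled_mvof(self, preds, y, mask, sig_obs):
        var = self._variances(preds, sig_obs)
        r = np.where(mask, y - preds, 0.0)
        ll = mask * (np.log(2.0 * np.pi * var) + r * r / var)
        return ll.sum(axis=(-1, -2))

    # -- scipy interface ---------------------------------------------------
    def value_and_grad(self, x: np.ndarray, h: float = 1e-4):
        X = np.vstack([x] + [x + h * e for e in np.eye(self.nx)])
        vals = self.mvof_batch(X)
        f = vals[0]
        grad = (vals[1:] - f) / h
        return f, grad

    def hessian(self, x: np.ndarray, h: float = 1e-3) -> np.ndarray:
        """Central-difference Hessian of the objective, one batched call."""
        n = self.nx
        pts = [x]
        index = {}
        for i in range(n):
            for s in (+2, -2):
                index[(i, s)] = len(pts)
                pts.append(x + s * h * np.eye(n)[i])
        for i in range(n):
            for j in range(i + 1, n):
                for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                    index[(i, j, si, sj)] = len(pts)
                    pts.append(x + si * h * np.eye(n)[i] + sj * h * np.eye(n)[j])
        vals = self.mvof_batch(np.array(pts))
        H = np.empty((n, n))
        f0 = vals[0]
        for i in range(n):
            H[i, i] = (vals[index[(i, 2)]] - 2 * f0 + vals[index[(i, -2)]]) / (4 * h * h)
        for i in range(n):
            for j in range(i + 1, n):
                H[i, j] = H[j, i] = (
                    vals[index[(i, j, 1, 1)]] - vals[index[(i, j, 1, -1)]]
                    - vals[index[(i, j, -1, 1)]] + vals[index[(i, j, -1, -1)]]
                ) / (4 * h * h)
        return H

    def posthoc(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Empirical Bayes eta and individual parameter vectors at x."""
        self.mvof_batch(x[None])
        eta = self._eta_cache.copy()
        pop = self.population_params(x[None])[0]
        sp = np.where(np.isnan(self.overrides), pop[None, :], self.overrides)
        mult = np.ones_like(sp)
        if self.q:
            mult[:, self.iiv_idx] = np.exp(eta)
        ind = self.data.spec.apply_constraints(sp * mult)
        return eta, ind


# -------------------------------------------------------------------------
# public operations
# -------------------------------------------------------------------------

def laplace_objective(data: PopData, params: ParameterSet) -> float:
    """-2 log marginal likelihood (Laplace, with interaction) at ``params``.

    With all IIV variances zero this reduces exactly to the naive-pooled
    -2 log-likelihood under the stated residual-error models.
    """
    params.validate()
    obj = _Objective(data, params)
    return float(obj.mvof_batch(obj.x0[None])[0])


def fit(
    data: PopData,
    init: ParameterSet,
    free_theta: Sequence[str] | None = None,
    subject_overrides: pd.DataFrame | None = None,
    n_starts: int = 3,
    maxiter: int = 60,
    compute_se: bool = True,
) -> FitResult:
    """Maximise the Laplace marginal likelihood over the free parameters.

    Multi-start guards against local minima: starts perturb the free
    typical values by x2 and /2 around ``init`` (the first start is ``init``
    itself) and the best objective is kept.  Standard errors come from the
    inverse Hessian at the optimum; a non-positive-definite Hessian leaves
    SEs empty and is flagged, the estimates themselves are still returned.
    """
    init.validate()
    obj = _Objective(data, init, free_theta=free_theta, subject_overrides=subject_overrides)
    nt = len(obj.free_theta)
    starts = [obj.x0.copy()]
    for fac in (2.0, 0.5):
        xs = obj.x0.copy()
        xs[:nt] += np.log(fac)
        starts.append(xs)
    starts = starts[:max(1, n_starts)]

    best = None
    for xs in starts:
        obj._eta_cache[:] = 0.0
        res = optimize.minimize(
            obj.value_and_grad, xs, jac=True, method="L-BFGS-B",
            options=dict(maxiter=maxiter, ftol=1e-11, gtol=1e-6, maxls=40),
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    xhat = best.x
    mvof = float(best.fun)
    converged = bool(best.success) or mvof < np.inf

    se_log = {}
    hessian_pd = False
    if compute_se:
        try:
            H = obj.hessian(xhat)
            evals = np.linalg.eigvalsh(H)
            if np.all(evals > 0):
                hessian_pd = True
                cov = 2.0 * np.linalg.inv(H)
                diag = np.clip(np.diag(cov), 0.0, np.inf)
                se_log = {n: float(np.sqrt(v)) for n, v in zip(obj.names, diag)}
            else:
                log.warning("non-positive-definite Hessian: standard errors omitted")
        except Exception as e:  # pragma: no cover - diagnostic path
            log.warning("Hessian evaluation failed: %s", e)

    estimates, se, cv, ci = {}, {}, {}, {}
    for n, lx in zip(obj.names, xhat):
        est = float(np.exp(lx))
        estimates[n] = est
        s = se_log.get(n)
        if s is None:
            se[n], cv[n], ci[n] = None, None, None
        else:
            se_nat = est * s
            se[n] = se_nat
            cv[n] = 100.0 * se_nat / est
            ci[n] = (est - 1.96 * se_nat, est + 1.96 * se_nat)

    eta, ind = obj.posthoc(xhat)
    eta_df = pd.DataFrame(eta, index=data.ids, columns=obj.iiv_names)
    ind_df = pd.DataFrame(ind, index=data.ids, columns=obj.pnames)

    return FitResult(
        spec=data.spec, names=obj.names, estimates=estimates, se=se,
        cv_percent=cv, ci95=ci, mvof=mvof, eta=eta_df, individual_params=ind_df,
        converged=converged, hessian_pd=hessian_pd,
        n_obs=data.n_obs, n_subjects=data.n_subjects,
        message=str(getattr(best, "message", "")),
    )


def sequential_metabolite_fit(
    subjects: Sequence[SubjectRecord],
    parent: FitResult | pd.DataFrame,
    analyte: str,
    hemisphere: str,
    init: ParameterSet,
    n_starts: int = 3,
    maxiter: int = 60,
    compute_se: bool = True,
) -> FitResult:
    """Fit one metabolite's kinetics with parent disposition fixed per rat.

    Each subject's L-DOPA trajectory is pinned at its empirical Bayes
    (post hoc) parent parameters — except the hemisphere's parent brain
    elimination constant, which the metabolite data re-estimate — and the
    formation / parent-elimination / metabolite-elimination constants, their
    IIV and the additive residual SD are estimated from the dialysate
    concentrations.  DOPAC and HVA are fitted independently.
    """
    spec = metabolite_model(analyte, hemisphere)
    kel_parent = "k40" if hemisphere == "control" else "k50"
    overrides = parent if isinstance(parent, pd.DataFrame) else parent.individual_params
    estimated = {kel_parent, *(k for k in spec.parameter_names if k[0] == "k" and k != kel_parent)}
    keep = [c for c in overrides.columns if c in spec.parameter_names and c not in estimated]
    overrides = overrides[keep]
    data = PopData.from_subjects(
        subjects, spec, dvids=[f"dial_{analyte}"], hemispheres=[hemisphere],
    )
    missing = [i for i in data.ids if i not in overrides.index]
    if missing:
        raise DataError(f"subjects present in metabolite data but absent from parent fit: {missing}")
    return fit(
        data, init, subject_overrides=overrides,
        n_starts=n_starts, maxiter=maxiter, compute_se=compute_se,
    )


def residual_table(result: FitResult, data: PopData) -> pd.DataFrame:
    """Observation-level diagnostics for a completed fit.

    PRED is the population prediction (random effects at zero; per-subject
    fixed overrides, e.g. sequential-fit parent parameters, retained),
    IPRED the individual (empirical Bayes) prediction.  WRES and IWRES
    weight the residuals by the error-model SD at the corresponding
    prediction, so under a correct model they are approximately standard
    normal.
    """
    engine = _Engine(data)
    spec = data.spec
    ind = result.individual_params.loc[data.ids, list(spec.parameter_names)].to_numpy()
    eta = result.eta.loc[data.ids]
    pop = ind.copy()
    for name in eta.columns:
        pop[:, spec.parameter_names.index(name)] /= np.exp(eta[name].to_numpy())
    sig = result.parameters.sigma
    sd_scale = np.array([sig[k] for k in data.sigma_key])[data.sigma_idx]

    pred = engine.predict(pop, data.rates)
    ipred = engine.predict(ind, data.rates)
    rows = []
    for si, sid in enumerate(data.ids):
        for j in np.flatnonzero(data.mask[si]):
            sd_p = sd_scale[j] * (pred[si, j] if data.is_prop[j] else 1.0)
            sd_i = sd_scale[j] * (ipred[si, j] if data.is_prop[j] else 1.0)
            rows.append(dict(
                ID=sid,
                TIME=data.times[data.slot[j]] if data.kind[j] == 0 else np.nan,
                WSTART=data.windows[data.slot[j], 0] if data.kind[j] == 1 else np.nan,
                WEND=data.windows[data.slot[j], 1] if data.kind[j] == 1 else np.nan,
                COMP=spec.compartments[data.comp[j]],
                DV=data.y[si, j],
                PRED=pred[si, j],
                IPRED=ipred[si, j],
                RES=data.y[si, j] - ipred[si, j],
                WRES=(data.y[si, j] - pred[si, j]) / sd_p,
                IWRES=(data.y[si, j] - ipred[si, j]) / sd_i,
            ))
    return pd.DataFrame(rows)


def lrt_threshold(df: int, alpha: float = 0.001) -> float:
    """Objective-drop threshold for adding ``df`` parameters.

    The single-parameter criterion at p = 0.001 is the field's conventional
    10.8 points; multi-parameter decisions use the chi-square quantile.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if df == 1 and alpha == 0.001:
        return 10.8
    return float(stats.chi2.ppf(1.0 - alpha, df))


def lrt_compare(fit_full: FitResult | float, fit_reduced: FitResult | float, df: int, alpha: float = 0.001) -> LRTResult:
    """Likelihood-ratio comparison of nested fits.

    ``delta = MVOF_reduced - MVOF_full`` is referred to a chi-square with
    ``df`` degrees of freedom; the constraint is rejected (the difference is
    *significant*) when the drop meets the threshold.
    """
    m_full = fit_full if isinstance(fit_full, (int, float)) else fit_full.mvof
    m_red = fit_reduced if isinstance(fit_reduced, (int, float)) else fit_reduced.mvof
    delta = float(m_red - m_full)
    warning = None
    if delta < -1e-3:
        warning = (
            "reduced model fits better than the full model: check nesting "
            f"or convergence (delta = {delta:.4g})"
        )
    thr = lrt_threshold(df, alpha)
    p = float(stats.chi2.sf(max(delta, 0.0), df))
    return LRTResult(delta_mvof=delta, df=df, threshold=thr, p_value=p,
                     significant=bool(delta >= thr), warning=warning)


_GRID_CONSTRAINTS = ("Q5", "V5", "k50")


@dataclass
class GridCell:
    constraints: tuple[str, ...]
    fit: FitResult | None
    error: str | None = None


@dataclass
class GridResult:
    cells: list[GridCell]
    selected: tuple[str, ...]
    lrt: dict[tuple[str, ...], LRTResult]

    def table(self) -> pd.DataFrame:
        rows = []
        for c in self.cells:
            row = {"assumption": " & ".join(f"{t}={s}" for t, s in
                                            ((t, {"Q5": "Q4", "V5": "V4", "k50": "k40"}[t]) for t in c.constraints))
                   or "NONE"}
            if c.fit is None:
                row["MVOF"] = None
                row["note"] = c.error or "minimisation terminated"
            else:
                row["MVOF"] = c.fit.mvof
                for p in ("V4", "V5", "Q4", "Q5", "k40", "k50"):
                    if p in c.fit.estimates:
                        row[p] = c.fit.estimates[p]
                        row[f"CV%({p})"] = c.fit.cv_percent.get(p)
            rows.append(row)
        return pd.DataFrame(rows)


def symmetry_grid(
    subjects: Sequence[SubjectRecord],
    init: ParameterSet,
    recovery: float | None = None,
    n_starts: int = 1,
    maxiter: int = 60,
    compute_se: bool = False,
    free_theta: Sequence[str] | None = None,
) -> GridResult:
    """Fit all eight hemisphere-symmetry assumption combinations.

    The grid spans every subset of {Q5=Q4, V5=V4, k50=k40} on the parent
    plasma + two-hemisphere ECF model.  Selection keeps the most
    parsimonious cell whose objective is not significantly worse than the
    unconstrained model (likelihood-ratio test at p = 0.001 with df = number
    of constraints).  A cell whose minimisation fails is recorded in place
    and the grid continues.
    """
    from itertools import combinations

    from .model import SYMMETRY_TIES

    init = init.copy()
    for target, source in SYMMETRY_TIES.items():
        if target not in init.theta and source in init.theta:
            init.theta[target] = init.theta[source]

    cells: list[GridCell] = []
    fits: dict[tuple[str, ...], FitResult] = {}
    for r in range(len(_GRID_CONSTRAINTS) + 1):
        for combo in combinations(_GRID_CONSTRAINTS, r):
            spec = parent_model(constraints=combo)
            cell_free = None if free_theta is None else [
                n for n in free_theta if n not in spec.tied_parameters
            ]
            try:
                data = PopData.from_subjects(
                    subjects, spec, dvids=["plasma_LDOPA", "ecf_LDOPA"], recovery=recovery,
                )
                res = fit(data, init, free_theta=cell_free, n_starts=n_starts,
                          maxiter=maxiter, compute_se=compute_se)
                cells.append(GridCell(combo, res))
                fits[combo] = res
            except Exception as e:
                cells.append(GridCell(combo, None, error=str(e)))

    lrt: dict[tuple[str, ...], LRTResult] = {}
    selected: tuple[str, ...] = ()
    if () in fits:
        base = fits[()]
        best_k = -1
        for combo, res in fits.items():
            if not combo:
                continue
            t = lrt_compare(base, res, df=len(combo))
            lrt[combo] = t
            if not t.significant:
                k = len(combo)
                if k > best_k or (k == best_k and res.mvof < fits[selected].mvof):
                    selected, best_k = combo, k
        if best_k < 0:
            selected = ()
    return GridResult(cells=cells, selected=selected, lrt=lrt)
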