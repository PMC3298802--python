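"""Synthetic-trial generator emulating the rotenone-model microdialysis study.

The generator reproduces the study design — three IV dose groups (10/25/50
mg/kg over 20 min), the printed plasma sampling schedule, interval-collected
striatal dialysate in both hemispheres, a retrodialysis recovery phase, and
TH-staining responder status — with lognormal inter-individual variability
on the flagged parameters, proportional residual error on L-DOPA and
additive residual error on the metabolites.

All randomness descends from a single root seed through per-subject child
streams (``numpy.random.SeedSequence.spawn``), so a population is fully
reproducible and individual subjects are independent of population size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import defaults as D
from .model import DoseEvent, PopModelSpec, build_ode_system
from .solver import solve_trajectory

__all__ = [
    "StudyDesign",
    "SubjectRecord",
    "draw_population",
    "simulate_observations",
    "simulate_retrodialysis",
    "simulate_trial",
    "plasma_study",
    "parent_study",
    "metabolite_study",
    "full_study",
]

log = logging.getLogger("ldopapop.simulate")

_DVID_UNITS = {
    "plasma_LDOPA": "ng/mL",
    "ecf_LDOPA": "ng/mL",
    "dial_DOPAC": "pmol/mL",
    "dial_HVA": "pmol/mL",
    "retro_LDOPA": "ng/mL",
}


@dataclass(frozen=True)
class StudyDesign:
    """Trial layout: who is dosed, what is sampled, and when.

    ``groups`` maps dose (mg/kg) to the number of subjects.  ``control_ecf``
    and ``diseased_ecf`` give per-group counts of subjects contributing ECF
    data from each hemisphere (``None`` means: all subjects for the control
    side, rotenone responders for the diseased side).  Subjects designated
    for diseased-hemisphere sampling are responders by construction.
    """

    groups: Mapping[float, int]
    plasma: bool = True
    control_ecf: Mapping[float, int] | None = None
    diseased_ecf: Mapping[float, int] | None = None
    metabolites: tuple[str, ...] = ()
    ecf_ldopa: bool = True
    plasma_times: tuple[float, ...] = D.PLASMA_TIMES
    post_windows: tuple[tuple[float, float], ...] = tuple(D.dialysate_windows())
    baseline_windows: tuple[tuple[float, float], ...] = tuple(D.baseline_windows())
    infusion_duration: float = D.INFUSION_DURATION_MIN
    body_weight_mean: float = D.BODY_WEIGHT_KG
    body_weight_sd: float = D.BODY_WEIGHT_SD_KG
    responder_probability: float = D.RESPONDER_PROBABILITY
    recovery_mean: float = D.RECOVERY_MEAN
    recovery_sd: float = D.RECOVERY_SD
    retro_perfusate: Mapping[float, float] = field(default_factory=lambda: dict(D.RETRO_PERFUSATE))
    retro_n_fractions: int = D.RETRO_N_FRACTIONS
    retro_noise_sd: float = 0.05
    lloq: Mapping[str, float] = field(default_factory=lambda: dict(D.LLOQ))
    dialysate_mode: str = "average"  # "average" (continuous collection) or "midpoint"

    def __post_init__(self):
        times = np.asarray(self.plasma_times)
        if times.size and np.any(np.diff(times) <= 0):
            raise ValueError("plasma sampling times must be strictly increasing")
        for wins in (self.baseline_windows, self.post_windows):
            arr = np.asarray(wins, float).reshape(-1, 2)
            if arr.size and (np.any(arr[:, 1] <= arr[:, 0]) or np.any(np.diff(arr.ravel())[1::2] < -1e-9)):
                raise ValueError("dialysate windows must be non-overlapping and ordered")
        if self.dialysate_mode not in ("average", "midpoint"):
            raise ValueError("dialysate_mode must be 'average' or 'midpoint'")

    @property
    def n_subjects(self) -> int:
        return int(sum(self.groups.values()))


@dataclass
class SubjectRecord:
    """One virtual rat: design slot, individual parameters and observations."""

    id: int
    dose_group: float  # mg/kg
    body_weight: float  # kg
    params: dict[str, float]  # individual values, typical * exp(eta)
    eta: dict[str, float]
    responder: bool
    th_percent: float
    recovery: float  # true relative loss of the probe
    hemispheres: tuple[str, ...]  # ECF sampling sides
    has_plasma: bool
    dose_events: tuple[DoseEvent, ...]
    observations: pd.DataFrame | None = None
    seed: int | None = None

    @property
    def dose_ng(self) -> float:
        return self.dose_group * self.body_weight * 1.0e6


def _counts_to_flags(groups: Mapping[float, int], counts: Mapping[float, int] | None):
    """Per-subject inclusion flags (first n of each group), or None for 'rule'."""
    if counts is None:
        return None
    flags = []
    for dose, n in groups.items():
        k = int(counts.get(dose, 0))
        if k > n:
            raise ValueError(f"cohort count {k} exceeds group size {n} for dose {dose}")
        flags += [True] * k + [False] * (n - k)
    return flags


def draw_population(
    design: StudyDesign,
    theta: Mapping[str, float],
    omega2: Mapping[str, float],
    seed: int | np.random.SeedSequence,
) -> list[SubjectRecord]:
    """Draw virtual subjects: weights, random effects, responder status.

    ``theta`` are typical values on the natural scale; ``omega2`` the
    lognormal IIV variances for exactly the parameters that carry a random
    effect.  Observations are not filled in (see
    :func:`simulate_observations` / :func:`simulate_trial`).
    """
    for name in omega2:
        if name not in theta:
            raise KeyError(f"omega^2 given for unknown parameter {name!r}")
        if omega2[name] < 0:
            raise ValueError(f"omega^2 for {name!r} must be >= 0")
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    n = design.n_subjects
    children = root.spawn(n)
    control_flags = _counts_to_flags(design.groups, design.control_ecf)
    diseased_flags = _counts_to_flags(design.groups, design.diseased_ecf)

    subjects = []
    i = 0
    for dose, size in design.groups.items():
        for _ in range(size):
            rng = np.random.default_rng(children[i])
            weight = max(rng.normal(design.body_weight_mean, design.body_weight_sd), 0.05)
            eta = {k: rng.normal(0.0, np.sqrt(v)) if v > 0 else 0.0 for k, v in omega2.items()}
            params = dict(theta)
            for k, e in eta.items():
                params[k] = theta[k] * np.exp(e)
            if diseased_flags is not None:
                responder = bool(diseased_flags[i])
            else:
                responder = bool(rng.random() < design.responder_probability)
            # responders lose >60% of striatal TH signal; non-responders are intact
            th = rng.uniform(5.0, 39.0) if responder else rng.uniform(91.0, 100.0)
            # probe recovery shared across both probes, truncated to (0, 1]
            rec = rng.normal(design.recovery_mean, design.recovery_sd)
            while not (0.0 < rec <= 1.0):
                rec = rng.normal(design.recovery_mean, design.recovery_sd)
            hemis = []
            if control_flags is None or control_flags[i]:
                hemis.append("control")
            if (diseased_flags is not None and diseased_flags[i]) or (
                diseased_flags is None and responder
            ):
                hemis.append("diseased")
            dose_ev = DoseEvent.iv_infusion(dose, weight, design.infusion_duration)
            subjects.append(
                SubjectRecord(
                    id=i + 1,
                    dose_group=dose,
                    body_weight=weight,
                    params=params,
                    eta=eta,
                    responder=responder,
                    th_percent=th,
                    recovery=rec,
                    hemispheres=tuple(hemis),
                    has_plasma=design.plasma,
                    dose_events=(dose_ev,),
                    seed=int(children[i].generate_state(1, np.uint32)[0]),
                )
            )
            i += 1
    return subjects


def _window_predictions(traj, windows, comp, mode):
    if mode == "average":
        return traj.window_averages[:, traj.compartments.index(comp)]
    mids = traj.window_bounds.mean(axis=1)
    idx = np.searchsorted(traj.times, mids)
    return traj.concentrations[idx, traj.compartments.index(comp)]


def simulate_observations(
    subject: SubjectRecord,
    spec: PopModelSpec,
    design: StudyDesign,
    sigma: Mapping = D.SIGMA,
    rng: np.random.Generator | int | None = None,
) -> SubjectRecord:
    """Fill in one subject's observation rows from its true parameters.

    Plasma and ECF L-DOPA observations are ``prediction * (1 + eps)`` with
    proportional SD per observation type; metabolite dialysate observations
    are ``prediction + eps`` with additive SD (negative results are clamped
    to zero and flagged, keeping the error distribution honest).  Dialysate
    predictions are interval averages of the compartment concentration; the
    L-DOPA dialysate is attenuated by the subject's probe recovery, exactly
    as the probe does in vivo.  Values below the quantification limit are
    flagged, not dropped.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(subject.seed or subject.id).spawn(1)[0])
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    system = build_ode_system(spec, subject.params)
    windows = np.asarray(list(design.baseline_windows) + list(design.post_windows), float)
    times = np.asarray(design.plasma_times if (subject.has_plasma and design.plasma) else [], float)
    traj = solve_trajectory(system, list(subject.dose_events), np.sort(times) if times.size else np.array([0.0]), windows=windows)

    rows = []
    n_clamped = 0
    if times.size:
        pred = traj.compartment("plasma")
        sd = float(sigma["plasma_LDOPA"])
        obs = pred * (1.0 + rng.normal(0.0, sd, size=pred.shape)) if sd > 0 else pred.copy()
        lloq = design.lloq.get("plasma_LDOPA", 0.0)
        for t, y in zip(traj.times, obs):
            rows.append(dict(TIME=t, WSTART=np.nan, WEND=np.nan, DVID="plasma_LDOPA",
                             HEMI="NA", DV=y, UNIT="ng/mL", BLQ=bool(y < lloq), LLOQ=lloq,
                             PHASE="predose" if t < 0 else "postdose"))
    for hemi in subject.hemispheres:
        if design.ecf_ldopa and f"ecf_{hemi}" in spec.compartments:
            pred = _window_predictions(traj, windows, f"ecf_{hemi}", design.dialysate_mode)
            pred = pred * subject.recovery  # dialysate sees recovery-attenuated ECF
            sd = float(sigma["ecf_LDOPA"])
            obs = pred * (1.0 + rng.normal(0.0, sd, size=pred.shape)) if sd > 0 else pred.copy()
            lloq = design.lloq.get("ecf_LDOPA", 0.0)
            for (ws, we), y in zip(windows, obs):
                rows.append(dict(TIME=np.nan, WSTART=ws, WEND=we, DVID="ecf_LDOPA",
                                 HEMI=hemi, DV=y, UNIT="ng/mL", BLQ=bool(y < lloq), LLOQ=lloq,
                                 PHASE="baseline" if we <= 0 else "postdose"))
        for analyte in design.metabolites:
            comp = f"{analyte.lower()}_{hemi}"
            if comp not in spec.compartments:
                continue
            pred = _window_predictions(traj, windows, comp, design.dialysate_mode)
            sd = float(sigma[(f"dial_{analyte}", hemi)])
            obs = pred + rng.normal(0.0, sd, size=pred.shape) if sd > 0 else pred.copy()
            clamped = obs < 0
            n_clamped += int(clamped.sum())
            obs = np.where(clamped, 0.0, obs)
            lloq = design.lloq.get(f"dial_{analyte}", 0.0)
            for (ws, we), y in zip(windows, obs):
                rows.append(dict(TIME=np.nan, WSTART=ws, WEND=we, DVID=f"dial_{analyte}",
                                 HEMI=hemi, DV=y, UNIT="pmol/mL", BLQ=bool(y < lloq), LLOQ=lloq,
                                 PHASE="baseline" if we <= 0 else "postdose"))
    if n_clamped:
        log.info("subject %d: clamped %d negative additive-error draws to zero", subject.id, n_clamped)
    out = replace_observations(subject, pd.DataFrame(rows))
    return out


def replace_observations(subject: SubjectRecord, obs: pd.DataFrame) -> SubjectRecord:
    return SubjectRecord(**{**subject.__dict__, "observations": obs})


def simulate_retrodialysis(
    subject: SubjectRecord,
    perfusate_conc: float,
    n_fractions: int = D.RETRO_N_FRACTIONS,
    rng: np.random.Generator | int | None = None,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Simulate the retrodialysis calibration phase for one probe.

    Each fraction's dialysate-out concentration is
    ``perfusate * (1 - true_loss) * (1 + noise)``; the per-fraction relative
    loss follows as ``(in - out)/in``.  Returns one row per fraction with
    both the outflow concentration and the derived loss.
    """
    if perfusate_conc <= 0:
        raise ValueError("perfusate concentration must be > 0")
    if n_fractions < 1:
        raise ValueError("need at least one retrodialysis fraction")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence((subject.seed or subject.id) + 7).spawn(1)[0])
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    noise = rng.normal(0.0, noise_sd, size=n_fractions) if noise_sd > 0 else np.zeros(n_fractions)
    out = perfusate_conc * (1.0 - subject.recovery) * (1.0 + noise)
    loss = (perfusate_conc - out) / perfusate_conc
    # retrodialysis runs in the hour preceding the 90-min washout
    starts = -150.0 + D.RETRO_FRACTION_MIN * np.arange(n_fractions)
    return pd.DataFrame(dict(
        TIME=np.nan, WSTART=starts, WEND=starts + D.RETRO_FRACTION_MIN,
        DVID="retro_LDOPA", HEMI="NA", DV=out, UNIT="ng/mL", BLQ=False,
        LLOQ=0.0, PHASE="retrodialysis", PERFUSATE=perfusate_conc, LOSS=loss,
    ))


def simulate_trial(
    design: StudyDesign,
    spec: PopModelSpec,
    theta: Mapping[str, float],
    omega2: Mapping[str, float],
    sigma: Mapping = D.SIGMA,
    seed: int | np.random.SeedSequence = 0,
    retrodialysis: bool = False,
) -> list[SubjectRecord]:
    """Draw a population and fill in all observation rows (one call)."""
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    pop_seq, obs_seq = root.spawn(2)
    subjects = draw_population(design, theta, omega2, pop_seq)
    streams = obs_seq.spawn(len(subjects))
    out = []
    for subj, ss in zip(subjects, streams):
        obs_rng, retro_rng = (np.random.default_rng(s) for s in ss.spawn(2))
        filled = simulate_observations(subj, spec, design, sigma, rng=obs_rng)
        if retrodialysis and subj.hemispheres:
            frames = [filled.observations]
            frames.append(
                simulate_retrodialysis(
                    filled, design.retro_perfusate[subj.dose_group],
                    design.retro_n_fractions, rng=retro_rng,
                    noise_sd=design.retro_noise_sd,
                )
            )
            filled = replace_observations(filled, pd.concat(frames, ignore_index=True))
        out.append(filled)
    return out


# -- study factories matching the analysis cohorts -------------------------

def plasma_study(**kw) -> StudyDesign:
    """Plasma-only cohort: 13 rats, 4/4/5 across 10/25/50 mg/kg."""
    return StudyDesign(groups=dict(D.PLASMA_GROUPS), control_ecf={}, diseased_ecf={}, **kw)


def parent_study(**kw) -> StudyDesign:
    """Plasma + two-hemisphere ECF cohort: 12 control, 7 diseased rats."""
    return StudyDesign(
        groups=dict(D.CONTROL_ECF_GROUPS),
        control_ecf=dict(D.CONTROL_ECF_GROUPS),
        diseased_ecf=dict(D.DISEASED_ECF_GROUPS),
        **kw,
    )


def metabolite_study(hemisphere: str = "control", analytes: Sequence[str] = ("DOPAC", "HVA"), **kw) -> StudyDesign:
    """Dialysate metabolite cohort for one hemisphere (12 control / 8 diseased)."""
    if hemisphere == "control":
        groups = dict(D.CONTROL_ECF_GROUPS)
        return StudyDesign(groups=groups, plasma=False, control_ecf=groups,
                           diseased_ecf={}, metabolites=tuple(analytes),
                           ecf_ldopa=False, **kw)
    groups = dict(D.DISEASED_MET_GROUPS)
    return StudyDesign(groups=groups, plasma=False, control_ecf={},
                       diseased_ecf=groups, metabolites=tuple(analytes),
                       ecf_ldopa=False, **kw)


def full_study(**kw) -> StudyDesign:
    """The complete 17-rat design (6/6/5), all observation streams."""
    return StudyDesign(
        groups={10.0: 6, 25.0: 6, 50.0: 5},
        metabolites=("DOPAC", "HVA"),
        **kw,
    )
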