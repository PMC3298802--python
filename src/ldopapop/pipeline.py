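"""End-to-end analysis driver: simulate/load -> calibrate -> fit -> report.

The pipeline reproduces the study's analysis sequence: probe-recovery
calibration from the retrodialysis phase, TH-based responder
classification (non-responders keep their control hemisphere but
contribute no diseased-hemisphere data), the simultaneous plasma +
brain-ECF parent fit, the hemisphere-symmetry assumption grid, the
sequential DOPAC and HVA fits per hemisphere, and dialysate baseline
summaries with Welch comparisons.  Every stage's output is written to the
report bundle; a failure aborts with the stage name, keeping partial
artifacts.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import defaults as D
from .estimate import (
    FitResult,
    ParameterSet,
    PopData,
    fit,
    residual_table,
    sequential_metabolite_fit,
    symmetry_grid,
)
from .microdialysis import baseline_summary, estimate_recovery, pooled_recovery
from .model import parent_model
from .simulate import (
    StudyDesign,
    SubjectRecord,
    full_study,
    metabolite_study,
    parent_study,
    plasma_study,
    simulate_trial,
)
from .thstain import classify_responder

__all__ = ["run_pipeline", "default_parent_init", "default_metabolite_init", "load_config"]

log = logging.getLogger("ldopapop.pipeline")

_STUDIES = {
    "plasma": plasma_study,
    "parent": parent_study,
    "metabolite": metabolite_study,
    "full": full_study,
}


def default_parent_init(constraints: Sequence[str] = ("Q5", "V5", "k50")) -> ParameterSet:
    theta = dict(D.PARENT_THETA)
    return ParameterSet(
        theta=theta,
        omega2=dict(D.PARENT_OMEGA2),
        sigma={"plasma_LDOPA": D.SIGMA_STREAMS["plasma_LDOPA"],
               "ecf_LDOPA": D.SIGMA_STREAMS["ecf_LDOPA"]},
    )


def default_metabolite_init(analyte: str, hemisphere: str) -> ParameterSet:
    return ParameterSet(
        theta=dict(D.METABOLITE_THETA[(analyte, hemisphere)]),
        omega2=dict(D.METABOLITE_OMEGA2[(analyte, hemisphere)]),
        sigma={f"dial_{analyte}:{hemisphere}": D.SIGMA_STREAMS[f"dial_{analyte}:{hemisphere}"]},
    )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _fit_report(res: FitResult) -> dict[str, Any]:
    return dict(
        estimates=res.estimates,
        se={k: v for k, v in res.se.items()},
        cv_percent=res.cv_percent,
        ci95={k: list(v) if v else None for k, v in res.ci95.items()},
        mvof=res.mvof,
        converged=res.converged,
        hessian_pd=res.hessian_pd,
        n_obs=res.n_obs,
        n_subjects=res.n_subjects,
    )


def format_fit_table(res: FitResult, title: str) -> str:
    """Plain-text estimate table: Parameter | Estimate | CV% | CI."""
    lines = [title, "-" * len(title),
             f"{'Parameter':<22}{'Estimate':>12}{'CV%':>8}   95% CI"]
    for name in res.names:
        est = res.estimates[name]
        cv = res.cv_percent.get(name)
        ci = res.ci95.get(name)
        cv_s = f"{cv:.0f}" if cv is not None else "-"
        ci_s = f"{ci[0]:.4g} - {ci[1]:.4g}" if ci else "-"
        lines.append(f"{name:<22}{est:>12.4g}{cv_s:>8}   {ci_s}")
    lines.append(f"MVOF: {res.mvof:.3f}")
    return "\n".join(lines)


def run_pipeline(config: Mapping[str, Any] | str | Path, outdir: str | Path = "ldopapop_out") -> dict[str, Any]:
    """Execute the configured stages; returns the in-memory report bundle.

    Config keys (all optional unless noted): ``simulate`` (study factory
    name, seed, overrides) or ``dataset`` (CSV path, required if no
    simulate block); ``stages`` with booleans ``grid``, ``metabolites``,
    ``baseline``; ``fit`` with ``n_starts``, ``maxiter``, ``constraints``.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"config": _jsonable(config), "version": __version__}
    stage = "setup"
    try:
        stage = "data"
        subjects, design = _obtain_subjects(config)
        report["n_subjects"] = len(subjects)

        stage = "recovery"
        recovery = _recovery_stage(subjects, design, report)

        stage = "th"
        responders = _th_stage(subjects, report)

        fitcfg = dict(config.get("fit", {}))
        n_starts = int(fitcfg.get("n_starts", 3))
        maxiter = int(fitcfg.get("maxiter", 60))
        constraints = tuple(fitcfg.get("constraints", ("Q5", "V5", "k50")))

        stage = "parent_fit"
        spec = parent_model(constraints=constraints)
        data = PopData.from_subjects(
            responders, spec, dvids=["plasma_LDOPA", "ecf_LDOPA"], recovery=recovery,
        )
        init = default_parent_init(constraints)
        parent = fit(data, init, n_starts=n_starts, maxiter=maxiter)
        report["parent_fit"] = _fit_report(parent)
        (outdir / "parent_fit.txt").write_text(format_fit_table(parent, "L-DOPA parent model"))
        residual_table(parent, data).to_csv(outdir / "parent_residuals.csv", index=False)

        stages = dict(config.get("stages", {}))
        if stages.get("grid", False):
            stage = "symmetry_grid"
            grid = symmetry_grid(responders, init, recovery=recovery,
                                 n_starts=1, maxiter=maxiter)
            report["grid"] = dict(
                selected=list(grid.selected),
                mvof={" & ".join(c.constraints) or "NONE": (c.fit.mvof if c.fit else None)
                      for c in grid.cells},
            )
            grid.table().to_csv(outdir / "symmetry_grid.csv", index=False)

        if stages.get("metabolites", True):
            stage = "metabolite_fits"
            report["metabolites"] = {}
            for analyte in ("DOPAC", "HVA"):
                for hemi in ("control", "diseased"):
                    has = any(
                        s.observations is not None
                        and ((s.observations["DVID"] == f"dial_{analyte}")
                             & (s.observations["HEMI"] == hemi)).any()
                        for s in responders
                    )
                    if not has:
                        continue
                    res = sequential_metabolite_fit(
                        responders, parent, analyte, hemi,
                        default_metabolite_init(analyte, hemi),
                        n_starts=n_starts, maxiter=maxiter,
                    )
                    key = f"{analyte}:{hemi}"
                    report["metabolites"][key] = _fit_report(res)
                    (outdir / f"fit_{analyte}_{hemi}.txt").write_text(
                        format_fit_table(res, f"{analyte} ({hemi} hemisphere)"))

        if stages.get("baseline", True):
            stage = "baseline_summary"
            frames = []
            for s in responders:
                if s.observations is None:
                    continue
                df = s.observations.copy()
                df["ID"] = s.id
                frames.append(df)
            allobs = pd.concat(frames, ignore_index=True)
            dial = allobs[allobs["DVID"].isin(["ecf_LDOPA", "dial_DOPAC", "dial_HVA"])]
            if (dial["PHASE"] == "baseline").any():
                summ = baseline_summary(dial)
                summ.to_csv(outdir / "baseline_summary.csv", index=False)
                report["baseline"] = summ.to_dict("records")

        with open(outdir / "report.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        return report
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        report["failed_stage"] = stage
        with open(outdir / "report_partial.json", "w") as fh:
            json.dump(_jsonable(report), fh, indent=2)
        raise


def _obtain_subjects(config) -> tuple[list[SubjectRecord], StudyDesign | None]:
    if "simulate" in config:
        sim = dict(config["simulate"])
        kind = sim.pop("study", "parent")
        seed = int(sim.pop("seed", 0))
        retro = bool(sim.pop("retrodialysis", True))
        factory = _STUDIES[kind]
        design = factory(**sim.pop("design", {}))
        theta = {**D.PARENT_THETA, **sim.pop("theta", {})}
        for block in D.METABOLITE_THETA.values():
            for k, v in block.items():
                theta.setdefault(k, v)
        omega2 = sim.pop("omega2", dict(D.PARENT_OMEGA2))
        from .model import full_model

        sym = ("Q5", "V5", "k50")
        spec = full_model(sym) if design.metabolites else parent_model(constraints=sym)
        subjects = simulate_trial(design, spec, theta, omega2, seed=seed, retrodialysis=retro)
        return subjects, design
    if "dataset" in config:
        from .dataset import dataset_to_subjects, read_dataset

        return dataset_to_subjects(read_dataset(config["dataset"])), None
    raise ValueError("config needs a 'simulate' or 'dataset' block")


def _recovery_stage(subjects, design, report) -> float | None:
    ests = []
    for s in subjects:
        if s.observations is None:
            continue
        retro = s.observations[s.observations["DVID"] == "retro_LDOPA"]
        if not len(retro):
            continue
        perf = (
            float(retro["PERFUSATE"].iloc[0])
            if "PERFUSATE" in retro and retro["PERFUSATE"].notna().any()
            else (design.retro_perfusate[s.dose_group] if design else np.nan)
        )
        ests.append(estimate_recovery(retro["DV"].to_numpy(), perf))
    if not ests:
        report["recovery"] = None
        return None
    pooled = pooled_recovery(ests)
    report["recovery"] = dict(mean=pooled.mean, sd=pooled.sd, n_animals=pooled.n_fractions)
    return pooled.mean


def _th_stage(subjects, report) -> list[SubjectRecord]:
    from .simulate import replace_observations

    rows = []
    kept = []
    for s in subjects:
        resp = classify_responder(s.th_percent) if np.isfinite(s.th_percent) else s.responder
        rows.append(dict(ID=s.id, th_percent=s.th_percent, responder=resp))
        if not resp and s.observations is not None:
            obs = s.observations[s.observations["HEMI"] != "diseased"]
            s = replace_observations(s, obs.reset_index(drop=True))
        kept.append(s)
    report["th"] = rows
    return kept


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj
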