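"""Probe-recovery calibration and dialysate baseline statistics.

Microdialysis probes under-sample the extracellular fluid: the dialysate
concentration is the ECF concentration attenuated by the probe's relative
recovery.  Retrodialysis estimates that recovery by perfusing the probe
with a known analyte concentration and measuring the relative *loss*
across the membrane, which under the usual symmetry assumption equals the
relative gain during sampling.  Dialysate concentrations divided by the
recovery estimate the ECF concentration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DialysateObservation",
    "RecoveryEstimate",
    "estimate_recovery",
    "pooled_recovery",
    "correct_to_ecf",
    "baseline_summary",
]

log = logging.getLogger("ldopapop.microdialysis")


@dataclass(frozen=True)
class DialysateObservation:
    """One interval-collected dialysate fraction."""

    window_start: float  # min
    window_end: float  # min
    analyte: str
    hemisphere: str
    concentration: float
    unit: str = "ng/mL"
    phase: str = "postdose"  # retrodialysis | washout | baseline | postdose
    recovery_corrected: bool = False

    def __post_init__(self):
        if self.window_end <= self.window_start:
            raise ValueError("window end must exceed window start")


@dataclass(frozen=True)
class RecoveryEstimate:
    mean: float  # relative loss, 0..1
    sd: float
    n_fractions: int
    n_excluded: int = 0


def estimate_recovery(fraction_out: Sequence[float], perfusate_conc: float) -> RecoveryEstimate:
    """Per-probe in vivo recovery from retrodialysis fractions.

    ``fraction_out`` are the dialysate outflow concentrations measured while
    perfusing at ``perfusate_conc``; per-fraction relative loss is
    ``(in - out)/in``.  Fractions showing a *gain* (out > in) are excluded
    with a warning — they indicate contamination, not transport.  The SD is
    the unbiased sample SD across the retained fractions (0 for a single
    fraction).
    """
    if perfusate_conc <= 0:
        raise ValueError("perfusate concentration must be > 0")
    out = np.asarray(fraction_out, float)
    if out.size == 0:
        raise ValueError("need at least one retrodialysis fraction")
    loss = (perfusate_conc - out) / perfusate_conc
    gain = loss < 0
    if gain.any():
        log.warning("excluding %d retrodialysis fraction(s) showing net gain", int(gain.sum()))
    kept = loss[~gain]
    if kept.size == 0:
        raise ValueError("all retrodialysis fractions show net gain; no recovery estimate")
    sd = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
    return RecoveryEstimate(mean=float(np.mean(kept)), sd=sd,
                            n_fractions=int(kept.size), n_excluded=int(gain.sum()))


def pooled_recovery(estimates: Sequence[RecoveryEstimate]) -> RecoveryEstimate:
    """Across-animal pooled recovery (the average applied study-wide)."""
    means = np.array([e.mean for e in estimates])
    if means.size == 0:
        raise ValueError("no recovery estimates to pool")
    sd = float(np.std(means, ddof=1)) if means.size > 1 else 0.0
    return RecoveryEstimate(mean=float(means.mean()), sd=sd, n_fractions=int(means.size))


def correct_to_ecf(obs: DialysateObservation, recovery: float | RecoveryEstimate) -> DialysateObservation:
    """Scale a dialysate concentration to an ECF estimate (divide by recovery)."""
    r = recovery.mean if isinstance(recovery, RecoveryEstimate) else float(recovery)
    if not (0.0 < r <= 1.0):
        raise ValueError(f"recovery must lie in (0, 1], got {r}")
    return replace(obs, concentration=obs.concentration / r, recovery_corrected=True)


def baseline_summary(
    observations: pd.DataFrame,
    phase: str = "baseline",
    group_keys: Sequence[str] = ("HEMI", "DVID"),
    value_col: str = "DV",
    subject_col: str = "ID",
) -> pd.DataFrame:
    """Per-group baseline means with Welch comparisons between hemispheres.

    The per-subject baseline is the mean of that subject's pre-dose
    fractions; group statistics (mean, SEM, n) are computed *across
    subjects*.  For each analyte observed in both hemispheres the two
    groups are compared by Welch's unequal-variance t-test with
    Welch-Satterthwaite degrees of freedom; groups with fewer than two
    subjects report summary statistics only.
    """
    df = observations
    if "PHASE" in df.columns:
        df = df[df["PHASE"] == phase]
    if not len(df):
        raise ValueError(f"no observations in phase {phase!r}")
    per_subject = (
        df.groupby([subject_col, *group_keys], dropna=False)[value_col]
        .mean()
        .reset_index()
    )
    rows = []
    other_keys = [k for k in group_keys if k != "HEMI"]
    grouped = per_subject.groupby(list(group_keys), dropna=False)
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        vals = sub[value_col].to_numpy()
        n = len(vals)
        rows.append(dict(zip(group_keys, key)) | dict(
            n=n,
            mean=float(np.mean(vals)),
            sem=float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
        ))
    summary = pd.DataFrame(rows)

    # Welch comparison control vs diseased, separately per analyte block
    summary["welch_t"] = np.nan
    summary["welch_df"] = np.nan
    summary["welch_p"] = np.nan
    if "HEMI" in group_keys:
        blocks = (
            [(dict(zip(other_keys, k if isinstance(k, tuple) else (k,))), g)
             for k, g in per_subject.groupby(other_keys, dropna=False)]
            if other_keys else [({}, per_subject)]
        )
        for keyvals, block in blocks:
            groups = {
                h: block.loc[block["HEMI"] == h, value_col].to_numpy()
                for h in ("control", "diseased")
            }
            if min(len(groups["control"]), len(groups["diseased"])) < 2:
                if groups["control"].size or groups["diseased"].size:
                    log.info("group too small for Welch test (%s): summary only", keyvals)
                continue
            t, p = stats.ttest_ind(groups["control"], groups["diseased"], equal_var=False)
            v = {h: np.var(groups[h], ddof=1) / len(groups[h]) for h in groups}
            dof = (v["control"] + v["diseased"]) ** 2 / (
                v["control"] ** 2 / (len(groups["control"]) - 1)
                + v["diseased"] ** 2 / (len(groups["diseased"]) - 1)
            )
            sel = np.ones(len(summary), dtype=bool)
            for k, val in keyvals.items():
                sel &= summary[k] == val
            summary.loc[sel, ["welch_t", "welch_df", "welch_p"]] = [t, dof, p]
    return summary
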