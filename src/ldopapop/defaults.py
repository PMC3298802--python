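"""Reference population estimates and study-design constants.

These are the published population-pharmacokinetic estimates for
intravenous L-DOPA (10/25/50 mg/kg, 20-min infusion) with bilateral
striatal microdialysis in the unilateral rat rotenone model.  They serve
two roles: as the true values of the synthetic-trial generator (the study
conditions every recovery test is run under) and as default initial values
for estimation.

Conventions
-----------
* ``Kin`` is implemented as a zero-order endogenous input in ng/min into
  each brain-ECF compartment (the printed unit label 1/min is kept in
  ``PARAMETER_UNITS`` as metadata; a first-order reading has no source
  amount in the model and cannot sustain a baseline).
* Inter-individual variability (``OMEGA2``) is the variance of a lognormal
  random effect, parameter_i = typical * exp(eta_i).
* Residual-error magnitudes (``SIGMA``) are standard deviations: the
  proportional SD for L-DOPA (0.087 = 8.7% CV in plasma) and the additive
  SD in pmol/mL for the metabolite dialysate concentrations.
* In the final parent model the brain elimination constant is shared
  between hemispheres (k40 = k50 = 0.175 1/min, the fully symmetric model);
  the sequential metabolite sub-models re-estimate their own hemisphere
  parent elimination (listed under the metabolite blocks).
"""

from __future__ import annotations

# -- typical values (theta) ------------------------------------------------

#: Parent (plasma + brain ECF) L-DOPA model, fully symmetric hemispheres.
PARENT_THETA = {
    "Cl": 30.0,     # mL/min total plasma clearance
    "V1": 98.0,     # mL central volume
    "V2": 157.0,    # mL shallow peripheral
    "V3": 599.0,    # mL deep peripheral
    "Q2": 22.0,     # mL/min
    "Q3": 11.0,     # mL/min
    "V4": 13300.0,  # mL apparent brain-ECF volume (control)
    "Q4": 22.0,     # mL/min BBB inter-compartmental clearance (control)
    "k40": 0.175,   # 1/min brain elimination (shared k40 = k50)
    "Kin": 5.8,     # ng/min endogenous input (printed label: 1/min)
}

#: Metabolite sub-model estimates: (analyte, hemisphere) -> parameters.
#: Each sub-model re-estimates the parent brain elimination for its
#: hemisphere alongside the formation and elimination constants.
METABOLITE_THETA = {
    ("DOPAC", "control"): {"k46": 4.4e-5, "k40": 0.53, "k60": 0.0053},
    ("HVA", "control"): {"k47": 2.3e-5, "k40": 0.19, "k70": 0.0044},
    ("DOPAC", "diseased"): {"k58": 5.4e-5, "k50": 0.36, "k80": 0.038},
    ("HVA", "diseased"): {"k59": 1.6e-5, "k50": 0.14, "k90": 0.011},
}

#: Inter-individual variances (omega^2) by parameter; parameters absent here
#: carry no random effect.  Metabolite-block entries are keyed by the
#: sub-model they belong to.
PARENT_OMEGA2 = {"Cl": 0.26, "V4": 0.075, "Kin": 0.94}
METABOLITE_OMEGA2 = {
    ("DOPAC", "control"): {"k46": 0.50, "k40": 0.42, "k60": 0.19},
    ("HVA", "control"): {"k47": 0.019, "k70": 0.14},
    ("DOPAC", "diseased"): {"k58": 1.0, "k50": 0.53},
    ("HVA", "diseased"): {"k59": 0.49},
}

#: Residual-error standard deviations keyed by observation type.
SIGMA = {
    "plasma_LDOPA": 0.087,              # proportional (CV 8.7%)
    "ecf_LDOPA": 0.17,                  # proportional (CV 17%)
    ("dial_DOPAC", "control"): 0.0020,  # additive, pmol/mL
    ("dial_HVA", "control"): 0.0028,    # additive, pmol/mL
    ("dial_DOPAC", "diseased"): 0.0014,  # additive, pmol/mL
    ("dial_HVA", "diseased"): 0.0034,   # additive, pmol/mL
}

#: same residual SDs keyed by estimation stream label.
SIGMA_STREAMS = {
    "plasma_LDOPA": 0.087,
    "ecf_LDOPA": 0.17,
    "dial_DOPAC:control": 0.0020,
    "dial_HVA:control": 0.0028,
    "dial_DOPAC:diseased": 0.0014,
    "dial_HVA:diseased": 0.0034,
}

PARAMETER_UNITS = {
    "Cl": "mL/min", "V1": "mL", "V2": "mL", "V3": "mL", "V4": "mL", "V5": "mL",
    "Q2": "mL/min", "Q3": "mL/min", "Q4": "mL/min", "Q5": "mL/min",
    "Kin": "ng/min (printed label: 1/min)",
    "k40": "1/min", "k50": "1/min",
    "k46": "1/min", "k47": "1/min", "k58": "1/min", "k59": "1/min",
    "k60": "1/min", "k70": "1/min", "k80": "1/min", "k90": "1/min",
}

# -- study design ----------------------------------------------------------

#: mg/kg dose groups with the plasma-analysis group sizes (13 rats).
PLASMA_GROUPS = {10.0: 4, 25.0: 4, 50.0: 5}
#: control-hemisphere ECF cohort (12 rats).
CONTROL_ECF_GROUPS = {10.0: 4, 25.0: 3, 50.0: 5}
#: rotenone-responder diseased-hemisphere L-DOPA cohort (7 rats).
DISEASED_ECF_GROUPS = {10.0: 1, 25.0: 2, 50.0: 4}
#: diseased-hemisphere metabolite cohort (8 rats).
DISEASED_MET_GROUPS = {10.0: 2, 25.0: 2, 50.0: 4}

BODY_WEIGHT_KG = 0.288
BODY_WEIGHT_SD_KG = 0.013

INFUSION_DURATION_MIN = 20.0

#: plasma sampling times (min relative to infusion start).
PLASMA_TIMES = (-5.0, 5.0, 10.0, 15.0, 20.0, 22.0, 24.0, 26.0, 28.0, 30.0,
                45.0, 50.0, 60.0, 75.0, 90.0, 120.0, 180.0, 240.0, 360.0)

#: retrodialysis calibration: perfusate L-DOPA (ng/mL) per dose group,
#: six 10-min fractions over 60 min.
RETRO_PERFUSATE = {10.0: 10.0, 25.0: 100.0, 50.0: 200.0}
RETRO_N_FRACTIONS = 6
RETRO_FRACTION_MIN = 10.0

#: in vivo probe recovery (relative loss): mean and SD across animals.
RECOVERY_MEAN = 0.30
RECOVERY_SD = 0.06

#: responder prevalence (12 of 17 rats) and the TH% classification bound.
RESPONDER_PROBABILITY = 12.0 / 17.0
RESPONDER_TH_MAX = 40.0

#: lower limits of quantification (concentration units as fitted).
LLOQ = {
    "plasma_LDOPA": 1.0,      # ng/mL
    "ecf_LDOPA": 1.0e-4,      # ng/mL (dialysate assay resolves sub-ng/mL baselines)
    "dial_DOPAC": 0.0,        # pmol/mL
    "dial_HVA": 0.0,          # pmol/mL
    "dial_DA": 0.01,          # ng/mL; dopamine never quantifiable
}

#: printed group baselines (pmol/mL, mean +/- SEM across animals) used by
#: the baseline-summary generator defaults.
BASELINE_DIALYSATE = {
    ("ecf_LDOPA", "control"): (0.024, 0.011),
    ("ecf_LDOPA", "diseased"): (0.010, 0.004),
    ("dial_DOPAC", "control"): (1.3, 0.17),
    ("dial_DOPAC", "diseased"): (0.2, 0.19),
    ("dial_HVA", "control"): (0.9, 0.08),
    ("dial_HVA", "diseased"): (0.25, 0.14),
}


def dialysate_windows(start: float = 0.0, end: float = 360.0) -> list[tuple[float, float]]:
    """Post-dose collection windows: 10-min to 120, 20-min to 180, 30-min to 360."""
    edges = [start]
    t = start
    while t < min(120.0, end):
        t += 10.0
        edges.append(t)
    while t < min(180.0, end):
        t += 20.0
        edges.append(t)
    while t < end:
        t += 30.0
        edges.append(t)
    return [(a, b) for a, b in zip(edges, edges[1:])]


def baseline_windows(n: int = 3, width: float = 10.0) -> list[tuple[float, float]]:
    """Pre-dose baseline fractions, contiguous 10-min windows ending at t=0."""
    return [(-(i + 1) * width, -i * width) for i in reversed(range(n))]
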