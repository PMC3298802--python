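"""Tyrosine-hydroxylase staining quantification and responder status.

Striatal TH immunostaining is measured as mean grey values (MGV) on
manually defined regions: slide background, cortex, corpus callosum,
dorsal striatum (CPu) and ventral striatum (NAcc), per hemisphere.
Striatal MGVs are corrected for non-specific staining by subtracting the
cortical (or corpus-callosum) MGV; the fraction of intact innervation in
the rotenone-treated hemisphere is the corrected striatal MGV expressed as
a percentage of the untreated hemisphere.  Animals retaining less than 40%
are classed as rotenone responders.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "StainMeasurement",
    "corrected_mgv",
    "percent_intact",
    "classify_responder",
    "th_table",
]

log = logging.getLogger("ldopapop.thstain")

RESPONDER_THRESHOLD = 40.0
STRIATAL_REGIONS = ("CPu", "NAcc")


@dataclass(frozen=True)
class StainMeasurement:
    """MGV readings for one hemisphere of one animal."""

    cpu: float  # dorsal striatum (caudate putamen)
    nacc: float  # ventral striatum (nucleus accumbens)
    cortex: float
    corpus_callosum: float = np.nan
    background: float = np.nan  # slide background: measured, unused in correction

    def __post_init__(self):
        for name in ("cpu", "nacc", "cortex"):
            v = getattr(self, name)
            if np.isfinite(v) and v < 0:
                raise ValueError(f"MGV {name} must be >= 0")


def corrected_mgv(m: StainMeasurement, region: str = "CPu", reference: str = "cortex") -> float:
    """Striatal MGV minus the non-specific-staining reference MGV.

    ``reference`` selects the control region subtracted: ``"cortex"``
    (default) or ``"corpus_callosum"``.
    """
    if region not in STRIATAL_REGIONS:
        raise ValueError(f"region must be one of {STRIATAL_REGIONS}")
    if reference not in ("cortex", "corpus_callosum"):
        raise ValueError("reference must be 'cortex' or 'corpus_callosum'")
    striatal = m.cpu if region == "CPu" else m.nacc
    ref = getattr(m, reference)
    if not np.isfinite(striatal):
        raise ValueError(f"missing striatal MGV for region {region}")
    if not np.isfinite(ref):
        raise ValueError(f"missing {reference} MGV")
    return float(striatal - ref)


def percent_intact(
    treated: StainMeasurement,
    untreated: StainMeasurement,
    region: str = "CPu",
    reference: str = "cortex",
) -> float:
    """TH% — corrected treated-hemisphere MGV as % of the untreated side."""
    denom = corrected_mgv(untreated, region, reference)
    if denom <= 0:
        raise ValueError("untreated corrected MGV must be > 0 for a TH% ratio")
    return 100.0 * corrected_mgv(treated, region, reference) / denom


def classify_responder(th_percent: float, threshold: float = RESPONDER_THRESHOLD) -> bool:
    """Responder iff TH% is strictly below the threshold (default 40%)."""
    if not (0.0 <= th_percent <= 200.0):
        log.warning("TH%% %.3g outside the sanity range [0, 200]", th_percent)
    return bool(th_percent < threshold)


def th_table(
    measurements: pd.DataFrame,
    region: str = "CPu",
    reference: str = "cortex",
) -> pd.DataFrame:
    """Per-animal TH% and responder flags from a long MGV table.

    ``measurements`` needs columns ID, HEMI ('treated'/'untreated'), CPU,
    NACC, CORTEX and optionally CORPUS_CALLOSUM, BACKGROUND.  TH% is
    computed on the dorsal striatum by default (the dialysis target); the
    ventral striatum is reported alongside.
    """
    out = []
    for sid, sub in measurements.groupby("ID"):
        ms = {}
        for r in sub.itertuples():
            ms[r.HEMI] = StainMeasurement(
                cpu=r.CPU, nacc=r.NACC, cortex=r.CORTEX,
                corpus_callosum=getattr(r, "CORPUS_CALLOSUM", np.nan),
                background=getattr(r, "BACKGROUND", np.nan),
            )
        if set(ms) != {"treated", "untreated"}:
            raise ValueError(f"subject {sid}: need exactly one treated and one untreated hemisphere")
        th = percent_intact(ms["treated"], ms["untreated"], region, reference)
        row = dict(ID=sid, th_percent=th, responder=classify_responder(th))
        other = [r for r in STRIATAL_REGIONS if r != region][0]
        try:
            row[f"th_percent_{other.lower()}"] = percent_intact(ms["treated"], ms["untreated"], other, reference)
        except ValueError:
            row[f"th_percent_{other.lower()}"] = np.nan
        out.append(row)
    return pd.DataFrame(out)


def simulate_stain(
    th_percent: float,
    rng: np.random.Generator,
    untreated_level: float = 100.0,
    cortex_level: float = 20.0,
    noise_sd: float = 0.0,
) -> tuple[StainMeasurement, StainMeasurement]:
    """Synthetic MGV pair consistent with a target TH% (test/round-trip aid)."""
    untreated = StainMeasurement(
        cpu=cortex_level + untreated_level + rng.normal(0, noise_sd),
        nacc=cortex_level + untreated_level + rng.normal(0, noise_sd),
        cortex=cortex_level,
        corpus_callosum=cortex_level * 0.9,
        background=5.0,
    )
    treated_level = untreated_level * th_percent / 100.0
    treated = StainMeasurement(
        cpu=cortex_level + treated_level + rng.normal(0, noise_sd),
        nacc=cortex_level + treated_level + rng.normal(0, noise_sd),
        cortex=cortex_level,
        corpus_callosum=cortex_level * 0.9,
        background=5.0,
    )
    return treated, untreated
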