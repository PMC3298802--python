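"""Long-format dataset I/O (NONMEM-style rows, plain CSV).

One row per dose event or observation.  Observation rows carry either a
point ``TIME`` (plasma samples) or a collection window ``WSTART``/``WEND``
(dialysate fractions), an observation stream ``DVID``, hemisphere ``HEMI``
(``NA`` for plasma), the value ``DV`` with its ``UNIT``, and below-LOQ
bookkeeping.  Dose rows carry ``AMT`` (ng), ``RATE`` (ng/min) and ``DUR``
(min) with ``MDV = 1``.  Times are minutes from infusion start, so
pre-dose rows have negative times.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import DoseEvent
from .simulate import SubjectRecord, replace_observations

__all__ = ["LongDataset", "read_dataset", "write_dataset", "subjects_to_dataset", "dataset_to_subjects"]

COLUMNS = [
    "ID", "GROUP", "WT", "TIME", "WSTART", "WEND", "DVID", "HEMI",
    "DV", "UNIT", "AMT", "RATE", "DUR", "MDV", "BLQ", "LLOQ", "PHASE",
]

KNOWN_DVIDS = {"plasma_LDOPA", "ecf_LDOPA", "dial_DOPAC", "dial_HVA", "retro_LDOPA", "dial_DA", "TH", "dose"}
KNOWN_HEMIS = {"control", "diseased", "NA"}


class DatasetError(ValueError):
    """Validation failure, reported with offending row numbers."""


@dataclass
class LongDataset:
    """Validated long-format trial dataset."""

    frame: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.frame
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing columns: {missing}")
        bad = df.index[~df["DVID"].isin(KNOWN_DVIDS)].tolist()
        if bad:
            raise DatasetError(f"unknown DVID at rows {bad[:10]}")
        bad = df.index[~df["HEMI"].astype(str).isin(KNOWN_HEMIS)].tolist()
        if bad:
            raise DatasetError(f"unknown HEMI at rows {bad[:10]}")
        doses = df[df["DVID"] == "dose"]
        bad = doses.index[(doses["AMT"].fillna(0) <= 0) | doses["DV"].notna()].tolist()
        if bad:
            raise DatasetError(f"dose rows need AMT > 0 and no DV: rows {bad[:10]}")
        obs = df[df["DVID"] != "dose"]
        has_time = obs["TIME"].notna()
        has_win = obs["WSTART"].notna() & obs["WEND"].notna()
        bad = obs.index[~(has_time ^ has_win)].tolist()
        if bad:
            raise DatasetError(f"observation rows need exactly one of TIME or WSTART/WEND: rows {bad[:10]}")
        no_dv = obs["DV"].isna() & ~obs["BLQ"].astype("boolean").fillna(False).astype(bool)
        bad = obs.index[no_dv].tolist()
        if bad:
            raise DatasetError(f"observation rows need DV or a below-LOQ flag: rows {bad[:10]}")
        missing_unit = obs.index[obs["UNIT"].isna()].tolist()
        if missing_unit:
            raise DatasetError(f"observation rows need units: rows {missing_unit[:10]}")
        for sid, sub in df[df["TIME"].notna()].groupby("ID"):
            per_stream = sub.groupby(["DVID", "HEMI"])["TIME"]
            for key, times in per_stream:
                t = times.to_numpy(float)
                if np.any(np.diff(t) < 0):
                    raise DatasetError(f"non-monotone times for subject {sid}, stream {key}")

    @property
    def subject_ids(self) -> list:
        return sorted(self.frame["ID"].unique().tolist())

    def observations(self, subject_id) -> pd.DataFrame:
        df = self.frame
        return df[(df["ID"] == subject_id) & (df["DVID"] != "dose")].reset_index(drop=True)


def subjects_to_dataset(subjects: Sequence[SubjectRecord]) -> LongDataset:
    """Flatten simulated subject records into one long table."""
    rows = []
    for s in subjects:
        for d in s.dose_events:
            rows.append(dict(
                ID=s.id, GROUP=s.dose_group, WT=s.body_weight, TIME=d.start,
                WSTART=np.nan, WEND=np.nan, DVID="dose", HEMI="NA", DV=np.nan,
                UNIT=np.nan, AMT=d.rate * d.duration, RATE=d.rate, DUR=d.duration,
                MDV=1, BLQ=False, LLOQ=np.nan, PHASE="dose",
            ))
        if s.observations is not None:
            for r in s.observations.to_dict("records"):
                rows.append(dict(
                    ID=s.id, GROUP=s.dose_group, WT=s.body_weight,
                    TIME=r.get("TIME", np.nan), WSTART=r.get("WSTART", np.nan),
                    WEND=r.get("WEND", np.nan), DVID=r["DVID"], HEMI=r["HEMI"],
                    DV=r["DV"], UNIT=r["UNIT"], AMT=np.nan, RATE=np.nan,
                    DUR=np.nan, MDV=0, BLQ=bool(r.get("BLQ", False)),
                    LLOQ=r.get("LLOQ", np.nan), PHASE=r.get("PHASE", ""),
                ))
    return LongDataset(pd.DataFrame(rows, columns=COLUMNS))


def dataset_to_subjects(ds: LongDataset) -> list[SubjectRecord]:
    """Rebuild minimal subject records (doses + observations) for fitting."""
    out = []
    for sid in ds.subject_ids:
        df = ds.frame[ds.frame["ID"] == sid]
        doses = tuple(
            DoseEvent(start=float(r.TIME), duration=float(r.DUR), rate=float(r.RATE))
            for r in df[df["DVID"] == "dose"].itertuples()
        )
        obs = ds.observations(sid)
        hemis = tuple(sorted(set(obs["HEMI"]) - {"NA"}))
        wt = float(df["WT"].iloc[0]) if df["WT"].notna().any() else np.nan
        group = float(df["GROUP"].iloc[0]) if df["GROUP"].notna().any() else np.nan
        out.append(SubjectRecord(
            id=sid, dose_group=group, body_weight=wt, params={}, eta={},
            responder="diseased" in hemis, th_percent=np.nan, recovery=np.nan,
            hemispheres=hemis, has_plasma=bool((obs["DVID"] == "plasma_LDOPA").any()),
            dose_events=doses, observations=obs,
        ))
    return out


def write_dataset(ds: LongDataset, path: str | Path) -> None:
    ds.frame.to_csv(path, index=False)


def read_dataset(path: str | Path) -> LongDataset:
    # keep_default_na=False preserves the literal "NA" hemisphere label
    df = pd.read_csv(path, keep_default_na=False, na_values=[""],
                     dtype={"DVID": str, "HEMI": str, "PHASE": str, "UNIT": str})
    df["BLQ"] = df["BLQ"].map(
        lambda v: v if isinstance(v, bool) else str(v).strip().lower() == "true"
    )
    return LongDataset(df)
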