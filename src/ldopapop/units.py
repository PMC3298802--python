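"""Unit handling for L-DOPA and its dopamine metabolites.

Concentrations appear in two conventions in this field: mass units (ng/mL,
typical for plasma assays) and molar units (pmol/mL, typical for
microdialysate work).  Conversion between the two goes through the analyte's
molar mass.  Dose bookkeeping additionally needs mg/kg -> ng given a body
weight.
"""

from __future__ import annotations

__all__ = ["MOLAR_MASS", "convert_units", "UnitError"]

# g/mol, standard reference values
MOLAR_MASS = {
    "L-DOPA": 197.19,
    "DOPAC": 168.15,
    "HVA": 182.17,
    "dopamine": 153.18,
}

_CONC_UNITS = {"ng/mL", "pmol/mL"}
_AMOUNT_UNITS = {"ng", "mg/kg"}


class UnitError(ValueError):
    """Raised for unknown analytes/units or impossible conversions."""


def ng_per_ml_to_pmol_per_ml(value: float, analyte: str) -> float:
    return value * 1000.0 / _molar_mass(analyte)


def pmol_per_ml_to_ng_per_ml(value: float, analyte: str) -> float:
    return value * _molar_mass(analyte) / 1000.0


def _molar_mass(analyte: str) -> float:
    try:
        return MOLAR_MASS[analyte]
    except KeyError:
        raise UnitError(f"unknown analyte {analyte!r}; known: {sorted(MOLAR_MASS)}")


def convert_units(
    value: float,
    analyte: str,
    from_unit: str,
    to_unit: str,
    body_weight_kg: float | None = None,
):
    """Convert ``value`` of ``analyte`` between supported units.

    Supported units: ``ng/mL`` <-> ``pmol/mL`` (via molar mass) and
    ``mg/kg`` <-> ``ng`` (via ``body_weight_kg``).  Identity conversions are
    returned unchanged for any known unit.
    """
    known = _CONC_UNITS | _AMOUNT_UNITS
    if from_unit not in known or to_unit not in known:
        bad = from_unit if from_unit not in known else to_unit
        raise UnitError(f"unknown unit {bad!r}; known: {sorted(known)}")
    _molar_mass(analyte)  # validate analyte even for identity
    if from_unit == to_unit:
        return value
    if {from_unit, to_unit} == {"ng/mL", "pmol/mL"}:
        if from_unit == "ng/mL":
            return ng_per_ml_to_pmol_per_ml(value, analyte)
        return pmol_per_ml_to_ng_per_ml(value, analyte)
    if {from_unit, to_unit} == {"mg/kg", "ng"}:
        if body_weight_kg is None:
            raise UnitError("mg/kg <-> ng conversion requires body_weight_kg")
        if from_unit == "mg/kg":
            return value * body_weight_kg * 1.0e6
        return value / (body_weight_kg * 1.0e6)
    raise UnitError(f"cannot convert {from_unit!r} -> {to_unit!r} (mixes amount and concentration)")
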