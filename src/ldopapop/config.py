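"""Model-definition serialization (YAML/JSON-friendly dicts).

A config carries the structural choices (which compartment blocks exist,
which hemisphere-symmetry ties are applied) plus the parameter values with
their units and IIV flags, so a fitted or assumed model can be stored next
to its outputs and rebuilt exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import yaml

from . import defaults as D
from .model import PopModelSpec

__all__ = ["spec_to_config", "spec_from_config", "save_model_config", "load_model_config"]


def spec_to_config(
    spec: PopModelSpec,
    theta: Mapping[str, float] | None = None,
    omega2: Mapping[str, float] | None = None,
    sigma: Mapping[str, float] | None = None,
) -> dict:
    cfg: dict = {
        "model": {
            "peripherals": spec.peripherals,
            "hemispheres": list(spec.hemispheres),
            "metabolites": [list(m) for m in spec.metabolites],
            "constraints": list(spec.constraints),
        }
    }
    if theta is not None:
        cfg["parameters"] = {
            name: {
                "value": float(theta[name]) if name in theta else None,
                "unit": D.PARAMETER_UNITS.get(name, ""),
                "iiv": bool(omega2 and name in omega2),
            }
            for name in spec.free_parameter_names
        }
    if omega2:
        cfg["omega2"] = {k: float(v) for k, v in omega2.items()}
    if sigma:
        cfg["sigma"] = {k: float(v) for k, v in sigma.items()}
    return cfg


def spec_from_config(cfg: Mapping) -> tuple[PopModelSpec, dict]:
    m = cfg["model"]
    spec = PopModelSpec(
        peripherals=int(m.get("peripherals", 2)),
        hemispheres=tuple(m.get("hemispheres", ())),
        metabolites=tuple(tuple(x) for x in m.get("metabolites", ())),
        constraints=tuple(m.get("constraints", ())),
    )
    theta = {
        name: entry["value"]
        for name, entry in cfg.get("parameters", {}).items()
        if entry.get("value") is not None
    }
    return spec, theta


def save_model_config(path: str | Path, spec: PopModelSpec, **kw) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(spec_to_config(spec, **kw), fh, sort_keys=False)


def load_model_config(path: str | Path) -> tuple[PopModelSpec, dict]:
    with open(path) as fh:
        return spec_from_config(yaml.safe_load(fh))
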