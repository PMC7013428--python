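"""Serialization helpers: parameter JSON, curve CSV, analysis config.

Parameter sets travel as JSON objects keyed by component name, each with
a ``model`` discriminator ("BP" or "Hill").  Concentrations are always
mol/L and effects are fractions in files; percent appears only in
rendered reports.  Configs may be JSON or YAML.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import pandas as pd
import yaml

from .mixtures import PredictedCurve
from .models import BiphasicParams, HillParams, InvalidInputError

log = logging.getLogger("segca")

#: Default effect-level panel (percent notation with branch suffix).
DEFAULT_LEVELS = ["80", "50", "20", "0", "-20R", "-30R", "-30L", "-20L",
                  "-10L"]


def molar_from_mass(mass_conc_g_per_L: float,
                    molecular_weight: float) -> float:
    """Convert a mass concentration (g/L) to molar (mol/L).

    All internal computation is molar; mass-based input is converted
    here, at the I/O boundary, using the component molecular weight.
    """
    if molecular_weight <= 0:
        raise InvalidInputError("molecular weight must be positive")
    return mass_conc_g_per_L / molecular_weight


def params_from_dict(d: dict) -> Union[BiphasicParams, HillParams]:
    model = d.get("model")
    if model == "BP":
        return BiphasicParams.from_dict(d)
    if model == "Hill":
        return HillParams.from_dict(d)
    raise InvalidInputError(f"unknown model tag {model!r}")


def load_params(path: Union[str, Path]) -> dict:
    """Load a component parameter file.

    Layout: {component: {"bp": {...}, "hill": {...}}} where each inner
    object carries the "model" tag; a bare {"model": ...} object is also
    accepted for single parameter sets.
    """
    with open(path) as fh:
        raw = json.load(fh)
    if "model" in raw:
        return {"_single": params_from_dict(raw)}
    out = {}
    for name, entry in raw.items():
        slot = {}
        for key in ("bp", "hill"):
            if key in entry:
                slot[key] = params_from_dict(entry[key])
        if not slot:
            raise InvalidInputError(f"component {name!r} has no parameter set")
        out[name] = slot
    return out


def dump_params(params_by_component: dict, path: Union[str, Path]) -> None:
    payload = {}
    for name, slot in params_by_component.items():
        payload[name] = {key: p.to_dict() for key, p in slot.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_config(path: Union[str, Path]) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yml", ".yaml")):
        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise InvalidInputError("config must be a mapping")
    return cfg


def curve_to_frame(curve: PredictedCurve) -> pd.DataFrame:
    rows = []
    for branch, arr in (("left", curve.left), ("right", curve.right)):
        for c, e in arr:
            rows.append((float(c), float(e), branch))
    return pd.DataFrame(rows, columns=["concentration_mol_per_L", "effect",
                                       "branch"])


def write_json(obj, path: Union[str, Path]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable))


def _jsonable(obj):
    try:
        return obj.to_dict()
    except AttributeError:
        pass
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
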