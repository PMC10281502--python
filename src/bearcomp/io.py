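"""Readers/writers for the package's CSV and JSON artifacts.

Tabular data are CSV with unit-tagged column names (length_m, mass_kg,
energy_MJ); parameter bundles, manifests and reports are JSON. All writes
are atomic (write to a temporary file in the target directory, then
rename), and JSON artifacts embed the package version and a hash of the
content that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import (AdiposeLipidParams, AdiposeProteinParams,
                          CompositionParams, EnergyDensities,
                          InvalidInputError, MuscleCompositionBounds,
                          StorageAllocationParams, StructuralParams)
from .smi import SMIParams

MORPHOMETRICS_COLUMNS = ["id", "sex", "age_years", "length_m", "mass_kg"]


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_csv(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(index=False))


def write_json(obj: dict, path) -> None:
    payload = dict(obj)
    payload.setdefault("version", __version__)
    body = json.dumps(payload, indent=2, sort_keys=True, default=float)
    payload["content_hash"] = hashlib.sha256(body.encode()).hexdigest()[:16]
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True,
                                       default=float))


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def params_to_dict(p: CompositionParams) -> dict:
    return {
        "structural": dataclasses.asdict(p.structural),
        "allocation": dataclasses.asdict(p.allocation),
        "adipose_lipid": dataclasses.asdict(p.adipose_lipid),
        "adipose_protein": dataclasses.asdict(p.adipose_protein),
        "smi": {**dataclasses.asdict(p.smi), "L0_unit": "m"},
        "muscle": dataclasses.asdict(p.muscle),
        "energy": {**dataclasses.asdict(p.energy), "unit": "MJ/kg"},
        "units": {"length": "m", "mass": "kg", "energy": "MJ"},
    }


def params_from_dict(d: dict) -> CompositionParams:
    units = d.get("units", {})
    if units.get("length", "m") != "m":
        raise InvalidInputError("parameter bundle must use meter lengths")
    smi = {k: v for k, v in d["smi"].items() if k in ("b_sma", "L0")}
    energy = {k: v for k, v in d["energy"].items() if k in ("lipid", "protein")}
    return CompositionParams(
        structural=StructuralParams(**d["structural"]),
        allocation=StorageAllocationParams(**d["allocation"]),
        adipose_lipid=AdiposeLipidParams(**d["adipose_lipid"]),
        adipose_protein=AdiposeProteinParams(**d["adipose_protein"]),
        smi=SMIParams(**smi),
        muscle=MuscleCompositionBounds(**d.get("muscle", {})),
        energy=EnergyDensities(**energy),
    )


def write_params(p: CompositionParams, path) -> None:
    write_json(params_to_dict(p), path)


def read_params(path) -> CompositionParams:
    return params_from_dict(read_json(path))


def _read_csv(path, required, what: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{what} CSV {path} missing columns {missing}")
    return df


def read_morphometrics(path) -> pd.DataFrame:
    df = _read_csv(path, MORPHOMETRICS_COLUMNS, "morphometrics")
    for i, row in df.iterrows():
        for col in ("length_m", "mass_kg"):
            if not row[col] > 0:
                raise InvalidInputError(
                    f"morphometrics row {i} (id={row['id']}): "
                    f"{col}={row[col]!r} must be positive")
        if row["sex"] not in ("F", "M"):
            raise InvalidInputError(
                f"morphometrics row {i} (id={row['id']}): "
                f"unknown sex {row['sex']!r}")
    return df


def read_dissection(path) -> pd.DataFrame:
    from .fitting import validate_dissection
    df = _read_csv(path, ["id", "sex", "length_m", "mass_kg", "muscle_kg",
                          "adipose_kg", "hide_kg", "viscera_kg", "bones_kg"],
                   "dissection")
    return validate_dissection(df)


def read_biopsy(path) -> pd.DataFrame:
    return _read_csv(path, ["id", "sex", "length_m", "mass_kg",
                            "lipid_proportion"], "biopsy")


def read_adipose_chem(path) -> pd.DataFrame:
    return _read_csv(path, ["lipid_proportion", "protein_proportion"],
                     "adipose chemistry")


def read_recaptures(path) -> pd.DataFrame:
    from .validation import RECAPTURE_COLUMNS, validate_recaptures
    return validate_recaptures(_read_csv(path, RECAPTURE_COLUMNS,
                                         "recapture"))
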