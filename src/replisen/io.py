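"""File formats: marker-dataset CSV and flat parameter files.

Dataset CSV dialect: comma-separated, UTF-8, header
``time_h,passage,marker,replicate,value`` (column order free); marker names
exactly ``PD, SA-b-Gal, Ki-67, gH2AX, TUNEL``; percentages on the 0-100
scale.

Parameter files are flat JSON or YAML with the rate-endpoint keys
``mP0P1, mPN1PN, mP0G, mPN1G, mP0S, mPN1S, mP0A, mPN1A`` (h^-1), the scalar
rates ``mGS, mAD``, the staining fractions ``PgH2AX, GKi67, GgH2AX`` and the
optional division limit ``N`` (default 50). The packaged reference file
carries the published optimised values.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .data import Dataset
from .errors import ConfigError, DataError
from .markers import MarkerParams
from .model import ModelParameters

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_params",
    "write_params",
    "reference_parameters",
]

_RATE_KEYS = ("mP0P1", "mPN1PN", "mP0G", "mPN1G", "mP0S", "mPN1S", "mP0A", "mPN1A", "mGS", "mAD")
_FRACTION_KEYS = ("PgH2AX", "GKi67", "GgH2AX")


def read_dataset(path) -> Dataset:
    """Read and validate a marker dataset CSV."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise DataError(f"cannot parse {path}: {exc}") from exc
    return Dataset(frame)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset CSV (stable column and row order for a given input)."""
    # %.17g keeps doubles exact across a write/read cycle
    dataset.frame.to_csv(path, index=False, float_format="%.17g")


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            obj = yaml.safe_load(text)
        else:
            obj = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse parameter file {path}: {exc}") from exc
    if not isinstance(obj, dict):
        raise ConfigError(f"parameter file {path} must contain a flat mapping")
    return obj


def params_from_dict(obj: dict) -> tuple[ModelParameters, MarkerParams]:
    """Build (ModelParameters, MarkerParams) from a flat key-value mapping."""
    missing = [k for k in _RATE_KEYS + _FRACTION_KEYS if k not in obj]
    if missing:
        raise ConfigError(f"parameter file missing keys: {missing}")
    try:
        vals = {k: float(obj[k]) for k in _RATE_KEYS + _FRACTION_KEYS}
        n_ages = int(obj.get("N", 50))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"non-numeric parameter value: {exc}") from exc
    for k in _RATE_KEYS:
        if vals[k] < 0:
            raise ConfigError(f"rate {k} must be non-negative, got {vals[k]}")
    for k in _FRACTION_KEYS:
        if not (0.0 <= vals[k] <= 1.0):
            raise ConfigError(f"fraction {k} must lie in [0, 1], got {vals[k]}")
    params = ModelParameters.from_endpoints(
        div=(vals["mP0P1"], vals["mPN1PN"]),
        sen=(vals["mP0S"], vals["mPN1S"]),
        arr=(vals["mP0G"], vals["mPN1G"]),
        apo=(vals["mP0A"], vals["mPN1A"]),
        m_GS=vals["mGS"],
        m_AD=vals["mAD"],
        n_ages=n_ages,
    )
    mparams = MarkerParams(
        frac_P_gH2AX=vals["PgH2AX"],
        frac_G_Ki67=vals["GKi67"],
        frac_G_gH2AX=vals["GgH2AX"],
    )
    return params, mparams


def read_params(path) -> tuple[ModelParameters, MarkerParams]:
    """Read a flat JSON/YAML parameter file (ladders built from endpoints)."""
    return params_from_dict(_load_mapping(path))


def write_params(params: ModelParameters, mparams: MarkerParams, path) -> None:
    """Write parameters to flat JSON or YAML (by file suffix)."""
    ep = params.endpoints()
    obj = {
        "mP0P1": ep["div"][0], "mPN1PN": ep["div"][1],
        "mP0G": ep["arr"][0], "mPN1G": ep["arr"][1],
        "mP0S": ep["sen"][0], "mPN1S": ep["sen"][1],
        "mP0A": ep["apo"][0], "mPN1A": ep["apo"][1],
        "mGS": params.m_GS, "mAD": params.m_AD,
        "N": params.n_ages,
        "PgH2AX": mparams.frac_P_gH2AX,
        "GKi67": mparams.frac_G_Ki67,
        "GgH2AX": mparams.frac_G_gH2AX,
    }
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2) + "\n")


def reference_parameters() -> tuple[ModelParameters, MarkerParams]:
    """The packaged optimised reference parameter set."""
    ref = resources.files("replisen").joinpath("resources/reference_params.json")
    with ref.open() as fh:
        return params_from_dict(json.load(fh))
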