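"""Parameter-set and histogram readers/writers.

Parameter files are JSON or YAML mappings with exactly the
:class:`~loopburst.params.RateParameters` field names; unknown fields are
rejected with a listing rather than silently ignored.  Histograms are CSV
with a required ``protein_count,cells`` header.  Floating-point output uses
17 significant digits so every round trip is exact.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import CellCountHistogram
from .fsp import JointDistribution
from .params import RateParameters, validate_parameters

__all__ = [
    "read_params",
    "write_params",
    "read_histogram",
    "write_histogram",
    "write_joint_distribution",
    "write_protein_marginal",
]

_FIELD_TYPES = {f.name: f for f in fields(RateParameters)}
_BOOL_FIELDS = {"has_aux_operators"}
_INT_FIELDS = {"transcribing_operator"}


def read_params(path: str | Path) -> RateParameters:
    """Read a parameter set from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter fields")
    unknown = sorted(set(raw) - set(_FIELD_TYPES))
    if unknown:
        raise ValueError(f"{path}: unknown parameter field(s): {unknown}")
    required = ["k_a", "k_d1", "nu", "g_m", "k_p", "g_p"]
    missing = [name for name in required if name not in raw]
    if missing:
        raise ValueError(f"{path}: missing required field(s): {missing}")
    clean = {}
    for name, value in raw.items():
        if name in _BOOL_FIELDS:
            if not isinstance(value, bool):
                raise ValueError(f"{path}: field {name} must be boolean")
            clean[name] = value
        elif name in _INT_FIELDS:
            clean[name] = int(value)
        elif value is None:
            clean[name] = None
        else:
            if isinstance(value, bool) or not isinstance(value, (int, float)):
                raise ValueError(f"{path}: field {name} must be numeric, "
                                 f"got {value!r}")
            clean[name] = float(value)
    return validate_parameters(RateParameters(**clean))


def write_params(p: RateParameters, path: str | Path) -> None:
    """Write a parameter set; format chosen by extension (YAML default)."""
    path = Path(path)
    data = p.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


def read_histogram(path: str | Path) -> CellCountHistogram:
    """Read a ``protein_count,cells`` CSV histogram."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty histogram file") from None
    expected = ["protein_count", "cells"]
    if list(df.columns[:2]) != expected:
        raise ValueError(
            f"{path}: expected header {expected!r}, got {list(df.columns)!r}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: histogram has no rows")
    if (df["cells"] < 0).any() or (df["protein_count"] < 0).any():
        raise ValueError(f"{path}: negative values are not allowed")
    pairs = [(int(k), int(v)) for k, v in zip(df["protein_count"], df["cells"])]
    return CellCountHistogram.from_pairs(pairs)


def write_histogram(h: CellCountHistogram, path: str | Path) -> None:
    ks, cs = h.as_arrays()
    pd.DataFrame({"protein_count": ks, "cells": cs}).to_csv(path, index=False)


def write_joint_distribution(dist: JointDistribution, path: str | Path) -> None:
    """Dense CSV export: state,m,n,probability."""
    S, M, N = dist.probs.shape
    s_idx, m_idx, n_idx = np.meshgrid(
        np.arange(S), np.arange(M), np.arange(N), indexing="ij"
    )
    df = pd.DataFrame(
        {
            "state": np.array(dist.state_labels)[s_idx.ravel()],
            "m": m_idx.ravel(),
            "n": n_idx.ravel(),
            "probability": dist.probs.ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def write_protein_marginal(
    pmf: np.ndarray, path: str | Path, column: str = "probability"
) -> None:
    """Protein-marginal CSV export: n,probability (17 significant digits)."""
    pd.DataFrame({"n": np.arange(len(pmf)), column: pmf}).to_csv(
        path, index=False, float_format="%.17g"
    )
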