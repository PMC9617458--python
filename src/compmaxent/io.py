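"""Readers and writers for composition tables and fitted models.

Tables are delimited text (``.tsv`` -> tab, anything else -> comma)
with a header of component names and an optional leading column of
sample identifiers.  Models are JSON documents carrying the full
parameterization (h, K, Q, component names) plus fit metadata, written
at 12+ significant digits so round trips are stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .pseudolikelihood import FitResult
from .types import CMEParameters, CompositionTable

__all__ = [
    "read_composition_table",
    "write_composition_table",
    "write_model",
    "read_model",
]

MODEL_FORMAT = "compmaxent-model"
MODEL_VERSION = 1


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_composition_table(path) -> CompositionTable:
    """Read a CSV/TSV relative-abundance table.

    Rows are samples, columns components; a non-numeric first column is
    taken as sample IDs.  Rows must sum to 1 within tolerance (they are
    renormalized exactly); invalid layouts produce distinct errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = fh.readline().strip()
    fields = [f.strip().strip('"') for f in header.split(_delimiter(path))]
    if len(set(fields)) != len(fields):
        raise ValueError(f"{path}: duplicate component names in header")
    df = pd.read_csv(path, sep=_delimiter(path), float_precision="round_trip")
    if df.shape[0] == 0:
        raise ValueError(f"{path}: table has no data rows")
    sample_ids = None
    first = df.columns[0]
    if not pd.api.types.is_numeric_dtype(df[first]):
        sample_ids = df[first].astype(str).tolist()
        df = df.drop(columns=[first])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 component columns")
    names = [str(c) for c in df.columns]
    if all(_looks_numeric(c) for c in names):
        raise ValueError(
            f"{path}: header row looks numeric; a header of component "
            "names is required"
        )
    if len(set(names)) != len(names):
        raise ValueError(f"{path}: duplicate component names in header")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in table body") from exc
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite cell in table body")
    return CompositionTable(values, names, sample_ids)


def _looks_numeric(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return False
    return True


def write_composition_table(table: CompositionTable, path) -> None:
    """Write a table as delimited text at full float precision.

    Full precision makes write/read an exact round trip (and therefore
    stable well past 12 significant digits).
    """
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.names)
    if table.sample_ids is not None:
        df.insert(0, "sample_id", table.sample_ids)
    df.to_csv(path, sep=_delimiter(path), index=False, float_format="%.17g")


def write_model(result: FitResult, path) -> None:
    """Serialize a fitted model (parameters + fit metadata) to JSON."""
    p = result.params
    doc = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        "n_components": p.n_components,
        "component_names": p.names
        or [f"c{i + 1}" for i in range(p.n_components)],
        "h": p.h.tolist(),
        "K": p.K.tolist(),
        "Q": p.Q.tolist(),
        "fit": {
            "objective_per_node": result.objective_per_node.tolist(),
            "converged": [bool(c) for c in result.converged],
            "n_iter": [int(k) for k in result.n_iter],
            "ridge": result.ridge,
            "seed": result.seed,
            "reference": result.reference,
        },
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_model(path) -> tuple[CMEParameters, dict]:
    """Read a serialized model; returns (parameters, fit metadata)."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: not a valid model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: not a {MODEL_FORMAT} document")
    if doc.get("version") != MODEL_VERSION:
        raise ValueError(
            f"{path}: unsupported model schema version {doc.get('version')!r}"
            f" (expected {MODEL_VERSION})"
        )
    params = CMEParameters(
        h=np.asarray(doc["h"], dtype=float),
        K=np.asarray(doc["K"], dtype=float),
        Q=np.asarray(doc["Q"], dtype=float),
        names=list(doc["component_names"]),
    )
    return params, dict(doc.get("fit", {}))
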