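"""File plumbing shared across the pipeline: tidy-CSV time series and
JSON result documents stamped with version, config hash and seeds."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .timeseries import COLUMNS, validate_timeseries, TimeSeriesError


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    """Write a culture time series as tidy CSV (validated first)."""
    validate_timeseries(df, require_sd="sd" in df.columns)
    df.to_csv(path, index=False)


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read a tidy-CSV culture time series, validating every row.

    Malformed rows are reported with 1-based CSV line numbers.  A missing
    ``sd`` column is accepted with a warning; downstream objectives that need
    per-point weights will refuse such tables.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns and c != "sd"]
    if missing:
        raise TimeSeriesError(f"{path}: missing columns {missing}")
    has_sd = "sd" in df.columns
    if not has_sd:
        warnings.warn(
            f"{path}: no 'sd' column; weighted fitting will require one",
            stacklevel=2,
        )
    bad = df.index[df["value"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # header is line 1
        raise TimeSeriesError(f"{path}: negative concentration at line(s) {lines}")
    try:
        validate_timeseries(df, require_sd=has_sd)
    except TimeSeriesError as exc:
        raise TimeSeriesError(f"{path}: {exc}") from None
    return df


def _jsonify(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_hash(config: dict | None) -> str:
    """Stable short hash of a configuration mapping."""
    payload = json.dumps(_jsonify(config or {}), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_result(
    obj: Any,
    path: str | Path,
    *,
    config: dict | None = None,
    seed: int | None = None,
) -> None:
    """Write a result object as JSON with provenance metadata embedded."""
    doc = {
        "eutflux_version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "result": _jsonify(obj),
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=False) + "\n")


def read_result(path: str | Path) -> dict:
    """Read back a JSON result document (returns the full envelope)."""
    return json.loads(Path(path).read_text())


def derive_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage seed (< 2**31) from a global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
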