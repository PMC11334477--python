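"""Tidy container for replicated culture time courses.

A culture time series is a long-format :class:`pandas.DataFrame` with columns
``replicate, time_h, quantity, label_state, value, sd``:

* ``replicate`` — replicate identifier (int or str);
* ``time_h`` — sampling time in hours;
* ``quantity`` — one of ``biomass`` (gDW/L), ``glycerol``, ``ethanolamine``,
  ``ethanol``, ``acetate``, ``acetaldehyde``, ``ammonium`` (all mM);
* ``label_state`` — ``total`` for label-blind measurements, or the pair
  ``unlabeled`` / ``U-13C`` for species quantified separately by isotopic
  state (e.g. 12C2- vs 13C2-ethanol in a tracer experiment);
* ``value`` — measured concentration;
* ``sd`` — per-point standard deviation used as the fitting weight.
"""

from __future__ import annotations

import pandas as pd

COLUMNS = ["replicate", "time_h", "quantity", "label_state", "value", "sd"]

LABEL_STATES = {"total", "unlabeled", "U-13C"}

QUANTITIES = {
    "biomass",
    "glycerol",
    "ethanolamine",
    "ethanol",
    "acetate",
    "acetaldehyde",
    "ammonium",
}


class TimeSeriesError(ValueError):
    """Raised when a table violates the culture time-series contract."""


def make_timeseries(rows: list[tuple]) -> pd.DataFrame:
    """Build a time-series table from ``(replicate, time_h, quantity,
    label_state, value, sd)`` tuples."""
    return pd.DataFrame(rows, columns=COLUMNS)


def validate_timeseries(df: pd.DataFrame, require_sd: bool = True) -> None:
    """Check the structural invariants of a culture time series.

    Raises :class:`TimeSeriesError` listing every violation found: missing
    columns, unknown quantities or label states, negative values, non-positive
    standard deviations, non-increasing times within a replicate series, or a
    quantity mixing 'total' with split label states within one replicate.
    """
    problems: list[str] = []
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        if "sd" in missing and not require_sd and missing == ["sd"]:
            pass
        else:
            raise TimeSeriesError(f"missing columns: {missing}")

    unknown_q = set(df["quantity"]) - QUANTITIES
    if unknown_q:
        problems.append(f"unknown quantities: {sorted(unknown_q)}")
    unknown_l = set(df["label_state"]) - LABEL_STATES
    if unknown_l:
        problems.append(f"unknown label states: {sorted(unknown_l)}")

    if (df["value"] < 0).any():
        bad = df.index[df["value"] < 0].tolist()[:5]
        problems.append(f"negative values at rows {bad}")
    if require_sd and "sd" in df.columns:
        if df["sd"].isna().any() or (df["sd"] <= 0).any():
            problems.append("sd must be > 0 for every fitted point")

    for (rep, q, ls), grp in df.groupby(["replicate", "quantity", "label_state"]):
        t = grp["time_h"].to_numpy()
        if len(t) > 1 and not (t[1:] > t[:-1]).all():
            problems.append(
                f"times not strictly increasing for replicate={rep!r}, "
                f"quantity={q!r}, label_state={ls!r}"
            )
    for (rep, q), grp in df.groupby(["replicate", "quantity"]):
        states = set(grp["label_state"])
        if "total" in states and states & {"unlabeled", "U-13C"}:
            problems.append(
                f"quantity {q!r} mixes 'total' with split label states "
                f"in replicate {rep!r}"
            )
    if problems:
        raise TimeSeriesError("; ".join(problems))


def series(
    df: pd.DataFrame,
    quantity: str,
    label_state: str = "total",
    replicate=None,
) -> pd.DataFrame:
    """Extract one (quantity, label_state[, replicate]) series sorted by time."""
    m = (df["quantity"] == quantity) & (df["label_state"] == label_state)
    if replicate is not None:
        m &= df["replicate"] == replicate
    return df[m].sort_values(["replicate", "time_h"]).reset_index(drop=True)
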