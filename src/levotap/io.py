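"""Readers and writers for time-series CSV files and parameter documents."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import BgParams, EffectParams, PkParams, SynapticWeights
from .timeseries import TimeSeries

__all__ = ["read_timeseries", "write_timeseries", "load_params",
           "dump_params", "ParseError"]


class ParseError(ValueError):
    """A malformed input file, with enough context to locate the problem."""


def read_timeseries(path, expected_unit: str = "dimensionless",
                    value_column: str | None = None) -> TimeSeries:
    """Read a ``time_min,<value>`` CSV into a validated series.

    Raises :class:`ParseError` naming the offending line for non-monotone
    times, duplicate times, or negative values where the unit forbids them.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if "time_min" not in frame.columns:
        raise ParseError(f"{path}: missing required column 'time_min'")
    if value_column is None:
        candidates = [c for c in frame.columns if c != "time_min"]
        if len(candidates) != 1:
            raise ParseError(
                f"{path}: expected exactly one value column, found {candidates}")
        value_column = candidates[0]
    times = frame["time_min"].to_numpy(dtype=float)
    values = frame[value_column].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)) or np.any(~np.isfinite(values)):
        bad = int(np.argmax(~(np.isfinite(times) & np.isfinite(values))))
        raise ParseError(f"{path}: non-numeric entry at line {bad + 2}")
    diffs = np.diff(times)
    if np.any(diffs == 0):
        line = int(np.flatnonzero(diffs == 0)[0]) + 3
        raise ParseError(f"{path}: duplicate time at line {line}")
    if np.any(diffs < 0):
        line = int(np.flatnonzero(diffs < 0)[0]) + 3
        raise ParseError(f"{path}: non-monotone time at line {line}")
    try:
        return TimeSeries(times, values, expected_unit, name=value_column)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_timeseries(ts: TimeSeries, path) -> None:
    ts.to_frame().to_csv(path, index=False, float_format="%.12g")


_PARAM_TYPES = {
    "pk": PkParams,
    "effect": EffectParams,
    "bg": BgParams,
    "weights": SynapticWeights,
}


def _load_document(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_params(path, kind: str):
    """Load a parameter document (YAML or JSON) as the requested type.

    ``kind`` is one of ``"pk"``, ``"effect"``, ``"bg"``, ``"weights"``.
    Field names mirror the dataclass fields; validation (positivity, sign
    patterns of the synaptic weights) runs in the type constructors, so a
    wrong-sign weight or missing field surfaces as a descriptive error.
    """
    if kind not in _PARAM_TYPES:
        raise ValueError(f"unknown parameter kind {kind!r}")
    cls = _PARAM_TYPES[kind]
    doc = _load_document(path)
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: expected a mapping of parameter fields")
    field_names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(doc) - field_names
    if unknown:
        raise ParseError(f"{path}: unknown fields {sorted(unknown)}")
    required = {f.name for f in dataclasses.fields(cls)
                if f.default is dataclasses.MISSING
                and f.default_factory is dataclasses.MISSING}
    missing = required - set(doc)
    if missing:
        raise ParseError(f"{path}: missing required fields {sorted(missing)}")
    try:
        return cls(**doc)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def dump_params(params, path) -> None:
    """Write a parameter dataclass to YAML (arrays as nested lists)."""
    doc = {}
    for f in dataclasses.fields(params):
        value = getattr(params, f.name)
        if isinstance(value, np.ndarray):
            value = value.tolist()
        doc[f.name] = value
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
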