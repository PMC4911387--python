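"""Sampled (time, value) signals used throughout the pipeline.

A :class:`TimeSeries` carries plasma concentration c1 [ug/ml], effect-site
concentration c3 [ug/ml], the dimensionless dopaminergic input D, or tapping
frequency [taps/min], together with a unit tag.  Times are minutes unless a
caller says otherwise; the basal-ganglia simulator keeps its own millisecond
clock and never goes through this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TimeSeries"]

#: units for which negative sample values are physically impossible
_NONNEGATIVE_UNITS = {"ug/ml", "taps/min"}


@dataclass(frozen=True)
class TimeSeries:
    """An irregularly sampled scalar signal with a unit tag.

    Parameters
    ----------
    times:
        Sample times, strictly increasing. Minutes by convention.
    values:
        Sampled quantity, same length as ``times``.
    unit:
        One of ``"ug/ml"``, ``"taps/min"``, ``"dimensionless"`` or any
        caller-defined tag.  Concentration- and count-valued units are
        validated as non-negative.
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "dimensionless"
    name: str = field(default="value", compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or v.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if t.shape != v.shape:
            raise ValueError(
                f"length mismatch: {t.size} times vs {v.size} values")
        if t.size and np.any(np.diff(t) <= 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise ValueError(
                f"times must be strictly increasing (violated at index {bad})")
        if self.unit in _NONNEGATIVE_UNITS and t.size and np.any(v < 0):
            raise ValueError(f"negative values not allowed for unit {self.unit!r}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size

    def interp(self, at: np.ndarray, left: float | None = None,
               right: float | None = None) -> np.ndarray:
        """Linear interpolation; end values are held unless overridden."""
        return np.interp(np.asarray(at, dtype=float), self.times, self.values,
                         left=left, right=right)

    def with_values(self, values: np.ndarray, unit: str | None = None,
                    name: str | None = None) -> "TimeSeries":
        return TimeSeries(self.times, values,
                          self.unit if unit is None else unit,
                          self.name if name is None else name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_min": self.times, self.name: self.values})
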