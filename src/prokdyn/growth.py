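"""Growth and product-formation summaries.

The central quantity is the specific product formation rate q: product
formed over a sampling interval, normalized to the mean cell dry weight on
the interval and to its duration,

    q_i = (P_i - P_{i-1}) / ( (X_i + X_{i-1})/2 * (t_i - t_{i-1}) )

in g(product) g(CDW)^-1 h^-1.  q is a direct, history-free indicator of
production activity over a defined period.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASES = ("lag", "growth", "transition", "stationary")


@dataclass
class GrowthSeries:
    """Time course of cell dry weight X (g/L) and product P (g/L)."""

    t: np.ndarray
    X: np.ndarray
    P: np.ndarray
    replicate: str = "mean"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if not (len(self.t) == len(self.X) == len(self.P)):
            raise ValueError("t, X, P must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if np.any(self.X < 0) or np.any(self.P < 0):
            raise ValueError("X and P must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, "X": self.X, "P": self.P,
                             "replicate": self.replicate})


@dataclass(frozen=True)
class RateInterval:
    t_start: float
    t_end: float
    q: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")


def specific_product_formation(series: GrowthSeries) -> list[RateInterval]:
    """One rate per consecutive sampling-interval pair.

    Mean CDW on an interval is the arithmetic mean of the two endpoint
    values.  Raises if the mean CDW on any interval is zero (undefined rate).
    """
    if len(series.t) < 2:
        raise ValueError("need at least 2 time points")
    out = []
    for i in range(1, len(series.t)):
        mean_x = 0.5 * (series.X[i] + series.X[i - 1])
        dt = series.t[i] - series.t[i - 1]
        if mean_x <= 0:
            raise ZeroDivisionError(
                f"zero mean CDW on interval [{series.t[i-1]}, {series.t[i]}]")
        q = (series.P[i] - series.P[i - 1]) / (mean_x * dt)
        out.append(RateInterval(float(series.t[i - 1]), float(series.t[i]), float(q)))
    return out


def rates_to_frame(rates: list[RateInterval]) -> pd.DataFrame:
    return pd.DataFrame({"t_start": [r.t_start for r in rates],
                         "t_end": [r.t_end for r in rates],
                         "q": [r.q for r in rates]})


def annotate_phases(t: np.ndarray, boundaries: tuple[float, float, float]) -> list[str]:
    """Label each time point with its growth phase.

    ``boundaries`` = (lag_end, growth_end, transition_end); labels follow
    the convention t <= lag_end -> lag; lag_end < t < growth_end -> growth;
    growth_end <= t <= transition_end -> transition; t > transition_end ->
    stationary.  Times outside [0, transition_end + anything] simply land in
    the nearest phase; negative times draw a warning.
    """
    t = np.asarray(t, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    b1, b2, b3 = boundaries
    if not (b1 < b2 < b3):
        raise ValueError("phase boundaries must be ordered")
    labels = []
    for ti in t:
        if ti < 0:
            warnings.warn(f"time {ti} outside configured range; labeled lag")
            labels.append("lag")
        elif ti <= b1:
            labels.append("lag")
        elif ti < b2:
            labels.append("growth")
        elif ti <= b3:
            labels.append("transition")
        else:
            labels.append("stationary")
    return labels
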