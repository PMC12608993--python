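"""Stratification of camera sites along disturbance gradients, and seasons.

Sites are split into three classes per covariate — either at explicit
breakpoints (the study defaults below) or at the first and third quartiles of
the observed distribution (linear-interpolation quantiles).  The middle class
is the closed interval [lower, upper]; values strictly below the lower break
take the first label and values strictly above the upper break take the
third, matching the "<a, a-b, >b" style of printed class definitions.

Detections are also split into a warm season (May-October) and a cold season
(the remaining months).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime

import numpy as np

#: Study-default schemes: covariate -> (breaks, labels).  Human presence is
#: in detections per 100 trap-days; distances and altitude in metres.
DEFAULT_SCHEMES: dict[str, tuple[tuple[float, float], tuple[str, str, str]]] = {
    "human_presence": ((1.98, 4.39), ("low", "moderate", "high")),
    "dist_settlement": ((500.0, 1000.0), ("near", "moderate", "far")),
    "dist_road": ((400.0, 1000.0), ("near", "moderate", "far")),
    "altitude": ((500.0, 800.0), ("low", "moderate", "high")),
}

WARM_MONTHS = range(5, 11)  # May through October, inclusive


@dataclass(frozen=True)
class StratumScheme:
    """Three-class split of a covariate at two breakpoints."""

    covariate: str
    breaks: tuple[float, float]
    labels: tuple[str, str, str]
    mode: str = "explicit"  # or "quartile"

    def __post_init__(self) -> None:
        if not self.breaks[0] < self.breaks[1]:
            raise ValueError("breaks must satisfy lower < upper")
        if len(self.labels) != 3:
            raise ValueError("exactly three class labels required")

    @classmethod
    def from_quartiles(
        cls,
        covariate: str,
        values: np.ndarray,
        labels: tuple[str, str, str] = ("low", "moderate", "high"),
    ) -> "StratumScheme":
        return cls(covariate, quartile_breaks(values), labels, mode="quartile")


def quartile_breaks(values: np.ndarray) -> tuple[float, float]:
    """First and third quartiles by the linear-interpolation convention."""
    values = np.asarray(values, dtype=float)
    if np.unique(values).size < 4:
        raise ValueError("quartile breaks need at least 4 distinct values")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # method='linear' (type 7)
    if q1 == q3:
        raise ValueError("degenerate stratification: Q1 equals Q3")
    return float(q1), float(q3)


def assign_stratum(value: float, scheme: StratumScheme) -> str:
    """Class label for a covariate value; the middle class is closed."""
    if value != value:  # NaN: missing covariate
        raise ValueError(f"missing {scheme.covariate} value")
    lo, hi = scheme.breaks
    if value < lo:
        return scheme.labels[0]
    if value > hi:
        return scheme.labels[2]
    return scheme.labels[1]


def season_of(d: date | datetime) -> str:
    """'warm' for May-October, 'cold' otherwise."""
    return "warm" if d.month in WARM_MONTHS else "cold"


def default_schemes() -> list[StratumScheme]:
    """The study's printed breakpoints as ready-made schemes."""
    return [
        StratumScheme(cov, breaks, labels)
        for cov, (breaks, labels) in DEFAULT_SCHEMES.items()
    ]
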