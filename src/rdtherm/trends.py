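"""Temperature-series aggregation and trend fits.

Collects per-structure scalars (water count, unit-cell volume, grid protein
volume) into series ordered by temperature, fits linear expansion trends
(slope, relative %/100 K, endpoint percent change) and a continuous
two-segment piecewise-linear changepoint — the tool used to locate the
~240 K drop in crystallographically ordered waters associated with the
protein dynamical transition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import protein_volume, unit_cell_volume
from .structure import StructureModel, water_count

logger = logging.getLogger(__name__)

METRICS = ("waters", "cell_volume", "protein_volume")


@dataclass(frozen=True)
class ThermalSeries:
    """(temperature, value) records for one metric, temperatures increasing."""

    temperatures: np.ndarray
    values: np.ndarray
    metric: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("temperatures and values must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"temperature_K": self.temperatures,
                             f"{self.metric or 'value'}": self.values})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExpansionFit:
    """OLS linear trend of a thermal series.

    `relative_slope` is expressed in % per 100 K relative to the fitted
    value at the series' minimum temperature; `endpoint_percent_change`
    uses the raw first/last values.
    """

    slope: float
    intercept: float
    relative_slope: float  # % per 100 K
    endpoint_percent_change: float
    residual_sd: float
    t_min: float

    def fitted(self, t: float) -> float:
        return self.intercept + self.slope * t


@dataclass(frozen=True)
class ChangepointFit:
    """Continuous two-segment piecewise-linear fit with scanned breakpoint."""

    breakpoint: float
    left_slope: float
    right_slope: float
    sse: float
    single_line_sse: float
    no_changepoint: bool


def collect_series(models: list[StructureModel], metric: str) -> ThermalSeries:
    """One record per model, sorted by temperature.

    metric ∈ {waters, cell_volume, protein_volume}.  Invariant to the
    order in which models are supplied.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if not models:
        raise ValueError("no models supplied")
    records = []
    for m in models:
        if metric == "waters":
            v = float(water_count(m))
        elif metric == "cell_volume":
            if m.cell is None:
                raise ValueError(
                    f"structure {m.label or m.temperature} has no unit cell")
            v = unit_cell_volume(m.cell)
        else:
            v = protein_volume(m)
        records.append((m.temperature, v))
    records.sort()
    t, v = zip(*records)
    units = {"waters": "count", "cell_volume": "A^3",
             "protein_volume": "A^3"}[metric]
    return ThermalSeries(np.array(t), np.array(v), metric=metric, units=units)


def expansion_fit(series: ThermalSeries) -> ExpansionFit:
    """Ordinary least squares value ~ temperature.

    relative slope = 100 · slope · 100 / fitted(T_min), in % per 100 K —
    the convention matching "from T_min to T_max we observed an x% increase".
    """
    if len(series) < 2:
        raise ValueError("expansion fit needs at least 2 points")
    t, v = series.temperatures, series.values
    res = stats.linregress(t, v)
    fitted = res.intercept + res.slope * t
    n = len(t)
    residual_sd = (math.sqrt(float(((v - fitted) ** 2).sum()) / (n - 2))
                   if n > 2 else 0.0)
    v_at_tmin = res.intercept + res.slope * t[0]
    if v_at_tmin == 0:
        raise ValueError("fitted value at minimum temperature is zero")
    return ExpansionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        relative_slope=float(100.0 * res.slope * 100.0 / v_at_tmin),
        endpoint_percent_change=float(100.0 * (v[-1] - v[0]) / v[0]),
        residual_sd=residual_sd,
        t_min=float(t[0]),
    )


def _piecewise_sse(t: np.ndarray, v: np.ndarray, b: float
                   ) -> tuple[float, float, float]:
    """LSQ fit of v = c0 + c1·t + c2·max(0, t−b); returns (sse, left, right)."""
    X = np.column_stack([np.ones_like(t), t, np.maximum(0.0, t - b)])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    return float(resid @ resid), float(coef[1]), float(coef[1] + coef[2])


def changepoint_fit(series: ThermalSeries, grid_step: float = 1.0,
                    flat_tol: float = 1e-8) -> ChangepointFit:
    """Continuous two-segment piecewise-linear fit with exhaustive scan.

    The breakpoint is scanned on a `grid_step` (default 1 K) grid between
    the 2nd and (n−1)th temperatures, minimizing total squared error; ties
    resolve to the lowest breakpoint.  If the best two-segment SSE improves
    on a single line by less than `flat_tol` (relative), the result is
    flagged `no_changepoint`.
    """
    if len(series) < 5:
        raise ValueError("changepoint fit needs at least 5 points")
    t, v = series.temperatures, series.values
    grid = np.arange(math.ceil(t[1] / grid_step) * grid_step,
                     t[-2] + grid_step / 2, grid_step)
    grid = grid[(grid >= t[1]) & (grid <= t[-2])]
    if grid.size == 0:
        grid = np.array([(t[1] + t[-2]) / 2.0])
    best = None
    for b in grid:
        sse, left, right = _piecewise_sse(t, v, float(b))
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(b), left, right)
    sse, b, left, right = best
    X1 = np.column_stack([np.ones_like(t), t])
    coef1, *_ = np.linalg.lstsq(X1, v, rcond=None)
    r1 = v - X1 @ coef1
    sse_line = float(r1 @ r1)
    flat = (sse_line - sse) <= flat_tol * max(1.0, sse_line)
    if flat:
        logger.info("changepoint indistinguishable from a single line "
                    "(ΔSSE=%.3g)", sse_line - sse)
    return ChangepointFit(breakpoint=b, left_slope=left, right_slope=right,
                          sse=sse, single_line_sse=sse_line,
                          no_changepoint=bool(flat))
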