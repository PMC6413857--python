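"""Fit the cumulative outlet fraction versus distance-to-school.

The discrete buffer histogram is turned into a continuous curve -- the
empirical CDF evaluated at bin upper edges, with the exact-zero spike merged
into the first point -- and ordinary least squares is run on each of the
four axis-scale combinations (linear/log x linear/log).  On the log-log
scale the slope is the power-law exponent; R^2 is the standard coefficient
of determination and the p-value comes from the slope's t statistic.  Fits
are produced overall and per deprivation tertile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .network_distances import BufferCurve, buffer_curve, DEFAULT_BIN_EDGES

logger = logging.getLogger(__name__)

SCALE_COMBOS = (("linear", "linear"), ("linear", "log"),
                ("log", "linear"), ("log", "log"))


@dataclass
class ContinuousCurve:
    """Cumulative fraction of outlets within each distance ``x`` (meters)."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.y) < -1e-12):
            raise ValueError("cumulative fractions must be non-decreasing")
        if np.any((self.y < -1e-12) | (self.y > 1 + 1e-12)):
            raise ValueError("fractions outside [0, 1]")


@dataclass
class FitResult:
    x_scale: str
    y_scale: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    tertile: str = "overall"  # overall | 1 | 2 | 3


def to_continuous(curve: BufferCurve) -> ContinuousCurve:
    """Empirical CDF at bin upper edges; the zero spike merges into the
    first positive edge so the x grid stays strictly positive (log-safe)."""
    edges = np.asarray(curve.bin_edges, dtype=float)
    pos_edges = edges[edges > 0]
    if pos_edges.size == 0:
        raise ValueError("no positive bin edge")
    frac = np.asarray(curve.fraction_within, dtype=float)
    y = frac[edges > 0]
    if curve.zero_count == curve.n_finite:
        raise ValueError("all mass at zero distance: log fit impossible")
    return ContinuousCurve(x=pos_edges, y=y)


def fit(curve: ContinuousCurve, x_scale: str, y_scale: str) -> FitResult:
    """OLS on the transformed coordinates of ``curve``."""
    if x_scale not in ("linear", "log") or y_scale not in ("linear", "log"):
        raise ValueError("scales must be 'linear' or 'log'")
    x = curve.x
    y = curve.y
    keep = np.ones(len(x), dtype=bool)
    if x_scale == "log" or y_scale == "log":
        if x_scale == "log" and np.any(x <= 0):
            raise ValueError("non-positive x under log transform")
        if y_scale == "log":
            keep = y > 0  # leading empty bins carry no information on a log axis
            if keep.sum() < 3:
                raise ValueError("fewer than 3 positive y values for log fit")
    x = np.log(x[keep]) if x_scale == "log" else x[keep]
    y = np.log(curve.y[keep]) if y_scale == "log" else curve.y[keep]
    if len(x) < 3:
        raise ValueError("need >= 3 points to fit")
    res = stats.linregress(x, y)
    return FitResult(
        x_scale=x_scale, y_scale=y_scale,
        slope=float(res.slope), intercept=float(res.intercept),
        r_squared=float(res.rvalue**2), p_value=float(res.pvalue),
    )


def fit_all(
    distances_by_tertile: Mapping[str, Iterable[float]],
    bin_edges: Sequence[float] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Four fits per stratum (overall + tertiles) of outlet-school distances.

    ``distances_by_tertile`` maps stratum labels ("1", "2", "3") to distance
    samples; the overall stratum is their union.  Empty or degenerate strata
    are skipped with a log entry.  Returns a table shaped like
    (tertile, x_scale, y_scale, slope, intercept, r_squared, p_value).
    """
    strata: dict[str, list[float]] = {"overall": []}
    for label, values in distances_by_tertile.items():
        vals = [float(v) for v in values if np.isfinite(v)]
        strata[str(label)] = vals
        strata["overall"].extend(vals)
    rows = []
    for label in ["overall"] + sorted(k for k in strata if k != "overall"):
        vals = strata[label]
        if not vals:
            logger.warning("stratum %s empty: skipped", label)
            continue
        try:
            curve = to_continuous(buffer_curve(vals, bin_edges))
        except ValueError as exc:
            logger.warning("stratum %s: %s", label, exc)
            continue
        for xs, ys in SCALE_COMBOS:
            try:
                result = fit(curve, xs, ys)
            except ValueError as exc:
                logger.warning("stratum %s %s-%s fit failed: %s", label, xs, ys, exc)
                continue
            rows.append({
                "tertile": label, "x_scale": xs, "y_scale": ys,
                "slope": result.slope, "intercept": result.intercept,
                "r_squared": result.r_squared, "p_value": result.p_value,
            })
    return pd.DataFrame(rows)
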