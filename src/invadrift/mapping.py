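"""Map products: Jenks natural-breaks classification and progression tables.

Settlement-count rasters are classed for hot/cold display with the Fisher
optimal 1-D partition (exactly minimal within-class sum of squared
deviations), the method behind "Jenks natural breaks" in desktop GIS.
Rendering is left to the caller; the tested artifacts are the break
values, the class raster and the step table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import SimulationResult
from .validation import quadrant_sequence

__all__ = [
    "MapClassification",
    "jenks_breaks",
    "classify_raster",
    "progression_map",
]


@dataclass
class MapClassification:
    """Class breaks plus the per-cell class assignment.

    ``breaks`` has k+1 values: the data minimum followed by each class's
    maximum.  Class maxima are strictly increasing; the leading minimum
    equals the first maximum only when the lowest class is a singleton.
    ``class_index`` is −1 for cells outside the classified data (zeros and
    land), else 0..k−1.
    """

    breaks: list[float]
    class_index: np.ndarray
    k: int


def jenks_breaks(values, k: int) -> list[float]:
    """Fisher optimal partition of 1-D data into k contiguous classes.

    Returns k+1 break values ``[min, upper_1, ..., upper_k]`` (jenkspy
    convention) minimizing the total within-class sum of squared
    deviations.  Requires at least k distinct values.
    """
    values = np.sort(np.asarray(values, dtype=float).ravel())
    if values.size == 0:
        raise ValueError("no values to classify")
    if k < 1:
        raise ValueError("k must be >= 1")
    distinct, counts = np.unique(values, return_counts=True)
    n = distinct.size
    if k > n:
        raise ValueError(f"k={k} exceeds {n} distinct values")

    # weighted prefix sums over distinct values
    w = counts.astype(float)
    cw = np.concatenate([[0.0], np.cumsum(w)])
    cwx = np.concatenate([[0.0], np.cumsum(w * distinct)])
    cwx2 = np.concatenate([[0.0], np.cumsum(w * distinct * distinct)])

    def sse(i: int, j: int) -> float:
        """Within-class SSE of distinct[i..j] inclusive, with counts."""
        W = cw[j + 1] - cw[i]
        S = cwx[j + 1] - cwx[i]
        S2 = cwx2[j + 1] - cwx2[i]
        return S2 - S * S / W

    INF = float("inf")
    # cost[c][j]: minimal SSE of distinct[0..j] split into c+1 classes
    cost = np.full((k, n), INF)
    cut = np.zeros((k, n), dtype=int)
    for j in range(n):
        cost[0, j] = sse(0, j)
    for c in range(1, k):
        for j in range(c, n):
            best, arg = INF, c
            for i in range(c, j + 1):
                v = cost[c - 1, i - 1] + sse(i, j)
                if v < best:
                    best, arg = v, i
            cost[c, j] = best
            cut[c, j] = arg
    # recover class upper bounds
    uppers = []
    j = n - 1
    for c in range(k - 1, -1, -1):
        uppers.append(distinct[j])
        if c > 0:
            j = cut[c, j] - 1
    uppers.reverse()
    return [float(distinct[0])] + [float(u) for u in uppers]


def classify_raster(raster: np.ndarray, k: int,
                    include_zeros: bool = False) -> MapClassification:
    """Jenks-class the nonzero (by default) cells of a count raster."""
    raster = np.asarray(raster, dtype=float)
    mask = np.isfinite(raster) & (include_zeros | (raster != 0))
    values = raster[mask]
    breaks = jenks_breaks(values, k)
    uppers = np.asarray(breaks[1:])
    idx = np.full(raster.shape, -1, dtype=int)
    idx[mask] = np.clip(np.searchsorted(uppers, raster[mask], side="left"), 0, k - 1)
    return MapClassification(breaks=breaks, class_index=idx, k=k)


def progression_map(result: SimulationResult, quadrant_deg: float = 0.5,
                    n_steps: int | None = None) -> pd.DataFrame:
    """Ordered invasion-step table: step number, establishment cycle and
    quadrant centroid coordinates, for plotting sequence(month) labels."""
    seq = quadrant_sequence(result, quadrant_deg)
    rows = []
    steps = seq.steps if n_steps is None else seq.steps[:n_steps]
    for i, (quad, cycle) in enumerate(steps, start=1):
        lat, lon = seq.centroid(quad)
        rows.append((i, cycle, lat, lon))
    return pd.DataFrame(rows, columns=["step", "cycle", "lat", "lon"])
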