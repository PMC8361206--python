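"""SDM training-data preparation.

Spatial thinning of presence records, accessible-area construction
(buffered bounding boxes), and pseudoabsence sampling constrained to the
accessible area.  Distances are Euclidean in planar km.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .raster import RasterGrid

__all__ = [
    "AccessibleArea",
    "thinning_distance_rule",
    "thin_occurrences",
    "accessible_area",
    "sample_pseudoabsences",
]

OCCURRENCE_COLUMNS = ["species_id", "x", "y", "provenance"]


@dataclass
class AccessibleArea:
    """Axis-aligned box assumed reachable by a species."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if not (self.xmin < self.xmax and self.ymin < self.ymax):
            raise ValueError("degenerate accessible area")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= self.xmin) & (x <= self.xmax) & (y >= self.ymin) & (y <= self.ymax)


def thinning_distance_rule(n_records: int) -> float:
    """Thinning distance (km) as a function of record count.

    1 km below 100 records, 5 km above 10,000, log-linear in between:
    ``1 + 2 * (log10(n) - 2)`` km, clamped to [1, 5].
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    if n_records < 100:
        return 1.0
    return float(np.clip(1.0 + 2.0 * (np.log10(n_records) - 2.0), 1.0, 5.0))


def _thin_one_species(
    xy: np.ndarray, distance: float, n_repeats: int, rng: np.random.Generator
) -> np.ndarray:
    """Randomized repeated-elimination thinning; returns retained row indices.

    Each pass repeatedly removes a random record among those with the most
    remaining too-close neighbours until no conflicts remain; the pass
    retaining the most records wins (ties: first such pass).
    """
    n = len(xy)
    if n <= 1:
        return np.arange(n)
    conflict = squareform(pdist(xy) < distance).astype(bool)
    np.fill_diagonal(conflict, False)
    if not conflict.any():
        return np.arange(n)
    best: np.ndarray | None = None
    for _ in range(max(1, n_repeats)):
        alive = np.ones(n, dtype=bool)
        counts = conflict.sum(axis=1).astype(int)
        while True:
            max_c = counts[alive].max() if alive.any() else 0
            if max_c == 0:
                break
            candidates = np.flatnonzero(alive & (counts == max_c))
            victim = int(rng.choice(candidates))
            alive[victim] = False
            counts[conflict[victim] & alive] -= 1
            counts[victim] = 0
        retained = np.flatnonzero(alive)
        if best is None or len(retained) > len(best):
            best = retained
    return best


def thin_occurrences(
    table: pd.DataFrame, distance: float, n_repeats: int = 25, seed: int = 0
) -> pd.DataFrame:
    """Spatially thin records so no two retained conspecific records are
    closer than ``distance`` km.

    Thinning is per species, via randomized repeated elimination
    (``n_repeats`` passes, best pass kept); deterministic given ``seed``.
    An empty table returns empty.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if table.empty:
        return table.copy()
    rng = np.random.default_rng(seed)
    kept_parts = []
    for _, sub in table.groupby("species_id", sort=True):
        idx = _thin_one_species(
            sub[["x", "y"]].to_numpy(float), distance, n_repeats, rng
        )
        kept_parts.append(sub.iloc[np.sort(idx)])
    return pd.concat(kept_parts).sort_index()


def accessible_area(
    table: pd.DataFrame,
    buffer_km: float = 300.0,
    extent: RasterGrid | None = None,
) -> AccessibleArea:
    """Bounding box of the records expanded by ``buffer_km`` on every side,
    clipped to the raster extent when one is supplied."""
    if table.empty:
        raise ValueError("cannot build an accessible area from an empty table")
    x = table["x"].to_numpy(float)
    y = table["y"].to_numpy(float)
    xmin, xmax = x.min() - buffer_km, x.max() + buffer_km
    ymin, ymax = y.min() - buffer_km, y.max() + buffer_km
    if extent is not None:
        xmin = max(xmin, extent.xmin)
        xmax = min(xmax, extent.xmax)
        ymin = max(ymin, extent.ymin)
        ymax = min(ymax, extent.ymax)
    return AccessibleArea(xmin=xmin, xmax=xmax, ymin=ymin, ymax=ymax)


def sample_pseudoabsences(
    area: AccessibleArea,
    n: int,
    presence_cells: set[tuple[int, int]],
    mask: RasterGrid,
    seed: int = 0,
    species_id: str = "",
) -> pd.DataFrame:
    """Sample ``n`` pseudoabsence points uniformly over valid cells.

    Valid cells are non-NaN cells of ``mask`` whose centres fall inside
    ``area``, excluding ``presence_cells`` (a set of (row, col) pairs).
    Cells are drawn without replacement and points placed at cell centres.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    xs = mask.x_centers
    ys = mask.y_centers
    cc, rr = np.meshgrid(np.arange(mask.n_cols), np.arange(mask.n_rows))
    inside = area.contains(xs[cc], ys[rr]) & ~np.isnan(mask.data)
    free = [
        (r, c)
        for r, c in zip(rr[inside].ravel(), cc[inside].ravel())
        if (r, c) not in presence_cells
    ]
    if len(free) < n:
        raise ValueError(
            f"cannot sample {n} pseudoabsences: only {len(free)} free cells "
            f"(shortfall {n - len(free)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(free), size=n, replace=False)
    rows = [free[i] for i in chosen]
    return pd.DataFrame(
        [(species_id, xs[c], ys[r], "pseudoabsence") for r, c in rows],
        columns=OCCURRENCE_COLUMNS,
    )
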