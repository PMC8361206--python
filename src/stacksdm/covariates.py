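"""Earth-observation-style covariate derivation and comparison.

Derives the 19 standard bioclimatic variables (BIO1-BIO19) from monthly
minimum/maximum temperature and precipitation stacks, leaf-area-index (LAI)
annual-cycle composites, integer-factor downscaling, and layer similarity
(Schoener's D and Spearman's rho).

Quarters are the 12 contiguous 3-month windows including wrap-around
(Dec-Jan-Feb etc.), the convention of ANUCLIM and the dismo ``biovars``
implementation.  Monthly mean temperature is (tmin + tmax) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.stats import spearmanr

from .raster import RasterGrid

__all__ = [
    "MonthlyClimateStack",
    "BioclimStack",
    "LAIComposite",
    "LayerSimilarity",
    "derive_bioclim",
    "derive_lai_composites",
    "downscale",
    "compare_layers",
    "schoener_d",
]

BIOCLIM_NAMES = tuple(f"bio{i}" for i in range(1, 20))


@dataclass
class MonthlyClimateStack:
    """12 monthly layers each of tmin, tmax (degC) and precipitation (mm)."""

    tmin: list[RasterGrid]
    tmax: list[RasterGrid]
    precip: list[RasterGrid]

    def __post_init__(self) -> None:
        for name, layers in (("tmin", self.tmin), ("tmax", self.tmax), ("precip", self.precip)):
            if len(layers) != 12:
                raise ValueError(f"{name} must have exactly 12 monthly layers")
        ref = self.tmin[0]
        for layer in [*self.tmin, *self.tmax, *self.precip]:
            if not ref.same_geometry(layer):
                raise ValueError("monthly layers are not on a common grid")
        tmin = np.stack([g.data for g in self.tmin])
        tmax = np.stack([g.data for g in self.tmax])
        if np.any(tmax < tmin):
            raise ValueError("tmax < tmin in at least one cell-month")

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.stack([g.data for g in self.tmin]),
            np.stack([g.data for g in self.tmax]),
            np.stack([g.data for g in self.precip]),
        )


@dataclass
class BioclimStack:
    """The 19 bioclimatic layers, keyed ``bio1`` .. ``bio19``.

    Temperature layers are in degC (bio4 is sd x 100, bio3 a percentage),
    precipitation layers in mm (bio15 a coefficient of variation in %).
    """

    layers: dict[str, RasterGrid]

    def __getitem__(self, key: str) -> RasterGrid:
        return self.layers[key]

    def __iter__(self):
        return iter(BIOCLIM_NAMES)


@dataclass
class LAIComposite:
    cumulative: RasterGrid   # annual sum of the monthly climatology
    minimum: RasterGrid      # cell-wise minimum of the monthly climatology
    seasonality: RasterGrid  # CV (%) of the monthly climatology


@dataclass
class LayerSimilarity:
    schoener_d: float
    spearman_rho: float | None


def _quarter_windows(x: np.ndarray, reducer) -> np.ndarray:
    """Apply ``reducer`` over the 12 wrap-around 3-month windows.

    ``x`` has shape (12, ...); the result has shape (12, ...), window ``i``
    covering months i, i+1, i+2 (mod 12).
    """
    stacked = np.stack(
        [reducer(np.stack([x[i], x[(i + 1) % 12], x[(i + 2) % 12]]), axis=0) for i in range(12)]
    )
    return stacked


def derive_bioclim(
    stack: MonthlyClimateStack, precip_cv_dialect: str = "plus-one"
) -> BioclimStack:
    """Derive BIO1-BIO19 from a monthly climate stack.

    ``precip_cv_dialect`` controls BIO15: ``"plus-one"`` (the dismo/biovars
    dialect) computes ``100 * sd(p) / (1 + mean(p))``, which is finite for
    all-zero precipitation; ``"raw"`` computes ``100 * sd(p) / mean(p)``.
    Standard deviations use the sample convention (ddof = 1).  Quarter
    selections (wettest/driest/warmest/coldest) take the first window
    attaining the extreme.
    """
    if precip_cv_dialect not in ("plus-one", "raw"):
        raise ValueError("precip_cv_dialect must be 'plus-one' or 'raw'")
    tmin, tmax, prec = stack.arrays()
    geom = stack.tmin[0]
    tmean = (tmin + tmax) / 2.0

    q_temp = _quarter_windows(tmean, np.mean)   # quarter mean temperature
    q_prec = _quarter_windows(prec, np.sum)     # quarter total precipitation

    wettest = np.argmax(q_prec, axis=0)
    driest = np.argmin(q_prec, axis=0)
    warmest = np.argmax(q_temp, axis=0)
    coldest = np.argmin(q_temp, axis=0)

    def pick(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
        return np.take_along_axis(values, idx[None, ...], axis=0)[0]

    out: dict[str, np.ndarray] = {}
    out["bio1"] = tmean.mean(axis=0)
    out["bio2"] = (tmax - tmin).mean(axis=0)
    out["bio4"] = tmean.std(axis=0, ddof=1) * 100.0
    out["bio5"] = tmax.max(axis=0)
    out["bio6"] = tmin.min(axis=0)
    out["bio7"] = out["bio5"] - out["bio6"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["bio3"] = np.where(out["bio7"] > 0, 100.0 * out["bio2"] / out["bio7"], 0.0)
    out["bio8"] = pick(q_temp, wettest)
    out["bio9"] = pick(q_temp, driest)
    out["bio10"] = pick(q_temp, warmest)
    out["bio11"] = pick(q_temp, coldest)
    out["bio12"] = prec.sum(axis=0)
    out["bio13"] = prec.max(axis=0)
    out["bio14"] = prec.min(axis=0)
    p_sd = prec.std(axis=0, ddof=1)
    p_mean = prec.mean(axis=0)
    if precip_cv_dialect == "plus-one":
        out["bio15"] = 100.0 * p_sd / (1.0 + p_mean)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            out["bio15"] = np.where(p_mean > 0, 100.0 * p_sd / p_mean, 0.0)
    out["bio16"] = pick(q_prec, wettest)
    out["bio17"] = pick(q_prec, driest)
    out["bio18"] = pick(q_prec, warmest)
    out["bio19"] = pick(q_prec, coldest)
    return BioclimStack(
        layers={name: geom.like(out[name], name=name) for name in BIOCLIM_NAMES}
    )


def derive_lai_composites(
    monthly_lai: list[RasterGrid], months: list[int]
) -> LAIComposite:
    """LAI composites from multi-year monthly layers.

    ``months[i]`` is the calendar month (1-12) of ``monthly_lai[i]``.  The
    per-month climatology is the mean over years; composites are the annual
    sum, the cell-wise minimum, and the CV (%) of the 12 climatology
    layers (sample sd over mean; 0 where the mean is 0).
    """
    if len(monthly_lai) != len(months):
        raise ValueError("need one month label per layer")
    present = set(months)
    if present != set(range(1, 13)):
        missing = sorted(set(range(1, 13)) - present)
        raise ValueError(f"incomplete monthly coverage; missing months {missing}")
    geom = monthly_lai[0]
    for layer in monthly_lai:
        if not geom.same_geometry(layer):
            raise ValueError("LAI layers are not on a common grid")
    data = np.stack([g.data for g in monthly_lai])
    labels = np.asarray(months)
    clim = np.stack([data[labels == m].mean(axis=0) for m in range(1, 13)])
    mean = clim.mean(axis=0)
    sd = clim.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, 100.0 * sd / mean, 0.0)
    return LAIComposite(
        cumulative=geom.like(clim.sum(axis=0), name="lai_cumulative"),
        minimum=geom.like(clim.min(axis=0), name="lai_minimum"),
        seasonality=geom.like(cv, name="lai_seasonality"),
    )


def downscale(layer: RasterGrid, factor: int, method: str = "bilinear") -> RasterGrid:
    """Refine a raster by an integer factor (each cell -> factor x factor).

    ``nearest`` replicates cell values; ``bilinear`` interpolates between
    input cell centres (edge half-cells are clamped to the nearest centre,
    so a linear gradient is reproduced exactly away from the border).
    """
    if not isinstance(factor, (int, np.integer)) or isinstance(factor, bool):
        raise ValueError("factor must be an integer")
    if factor < 2:
        raise ValueError("factor must be >= 2")
    if method == "nearest":
        data = np.kron(layer.data, np.ones((factor, factor)))
    elif method == "bilinear":
        n_rows, n_cols = layer.data.shape
        out_r = (np.arange(n_rows * factor) + 0.5) / factor - 0.5
        out_c = (np.arange(n_cols * factor) + 0.5) / factor - 0.5
        rr, cc = np.meshgrid(out_r, out_c, indexing="ij")
        data = map_coordinates(layer.data, [rr, cc], order=1, mode="nearest")
    else:
        raise ValueError("method must be 'nearest' or 'bilinear'")
    return RasterGrid(
        data=data,
        cell_size=layer.cell_size / factor,
        xmin=layer.xmin,
        ymin=layer.ymin,
        name=layer.name,
    )


def _normalized_mass(values: np.ndarray) -> np.ndarray:
    """Min-shift to non-negative and normalize to sum 1.

    A constant layer carries no spatial contrast and is treated as a
    uniform density.
    """
    shifted = values - values.min()
    total = shifted.sum()
    if total == 0:
        return np.full(values.shape, 1.0 / values.size)
    return shifted / total


def schoener_d(a: np.ndarray, b: np.ndarray) -> float:
    """Schoener's D = 1 - 0.5 * sum |p_a - p_b| over shared valid cells."""
    pa = _normalized_mass(a)
    pb = _normalized_mass(b)
    return float(1.0 - 0.5 * np.abs(pa - pb).sum())


def compare_layers(a: RasterGrid, b: RasterGrid) -> LayerSimilarity:
    """Similarity of two layers on one grid: Schoener's D and Spearman rho.

    D treats each layer as a normalized spatial density (min-shifted to be
    non-negative); rho is the rank correlation of raw paired cell values.
    Cells that are NaN in either layer are excluded.  An all-constant layer
    leaves Spearman undefined; it is reported as ``None`` with a warning.
    """
    if not a.same_geometry(b):
        raise ValueError("layers are not on the same grid")
    valid = ~(np.isnan(a.data) | np.isnan(b.data))
    if valid.sum() < 2:
        raise ValueError("need at least 2 shared valid cells")
    av = a.data[valid]
    bv = b.data[valid]
    d = schoener_d(av, bv)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        warnings.warn("constant layer: Spearman correlation undefined", stacklevel=2)
        rho = None
    else:
        rho = float(spearmanr(av, bv).statistic)
    return LayerSimilarity(schoener_d=d, spearman_rho=rho)
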