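"""Synthetic landscapes, virtual species, occurrence samples and surveys.

Everything downstream of this module (thinning, SDM fitting, stacking,
assemblage evaluation, phylogenetic structure) is exercised against data
generated here, where the true occurrence probability of every species in
every cell is known.  The generators emulate the shape of the real inputs a
stacked-SDM study consumes — spatially autocorrelated environmental rasters,
presence-only point records with sampling bias, nested plot/site surveys
with imperfect detection, and a phylogeny whose tips carry the species'
niches with tunable niche conservatism — without attempting to mimic any
particular sensor or field protocol.

Coordinates are planar kilometres; see :mod:`stacksdm.raster` for the shared
grid convention.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import RasterGrid

__all__ = [
    "LandscapeConfig",
    "Landscape",
    "SpeciesNiche",
    "SurveyDesign",
    "TrueState",
    "SurveyResult",
    "UnsampleableSpeciesError",
    "generate_landscape",
    "generate_species_and_tree",
    "niche_probability",
    "realize_occurrences",
    "generate_survey",
]


class UnsampleableSpeciesError(ValueError):
    """Raised when a species has zero sampling weight everywhere."""


@dataclass
class LandscapeConfig:
    """Dimensions and autocorrelation of a synthetic landscape.

    ``autocorr_range`` is the Gaussian smoothing scale in km; 0 gives white
    noise.  Covariate layers are standardized to mean 0, sd 1.
    """

    n_rows: int = 32
    n_cols: int = 32
    cell_size: float = 1.0
    autocorr_range: float = 4.0
    n_covariates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("landscape must be at least 8x8 cells")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.autocorr_range < 0:
            raise ValueError("autocorr_range must be >= 0")
        if self.n_covariates < 1:
            raise ValueError("need at least one covariate")


@dataclass
class Landscape:
    """Covariate stack plus monthly climate stacks on one grid."""

    covariates: list[RasterGrid]
    tmin: list[RasterGrid]   # 12 monthly layers, degC
    tmax: list[RasterGrid]   # 12 monthly layers, degC
    precip: list[RasterGrid]  # 12 monthly layers, mm
    config: LandscapeConfig

    @property
    def covariate_names(self) -> list[str]:
        return [g.name for g in self.covariates]

    @property
    def grid(self) -> RasterGrid:
        return self.covariates[0]

    def covariate_array(self) -> np.ndarray:
        """Stack covariates into shape (n_cov, n_rows, n_cols)."""
        return np.stack([g.data for g in self.covariates])


@dataclass
class SpeciesNiche:
    """Logit-scale linear + quadratic response to each covariate.

    Occurrence probability in a cell is
    ``expit(intercept + sum_k a_k x_k + b_k x_k^2)``.  A unimodal (Gaussian)
    response to covariate k corresponds to ``b_k < 0`` with optimum at
    ``-a_k / (2 b_k)``.
    """

    species_id: str
    linear: np.ndarray
    quadratic: np.ndarray
    intercept: float = 0.0
    prevalence_target: float | None = None
    optima: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        if self.linear.shape != self.quadratic.shape:
            raise ValueError("linear and quadratic coefficient lengths differ")


@dataclass
class SurveyDesign:
    """Nested plot-within-site survey layout with imperfect detection."""

    n_sites: int = 10
    plots_per_site: int = 6
    site_extent: float = 5.0
    detection_prob: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.n_sites < 1 or self.plots_per_site < 1:
            raise ValueError("need at least one site and one plot per site")
        if self.site_extent <= 0:
            raise ValueError("site_extent must be positive")


@dataclass
class TrueState:
    """Ground truth attached to a synthetic experiment."""

    probability_surfaces: dict[str, RasterGrid]
    presence_grids: dict[str, RasterGrid]
    true_plot_matrix: pd.DataFrame | None = None
    true_site_matrix: pd.DataFrame | None = None

    @property
    def species(self) -> list[str]:
        return list(self.probability_surfaces)


@dataclass
class SurveyResult:
    """Observed community matrices and the plot -> site hierarchy."""

    plot_matrix: pd.DataFrame
    site_matrix: pd.DataFrame
    hierarchy: pd.DataFrame  # columns plot_id, site_id, x, y


def _smooth_field(rng: np.random.Generator, config: LandscapeConfig) -> np.ndarray:
    noise = rng.standard_normal((config.n_rows, config.n_cols))
    sigma = config.autocorr_range / config.cell_size
    if sigma > 0:
        noise = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return noise


def generate_landscape(config: LandscapeConfig) -> Landscape:
    """Generate standardized covariate layers and monthly climate stacks.

    Covariates are smoothed Gaussian white noise (scale ``autocorr_range``),
    standardized to mean 0 / sd 1.  Monthly minimum/maximum temperature and
    precipitation are built from smooth base fields with a sinusoidal
    seasonal cycle peaking mid-year, so the bioclimatic derivation module
    has realistic inputs (tmax >= tmin everywhere, precip >= 0).
    """
    rng = np.random.default_rng(config.seed)
    geom = RasterGrid(
        np.zeros((config.n_rows, config.n_cols)), cell_size=config.cell_size
    )
    covariates = [
        geom.like(_smooth_field(rng, config), name=f"cov{k + 1}")
        for k in range(config.n_covariates)
    ]

    # climate: smooth spatial fields modulating a shared seasonal cycle
    t_base = 12.0 + 4.0 * _smooth_field(rng, config)       # annual mean, degC
    t_amp = 10.0 + 2.0 * _smooth_field(rng, config)        # seasonal amplitude
    t_range = np.clip(8.0 + 2.0 * _smooth_field(rng, config), 1.0, None)
    p_base = 80.0 * np.exp(0.4 * _smooth_field(rng, config))  # mm / month

    months = np.arange(12)
    season = np.cos(2 * np.pi * (months - 6) / 12.0)  # peak July (index 6)
    tmin, tmax, precip = [], [], []
    for m in range(12):
        tmean = t_base + t_amp * season[m]
        tmin.append(geom.like(tmean - t_range / 2.0, name=f"tmin{m + 1:02d}"))
        tmax.append(geom.like(tmean + t_range / 2.0, name=f"tmax{m + 1:02d}"))
        pm = p_base * (1.0 + 0.6 * season[m])
        precip.append(geom.like(np.clip(pm, 0.0, None), name=f"prec{m + 1:02d}"))
    return Landscape(covariates=covariates, tmin=tmin, tmax=tmax, precip=precip, config=config)


def _brownian_tip_values(
    tree: dendropy.Tree, rng: np.random.Generator
) -> dict[str, float]:
    """One Brownian-motion realization along the tree; returns tip values."""
    values: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = values[id(node.parent_node)]
        length = max(node.edge.length or 0.0, 0.0)
        values[id(node)] = parent + rng.normal(0.0, np.sqrt(length))
    return {
        leaf.taxon.label: values[id(leaf)] for leaf in tree.leaf_node_iter()
    }


def _calibrate_intercept(
    eta_no_intercept: np.ndarray, target: float, tol: float = 1e-6
) -> float:
    """Bisection on the intercept so mean probability hits ``target``."""
    lo, hi = -30.0, 30.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        prev = expit(mid + eta_no_intercept).mean()
        if abs(prev - target) < tol:
            return mid
        if prev < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_species_and_tree(
    n_species: int,
    phylo_signal: float,
    landscape: Landscape,
    seed: int = 0,
    niche_width: float = 1.2,
    prevalence_target: float = 0.25,
) -> tuple[list[SpeciesNiche], dendropy.Tree]:
    """Simulate a pure-birth phylogeny and niches evolved along it.

    Niche optima per covariate are a mixture of a Brownian-motion
    realization on the tree (weight ``sqrt(phylo_signal)``) and i.i.d.
    draws (weight ``sqrt(1 - phylo_signal)``), each standardized across
    tips, so ``phylo_signal = 0`` gives fully independent niches and
    ``phylo_signal = 1`` gives maximal niche conservatism.  Responses are
    Gaussian on the logit scale with width ``niche_width`` (covariate sd
    units) and the intercept is calibrated by bisection so the landscape
    mean occurrence probability equals ``prevalence_target``.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if not 0.0 <= phylo_signal <= 1.0:
        raise ValueError("phylo_signal must be in [0, 1]")
    rng = np.random.default_rng(seed)

    taxa = dendropy.TaxonNamespace([f"sp{i + 1:02d}" for i in range(n_species)])
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=_pyrandom.Random(int(rng.integers(2**31 - 1))),
    )
    tree.is_rooted = True
    # the simulator stops at the speciation event that creates the n-th tip,
    # leaving zero-length pendant edges; run the clock to the next event so
    # every branch is positive and the tree stays ultrametric
    extra = rng.exponential(1.0 / n_species)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra

    labels = [t.label for t in taxa]
    n_cov = landscape.config.n_covariates
    optima = np.zeros((n_species, n_cov))
    for k in range(n_cov):
        bm = _brownian_tip_values(tree, rng)
        bm_vec = np.array([bm[lab] for lab in labels])
        if bm_vec.std() > 0:
            bm_vec = (bm_vec - bm_vec.mean()) / bm_vec.std()
        iid = rng.standard_normal(n_species)
        optima[:, k] = (
            np.sqrt(phylo_signal) * bm_vec + np.sqrt(1.0 - phylo_signal) * iid
        )

    cov_stack = landscape.covariate_array()
    niches = []
    for i, lab in enumerate(labels):
        quad = np.full(n_cov, -1.0 / (2.0 * niche_width**2))
        lin = optima[i] / niche_width**2
        eta = (
            np.tensordot(lin, cov_stack, axes=1)
            + np.tensordot(quad, cov_stack**2, axes=1)
        )
        intercept = _calibrate_intercept(eta.ravel(), prevalence_target)
        niches.append(
            SpeciesNiche(
                species_id=lab,
                linear=lin,
                quadratic=quad,
                intercept=intercept,
                prevalence_target=prevalence_target,
                optima=optima[i].copy(),
            )
        )
    return niches, tree


def niche_probability(niche: SpeciesNiche, landscape: Landscape) -> RasterGrid:
    """True occurrence probability surface of a species."""
    cov = landscape.covariate_array()
    if len(niche.linear) != cov.shape[0]:
        raise ValueError("niche coefficient length does not match covariates")
    eta = (
        niche.intercept
        + np.tensordot(niche.linear, cov, axes=1)
        + np.tensordot(niche.quadratic, cov**2, axes=1)
    )
    return landscape.grid.like(expit(eta), name=f"prob_{niche.species_id}")


def realize_occurrences(
    niches: list[SpeciesNiche],
    landscape: Landscape,
    n_per_species: int,
    bias_strength: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, TrueState]:
    """Draw presence-only records and realize true presence grids.

    Records are cell draws with weight proportional to true probability
    times a multiplicative smooth sampling-bias field ``exp(bias_strength *
    G)`` (G a standardized smooth field), jittered uniformly within the
    cell.  Presence grids are independent Bernoulli draws from the
    probability surfaces.
    """
    if n_per_species < 1:
        raise ValueError("n_per_species must be >= 1")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    rng = np.random.default_rng(seed)
    grid = landscape.grid
    bias = np.exp(bias_strength * _smooth_field(rng, landscape.config))

    xs = grid.x_centers
    ys = grid.y_centers
    records = []
    prob_surfaces: dict[str, RasterGrid] = {}
    presence: dict[str, RasterGrid] = {}
    for niche in niches:
        p = niche_probability(niche, landscape)
        prob_surfaces[niche.species_id] = p
        w = (p.data * bias).ravel()
        total = w.sum()
        if total <= 0:
            raise UnsampleableSpeciesError(
                f"species {niche.species_id!r} has zero sampling weight everywhere"
            )
        cells = rng.choice(w.size, size=n_per_species, replace=True, p=w / total)
        rows, cols = np.unravel_index(cells, p.data.shape)
        jx = (rng.random(n_per_species) - 0.5) * grid.cell_size
        jy = (rng.random(n_per_species) - 0.5) * grid.cell_size
        for r, c, dx, dy in zip(rows, cols, jx, jy):
            records.append((niche.species_id, xs[c] + dx, ys[r] + dy, "observed"))
        presence[niche.species_id] = grid.like(
            (rng.random(p.data.shape) < p.data).astype(float),
            name=f"presence_{niche.species_id}",
        )
    table = pd.DataFrame(records, columns=["species_id", "x", "y", "provenance"])
    return table, TrueState(probability_surfaces=prob_surfaces, presence_grids=presence)


def generate_survey(
    true_state: TrueState,
    design: SurveyDesign,
    landscape: Landscape,
) -> SurveyResult:
    """Place nested plots in sites and record detections.

    Plot incidence is the species' true presence in the plot's cell thinned
    by ``detection_prob``; the detection uniforms are drawn independently of
    ``detection_prob`` so raising it can only add detections (coupled
    draws).  Site matrices are the column-wise union (max) over member
    plots; the ground-truth matrices are stored on ``true_state``.
    """
    rng = np.random.default_rng(design.seed)
    grid = landscape.grid
    half = design.site_extent / 2.0
    if grid.xmax - grid.xmin < design.site_extent or grid.ymax - grid.ymin < design.site_extent:
        raise ValueError("site_extent larger than the landscape")

    species = true_state.species
    plot_rows, hier = [], []
    for s in range(design.n_sites):
        cx = rng.uniform(grid.xmin + half, grid.xmax - half)
        cy = rng.uniform(grid.ymin + half, grid.ymax - half)
        site_id = f"S{s + 1:02d}"
        for p in range(design.plots_per_site):
            px = rng.uniform(cx - half, cx + half)
            py = rng.uniform(cy - half, cy + half)
            plot_id = f"{site_id}P{p + 1:02d}"
            hier.append((plot_id, site_id, px, py))
            r, c = grid.cell_index(px, py)
            plot_rows.append(
                [int(true_state.presence_grids[sp].data[r, c] > 0) for sp in species]
            )
    hierarchy = pd.DataFrame(hier, columns=["plot_id", "site_id", "x", "y"])
    true_plot = pd.DataFrame(
        plot_rows, index=hierarchy["plot_id"], columns=species, dtype=int
    )

    u = rng.random(true_plot.shape)
    observed_plot = pd.DataFrame(
        (true_plot.to_numpy() == 1) & (u < design.detection_prob),
        index=true_plot.index,
        columns=species,
    ).astype(int)

    site_of = hierarchy.set_index("plot_id")["site_id"]
    observed_site = observed_plot.groupby(site_of).max()
    true_site = true_plot.groupby(site_of).max()
    true_state.true_plot_matrix = true_plot
    true_state.true_site_matrix = true_site
    return SurveyResult(
        plot_matrix=observed_plot, site_matrix=observed_site, hierarchy=hierarchy
    )
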