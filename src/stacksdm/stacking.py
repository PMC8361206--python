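"""Stacking per-species predictions into assemblage predictions.

Three stacking procedures:

* **bS-SDM** — stack the thresholded binary layers; richness is the count
  of predicted presences.
* **pS-SDM** — stack the raw probability layers; richness is the sum of
  probabilities (an expected richness, real-valued).
* **cS-SDM** — the probability ranking rule (PRR): in each assemblage the
  species are ranked by occurrence probability and the top ``k`` selected,
  where ``k`` is that assemblage's observed richness constraint.  Ties are
  broken by species name (alphabetical) for reproducibility, or randomly
  under a seed.

Assemblage units can be raster cells or survey plots/sites; plot-level
predictions aggregate to sites by species-wise union (binary) or maximum
(probability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bart import PosteriorPrediction
from .raster import RasterGrid

__all__ = [
    "SpeciesPrediction",
    "SpeciesPredictionSet",
    "AssemblagePrediction",
    "extract_at_units",
    "stack_binary",
    "stack_probability",
    "stack_constrained_prr",
    "aggregate_to_sites",
    "stack_uncertainty",
]


@dataclass
class SpeciesPrediction:
    """One species' prediction bundle: probability, binary map, threshold,
    credible-interval width."""

    species_id: str
    prediction: PosteriorPrediction
    threshold: float
    binary: RasterGrid

    def __post_init__(self) -> None:
        expected = (self.prediction.mean_probability.data >= self.threshold).astype(float)
        if not np.array_equal(self.binary.data, expected):
            raise ValueError("binary layer inconsistent with threshold rule")


@dataclass
class SpeciesPredictionSet:
    predictions: list[SpeciesPrediction]

    def __post_init__(self) -> None:
        if not self.predictions:
            raise ValueError("need at least one species")
        geom = self.predictions[0].prediction.mean_probability
        for sp in self.predictions:
            for grid in (sp.prediction.mean_probability, sp.prediction.ci_width, sp.binary):
                if not geom.same_geometry(grid):
                    raise ValueError("prediction grids do not share one geometry")

    @property
    def species(self) -> list[str]:
        return [sp.species_id for sp in self.predictions]

    @property
    def geometry(self) -> RasterGrid:
        return self.predictions[0].prediction.mean_probability


@dataclass
class AssemblagePrediction:
    """Per-unit species vectors plus richness.

    ``kind`` is ``"binary"``, ``"probability"`` or ``"prr"``; richness is
    integer-valued for binary/PRR and real for probability stacks.
    """

    matrix: pd.DataFrame  # units x species
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("binary", "probability", "prr"):
            raise ValueError("kind must be binary, probability or prr")
        vals = self.matrix.to_numpy(dtype=float)
        if self.kind in ("binary", "prr"):
            if not np.isin(vals, (0.0, 1.0)).all():
                raise ValueError("binary/PRR matrix must be 0/1")
        elif ((vals < 0) | (vals > 1)).any():
            raise ValueError("probabilities outside [0, 1]")

    @property
    def richness(self) -> pd.Series:
        return self.matrix.sum(axis=1).rename("richness")


def extract_at_units(
    preds: SpeciesPredictionSet, units: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probability and binary vectors at unit point locations.

    ``units`` needs columns ``x``/``y`` and an index of unit ids.  Each
    unit takes the value of the cell containing its point (cell-centre
    convention; shared edges go to the south-east cell).
    """
    geom = preds.geometry
    try:
        rows, cols = geom.cell_indices(units["x"].to_numpy(), units["y"].to_numpy())
    except ValueError as err:
        raise ValueError(f"unit outside raster extent: {err}") from err
    prob = pd.DataFrame(
        {sp.species_id: sp.prediction.mean_probability.data[rows, cols] for sp in preds.predictions},
        index=units.index,
    )
    binary = pd.DataFrame(
        {sp.species_id: sp.binary.data[rows, cols].astype(int) for sp in preds.predictions},
        index=units.index,
    )
    return prob, binary


def cell_matrix(preds: SpeciesPredictionSet, which: str = "binary") -> pd.DataFrame:
    """Units-x-species matrix over all raster cells (unit ids ``r<row>c<col>``)."""
    geom = preds.geometry
    index = pd.Index(
        [f"r{r}c{c}" for r in range(geom.n_rows) for c in range(geom.n_cols)],
        name="cell",
    )
    if which == "binary":
        cols = {sp.species_id: sp.binary.data.ravel().astype(int) for sp in preds.predictions}
    elif which == "probability":
        cols = {
            sp.species_id: sp.prediction.mean_probability.data.ravel()
            for sp in preds.predictions
        }
    else:
        raise ValueError("which must be 'binary' or 'probability'")
    return pd.DataFrame(cols, index=index)


def stack_binary(preds: SpeciesPredictionSet | pd.DataFrame) -> AssemblagePrediction:
    """bS-SDM: per-unit composition is the binary vector, richness its sum.

    Accepts a full prediction set (units = raster cells) or an already
    extracted units-x-species binary matrix.
    """
    if isinstance(preds, SpeciesPredictionSet):
        preds = cell_matrix(preds, "binary")
    return AssemblagePrediction(matrix=preds.astype(int), kind="binary")


def stack_probability(preds: SpeciesPredictionSet | pd.DataFrame) -> AssemblagePrediction:
    """pS-SDM: composition is the probability vector, richness its sum."""
    if isinstance(preds, SpeciesPredictionSet):
        preds = cell_matrix(preds, "probability")
    return AssemblagePrediction(matrix=preds.astype(float), kind="probability")


def stack_constrained_prr(
    prob_matrix: pd.DataFrame,
    richness_constraints: pd.Series,
    seed: int | None = None,
) -> AssemblagePrediction:
    """cS-SDM via the probability ranking rule.

    Per unit, the ``k`` highest-probability species are marked present,
    ``k`` being that unit's richness constraint (capped at the species
    count).  Ties are broken alphabetically by species id, or uniformly at
    random when ``seed`` is given.
    """
    if (richness_constraints < 0).any():
        raise ValueError("richness constraints must be >= 0")
    missing = prob_matrix.index.difference(richness_constraints.index)
    if len(missing):
        raise ValueError(f"no richness constraint for units: {list(missing)}")
    cols = sorted(prob_matrix.columns)
    probs = prob_matrix[cols].to_numpy(dtype=float)
    rng = np.random.default_rng(seed) if seed is not None else None
    out = np.zeros_like(probs, dtype=int)
    for i, unit in enumerate(prob_matrix.index):
        k = min(int(richness_constraints.loc[unit]), len(cols))
        if k == 0:
            continue
        if rng is None:
            # alphabetical tie-break: earlier column wins at equal probability
            order = np.lexsort((np.arange(len(cols)), -probs[i]))
        else:
            order = np.lexsort((rng.random(len(cols)), -probs[i]))
        out[i, order[:k]] = 1
    matrix = pd.DataFrame(out, index=prob_matrix.index, columns=cols)
    return AssemblagePrediction(matrix=matrix[prob_matrix.columns], kind="prr")


def aggregate_to_sites(
    plot_pred: AssemblagePrediction, hierarchy: pd.DataFrame, probability_rule: str = "max"
) -> AssemblagePrediction:
    """Aggregate a plot-level assemblage prediction to sites.

    Binary and PRR matrices take the species-wise union (max) over member
    plots.  Probability matrices take the species-wise max by default (the
    probability in the best plot); ``probability_rule="noisy-or"`` instead
    uses ``1 - prod(1 - p)`` (presence in at least one plot under
    independence).
    """
    site_of = hierarchy.set_index("plot_id")["site_id"]
    orphans = plot_pred.matrix.index.difference(site_of.index)
    if len(orphans):
        raise ValueError(f"plots missing from hierarchy: {list(orphans)}")
    groups = plot_pred.matrix.groupby(site_of.reindex(plot_pred.matrix.index))
    if plot_pred.kind in ("binary", "prr") or probability_rule == "max":
        matrix = groups.max()
    elif probability_rule == "noisy-or":
        matrix = 1.0 - (1.0 - plot_pred.matrix).groupby(
            site_of.reindex(plot_pred.matrix.index)
        ).prod()
    else:
        raise ValueError("probability_rule must be 'max' or 'noisy-or'")
    matrix.index.name = "site_id"
    return AssemblagePrediction(matrix=matrix, kind=plot_pred.kind)


def stack_uncertainty(preds: SpeciesPredictionSet) -> RasterGrid:
    """Assemblage-level uncertainty: per-cell sum of the per-species 95%
    credible-interval widths."""
    total = np.zeros_like(preds.geometry.data)
    for sp in preds.predictions:
        total = total + sp.prediction.ci_width.data
    return preds.geometry.like(total, name="stacked_uncertainty")
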