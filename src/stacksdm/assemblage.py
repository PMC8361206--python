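"""Assemblage prediction evaluation.

Scores predicted assemblages against observed incidence with five metrics:
species-richness (SR) deviation and SR change, prediction success, the true
skill statistic (TSS) and the Sørensen similarity index.  Binary
predictions use counting confusion cells; probabilistic predictions use
expected confusion cells (each species contributes its probability to the
"predicted present" cells and its complement to the "predicted absent"
cells), the standard convention for evaluating probability stacks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacking import AssemblagePrediction

__all__ = [
    "ConfusionCells",
    "EvaluationReport",
    "confusion_cells",
    "sr_deviation",
    "sr_change",
    "composition_metrics",
    "evaluate_assemblages",
]

logger = logging.getLogger(__name__)

METRICS = ("sr_deviation", "sr_change", "prediction_success", "tss", "sorensen")


@dataclass
class ConfusionCells:
    """Contingency quantities for one assemblage.

    a: predicted and observed present; b: predicted present, observed
    absent; c: predicted absent, observed present; d: both absent.
    Real-valued for probabilistic predictions.
    """

    a: float
    b: float
    c: float
    d: float

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d


@dataclass
class EvaluationReport:
    """Per-unit metric table plus mean ± SD summaries for one scale."""

    scale: str
    kind: str
    per_unit: pd.DataFrame
    summary: pd.DataFrame  # index metric, columns mean / sd


def confusion_cells(observed: np.ndarray, predicted: np.ndarray) -> ConfusionCells:
    """Confusion cells between a 0/1 observed vector and a 0/1 or [0, 1]
    predicted vector (probabilities give expected cells)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted lengths differ")
    if observed.size < 1:
        raise ValueError("empty vectors")
    if not np.isin(observed, (0.0, 1.0)).all():
        raise ValueError("observed vector must be 0/1")
    if ((predicted < 0) | (predicted > 1)).any():
        raise ValueError("predicted values must lie in [0, 1]")
    pres = observed == 1
    return ConfusionCells(
        a=float(predicted[pres].sum()),
        c=float((1.0 - predicted[pres]).sum()),
        b=float(predicted[~pres].sum()),
        d=float((1.0 - predicted[~pres]).sum()),
    )


def sr_deviation(
    obs_richness: float, pred_richness: float, max_observed_richness: float
) -> float:
    """|predicted - observed| richness scaled by the maximum observed
    richness of the survey."""
    if max_observed_richness <= 0:
        raise ValueError("max_observed_richness must be > 0")
    return abs(pred_richness - obs_richness) / max_observed_richness


def sr_change(obs_richness: float, pred_richness: float) -> float:
    """Signed richness difference: negative = species lost
    (underprediction), positive = gained (overprediction)."""
    return pred_richness - obs_richness


def composition_metrics(cells: ConfusionCells) -> dict[str, float]:
    """Prediction success, TSS and Sørensen from confusion cells.

    TSS components with a degenerate denominator (no observed presences, or
    no observed absences) leave the metric undefined (NaN, with a warning).
    """
    if cells.n <= 0:
        raise ValueError("all-zero confusion cells")
    success = (cells.a + cells.d) / cells.n
    if cells.a + cells.c == 0 or cells.b + cells.d == 0:
        warnings.warn("degenerate confusion margin: TSS undefined", stacklevel=2)
        tss = np.nan
    else:
        tss = cells.a / (cells.a + cells.c) + cells.d / (cells.b + cells.d) - 1.0
    denom = 2 * cells.a + cells.b + cells.c
    sorensen = 2 * cells.a / denom if denom > 0 else np.nan
    return {"prediction_success": success, "tss": tss, "sorensen": sorensen}


def evaluate_assemblages(
    observed: pd.DataFrame,
    predicted: AssemblagePrediction,
    scale: str = "",
    max_observed_richness: float | None = None,
) -> EvaluationReport:
    """Score a predicted assemblage set against observed incidence.

    Units are matched by id (shared units only; none shared is an error).
    Species columns are outer-joined with zero fill, which is logged since
    it inflates the both-absent cell.  SR deviation and SR change are
    skipped for PRR predictions, whose richness is constrained by the
    observed data.  ``max_observed_richness`` defaults to the maximum
    observed row sum.
    """
    shared = observed.index.intersection(predicted.matrix.index)
    if len(shared) == 0:
        raise ValueError("no shared units between observed and predicted")
    obs_cols = set(observed.columns)
    pred_cols = set(predicted.matrix.columns)
    if obs_cols != pred_cols:
        logger.info(
            "species columns differ (observed-only=%s, predicted-only=%s); "
            "outer join with zero fill",
            sorted(obs_cols - pred_cols),
            sorted(pred_cols - obs_cols),
        )
    species = sorted(obs_cols | pred_cols)
    obs = observed.reindex(index=shared, columns=species, fill_value=0)
    pred = predicted.matrix.reindex(index=shared, columns=species, fill_value=0)

    if max_observed_richness is None:
        max_observed_richness = float(obs.sum(axis=1).max())

    rows = []
    for unit in shared:
        o = obs.loc[unit].to_numpy(dtype=float)
        p = pred.loc[unit].to_numpy(dtype=float)
        cells = confusion_cells(o, p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = composition_metrics(cells)
        if predicted.kind != "prr":
            metrics["sr_deviation"] = sr_deviation(o.sum(), p.sum(), max_observed_richness)
            metrics["sr_change"] = sr_change(o.sum(), p.sum())
        rows.append({"unit_id": unit, **metrics})
    per_unit = pd.DataFrame(rows).set_index("unit_id")
    summary = pd.DataFrame(
        {"mean": per_unit.mean(), "sd": per_unit.std(ddof=1)}
    )
    return EvaluationReport(
        scale=scale, kind=predicted.kind, per_unit=per_unit, summary=summary
    )
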