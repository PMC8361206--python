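"""End-to-end orchestration of the synthetic stacked-SDM experiment.

Stage order mirrors the modelling workflow: landscape and virtual species
-> occurrence realization -> nested survey -> per-species training data
(thinning, accessible area, pseudoabsences) -> probit BART fits and
predictions -> stacking (bS / pS / cS) at plot and site scales ->
assemblage evaluation -> phylogenetic structure -> Bayesian comparisons.

Every stage draws its seed deterministically from the master seed, so the
same configuration always yields byte-identical outputs; when an output
directory is given, all artifacts are written (text formats only) together
with a manifest recording seeds, timings and file checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bart, occurrences, phylo, stacking, synthetic
from .assemblage import EvaluationReport, evaluate_assemblages
from .bayes import McmcConfig, bayes_anova, robust_correlation
from .raster import write_ascii_grid
from .synthetic import LandscapeConfig, SurveyDesign

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_STAGES = (
    "landscape",
    "species",
    "occurrences",
    "survey",
    "sdm",
    "stacking",
    "evaluation",
    "phylo",
    "stats",
)


@dataclass
class PipelineConfig:
    """Full experiment configuration; defaults define the reference
    synthetic fixture (see docs/methods.md for the rationale)."""

    master_seed: int = 0
    # landscape
    n_rows: int = 32
    n_cols: int = 32
    cell_size: float = 1.0
    autocorr_range: float = 4.0
    n_covariates: int = 4
    # species
    n_species: int = 8
    phylo_signal: float = 0.7
    prevalence_target: float = 0.25
    niche_width: float = 1.2
    # occurrences
    n_per_species: int = 150
    bias_strength: float = 0.5
    thinning_repeats: int = 25
    accessible_buffer_km: float = 300.0
    # survey
    n_sites: int = 10
    plots_per_site: int = 6
    site_extent: float = 5.0
    detection_prob: float = 0.9
    # SDM; the model is denied the covariates named here even though the
    # truth uses them (a microhabitat axis unobserved by the modeller)
    n_trees: int = 20
    n_iterations: int = 200
    burn_in_fraction: float = 0.2
    omit_covariates: tuple[str, ...] = ("cov4",)
    # phylo
    n_null: int = 499
    # stats
    mcmc_iterations: int = 1000
    mcmc_chains: int = 4

    def stage_seed(self, stage: str) -> int:
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.master_seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "omit_covariates" in data and data["omit_covariates"] is not None:
            data["omit_covariates"] = tuple(data["omit_covariates"])
        return cls(**data)


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: synthetic.Landscape
    tree: object
    occurrences_raw: pd.DataFrame
    occurrences_thinned: pd.DataFrame
    truth: synthetic.TrueState
    survey: synthetic.SurveyResult
    diagnostics: pd.DataFrame
    prediction_set: stacking.SpeciesPredictionSet
    assemblages: dict[tuple[str, str], stacking.AssemblagePrediction]
    reports: dict[tuple[str, str], EvaluationReport]
    ses: dict[tuple[str, str], pd.DataFrame]
    stats: dict[str, object]
    summary: dict[str, float]
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic experiment; optionally write all artifacts.

    Any stage failure is re-raised annotated with the stage name; partial
    outputs already written are kept alongside a ``FAILED`` marker file.
    """
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "landscape"
    try:
        result = _run_stages(config, timings)
    except Exception as err:
        stage = getattr(err, "_stage", stage)
        if out is not None:
            (out / "FAILED").write_text(f"stage={stage}\nerror={err}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    if out is not None:
        manifest = _write_outputs(result, out, timings)
        result.manifest = manifest
    return result


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                value = fn(*args, **kwargs)
            except Exception as err:
                err._stage = name
                raise
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return value, time.perf_counter() - t0
        return inner
    return wrap


def _run_stages(config: PipelineConfig, timings: dict[str, float]) -> PipelineResult:
    land_cfg = LandscapeConfig(
        n_rows=config.n_rows,
        n_cols=config.n_cols,
        cell_size=config.cell_size,
        autocorr_range=config.autocorr_range,
        n_covariates=config.n_covariates,
        seed=config.stage_seed("landscape"),
    )
    landscape, timings["landscape"] = _stage("landscape")(synthetic.generate_landscape)(land_cfg)

    (niches, tree), timings["species"] = _stage("species")(synthetic.generate_species_and_tree)(
        config.n_species,
        config.phylo_signal,
        landscape,
        seed=config.stage_seed("species"),
        niche_width=config.niche_width,
        prevalence_target=config.prevalence_target,
    )

    (occ_raw, truth), timings["occurrences"] = _stage("occurrences")(synthetic.realize_occurrences)(
        niches,
        landscape,
        n_per_species=config.n_per_species,
        bias_strength=config.bias_strength,
        seed=config.stage_seed("occurrences"),
    )

    design = SurveyDesign(
        n_sites=config.n_sites,
        plots_per_site=config.plots_per_site,
        site_extent=config.site_extent,
        detection_prob=config.detection_prob,
        seed=config.stage_seed("survey"),
    )
    survey, timings["survey"] = _stage("survey")(synthetic.generate_survey)(truth, design, landscape)

    (occ_thin, diag, pred_set), timings["sdm"] = _stage("sdm")(_fit_all_species)(
        config, landscape, occ_raw
    )

    assemblages, timings["stacking"] = _stage("stacking")(_stack_all)(pred_set, survey)

    reports, timings["evaluation"] = _stage("evaluation")(_evaluate_all)(assemblages, survey)

    ses_tables, timings["phylo"] = _stage("phylo")(_phylo_all)(config, tree, assemblages, survey)

    (stats, summary), timings["stats"] = _stage("stats")(_stats_all)(
        config, assemblages, reports, survey
    )

    return PipelineResult(
        config=config,
        landscape=landscape,
        tree=tree,
        occurrences_raw=occ_raw,
        occurrences_thinned=occ_thin,
        truth=truth,
        survey=survey,
        diagnostics=diag,
        prediction_set=pred_set,
        assemblages=assemblages,
        reports=reports,
        ses=ses_tables,
        stats=stats,
        summary=summary,
    )


def _fit_all_species(config: PipelineConfig, landscape, occ_raw):
    grid = landscape.grid
    model_grids = [
        g for g in landscape.covariates if g.name not in config.omit_covariates
    ]
    if not model_grids:
        raise ValueError("omit_covariates removed every covariate")
    sdm_seed = config.stage_seed("sdm")
    thinned_parts, diag_rows, predictions = [], [], []
    for i, (species, sub) in enumerate(occ_raw.groupby("species_id", sort=True)):
        dist = occurrences.thinning_distance_rule(len(sub))
        thinned = occurrences.thin_occurrences(
            sub, dist, n_repeats=config.thinning_repeats, seed=sdm_seed + 7 * i
        )
        thinned_parts.append(thinned)
        area = occurrences.accessible_area(
            thinned, buffer_km=config.accessible_buffer_km, extent=grid
        )
        rows, cols = grid.cell_indices(
            thinned["x"].to_numpy(), thinned["y"].to_numpy()
        )
        presence_cells = set(zip(rows.tolist(), cols.tolist()))
        pseudo = occurrences.sample_pseudoabsences(
            area,
            n=len(thinned),
            presence_cells=presence_cells,
            mask=grid,
            seed=sdm_seed + 7 * i + 1,
            species_id=species,
        )
        pts = pd.concat([thinned, pseudo], ignore_index=True)
        pr, pc = grid.cell_indices(pts["x"].to_numpy(), pts["y"].to_numpy())
        X = pd.DataFrame(
            {g.name: g.data[pr, pc] for g in model_grids}
        )
        y = (pts["provenance"] == "observed").to_numpy().astype(int)
        dm = bart.DesignMatrix(X=X, y=y)
        bcfg = bart.BARTConfig(
            n_trees=config.n_trees,
            n_iterations=config.n_iterations,
            burn_in_fraction=config.burn_in_fraction,
            seed=sdm_seed + 7 * i + 2,
        )
        model = bart.fit_bart(dm, bcfg)
        in_sample = model.train_probability()
        fit_diag = bart.evaluate_model(in_sample, y)
        prediction = bart.predict_occurrence(model, model_grids)
        binary = bart.binarize(prediction, fit_diag.threshold)
        predictions.append(
            stacking.SpeciesPrediction(
                species_id=species,
                prediction=prediction,
                threshold=fit_diag.threshold,
                binary=binary,
            )
        )
        diag_rows.append(
            {
                "species_id": species,
                "n_raw": len(sub),
                "n_thinned": len(thinned),
                "thinning_km": dist,
                "auc": fit_diag.auc,
                "tss": fit_diag.tss,
                "threshold": fit_diag.threshold,
            }
        )
    occ_thin = pd.concat(thinned_parts, ignore_index=True)
    diag = pd.DataFrame(diag_rows).set_index("species_id")
    return occ_thin, diag, stacking.SpeciesPredictionSet(predictions)


def _stack_all(pred_set, survey):
    plots = survey.hierarchy.set_index("plot_id")[["x", "y", "site_id"]]
    prob_plot, bin_plot = stacking.extract_at_units(pred_set, plots)
    out: dict[tuple[str, str], stacking.AssemblagePrediction] = {}
    out[("plot", "binary")] = stacking.stack_binary(bin_plot)
    out[("plot", "probability")] = stacking.stack_probability(prob_plot)
    out[("plot", "prr")] = stacking.stack_constrained_prr(
        prob_plot, survey.plot_matrix.sum(axis=1)
    )
    for mode in ("binary", "probability"):
        out[("site", mode)] = stacking.aggregate_to_sites(
            out[("plot", mode)], survey.hierarchy
        )
    # cS at site scale re-ranks against the observed site richness rather
    # than inheriting the plot-level unions
    site_prob = out[("site", "probability")]
    out[("site", "prr")] = stacking.stack_constrained_prr(
        site_prob.matrix, survey.site_matrix.sum(axis=1)
    )
    return out


def _evaluate_all(assemblages, survey):
    observed = {"plot": survey.plot_matrix, "site": survey.site_matrix}
    max_plot_richness = float(survey.plot_matrix.sum(axis=1).max())
    reports = {}
    for (scale, mode), pred in assemblages.items():
        reports[(scale, mode)] = evaluate_assemblages(
            observed[scale], pred, scale=scale, max_observed_richness=max_plot_richness
        )
    return reports


def _phylo_all(config, tree, assemblages, survey):
    distances = phylo.cophenetic_distances(tree)
    n_null = config.n_null
    seed = config.stage_seed("phylo")
    tables = {}
    tables[("plot", "observed")] = phylo.ses_mpd(survey.plot_matrix, distances, n_null, seed)
    tables[("site", "observed")] = phylo.ses_mpd(survey.site_matrix, distances, n_null, seed)
    for scale in ("plot", "site"):
        for mode in ("binary", "prr"):
            tables[(scale, mode)] = phylo.ses_mpd(
                assemblages[(scale, mode)].matrix, distances, n_null, seed
            )
    return tables


def _stats_all(config, assemblages, reports, survey):
    mcfg = McmcConfig(
        n_chains=config.mcmc_chains,
        n_iterations=config.mcmc_iterations,
        seed=config.stage_seed("stats"),
    )
    observed = {"plot": survey.plot_matrix, "site": survey.site_matrix}
    stats: dict[str, object] = {}
    summary: dict[str, float] = {}
    for scale in ("plot", "site"):
        obs_r = observed[scale].sum(axis=1)
        pred_r = assemblages[(scale, "binary")].richness.reindex(obs_r.index)
        degenerate = obs_r.nunique() < 2 or pred_r.nunique() < 2
        if degenerate:
            logger.warning(
                "constant richness at %s scale: correlations undefined", scale
            )
        summary[f"richness_pearson_{scale}_bs"] = (
            float("nan") if degenerate else float(np.corrcoef(obs_r, pred_r)[0, 1])
        )
        summary[f"mean_sorensen_{scale}_bs"] = float(
            reports[(scale, "binary")].summary.loc["sorensen", "mean"]
        )
        summary[f"mean_sr_change_{scale}_bs"] = float(
            reports[(scale, "binary")].summary.loc["sr_change", "mean"]
        )
        stats[f"richness_correlation_{scale}"] = (
            None
            if degenerate
            else robust_correlation(obs_r.to_numpy(float), pred_r.to_numpy(float), mcfg)
        )
    # compare stacking procedures on per-plot Sørensen, plots as random effect
    frames = []
    for mode in ("binary", "probability", "prr"):
        per_unit = reports[("plot", mode)].per_unit
        frames.append(
            pd.DataFrame(
                {
                    "value": per_unit["sorensen"],
                    "group": mode,
                    "unit": per_unit.index,
                }
            )
        )
    long = pd.concat(frames, ignore_index=True).dropna(subset=["value"])
    stats["sorensen_anova_plot"] = bayes_anova(
        long["value"].to_numpy(),
        long["group"].to_numpy(),
        long["unit"].to_numpy(),
        mcfg,
    )
    return stats, summary


def _write_outputs(result: PipelineResult, out: Path, timings: dict[str, float]) -> dict:
    files: list[Path] = []

    def save_df(df: pd.DataFrame, rel: str, **kwargs):
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, **kwargs)
        files.append(path)

    def save_grid(grid, rel: str):
        path = out / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        write_ascii_grid(grid, path)
        files.append(path)

    result.config.to_yaml(out / "config.yaml")
    files.append(out / "config.yaml")

    for g in result.landscape.covariates:
        save_grid(g, f"covariates/{g.name}.asc")
    save_df(result.occurrences_raw, "occurrences/raw.csv", index=False)
    save_df(result.occurrences_thinned, "occurrences/thinned.csv", index=False)
    for sp in result.prediction_set.predictions:
        save_grid(sp.prediction.mean_probability, f"predictions/{sp.species_id}_probability.asc")
        save_grid(sp.prediction.ci_width, f"predictions/{sp.species_id}_ci_width.asc")
        save_grid(sp.binary, f"predictions/{sp.species_id}_binary.asc")
    richness = stacking.stack_binary(result.prediction_set)
    grid = result.prediction_set.geometry
    save_grid(
        grid.like(richness.richness.to_numpy().reshape(grid.data.shape)),
        "assemblage/richness_bs.asc",
    )
    save_grid(stacking.stack_uncertainty(result.prediction_set), "assemblage/uncertainty.asc")
    save_df(result.survey.plot_matrix, "survey/observed_plots.csv")
    save_df(result.survey.site_matrix, "survey/observed_sites.csv")
    save_df(result.survey.hierarchy, "survey/hierarchy.csv", index=False)
    save_df(result.diagnostics, "sdm/diagnostics.csv")
    tree_path = out / "phylogeny.nwk"
    tree_path.write_text(result.tree.as_string(schema="newick"))
    files.append(tree_path)
    for (scale, mode), pred in result.assemblages.items():
        save_df(pred.matrix, f"assemblage/{scale}_{mode}_matrix.csv")
    for (scale, mode), report in result.reports.items():
        save_df(report.per_unit, f"evaluation/{scale}_{mode}_per_unit.csv")
    summaries = {
        f"{scale}_{mode}": report.summary.to_dict()
        for (scale, mode), report in result.reports.items()
    }
    summary_path = out / "evaluation/summaries.json"
    summary_path.parent.mkdir(parents=True, exist_ok=True)
    summary_path.write_text(json.dumps(summaries, indent=2, sort_keys=True))
    files.append(summary_path)
    for (scale, source), table in result.ses.items():
        save_df(table, f"phylo/ses_mpd_{scale}_{source}.csv")
    stats_path = out / "stats/summary.json"
    stats_path.parent.mkdir(parents=True, exist_ok=True)
    stats_payload = dict(result.summary)
    for scale in ("plot", "site"):
        corr = result.stats[f"richness_correlation_{scale}"]
        if corr is not None:
            stats_payload[f"rho_median_{scale}"] = corr.rho_median
            stats_payload[f"rho_ci_low_{scale}"] = corr.ci_low
            stats_payload[f"rho_ci_high_{scale}"] = corr.ci_high
    stats_path.write_text(json.dumps(stats_payload, indent=2, sort_keys=True))
    files.append(stats_path)

    manifest = {
        "seeds": {stage: result.config.stage_seed(stage) for stage in _STAGES},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(files)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
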