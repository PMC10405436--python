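"""End-to-end orchestration: simulate -> preprocess -> steps -> fit ->
population -> RSS, with file I/O and an audit log.

Every stage appends keep/drop records to one audit list and writes its
outputs as plain CSV, so a run is reproducible and each filtered object
carries a reason code.  All randomness flows from the configured root seed
through per-stage derived streams.
"""

from __future__ import annotations

import glob
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig, SimulationConfig
from .errors import FishSSFError
from .model import backward_stepwise, correlation_screen, saturated_spec_for_fish
from .population import assemble_coefficient_table, size_coefficient_models, \
    summarize_population_terms
from .rss import population_rss_curves
from .solar import SunCalendar
from .steps import annotate_covariates, build_steps, check_stratum_invariants, \
    fit_movement_distributions, generate_candidate_strata, transform_standardize
from .synthetic import ScenarioBundle, generate_scenario, write_scenario
from .terms import CONTINUOUS_COLUMNS, GlobalStandardization, is_tod_term
from .tracks import extract_approach_windows, post_filters, regularize
from .rasters import read_raster_stack


@dataclass
class PipelineResult:
    config: PipelineConfig
    step_table: pd.DataFrame
    standardization: GlobalStandardization
    models: list
    coefficient_table: object
    population_summaries: dict  # species -> DataFrame
    size_models: dict  # species -> DataFrame
    rss_curves: dict  # species -> {covariate: RSSCurve}
    audit: list
    stage_counts: list = field(default_factory=list)


def read_inputs(input_dir: str):
    """Load a scenario directory written by the simulator (or hand-built).

    Expects ``rasters/stack_q*.yaml`` sidecars, ``detections.csv``,
    ``temperature.csv`` and ``metadata.csv``.  Timestamps must be ISO-8601
    UTC and strictly increasing per fish.
    """
    raster_dir = os.path.join(input_dir, "rasters")
    sidecars = sorted(glob.glob(os.path.join(raster_dir, "stack_q*.yaml")))
    if not sidecars:
        raise FishSSFError(f"no raster sidecars found under {raster_dir!r}")
    rasters = {}
    shape = None
    for sc in sidecars:
        stack = read_raster_stack(sc)
        if shape is None:
            shape = (stack.n_rows, stack.n_cols)
        elif (stack.n_rows, stack.n_cols) != shape:
            raise FishSSFError("raster stacks disagree in shape across discharges")
        rasters[stack.meta.get("discharge_m3s")] = stack

    det = pd.read_csv(os.path.join(input_dir, "detections.csv"))
    for col in ("fish_id", "time", "x", "y"):
        if col not in det.columns:
            raise FishSSFError(f"detections.csv missing column {col!r}")
    det["time"] = pd.to_datetime(det["time"], utc=True, format="ISO8601")
    for fish_id, g in det.groupby("fish_id"):
        dt = g["time"].diff().dt.total_seconds().dropna()
        if (dt <= 0).any():
            line = int(g.index[1:][(dt <= 0).to_numpy()][0]) + 2
            raise FishSSFError(
                f"non-monotone timestamps for fish {fish_id!r} at line {line}"
            )
    temp = pd.read_csv(os.path.join(input_dir, "temperature.csv"))
    temp["time"] = pd.to_datetime(temp["time"], utc=True, format="ISO8601")
    meta = pd.read_csv(os.path.join(input_dir, "metadata.csv"))
    return rasters, det, temp, meta


def _pick_raster(rasters: dict, discharge: float):
    key = min(rasters, key=lambda q: abs(float(q) - discharge))
    return rasters[key]


def run_pipeline(config: PipelineConfig,
                 bundle: ScenarioBundle | None = None,
                 input_dir: str | None = None,
                 sim_config: SimulationConfig | None = None,
                 out_dir: str | None = None) -> PipelineResult:
    """Execute the full analysis on a scenario bundle or input directory."""
    config.validate()
    audit: list = []
    counts: list = []

    if bundle is None and input_dir is None:
        sim_config = sim_config or SimulationConfig(seed=config.seed)
        bundle = generate_scenario(sim_config)
    if bundle is not None:
        rasters = bundle.rasters
        detections, temperature, metadata = (
            bundle.detections, bundle.temperature, bundle.metadata)
    else:
        rasters, detections, temperature, metadata = read_inputs(input_dir)
    stack = _pick_raster(rasters, config.discharge)
    calendar = SunCalendar(config.site_lat, config.site_lon)
    species_of = dict(zip(metadata["fish_id"], metadata["species"]))
    tag_of = dict(zip(metadata["fish_id"], metadata.get("tag_date", [None] * len(metadata))))

    # --- preprocess: windows -> regular tracks -> post filters
    windows = extract_approach_windows(detections, config.pass_xy, config, audit=audit)
    counts.append(dict(stage="extract", records_in=len(detections),
                       records_out=len(windows)))
    tracks = []
    for w in windows:
        rt = regularize(w, config, extent=stack, audit=audit)
        keep, reason = post_filters(rt, config.pass_xy,
                                    species_of.get(w.fish_id, "barbel"),
                                    config, tag_date=tag_of.get(w.fish_id))
        audit.append(dict(fish_id=w.fish_id, object="track",
                          time=str(w.trigger_time),
                          decision="keep" if keep else "drop", reason=reason))
        if keep:
            tracks.append(rt)
    counts.append(dict(stage="tracks", records_in=len(windows),
                       records_out=len(tracks)))

    # --- steps and strata
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    per_fish_steps: dict = {}
    for rt in tracks:
        per_fish_steps.setdefault(rt.fish_id, []).append(build_steps(rt))
    strata_frames = []
    for fish_id, frames in sorted(per_fish_steps.items()):
        steps = pd.concat(frames, ignore_index=True)
        try:
            dists = fit_movement_distributions(
                steps, scope=config.distribution_scope,
                sl_floor=config.sl_floor_m, kappa_max=config.kappa_max)
        except Exception as exc:  # too few steps for this fish
            audit.append(dict(fish_id=fish_id, object="fish", time="",
                              decision="drop", reason=f"distributions: {exc}"))
            continue
        strata = generate_candidate_strata(
            steps, dists, stack, n_raw=config.n_raw_steps,
            k=config.n_kept_steps, seed=int(rng.integers(2**31)), audit=audit)
        if len(strata):
            strata_frames.append(strata)
    if not strata_frames:
        raise FishSSFError("no strata survived preprocessing")
    strata = pd.concat(strata_frames, ignore_index=True)
    strata = annotate_covariates(strata, stack, temperature, calendar,
                                 sl_floor=config.sl_floor_m, audit=audit)
    check_stratum_invariants(strata, k=config.n_kept_steps)
    step_table, stz = transform_standardize(strata)
    counts.append(dict(stage="strata", records_in=len(tracks),
                       records_out=int(step_table["stratum"].nunique())))

    screen = correlation_screen(
        step_table, columns=[c for c in CONTINUOUS_COLUMNS if c in step_table])

    # --- per-fish models
    models = []
    for fish_id, df in step_table.groupby("fish_id", sort=True):
        spec = saturated_spec_for_fish(df, fish_id=fish_id,
                                       reference_tod=config.reference_tod)
        # terms untestable for this fish (collinear within its data, e.g.
        # temperature constant over a single short approach) are pruned and
        # logged, mirroring the single-TOD rule
        from .errors import RankDeficiencyError
        from .model import ModelSpec
        terms = list(spec.terms)
        while True:
            try:
                model, history = backward_stepwise(
                    df, ModelSpec(terms, spec.reference_tod, fish_id),
                    delta=config.delta_aic, fish_id=fish_id,
                    enforce_hierarchy=config.enforce_hierarchy,
                    separation_threshold=config.separation_threshold)
                break
            except RankDeficiencyError as exc:
                drop = {t for t in terms
                        for col in exc.columns if col.startswith(t)}
                if not drop:
                    raise
                for t in sorted(drop):
                    audit.append(dict(fish_id=fish_id, object="term", time="",
                                      decision="drop",
                                      reason="collinear_in_fish_data"))
                terms = [t for t in terms if t not in drop]
        models.append(model)
    counts.append(dict(stage="fit", records_in=int(step_table["fish_id"].nunique()),
                       records_out=len(models)))

    # --- population per species
    summaries, size_models, curves = {}, {}, {}
    species = pd.Series({m.fish_id: species_of.get(m.fish_id, "all")
                         for m in models})
    coef_table = None
    for sp in sorted(set(species)):
        sp_models = [m for m in models if species[m.fish_id] == sp]
        if len(sp_models) < 2:
            continue
        table = assemble_coefficient_table(sp_models, species=species[species == sp])
        coef_table = table if coef_table is None else coef_table
        summary = summarize_population_terms(
            table, outlier_rule=config.outlier_rule, fences=config.iqr_fences,
            ci_level=config.ci_level)
        summaries[sp] = summary
        if {"weight_g", "fork_length_mm", "total_length_mm"} <= set(metadata.columns):
            size_models[sp] = size_coefficient_models(table, metadata)
        means = dict(zip(summary["term"], summary["mean"]))
        sp_curves = {}
        for cov in ("WV (end)", "D (end)", "SVG (end)",
                    "DiffVang (end)", "DiffSVGang (end)", "log(SL)"):
            pop = {t: b for t, b in means.items() if not is_tod_term(t)}
            sp_curves[cov] = population_rss_curves(sp_models, pop, cov, stz)
        curves[sp] = sp_curves

    result = PipelineResult(
        config=config, step_table=step_table, standardization=stz,
        models=models, coefficient_table=coef_table,
        population_summaries=summaries, size_models=size_models,
        rss_curves=curves, audit=audit, stage_counts=counts)
    result.stage_counts.append(dict(stage="correlation_screen",
                                    records_in=len(screen),
                                    records_out=int(screen["flagged"].sum())))
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str,
                  plots: bool = False) -> None:
    os.makedirs(out_dir, exist_ok=True)
    if plots:
        from .rss import plot_rss_curve

        plot_dir = os.path.join(out_dir, "plots")
        os.makedirs(plot_dir, exist_ok=True)
        for sp, sp_curves in result.rss_curves.items():
            for cov, curve in sp_curves.items():
                ax = plot_rss_curve(curve, title=f"{sp}: {cov}")
                safe = cov.replace(" ", "").replace("(", "_").replace(")", "")
                safe = safe.replace(":", "-").replace("/", "-")
                ax.figure.savefig(os.path.join(plot_dir, f"{sp}_{safe}.png"),
                                  dpi=120, bbox_inches="tight")
                import matplotlib.pyplot as plt

                plt.close(ax.figure)
    ff = "%.10g"
    result.step_table.to_csv(os.path.join(out_dir, "steps.csv"),
                             index=False, float_format=ff)
    result.standardization.to_csv(os.path.join(out_dir, "standardization.csv"))
    pd.DataFrame(result.audit).to_csv(os.path.join(out_dir, "filter_audit.csv"),
                                      index=False)
    recs = []
    for m in result.models:
        recs.append(dict(
            fish_id=m.fish_id, terms=m.terms, column_labels=m.column_labels,
            beta=[float(b) for b in m.beta], se=[float(s) for s in m.se],
            loglik=m.loglik, aic=m.aic, concordance=m.concordance,
            converged=m.converged, separation=m.separation))
    with open(os.path.join(out_dir, "models.json"), "w") as fh:
        json.dump(recs, fh, indent=1, sort_keys=True)
    for sp, summary in result.population_summaries.items():
        summary.to_csv(os.path.join(out_dir, f"population_{sp}.csv"),
                       index=False, float_format=ff)
    for sp, sm in result.size_models.items():
        sm.to_csv(os.path.join(out_dir, f"size_models_{sp}.csv"),
                  index=False, float_format=ff)
    rows = []
    for sp, sp_curves in result.rss_curves.items():
        for cov, curve in sp_curves.items():
            for i in range(len(curve.grid_raw)):
                row = dict(species=sp, term=cov, value=curve.grid_raw[i],
                           population=curve.population[i])
                rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "rss_curves.csv"),
                              index=False, float_format=ff)
    with open(os.path.join(out_dir, "audit_summary.txt"), "w") as fh:
        for c in result.stage_counts:
            fh.write(f"{c}\n")


def simulate_and_write(sim_config: SimulationConfig, out_dir: str,
                       force: bool = False) -> ScenarioBundle:
    bundle = generate_scenario(sim_config)
    write_scenario(bundle, out_dir, force=force)
    return bundle
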