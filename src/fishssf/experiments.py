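"""Replicated simulation studies: coefficient recovery, null calibration,
stepwise behaviour, and population-CI coverage.

These studies exercise the full inferential chain -- simulate
habitat-selective steps with known coefficients, build matched strata with
random steps, fit per-fish conditional-logistic models with backward
stepwise selection, and pool coefficients with the two-step population
procedure -- and measure how well the chain recovers the truth.

Two deliberate design choices keep the estimand well defined:

* The random-step proposal used for *fitting* is the same gamma/von-Mises
  kernel that *generated* the movement.  A proposal refitted to the
  selection-tilted observed steps changes what the movement coefficients
  estimate (log(SL) would absorb the proposal correction instead of the
  generative tilt), so recovery is only meaningful against the known kernel.
* One fixed global standardization (raster and kernel moments) is shared by
  generation and fitting, so the true coefficients live on exactly the scale
  the model estimates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .config import MovementProposal, SimulationConfig
from .errors import SimulationStalledError
from .model import ModelSpec, backward_stepwise, build_design, fit_clogit
from .population import assemble_coefficient_table, summarize_population_terms
from .steps import MovementDistributions, annotate_covariates, build_steps, \
    generate_candidate_strata, transform_standardize
from .synthetic import generate_hydraulic_rasters, reference_standardization, \
    simulate_track
from .terms import saturated_term_labels
from .tracks import RegularTrack

TRUE_BETA = {
    "WV (end)": 0.6,
    "D (end)": 0.4,
    "DiffVang (end)": 0.25,
    "log(SL)": 1.0,
    "log(SL):WV (start)": -0.5,
}

#: real covariate terms carrying no generative effect (pure noise for selection)
NOISE_TERMS = (
    "SVG (end)",
    "DiffSVGang (end)",
    "WV (end):D (end)",
    "cos(TA)",
    "log(SL):D (start)",
)


def study_universe():
    """True + noise terms, ordered as in the saturated display order."""
    wanted = set(TRUE_BETA) | set(NOISE_TERMS)
    return [t for t in saturated_term_labels(include_tod=False) if t in wanted]


@dataclass
class StudyDesign:
    n_fish: int = 30
    n_strata: int = 300
    n_raw: int = 100
    k: int = 10
    m_generate: int = 200  # softmax candidates in the generative step
    channel_length: float = 260.0
    channel_width: float = 40.0
    margin: float = 20.0  # keep simulated starts away from the ends

    def config(self) -> SimulationConfig:
        return SimulationConfig(
            channel_length=self.channel_length,
            channel_width=self.channel_width,
            proposal=MovementProposal(),
            n_candidates=self.m_generate,
            approach_bias=0.0,
        )


@lru_cache(maxsize=4)
def _study_context(design: "tuple"):
    """Raster stack + standardization for a hashable design tuple."""
    d = StudyDesign(*design)
    cfg = d.config()
    rasters = generate_hydraulic_rasters(cfg, cfg.ref_discharge)
    stz = reference_standardization(rasters, cfg)
    return cfg, rasters, stz


def _as_tuple(d: StudyDesign):
    return (d.n_fish, d.n_strata, d.n_raw, d.k, d.m_generate,
            d.channel_length, d.channel_width, d.margin)


def _proposal_dists(cfg: SimulationConfig) -> MovementDistributions:
    p = cfg.proposal
    return MovementDistributions(gamma_shape=p.gamma_shape,
                                 gamma_scale=p.gamma_scale,
                                 vm_mu=p.vm_mu, vm_kappa=p.vm_kappa,
                                 scope="known")


def _random_start(rasters, cfg, margin, rng):
    m = rasters.usable_mask.copy()
    depth_ok = rasters.depth > np.percentile(rasters.depth[m], 40)
    m &= depth_ok
    rows, cols = np.nonzero(m)
    xs = (cols + 0.5) * rasters.cell_size
    keep = (xs > margin) & (xs < cfg.channel_length - margin)
    rows, cols = rows[keep], cols[keep]
    i = rng.integers(len(rows))
    x = (cols[i] + 0.5) * rasters.cell_size
    y = rasters.y_max - (rows[i] + 0.5) * rasters.cell_size
    return (float(x), float(y))


def simulate_fish_step_table(beta: dict, design: StudyDesign, seed: int,
                             per_fish_beta: dict | None = None):
    """One fish's standardized stratified step table under known truth."""
    cfg, rasters, stz = _study_context(_as_tuple(design))
    rng = np.random.default_rng(seed)
    use_beta = per_fish_beta if per_fish_beta is not None else beta
    for attempt in range(6):
        try:
            start = _random_start(rasters, cfg, design.margin, rng)
            path = simulate_track(
                rasters, use_beta, cfg, int(rng.integers(2**31)),
                standardization=stz, n_steps=design.n_strata + 2,
                start_xy=start, start_heading=float(rng.uniform(0, 360)),
                goal_bias=0.0, fish_id=f"f{seed}",
            )
            break
        except SimulationStalledError:
            continue
    else:
        raise SimulationStalledError(0.0, 0.0, -1)
    track = RegularTrack(fish_id=path.fish_id, approach_index=1,
                         segments=[path.df], method="truth")
    steps = build_steps(track)
    strata = generate_candidate_strata(
        steps, _proposal_dists(cfg), rasters,
        n_raw=design.n_raw, k=design.k, seed=int(rng.integers(2**31)),
    )
    strata = annotate_covariates(strata, rasters, None, None)
    table, _ = transform_standardize(strata, stz)
    return table, stz


def _fit_fish(table, universe, fish_id, stepwise: bool = True):
    spec = ModelSpec(terms=list(universe), fish_id=fish_id)
    if stepwise:
        model, _ = backward_stepwise(table, spec, delta=2.0, fish_id=fish_id)
    else:
        design = build_design(table, spec)
        model = fit_clogit(design, fish_id=fish_id, terms=spec.terms)
    return model


def _replicate(beta, design, rep_seed, universe, stepwise=True,
               outlier_rule="iqr"):
    models = []
    ss = np.random.SeedSequence(rep_seed)
    for i, child in enumerate(ss.spawn(design.n_fish)):
        seed = int(child.generate_state(1)[0] % (2**31))
        table, _ = simulate_fish_step_table(beta, design, seed)
        model = _fit_fish(table, universe, fish_id=f"fish{i:02d}",
                          stepwise=stepwise)
        models.append(model)
    table = assemble_coefficient_table(models)
    summary = summarize_population_terms(table, outlier_rule=outlier_rule)
    return models, summary


def coefficient_recovery_study(seed: int, n_reps: int = 50,
                               design: StudyDesign | None = None) -> dict:
    """Recovery study: does the population CI cover each true coefficient?

    Returns per-term CI coverage over replicates, per-term per-fish
    retention rates, and per-noise-term survival rates.

    The population summary runs without outlier trimming: the replicates
    produce homogeneous per-fish estimates, and trimming a clean sample
    narrows the t-interval below nominal coverage (the same reason the CI
    calibration study disables the rule).
    """
    design = design or StudyDesign()
    universe = study_universe()
    covered = {t: 0 for t in TRUE_BETA}
    union_present = {t: 0 for t in TRUE_BETA}
    retained = {t: 0 for t in universe}
    n_models = 0
    ss = np.random.SeedSequence([seed, 101])
    for rep, child in enumerate(ss.spawn(n_reps)):
        models, summary = _replicate(TRUE_BETA, design,
                                     int(child.generate_state(1)[0] % (2**31)),
                                     universe, outlier_rule="none")
        n_models += len(models)
        for m in models:
            for t in m.terms:
                retained[t] = retained.get(t, 0) + 1
        s = summary.set_index("term")
        for t, b in TRUE_BETA.items():
            if t in s.index:
                union_present[t] += 1
                row = s.loc[t]
                if row["ci_low"] <= b <= row["ci_high"]:
                    covered[t] += 1
    return dict(
        n_reps=n_reps, n_models=n_models,
        coverage={t: covered[t] / n_reps for t in TRUE_BETA},
        union_presence={t: union_present[t] / n_reps for t in TRUE_BETA},
        true_term_retention={t: retained[t] / n_models for t in TRUE_BETA},
        noise_term_survival={t: retained.get(t, 0) / n_models
                             for t in NOISE_TERMS},
    )


def null_calibration_study(seed: int, n_reps: int = 50,
                           design: StudyDesign | None = None) -> dict:
    """All-zero coefficients: false cohesive-effect rate and concordance."""
    design = design or StudyDesign()
    universe = study_universe()
    cohesive = {t: 0 for t in universe}
    concordances = []
    ss = np.random.SeedSequence([seed, 202])
    for child in ss.spawn(n_reps):
        models, summary = _replicate({}, design,
                                     int(child.generate_state(1)[0] % (2**31)),
                                     universe, outlier_rule="none")
        concordances.extend(m.concordance for m in models)
        for _, row in summary.iterrows():
            if row["cohesive"]:
                cohesive[row["term"]] = cohesive.get(row["term"], 0) + 1
    return dict(
        n_reps=n_reps,
        cohesive_rate={t: cohesive.get(t, 0) / n_reps for t in universe},
        max_cohesive_rate=max(cohesive.values()) / n_reps if cohesive else 0.0,
        mean_concordance=float(np.mean(concordances)),
    )


def ci_coverage_study(seed: int, n_reps: int = 200, n_fish: int = 30,
                      n_strata: int = 150, mu: float = 0.4,
                      tau: float = 0.3, term: str = "D (end)") -> dict:
    """Hierarchical simulation: fish-level beta ~ Normal(mu, tau^2).

    Each fish's steps are generated under its own coefficient, fitted with
    the known-term model (no selection step), and the population t-interval
    checked for coverage of mu.  The outlier rule is disabled so the CI is
    the plain two-step interval.  Generation uses a lighter candidate count
    (M = 50): the interval width is dominated by the between-fish spread
    tau, so the finite-M approximation is immaterial here.
    """
    design = StudyDesign(n_fish=n_fish, n_strata=n_strata, m_generate=50)
    hits = 0
    ss = np.random.SeedSequence([seed, 303])
    for child in ss.spawn(n_reps):
        rep_rng = np.random.default_rng(child)
        models = []
        for i in range(n_fish):
            beta_i = {term: float(rep_rng.normal(mu, tau))}
            fish_seed = int(rep_rng.integers(2**31))
            table, _ = simulate_fish_step_table({}, design, fish_seed,
                                                per_fish_beta=beta_i)
            models.append(_fit_fish(table, [term], fish_id=f"fish{i:02d}",
                                    stepwise=False))
        table = assemble_coefficient_table(models)
        summary = summarize_population_terms(table, outlier_rule="none")
        row = summary.set_index("term").loc[term]
        if row["ci_low"] <= mu <= row["ci_high"]:
            hits += 1
    return dict(n_reps=n_reps, coverage=hits / n_reps, mu=mu, tau=tau)
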