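"""Synthetic river scenario: hydraulics, habitat-selective tracks, detections.

The generator stands in for the study's hydraulic model and telemetry array.
Depth uses a parabolic cross-section plus a scour pool near the pass; flow
velocity follows a meandering thalweg profile scaled with discharge; SVG
fields derive from the velocity grid by finite differences.  Fish tracks are
simulated by the exact generative mirror of the fitted step-selection model:
at each 20 s step, M candidate endpoints are drawn from the gamma/von-Mises
movement kernel and one is chosen with probability proportional to
exp(beta' x) of its standardized covariates.  Detections degrade the true
path with exponential ping intervals, dropout and isotropic Gaussian noise.

All stochastic operations are pure functions of (inputs, seed).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from .config import SimulationConfig
from .errors import ConfigurationError, FishSSFError, SimulationStalledError
from .rasters import HydraulicRasterStack, derive_svg_fields, write_raster_stack
from .terms import CONTINUOUS_COLUMNS, GlobalStandardization, \
    compile_linear_predictor


def bearing_deg(dx, dy):
    """Bearing of displacement (east, north), degrees clockwise from north."""
    return np.degrees(np.arctan2(dx, dy)) % 360.0


# ---------------------------------------------------------------------------
# hydraulic rasters


def generate_hydraulic_rasters(config: SimulationConfig, discharge: float) -> HydraulicRasterStack:
    """Build the five covariate grids for one discharge scenario.

    The cross-channel depth profile is parabolic with a Gaussian scour pool
    centred on the pass entrance; the velocity core meanders across the
    channel so that velocity and depth are informative but not collinear.
    Depth and velocity scale as power laws of discharge, so higher discharge
    gives pointwise non-decreasing velocity.
    """
    config.validate()
    if discharge <= 0:
        raise ConfigurationError("discharge must be positive")
    n_rows, n_cols = config.n_rows, config.n_cols
    res = config.cell_size
    x = (np.arange(n_cols) + 0.5) * res
    y_top = config.channel_width
    y = y_top - (np.arange(n_rows) + 0.5) * res  # row 0 at the top
    X, Y = np.meshgrid(x, y)
    yc = config.channel_width / 2.0

    u = (Y - yc) / (config.channel_width / 2.0)
    parab = np.clip(1.0 - u * u, 0.0, None) ** config.cross_section_flatness
    px, py = config.pass_xy
    pool = config.pool_rel_depth * np.exp(
        -((X - px) ** 2 + (Y - py) ** 2) / (2.0 * config.pool_radius**2)
    )
    dunes = 1.0 + config.dune_rel_amplitude * np.sin(
        2.0 * np.pi * X / config.dune_wavelength + 0.8 * np.pi * u
    )
    depth_raw = parab * (1.0 + pool) * dunes
    rel_q = (discharge / config.ref_discharge) ** config.depth_discharge_exponent
    mask = depth_raw > 1e-3
    scale = config.target_mean_depth / depth_raw[mask].mean()
    depth = depth_raw * scale * rel_q
    river_mask = depth > config.dry_depth

    yoff = config.thalweg_amplitude * np.sin(2.0 * np.pi * X / config.thalweg_wavelength)
    # velocity ripples run cross-channel, roughly orthogonal to the depth
    # dunes, so the two fields are not locally collinear
    ripples = 1.0 + config.ripple_rel_amplitude * np.sin(
        2.0 * np.pi * Y / config.ripple_wavelength
        + 0.6 * np.pi * np.sin(2.0 * np.pi * X / config.thalweg_wavelength)
    )
    shape = (0.15 + np.exp(-((Y - yc - yoff) ** 2) / (2.0 * config.thalweg_width**2))) * ripples
    rel_v = (discharge / config.ref_discharge) ** config.velocity_discharge_exponent
    vel = shape * (config.target_mean_velocity / shape[river_mask].mean()) * rel_v
    vel = np.where(river_mask, vel, 0.0)

    flow_dir = (90.0 + config.flow_dir_amplitude * u * np.sin(2.0 * np.pi * X / config.channel_length)) % 360.0
    svg, svg_dir = derive_svg_fields(vel, res, mask=river_mask)

    stack = HydraulicRasterStack(
        velocity=vel, depth=np.where(river_mask, depth, 0.0),
        svg=svg, flow_dir=flow_dir, svg_dir=svg_dir,
        origin_x=0.0, origin_y=0.0, cell_size=res, river_mask=river_mask,
        meta={"discharge_m3s": float(discharge)},
    )
    stack.validate()
    return stack


def reference_standardization(rasters: HydraulicRasterStack, config: SimulationConfig) -> GlobalStandardization:
    """Analytic/raster-moment standardization for the generative model.

    WV, D, SVG use wetted-cell moments; DiffVang/DiffSVGang use the moments
    of the cosine of a uniform angle (mean 0, SD sqrt(1/2)); log(SL) uses the
    digamma/trigamma moments of the log-gamma; cos(TA) uses Bessel-function
    moments of the von Mises kernel.
    """
    rows = {}
    m = rasters.usable_mask
    for cov, grid in (("wv", rasters.velocity), ("d", rasters.depth), ("svg", rasters.svg)):
        v = grid[m]
        for side in ("start", "end"):
            rows[f"{cov}_{side}"] = dict(
                mean=float(v.mean()), sd=float(v.std(ddof=1)),
                min=float(v.min()), max=float(v.max()),
            )
    for cov in ("diffvang", "diffsvgang"):
        for side in ("start", "end"):
            rows[f"{cov}_{side}"] = dict(mean=0.0, sd=float(np.sqrt(0.5)), min=-1.0, max=1.0)
    k, th = config.proposal.gamma_shape, config.proposal.gamma_scale
    rows["log_sl"] = dict(
        mean=float(special.digamma(k) + np.log(th)),
        sd=float(np.sqrt(special.polygamma(1, k))),
        min=float(special.digamma(k) + np.log(th) - 4 * np.sqrt(special.polygamma(1, k))),
        max=float(special.digamma(k) + np.log(th) + 4 * np.sqrt(special.polygamma(1, k))),
    )
    kap = config.proposal.vm_kappa
    a1 = float(special.iv(1, kap) / special.iv(0, kap))
    a2 = float(special.iv(2, kap) / special.iv(0, kap))
    var_cos = max((1.0 + a2) / 2.0 - a1 * a1, 1e-6)
    rows["cos_ta"] = dict(mean=a1, sd=float(np.sqrt(var_cos)), min=-1.0, max=1.0)
    rows["temp"] = dict(mean=config.temp_base_c, sd=max(config.temp_seasonal_amp_c, 0.5),
                        min=config.temp_base_c - 5, max=config.temp_base_c + 5)
    stats = pd.DataFrame(rows).T[["mean", "sd", "min", "max"]]
    stats = stats.loc[[c for c in CONTINUOUS_COLUMNS if c in stats.index]]
    return GlobalStandardization(stats=stats)


# ---------------------------------------------------------------------------
# track simulation


@dataclass
class TruePath:
    """Ground-truth 20 s track with the generating coefficients."""

    fish_id: str
    df: pd.DataFrame  # time (UTC), x, y
    chosen_index: np.ndarray
    beta: dict
    seed: int
    meta: dict = field(default_factory=dict)


def _candidate_covariates(rasters, start_xy, headings, ends_x, ends_y, sl, ta,
                          temp_c, sl_floor, needed=None):
    """Raw covariate columns for a batch of candidate steps from one start.

    `needed` restricts computation to the columns a linear predictor uses
    (the inner simulation loop is hot); None computes everything.
    """
    sx, sy = start_xy
    start_cov = rasters.sample_all(np.array([sx]), np.array([sy]))
    end_cov = rasters.sample_all(ends_x, ends_y)
    rad = np.radians
    n = len(sl)
    makers = {
        "wv_start": lambda: np.full(n, start_cov["velocity"][0]),
        "d_start": lambda: np.full(n, start_cov["depth"][0]),
        "svg_start": lambda: np.full(n, start_cov["svg"][0]),
        "wv_end": lambda: end_cov["velocity"],
        "d_end": lambda: end_cov["depth"],
        "svg_end": lambda: end_cov["svg"],
        "diffvang_start": lambda: np.cos(rad(headings - start_cov["flow_dir"][0])),
        "diffsvgang_start": lambda: np.cos(rad(headings - start_cov["svg_dir"][0])),
        "diffvang_end": lambda: np.cos(rad(headings - end_cov["flow_dir"])),
        "diffsvgang_end": lambda: np.cos(rad(headings - end_cov["svg_dir"])),
        "log_sl": lambda: np.log(np.maximum(sl, sl_floor)),
        "cos_ta": lambda: np.cos(ta),
        "temp": lambda: np.full(n, temp_c),
    }
    keys = makers.keys() if needed is None else needed
    return {k: makers[k]() for k in keys}


def simulate_track(
    rasters: HydraulicRasterStack,
    beta: dict,
    config: SimulationConfig,
    seed: int,
    *,
    standardization: GlobalStandardization | None = None,
    n_steps: int | None = None,
    start_xy: tuple | None = None,
    start_heading: float | None = None,
    start_time=None,
    n_candidates: int | None = None,
    goal_xy: tuple | None = None,
    goal_bias: float | None = None,
    fish_id: str = "fish",
    sl_floor: float = 1e-3,
    temp_c: float | None = None,
) -> TruePath:
    """Simulate one habitat-selective track on the 20 s grid.

    At every step M candidate endpoints are drawn from the movement kernel;
    candidates off the usable raster are excluded; one survivor is selected
    with softmax probability over the standardized linear predictor.  An
    optional goal bias (cosine alignment with the bearing to ``goal_xy``)
    models the migration drive toward the pass without entering the fitted
    covariate set.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    stz = standardization or reference_standardization(rasters, config)
    M = n_candidates or config.n_candidates
    n_steps = n_steps if n_steps is not None else config.n_steps
    pos = np.array(start_xy if start_xy is not None else config.release_xy, dtype=float)
    if not rasters.is_usable(np.array([pos[0]]), np.array([pos[1]]))[0]:
        raise ConfigurationError("release location is not inside the river")
    goal = np.array(goal_xy if goal_xy is not None else config.pass_xy, dtype=float)
    gbias = config.approach_bias if goal_bias is None else goal_bias
    heading = (
        start_heading
        if start_heading is not None
        else bearing_deg(goal[0] - pos[0], goal[1] - pos[1])
    )
    temp_c = config.temp_base_c if temp_c is None else temp_c
    shape, scale = config.proposal.gamma_shape, config.proposal.gamma_scale
    mu, kappa = config.proposal.vm_mu, config.proposal.vm_kappa
    evaluate_lp, needed_cols = compile_linear_predictor(beta, stz)

    xs = [pos[0]]; ys = [pos[1]]; chosen = []
    for step in range(n_steps):
        for _ in range(config.max_retries):
            sl = rng.gamma(shape, scale, size=M)
            ta = rng.vonmises(mu, kappa, size=M)
            cand_head = (heading + np.degrees(ta)) % 360.0
            ex = pos[0] + sl * np.sin(np.radians(cand_head))
            ey = pos[1] + sl * np.cos(np.radians(cand_head))
            valid = rasters.is_usable(ex, ey)
            if valid.any():
                break
        else:
            raise SimulationStalledError(pos[0], pos[1], step)
        cols = _candidate_covariates(rasters, pos, cand_head, ex, ey, sl, ta,
                                     temp_c, sl_floor, needed=needed_cols)
        lp = np.broadcast_to(evaluate_lp(cols), (M,)).copy()
        if gbias:
            to_goal = bearing_deg(goal[0] - pos[0], goal[1] - pos[1])
            lp += gbias * np.cos(np.radians(cand_head - to_goal))
        lp[~valid] = -np.inf
        lp -= lp.max()
        p = np.exp(lp)
        cum = np.cumsum(p)
        idx = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        chosen.append(idx)
        pos = np.array([ex[idx], ey[idx]])
        heading = cand_head[idx]
        xs.append(pos[0]); ys.append(pos[1])

    t0 = pd.Timestamp(start_time) if start_time is not None else pd.Timestamp("2018-05-10T09:00:00+00:00")
    if t0.tzinfo is None:
        t0 = t0.tz_localize("UTC")
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * config.dt, unit="s")
    df = pd.DataFrame({"time": times, "x": xs, "y": ys})
    return TruePath(fish_id=fish_id, df=df, chosen_index=np.array(chosen, dtype=int),
                    beta=dict(beta), seed=int(seed),
                    meta={"n_candidates": M, "goal_bias": gbias})


def degrade_to_detections(path: TruePath, config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Observation model: exponential ping times, dropout, Gaussian noise.

    The true path is treated as piecewise linear between its 20 s nodes.
    """
    if len(path.df) == 0:
        raise FishSSFError("cannot degrade an empty path")
    det = config.detection
    rng = np.random.default_rng(seed)
    node_t = (path.df["time"].astype("int64") / 1e9).to_numpy()
    duration = node_t[-1] - node_t[0]
    if det.dropout_prob >= 1.0:
        warnings.warn("dropout probability 1: no detections produced")
        return pd.DataFrame(columns=["fish_id", "time", "x", "y"])
    # draw enough exponential gaps to cover the track, then truncate
    n_guess = int(duration / det.mean_interval_s * 1.5) + 20
    gaps = rng.exponential(det.mean_interval_s, size=n_guess)
    t_rel = np.cumsum(gaps)
    while t_rel[-1] < duration:
        more = rng.exponential(det.mean_interval_s, size=n_guess)
        t_rel = np.concatenate([t_rel, t_rel[-1] + np.cumsum(more)])
    t_rel = t_rel[t_rel <= duration]
    keep = rng.random(t_rel.shape) >= det.dropout_prob
    t_rel = t_rel[keep]
    t_abs = node_t[0] + t_rel
    x = np.interp(t_abs, node_t, path.df["x"].to_numpy())
    y = np.interp(t_abs, node_t, path.df["y"].to_numpy())
    if det.noise_sd_m > 0:
        x = x + rng.normal(0.0, det.noise_sd_m, size=x.shape)
        y = y + rng.normal(0.0, det.noise_sd_m, size=y.shape)
    times = pd.to_datetime(t_abs * 1e9, utc=True)
    return pd.DataFrame({"fish_id": path.fish_id, "time": times, "x": x, "y": y})


# ---------------------------------------------------------------------------
# temperature, metadata, full scenario


def generate_temperature(config: SimulationConfig) -> pd.DataFrame:
    """Median receiver temperature every 15 min: smooth seasonal + diel curve."""
    start = pd.Timestamp(config.study_start, tz="UTC") - pd.Timedelta(days=1)
    end = pd.Timestamp(config.study_end, tz="UTC") + pd.Timedelta(days=1)
    times = pd.date_range(start, end, freq="15min")
    doy = times.dayofyear.to_numpy()
    hour = times.hour.to_numpy() + times.minute.to_numpy() / 60.0
    temp = (
        config.temp_base_c
        + config.temp_seasonal_amp_c * np.sin(2 * np.pi * (doy - 100) / 365.0)
        + config.temp_diel_amp_c * np.sin(2 * np.pi * (hour - 9) / 24.0)
    )
    return pd.DataFrame({"time": times, "temp_c": temp})


_SIZE_PARAMS = {  # TL mean/SD (mm), weight mean/SD (g)
    "barbel": (498.0, 73.0, 1356.0, 592.0),
    "grayling": (367.0, 56.0, 630.0, 270.0),
}


def generate_metadata(fish_ids, species, tag_dates, seed) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for fid, sp, tag in zip(fish_ids, species, tag_dates):
        tl_m, tl_s, w_m, w_s = _SIZE_PARAMS[sp]
        tl = max(float(rng.normal(tl_m, tl_s)), 120.0)
        rows.append(
            dict(fish_id=fid, species=sp,
                 total_length_mm=round(tl, 1),
                 fork_length_mm=round(0.93 * tl, 1),
                 weight_g=round(max(float(rng.normal(w_m, w_s)), 50.0), 1),
                 tag_date=pd.Timestamp(tag).date().isoformat())
        )
    return pd.DataFrame(rows)


@dataclass
class ScenarioBundle:
    config: SimulationConfig
    rasters: dict  # discharge -> HydraulicRasterStack
    detections: pd.DataFrame
    temperature: pd.DataFrame
    metadata: pd.DataFrame
    true_paths: list
    standardization: GlobalStandardization


def generate_scenario(config: SimulationConfig | None = None) -> ScenarioBundle:
    """Build the complete self-consistent input bundle with known truth."""
    config = config or SimulationConfig()
    config.validate()
    rasters = {q: generate_hydraulic_rasters(config, q) for q in config.discharges}
    stack = rasters[min(config.discharges, key=lambda q: abs(q - config.ref_discharge))]
    stz = reference_standardization(stack, config)
    ss = np.random.SeedSequence(config.seed)
    track_seeds = ss.spawn(config.n_fish)
    paths, detections = [], []
    fish_ids, species_list, tag_dates = [], [], []
    for i in range(config.n_fish):
        sp = config.species_cycle[i % len(config.species_cycle)]
        fid = f"{sp[:1].upper()}{i + 1:03d}"
        start = pd.Timestamp(config.track_starts[sp]) + pd.Timedelta(
            days=(i // len(config.species_cycle)) * config.track_spacing_days
        )
        child = track_seeds[i].generate_state(2)
        path = simulate_track(
            stack, config.true_beta, config, int(child[0] % (2**31)),
            standardization=stz, start_time=start, fish_id=fid,
        )
        det = degrade_to_detections(path, config, int(child[1] % (2**31)))
        paths.append(path)
        detections.append(det)
        fish_ids.append(fid)
        species_list.append(sp)
        tag_dates.append(start - pd.Timedelta(days=3))
    det_df = (
        pd.concat(detections, ignore_index=True)
        if detections
        else pd.DataFrame(columns=["fish_id", "time", "x", "y"])
    )
    meta = generate_metadata(fish_ids, species_list, tag_dates, config.seed + 1)
    return ScenarioBundle(
        config=config, rasters=rasters, detections=det_df,
        temperature=generate_temperature(config), metadata=meta,
        true_paths=paths, standardization=stz,
    )


def write_scenario(bundle: ScenarioBundle, out_dir: str, force: bool = False) -> None:
    """Write the bundle as text files (ESRI ASCII grids + CSV + truth)."""
    if os.path.exists(out_dir) and os.listdir(out_dir) and not force:
        raise FishSSFError(f"output directory {out_dir!r} is not empty (use force)")
    os.makedirs(out_dir, exist_ok=True)
    raster_dir = os.path.join(out_dir, "rasters")
    for q, stack in bundle.rasters.items():
        write_raster_stack(stack, raster_dir, q)
    det = bundle.detections.copy()
    det["time"] = pd.to_datetime(det["time"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    det.to_csv(os.path.join(out_dir, "detections.csv"), index=False, float_format="%.6f")
    temp = bundle.temperature.copy()
    temp["time"] = temp["time"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    temp.to_csv(os.path.join(out_dir, "temperature.csv"), index=False, float_format="%.4f")
    bundle.metadata.to_csv(os.path.join(out_dir, "metadata.csv"), index=False)
    bundle.standardization.to_csv(os.path.join(out_dir, "standardization.csv"))
    with open(os.path.join(out_dir, "true_coefficients.txt"), "w") as fh:
        fh.write(f"# generating coefficients (standardized scale); seed {bundle.config.seed}\n")
        for term, b in bundle.config.true_beta.items():
            fh.write(f"{term}\t{b!r}\n")
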