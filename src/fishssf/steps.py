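"""True steps, movement distributions, random-step strata, covariates.

A *step* joins consecutive points of a regularized track; a *stratum* is the
matched set of one true step plus exactly `k` random alternatives sharing its
start point, start time and previous heading.  Random steps are drawn from
gamma (step length) and von Mises (turning angle) distributions fitted to the
true steps, the standard integrated-SSF construction.

Step tables are plain pandas DataFrames with the column vocabulary of
:mod:`fishssf.terms`; strata are identified by the ``stratum`` column with a
boolean ``case`` flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import EmptyInputError, EstimationError
from .rasters import HydraulicRasterStack
from .solar import SunCalendar, classify_time_of_day
from .synthetic import bearing_deg
from .terms import CONTINUOUS_COLUMNS, GlobalStandardization
from .tracks import RegularTrack


def build_steps(track: RegularTrack) -> pd.DataFrame:
    """True steps from a regularized track.

    SL is the Euclidean start->end distance; heading the displacement bearing
    (degrees clockwise from north); TA the signed change of heading wrapped
    to (-180, 180].  The first step of each segment has no previous heading,
    so its TA is NaN.  Zero-length steps keep SL = 0, carry the previous
    heading forward and are flagged.
    """
    rows = []
    for seg_idx, seg in enumerate(track.segments):
        if len(seg) < 2:
            continue
        x = seg["x"].to_numpy(); y = seg["y"].to_numpy()
        t = seg["time"].to_numpy()
        dx = np.diff(x); dy = np.diff(y)
        sl = np.hypot(dx, dy)
        heading = bearing_deg(dx, dy)
        flagged = sl == 0
        for i in range(1, len(heading)):  # carry heading through zero steps
            if flagged[i]:
                heading[i] = heading[i - 1]
        ta = np.full(len(sl), np.nan)
        dh = (heading[1:] - heading[:-1] + 180.0) % 360.0 - 180.0
        dh = np.where(dh == -180.0, 180.0, dh)
        ta[1:] = dh
        for i in range(len(sl)):
            rows.append(dict(
                fish_id=track.fish_id, approach=track.approach_index,
                segment=seg_idx, step=i,
                t_start=t[i], t_end=t[i + 1],
                x_start=x[i], y_start=y[i], x_end=x[i + 1], y_end=y[i + 1],
                sl=sl[i], heading=heading[i], ta=ta[i],
                prev_heading=heading[i - 1] if i > 0 else np.nan,
                zero_length=bool(flagged[i]),
            ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# movement distributions


@dataclass
class MovementDistributions:
    gamma_shape: float
    gamma_scale: float  # m
    vm_mu: float  # rad
    vm_kappa: float
    scope: str = "fish"
    capped: bool = False


def _kappa_estimate(r_bar: float) -> float:
    """Best & Fisher approximation for the von Mises concentration."""
    if r_bar < 0.53:
        return 2 * r_bar + r_bar**3 + 5 * r_bar**5 / 6
    if r_bar < 0.85:
        return -0.4 + 1.39 * r_bar + 0.43 / (1 - r_bar)
    denom = r_bar**3 - 4 * r_bar**2 + 3 * r_bar
    return np.inf if denom <= 0 else 1.0 / denom


def fit_movement_distributions(steps: pd.DataFrame, scope: str = "fish",
                               sl_floor: float = 1e-3,
                               kappa_max: float = 50.0) -> MovementDistributions:
    """ML gamma on SL and ML von Mises on TA (degrees in the table).

    The von Mises fit uses the mean resultant length with the standard
    approximation for kappa refined by one Newton step on A(kappa) = R.
    """
    sl = steps["sl"].to_numpy(dtype=float)
    sl = sl[np.isfinite(sl)]
    if len(sl) < 30:
        raise EstimationError("need at least 30 usable steps to fit distributions")
    if np.ptp(sl) == 0:
        raise EstimationError(
            "degenerate step lengths (all equal); consider raising the SL floor"
        )
    sl = np.maximum(sl, sl_floor)
    shape, _, scale = stats.gamma.fit(sl, floc=0.0)

    ta = np.radians(steps["ta"].to_numpy(dtype=float))
    ta = ta[np.isfinite(ta)]
    if len(ta) == 0:
        raise EstimationError("no usable turning angles")
    c, s = np.cos(ta).mean(), np.sin(ta).mean()
    mu = float(np.arctan2(s, c))
    r_bar = float(np.hypot(c, s))
    kappa = _kappa_estimate(r_bar)
    capped = False
    if np.isfinite(kappa) and kappa > 0:
        a = special.iv(1, kappa) / special.iv(0, kappa)
        a_prime = 1.0 - a / kappa - a * a
        if a_prime > 1e-12:
            kappa = kappa - (a - r_bar) / a_prime
    if not np.isfinite(kappa) or kappa > kappa_max:
        warnings.warn(f"kappa capped at {kappa_max} (near-degenerate turning angles)")
        kappa, capped = kappa_max, True
    kappa = max(float(kappa), 1e-8)
    return MovementDistributions(gamma_shape=float(shape), gamma_scale=float(scale),
                                 vm_mu=mu, vm_kappa=kappa, scope=scope, capped=capped)


# ---------------------------------------------------------------------------
# random-step strata


def generate_candidate_strata(true_steps: pd.DataFrame,
                              dists: MovementDistributions,
                              rasters: HydraulicRasterStack,
                              n_raw: int = 100, k: int = 10,
                              seed: int = 0,
                              audit: list | None = None) -> pd.DataFrame:
    """Attach `k` random steps to every usable true step.

    For each true step, `n_raw` (SL, TA) pairs are drawn from the fitted
    distributions, turned into endpoints relative to the previous *true*
    heading, filtered to the usable raster, and `k` survivors sampled
    uniformly without replacement.  Steps with no previous heading are
    skipped; strata with fewer than `k` survivors are dropped and logged.
    """
    audit = audit if audit is not None else []
    usable = true_steps.loc[np.isfinite(true_steps["ta"].to_numpy(dtype=float))]
    usable = usable.loc[rasters.is_usable(usable["x_end"].to_numpy(),
                                          usable["y_end"].to_numpy())]
    n = len(usable)
    if n == 0:
        return pd.DataFrame()
    rng = np.random.default_rng(seed)
    sl = rng.gamma(dists.gamma_shape, dists.gamma_scale, size=(n, n_raw))
    ta = rng.vonmises(dists.vm_mu, dists.vm_kappa, size=(n, n_raw))
    prev = usable["prev_heading"].to_numpy()[:, None]
    head = (prev + np.degrees(ta)) % 360.0
    sx = usable["x_start"].to_numpy()[:, None]
    sy = usable["y_start"].to_numpy()[:, None]
    ex = sx + sl * np.sin(np.radians(head))
    ey = sy + sl * np.cos(np.radians(head))
    valid = rasters.is_usable(ex.ravel(), ey.ravel()).reshape(n, n_raw)
    # uniform without-replacement sampling via random-key ordering
    keys = rng.random((n, n_raw))
    keys[~valid] = 2.0
    order = np.argsort(keys, axis=1)[:, :k]
    enough = valid.sum(axis=1) >= k

    cols_true = usable.reset_index(drop=True)
    for i in np.flatnonzero(~enough):
        row = cols_true.iloc[i]
        audit.append(dict(fish_id=row["fish_id"], object="stratum",
                          time=str(row["t_start"]), decision="drop",
                          reason="insufficient_valid_random_steps"))
    ok = np.flatnonzero(enough)
    if ok.size == 0:
        return pd.DataFrame()
    g = k + 1  # rows per stratum: the true step first, then k random steps
    sel = order[ok]
    take = lambda a: np.take_along_axis(a[ok], sel, axis=1)

    def interleave(case_vals, rand_vals):
        block = np.concatenate([np.asarray(case_vals)[:, None], rand_vals], axis=1)
        return block.ravel()

    tv = cols_true.iloc[ok]
    out = pd.DataFrame({
        "fish_id": np.repeat(tv["fish_id"].to_numpy(), g),
        "approach": np.repeat(tv["approach"].to_numpy(), g),
        "segment": np.repeat(tv["segment"].to_numpy(), g),
        "step": np.repeat(tv["step"].to_numpy(), g),
        "t_start": np.repeat(tv["t_start"].to_numpy(), g),
        "t_end": np.repeat(tv["t_end"].to_numpy(), g),
        "x_start": np.repeat(tv["x_start"].to_numpy(), g),
        "y_start": np.repeat(tv["y_start"].to_numpy(), g),
        "prev_heading": np.repeat(tv["prev_heading"].to_numpy(), g),
        "case": np.tile(np.r_[True, np.zeros(k, dtype=bool)], ok.size),
        "x_end": interleave(tv["x_end"].to_numpy(), take(ex)),
        "y_end": interleave(tv["y_end"].to_numpy(), take(ey)),
        "sl": interleave(tv["sl"].to_numpy(), take(sl)),
        "ta": interleave(tv["ta"].to_numpy(), np.degrees(take(ta))),
        "heading": interleave(tv["heading"].to_numpy(), take(head)),
    })
    sid = np.char.add(
        np.char.add(tv["fish_id"].astype(str).to_numpy(dtype="U"), "/"),
        np.char.add(tv["approach"].astype(str).to_numpy(dtype="U") + "/",
                    np.arange(1, ok.size + 1).astype("U")),
    )
    out.insert(0, "stratum", np.repeat(sid, g))
    return out


# ---------------------------------------------------------------------------
# covariate annotation


def annotate_covariates(strata: pd.DataFrame, rasters: HydraulicRasterStack,
                        temperature: pd.DataFrame | None,
                        calendar: SunCalendar | None,
                        sl_floor: float = 1e-3,
                        audit: list | None = None) -> pd.DataFrame:
    """Add hydraulic, temperature and time-of-day covariates to step records.

    Raster values are point-in-cell lookups at the start and end points;
    DiffVang/DiffSVGang are cosines of the angle between the step heading
    and the local flow/SVG direction; Temp is the series value nearest in
    time to the step start; TOD is classified at the step start.  Strata with
    any member in a no-data cell are dropped with a reason.
    """
    audit = audit if audit is not None else []
    if strata.empty:
        return strata
    df = strata.copy()
    start_cov = rasters.sample_all(df["x_start"].to_numpy(), df["y_start"].to_numpy())
    end_cov = rasters.sample_all(df["x_end"].to_numpy(), df["y_end"].to_numpy())
    rad = np.radians
    heading = df["heading"].to_numpy(dtype=float)
    df["wv_start"] = start_cov["velocity"]; df["wv_end"] = end_cov["velocity"]
    df["d_start"] = start_cov["depth"]; df["d_end"] = end_cov["depth"]
    df["svg_start"] = start_cov["svg"]; df["svg_end"] = end_cov["svg"]
    df["diffvang_start"] = np.cos(rad(heading - start_cov["flow_dir"]))
    df["diffvang_end"] = np.cos(rad(heading - end_cov["flow_dir"]))
    df["diffsvgang_start"] = np.cos(rad(heading - start_cov["svg_dir"]))
    df["diffsvgang_end"] = np.cos(rad(heading - end_cov["svg_dir"]))
    df["log_sl"] = np.log(np.maximum(df["sl"].to_numpy(dtype=float), sl_floor))
    df["cos_ta"] = np.cos(rad(df["ta"].to_numpy(dtype=float)))

    t_start = pd.to_datetime(df["t_start"], utc=True)
    if temperature is not None and len(temperature):
        temp = temperature.sort_values("time")
        merged = pd.merge_asof(
            pd.DataFrame({"time": t_start}).sort_values("time").reset_index(),
            temp, on="time", direction="nearest",
        ).set_index("index").sort_index()
        df["temp"] = merged["temp_c"].to_numpy()
    else:
        df["temp"] = np.nan
    if calendar is not None:
        per_stratum = df.groupby("stratum", sort=False)["t_start"].first()
        tod = {s: classify_time_of_day(t, calendar) for s, t in per_stratum.items()}
        df["tod"] = df["stratum"].map(tod)
    else:
        df["tod"] = "day"

    hydro = ["wv_start", "wv_end", "d_start", "d_end", "svg_start", "svg_end",
             "diffvang_start", "diffvang_end", "diffsvgang_start", "diffsvgang_end"]
    bad = ~np.isfinite(df[hydro].to_numpy(dtype=float)).all(axis=1)
    bad_strata = set(df.loc[bad, "stratum"])
    for s in sorted(bad_strata):
        audit.append(dict(fish_id=df.loc[df["stratum"] == s, "fish_id"].iloc[0],
                          object="stratum", time="", decision="drop",
                          reason="no_data_cell"))
    if bad_strata:
        df = df.loc[~df["stratum"].isin(bad_strata)].reset_index(drop=True)
    return df


def transform_standardize(steps: pd.DataFrame,
                          stats_in: GlobalStandardization | None = None):
    """Z-score every continuous covariate with global statistics.

    When `stats_in` is given it is applied unchanged (held-out data);
    otherwise statistics are computed over the full table (true and random
    steps pooled).  Returns ``(table, stats)`` with ``*_z`` columns added.
    """
    if steps.empty:
        raise EmptyInputError("no step records to standardize")
    stz = stats_in or GlobalStandardization.from_table(steps)
    df = steps.copy()
    for col in CONTINUOUS_COLUMNS:
        if col in df.columns and col in stz.stats.index:
            df[col + "_z"] = stz.zscore(col, df[col].to_numpy(dtype=float))
    return df, stz


def check_stratum_invariants(strata: pd.DataFrame, k: int = 10) -> None:
    """Assert the matched-set structure (one case + k controls, shared start)."""
    g = strata.groupby("stratum")
    sizes = g.size()
    if not (sizes == k + 1).all():
        raise EstimationError("stratum size differs from 1 + k")
    if not (g["case"].sum() == 1).all():
        raise EstimationError("stratum must contain exactly one true step")
    for col in ("x_start", "y_start", "tod"):
        if col in strata.columns and (g[col].nunique() != 1).any():
            raise EstimationError(f"start column {col} varies within a stratum")
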