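"""Relative selection strength (log-RSS) curves.

The log-RSS compares the selection probability of a location with covariate
value v against one holding the covariate at its mean, all other covariates
fixed at their means (standardized zero).  For a linear model this is

    log-RSS(v) = beta * z(v)

per single effect; for an interaction panel the moderator is fixed at its
observed minimum, midpoint and maximum, giving the moderated slope
beta_focal + beta_int * z(moderator).  Coefficients live on the standardized
scale, so a one-unit standardized increase changes the log-RSS by exactly
the coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DesignError
from .terms import GlobalStandardization, factor_column, is_tod_term, term_factors


@dataclass
class RSSCurve:
    term: str
    grid_raw: np.ndarray
    grid_z: np.ndarray
    population: np.ndarray
    per_fish: dict = field(default_factory=dict)
    reference_value: float = 0.0
    moderator: str | None = None
    moderator_value: float | None = None


def _covariate_grid(covariate: str, stz: GlobalStandardization, n: int = 101,
                    grid=None):
    col = factor_column(covariate)
    s = stz.stats.loc[col]
    if grid is None:
        grid = np.linspace(s["min"], s["max"], n)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid.min() < s["min"] or grid.max() > s["max"]:
            warnings.warn(f"grid clipped to observed range of {covariate}")
            grid = np.clip(grid, s["min"], s["max"])
    return grid, (grid - s["mean"]) / s["sd"], col


def log_rss_values(coefs: dict, covariate: str, grid_z: np.ndarray) -> np.ndarray:
    """Log-RSS over standardized grid values, all other covariates at mean.

    Any term whose factors are all the target covariate contributes
    beta * z^m; terms involving other covariates vanish because those sit at
    their (standardized-zero) means.  TOD-involving terms stay at the
    reference category.
    """
    out = np.zeros_like(grid_z, dtype=float)
    for label, b in coefs.items():
        if is_tod_term(label):
            continue
        factors = term_factors(label)
        if all(f == covariate for f in factors):
            out += b * grid_z ** len(factors)
    return out


def log_rss_curve(coefs: dict, covariate: str, stz: GlobalStandardization,
                  n: int = 101, grid=None) -> RSSCurve:
    """Single-effect curve from the observed minimum to maximum."""
    grid_raw, grid_z, col = _covariate_grid(covariate, stz, n, grid)
    if col == "log_sl":  # stats live in log space; display the raw SL metres
        grid_raw = np.exp(grid_raw)
    return RSSCurve(term=covariate, grid_raw=grid_raw, grid_z=grid_z,
                    population=log_rss_values(coefs, covariate, grid_z),
                    reference_value=float(stz.stats.loc[col, "mean"]))


def _interaction_label(coefs: dict, focal: str, moderator: str):
    for lbl in (f"{focal}:{moderator}", f"{moderator}:{focal}"):
        if lbl in coefs:
            return lbl
    raise DesignError(f"no interaction between {focal!r} and {moderator!r} in model")


def log_rss_interaction_panel(coefs: dict, focal: str, moderator: str,
                              stz: GlobalStandardization, n: int = 101):
    """Three focal-covariate curves at moderator = min, midpoint, max."""
    int_label = _interaction_label(coefs, focal, moderator)
    b_int = coefs[int_label]
    b_focal = coefs.get(focal, 0.0)
    mcol = factor_column(moderator)
    s = stz.stats.loc[mcol]
    if not np.isfinite(s["sd"]) or s["max"] == s["min"]:
        raise DesignError(f"moderator {moderator!r} has no range in the data")
    grid_raw, grid_z, _ = _covariate_grid(focal, stz, n)
    curves = []
    for m_raw in (s["min"], 0.5 * (s["min"] + s["max"]), s["max"]):
        z_m = (m_raw - s["mean"]) / s["sd"]
        slope = b_focal + b_int * z_m
        curves.append(RSSCurve(
            term=f"{focal} | {moderator}", grid_raw=grid_raw, grid_z=grid_z,
            population=slope * grid_z, moderator=moderator,
            moderator_value=float(m_raw),
            reference_value=float(stz.stats.loc[factor_column(focal), "mean"]),
        ))
    return curves


def population_rss_curves(models, pop_means: dict, covariate: str,
                          stz: GlobalStandardization, n: int = 101) -> RSSCurve:
    """Per-fish curves plus the population-mean curve for one covariate."""
    curve = log_rss_curve(pop_means, covariate, stz, n=n)
    for m in models:
        curve.per_fish[m.fish_id] = log_rss_values(m.coef(), covariate,
                                                   curve.grid_z)
    return curve


def plot_rss_curve(curve: RSSCurve, ax=None, title=None):
    """Population line emphasised over per-fish lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.2))
    for fid, vals in curve.per_fish.items():
        ax.plot(curve.grid_raw, vals, color="0.7", lw=0.8, zorder=1)
    ax.plot(curve.grid_raw, curve.population, color="black", lw=2.0, zorder=2,
            label="population")
    ax.axhline(0.0, color="0.85", lw=0.6)
    ax.set_xlabel(curve.term)
    ax.set_ylabel("log-RSS")
    if title:
        ax.set_title(title)
    return ax
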