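"""Two-step population inference over per-fish model coefficients.

Individual fish are fitted separately; their coefficients are then pooled
per species.  A term absent from a fish's selected model contributes a zero
("no effect").  Per term the population summary reports mean, SD, SE,
CV = SD/mean, a 95% t confidence interval and a one-sample t-test against
zero; a term has a *cohesive* population effect only when the CI excludes
zero and p < 0.05.  Outlying coefficients can be removed (default: outside
median +/- 1.5 IQR fences) before all summary statistics, so one extreme
fish cannot flip the direction of a population mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import EstimationError


@dataclass
class CoefficientTable:
    values: pd.DataFrame  # rows: fish; columns: term labels; zero-filled
    fitted: pd.DataFrame  # bool: did the fish's model actually contain the term
    species: pd.Series  # per fish


def assemble_coefficient_table(models, species=None) -> CoefficientTable:
    """Union of term columns across fish models, zero-filled where absent."""
    if len(models) < 2:
        raise EstimationError("need at least two fish to describe a population")
    ids = [m.fish_id for m in models]
    if len(set(ids)) != len(ids):
        raise EstimationError("duplicate fish id in model list")
    columns = []
    for m in models:
        for lbl in m.column_labels:
            if lbl not in columns:
                columns.append(lbl)
    values = pd.DataFrame(0.0, index=ids, columns=columns)
    fitted = pd.DataFrame(False, index=ids, columns=columns)
    for m in models:
        coefs = m.coef()
        for lbl, b in coefs.items():
            values.loc[m.fish_id, lbl] = b
            fitted.loc[m.fish_id, lbl] = True
    if species is None:
        species = pd.Series("all", index=ids)
    else:
        species = pd.Series(species, index=ids) if not isinstance(species, pd.Series) else species
    return CoefficientTable(values=values, fitted=fitted, species=species)


def _iqr_outliers(v: np.ndarray, fences: float):
    med = np.median(v)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = med - fences * iqr, med + fences * iqr
    return (v < lo) | (v > hi)


def summarize_population_terms(table: CoefficientTable,
                               outlier_rule: str = "iqr",
                               fences: float = 1.5,
                               ci_level: float = 0.95) -> pd.DataFrame:
    """Per-term population summary with the cohesive-effect flag."""
    rows = []
    for term in table.values.columns:
        v = table.values[term].to_numpy(dtype=float)
        fish = np.asarray(table.values.index)
        removed = np.zeros(len(v), dtype=bool)
        if outlier_rule == "iqr" and len(v) >= 4:
            removed = _iqr_outliers(v, fences)
        kept = v[~removed]
        row = dict(term=term, n_total=len(v), n_used=len(kept),
                   outlier_fish=";".join(map(str, fish[removed])))
        if len(kept) == 0:
            row.update(mean=np.nan, sd=np.nan, se=np.nan, cv=np.nan,
                       ci_low=np.nan, ci_high=np.nan, t=np.nan, p=np.nan,
                       cohesive=False, degenerate=False, indeterminate=True,
                       unstable=True)
            rows.append(row)
            continue
        n = len(kept)
        mean = float(np.mean(kept))
        sd = float(np.std(kept, ddof=1)) if n > 1 else np.nan
        se = sd / np.sqrt(n) if n > 1 else np.nan
        cv = sd / mean if (n > 1 and mean != 0) else np.nan
        degenerate = bool(n > 1 and sd == 0.0)
        if n > 1 and not degenerate:
            tcrit = sps.t.ppf(0.5 + ci_level / 2.0, n - 1)
            ci = (mean - tcrit * se, mean + tcrit * se)
            tstat = mean / se
            p = float(2.0 * sps.t.sf(abs(tstat), n - 1))
        elif degenerate:
            ci = (mean, mean)
            tstat = np.inf if mean != 0 else 0.0
            p = 0.0 if mean != 0 else 1.0
        else:
            ci, tstat, p = (np.nan, np.nan), np.nan, np.nan
        ci_excludes_zero = bool(np.isfinite(ci[0]) and (ci[0] > 0 or ci[1] < 0)
                                or (degenerate and mean != 0))
        cohesive = bool(ci_excludes_zero and np.isfinite(p) and p < 0.05)
        row.update(mean=mean, sd=sd, se=se, cv=cv,
                   ci_low=ci[0], ci_high=ci[1], t=float(tstat), p=p,
                   cohesive=cohesive, degenerate=degenerate,
                   indeterminate=False, unstable=bool(n < 3))
        rows.append(row)
    return pd.DataFrame(rows)


def best_size_model(aics: dict, delta: float = 2.0) -> str:
    """Pick the AIC-best size model, requiring it to beat the null by at
    least `delta` units; any tie (or smaller improvement) keeps the null."""
    others = [k for k in aics if k != "null"]
    best_other = min(others, key=lambda k: aics[k])
    if aics[best_other] < aics["null"] - delta:
        return best_other
    return "null"


def size_coefficient_models(table: CoefficientTable,
                            metadata: pd.DataFrame,
                            delta: float = 2.0) -> pd.DataFrame:
    """Null vs weight vs fork-length vs total-length linear models per term.

    Ordinary linear models of coefficient on each size measure are compared
    by AIC with the same parsimony convention as the stepwise selection: a
    size model is preferred only when its AIC is at least `delta` units
    below the null's, and ties resolve toward the null (intercept-only)
    model.
    """
    import statsmodels.api as sm

    meta = metadata.set_index("fish_id")
    missing_meta = [f for f in table.values.index if f not in meta.index]
    if missing_meta:
        raise EstimationError(f"metadata missing for fish: {missing_meta}")
    measures = ("weight_g", "fork_length_mm", "total_length_mm")
    rows = []
    for term in table.values.columns:
        if not table.fitted[term].any():
            continue
        y_all = table.values[term]
        sizes = meta.loc[y_all.index, list(measures)]
        ok = sizes.notna().all(axis=1)
        excluded = list(y_all.index[~ok])
        y = y_all[ok].to_numpy(dtype=float)
        if len(y) < 3:
            continue
        aics = {"null": float(sm.OLS(y, np.ones((len(y), 1))).fit().aic)}
        for msr in measures:
            Xm = sm.add_constant(sizes.loc[ok, msr].to_numpy(dtype=float))
            aics[msr] = float(sm.OLS(y, Xm).fit().aic)
        best = best_size_model(aics, delta=delta)
        rows.append(dict(term=term, n=len(y),
                         aic_null=aics["null"], aic_weight=aics["weight_g"],
                         aic_fork=aics["fork_length_mm"],
                         aic_total=aics["total_length_mm"],
                         best_model=best,
                         delta_aic_null=aics["null"] - aics[best],
                         excluded_fish=";".join(map(str, excluded))))
    return pd.DataFrame(rows)
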