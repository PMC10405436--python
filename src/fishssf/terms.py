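"""Model-term vocabulary and global standardization.

Term labels follow the field's display notation, e.g. ``"WV (end)"``,
``"log(SL):WV (start)"``, with ``:`` marking an interaction.  The saturated
universe contains 33 terms: 5 end-of-step habitat main effects, 9 pairwise
end-covariate interactions, 5 TOD-by-end interactions, 5 same-covariate
start-by-end interactions, and 9 movement terms (log step length, cosine of
the turning angle, and log(SL) interactions with the start habitat,
temperature and TOD).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import DesignError, EstimationError

END_COVARIATES = ("WV", "D", "SVG", "DiffVang", "DiffSVGang")

#: continuous step-table columns that get z-scored
CONTINUOUS_COLUMNS = (
    "wv_start", "wv_end", "d_start", "d_end", "svg_start", "svg_end",
    "diffvang_start", "diffvang_end", "diffsvgang_start", "diffsvgang_end",
    "temp", "log_sl", "cos_ta",
)

TOD_CATEGORIES = ("dawn", "day", "dusk", "night")

_FACTOR_TO_COLUMN = {
    "log(SL)": "log_sl",
    "cos(TA)": "cos_ta",
    "Temp": "temp",
    "Temp (start)": "temp",
}
for _c, _col in zip(END_COVARIATES,
                    ("wv", "d", "svg", "diffvang", "diffsvgang")):
    _FACTOR_TO_COLUMN[f"{_c} (end)"] = f"{_col}_end"
    _FACTOR_TO_COLUMN[f"{_c} (start)"] = f"{_col}_start"

TOD_FACTORS = ("TOD (end)", "TOD (start)")


#: the 9 pairwise end-habitat interactions of the saturated model (the
#: DiffVang x DiffSVGang pair is not part of the term set)
END_PAIRS = tuple(
    p for p in combinations(END_COVARIATES, 2)
    if p != ("DiffVang", "DiffSVGang")
)


def saturated_term_labels(include_tod: bool = True) -> list[str]:
    """The full saturated term set, in display order."""
    terms = [f"{c} (end)" for c in END_COVARIATES]
    terms += [f"{a} (end):{b} (end)" for a, b in END_PAIRS]
    if include_tod:
        terms += [f"TOD (end):{c} (end)" for c in END_COVARIATES]
    terms += [f"{c} (start):{c} (end)" for c in END_COVARIATES]
    terms += ["log(SL)", "cos(TA)"]
    terms += [f"log(SL):{c} (start)" for c in END_COVARIATES]
    terms += ["log(SL):Temp (start)"]
    if include_tod:
        terms += ["log(SL):TOD (start)"]
    return terms


def term_factors(label: str) -> list[str]:
    return [f.strip() for f in label.split(":")]


def is_tod_term(label: str) -> bool:
    return any(f in TOD_FACTORS for f in term_factors(label))


def factor_column(factor: str) -> str:
    """Continuous-factor label -> step-table column name."""
    try:
        return _FACTOR_TO_COLUMN[factor]
    except KeyError:
        raise DesignError(f"unknown model factor: {factor!r}") from None


@dataclass
class GlobalStandardization:
    """Per-column global mean/SD (and observed min/max for RSS grids)."""

    stats: pd.DataFrame  # index: column name; columns: mean, sd, min, max

    @classmethod
    def from_table(cls, df: pd.DataFrame, columns=CONTINUOUS_COLUMNS):
        rows = {}
        for col in columns:
            if col not in df:
                continue
            v = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue  # covariate entirely absent (e.g. no temperature data)
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            if sd == 0.0:
                raise EstimationError(
                    f"zero global standard deviation for covariate {col!r}"
                )
            rows[col] = dict(mean=float(np.mean(v)), sd=sd,
                             min=float(np.min(v)), max=float(np.max(v)))
        return cls(stats=pd.DataFrame(rows).T[["mean", "sd", "min", "max"]])

    def zscore(self, column: str, values):
        s = self.stats.loc[column]
        return (np.asarray(values, dtype=float) - s["mean"]) / s["sd"]

    def unscale(self, column: str, z):
        s = self.stats.loc[column]
        return np.asarray(z, dtype=float) * s["sd"] + s["mean"]

    def to_csv(self, path):
        self.stats.rename_axis("column").to_csv(path)

    @classmethod
    def from_csv(cls, path):
        return cls(stats=pd.read_csv(path, index_col="column"))


def compile_linear_predictor(beta: dict, stz: GlobalStandardization):
    """Pre-resolve term factors and z-scaling into plain floats.

    Returns ``(evaluate, needed_columns)`` where ``evaluate(columns)`` maps a
    dict of raw covariate arrays to the linear predictor.  TOD factors are
    not supported here (the generator never selects on TOD).
    """
    compiled = []
    needed = set()
    for label, b in beta.items():
        factors = []
        for f in term_factors(label):
            if f in TOD_FACTORS:
                raise DesignError("TOD factors are not supported in linear_predictor")
            col = factor_column(f)
            s = stz.stats.loc[col]
            factors.append((col, float(s["mean"]), float(s["sd"])))
            needed.add(col)
        compiled.append((float(b), factors))

    def evaluate(columns):
        lp = None
        for b, factors in compiled:
            term = b
            for col, mean, sd in factors:
                term = term * ((columns[col] - mean) / sd)
            lp = term if lp is None else lp + term
        return np.asarray(0.0 if lp is None else lp, dtype=float)

    return evaluate, needed


def linear_predictor(beta: dict, columns: dict, stz: GlobalStandardization):
    """One-shot convenience wrapper around :func:`compile_linear_predictor`."""
    evaluate, _ = compile_linear_predictor(beta, stz)
    return evaluate({k: np.asarray(v, dtype=float) for k, v in columns.items()})
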