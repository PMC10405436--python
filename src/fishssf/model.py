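"""Per-fish integrated step-selection models.

The estimator is stratified conditional logistic regression: within each
matched set (one observed step, k random alternatives) the observed step's
selection probability is the softmax of the linear predictor over the set.
The stratum-specific intercepts are conditioned out, so the negative
log-likelihood is

    NLL(beta) = sum_strata [ logsumexp_j(beta' x_j) - beta' x_case ]

which is convex in beta.  Fitting uses damped Newton iterations with an
analytic gradient and Hessian.  Model selection is backward stepwise on AIC
with the "at least two units lower" retention rule; performance is the
concordance of case-versus-control linear predictors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import qr

from .errors import DesignError, EstimationError, RankDeficiencyError
from .terms import (TOD_FACTORS, factor_column, saturated_term_labels,
                    term_factors)


@dataclass
class ModelSpec:
    terms: list
    reference_tod: str = "day"
    fish_id: str | None = None

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise DesignError("duplicate term labels in model spec")


@dataclass
class DesignData:
    X: np.ndarray  # (n, p), rows sorted by stratum
    column_labels: list  # length p
    column_terms: list  # owning term label per column
    strata: np.ndarray  # int codes, contiguous
    case: np.ndarray  # bool
    group_sizes: np.ndarray

    @property
    def n_strata(self) -> int:
        return len(self.group_sizes)


@dataclass
class FittedModel:
    fish_id: str | None
    terms: list
    column_labels: list
    beta: np.ndarray
    cov: np.ndarray
    se: np.ndarray
    loglik: float
    aic: float
    concordance: float
    n_strata: int
    converged: bool
    separation: list = field(default_factory=list)
    notes: str = ""

    def coef(self) -> dict:
        return dict(zip(self.column_labels, self.beta))


def saturated_spec_for_fish(steps: pd.DataFrame, fish_id=None,
                            reference_tod: str = "day") -> ModelSpec:
    """The full saturated term set, dropping TOD terms for single-TOD fish."""
    required = {factor_column(f)
                for t in saturated_term_labels(include_tod=False)
                for f in term_factors(t)}
    missing = sorted(c + "_z" for c in required if c + "_z" not in steps.columns)
    if missing:
        raise DesignError(f"missing standardized covariate columns: {missing}")
    tods = set(steps["tod"].unique()) if "tod" in steps.columns else set()
    include_tod = len(tods) > 1
    return ModelSpec(terms=saturated_term_labels(include_tod=include_tod),
                     reference_tod=reference_tod, fish_id=fish_id)


def build_design(steps: pd.DataFrame, spec: ModelSpec) -> DesignData:
    """Design matrix with interaction columns as products of z-scored mains.

    TOD enters only through interactions, expanded to indicator contrasts
    against the reference category; a pure TOD main effect (or any column
    constant within every stratum) is rejected at build time.
    """
    df = steps.sort_values("stratum", kind="stable").reset_index(drop=True)
    strata_codes, _ = pd.factorize(df["stratum"], sort=False)
    case = df["case"].to_numpy(dtype=bool)
    tod = df["tod"].astype(str).to_numpy() if "tod" in df.columns else None

    cols, labels, owners = [], [], []
    for label in spec.terms:
        factors = term_factors(label)
        tod_factors = [f for f in factors if f in TOD_FACTORS]
        cont = [f for f in factors if f not in TOD_FACTORS]
        if tod_factors and not cont:
            raise DesignError(
                "TOD main effects are not identifiable: time of day is "
                "constant within a stratum and enters only via interactions"
            )
        base = np.ones(len(df))
        for f in cont:
            col = factor_column(f) + "_z"
            if col not in df.columns:
                raise DesignError(f"term {label!r} needs missing column {col!r}")
            base = base * df[col].to_numpy(dtype=float)
        if not tod_factors:
            cols.append(base); labels.append(label); owners.append(label)
        else:
            if tod is None:
                raise DesignError("TOD term requested but no 'tod' column present")
            cats = [c for c in pd.unique(tod) if c != spec.reference_tod]
            for c in sorted(cats):
                cols.append(base * (tod == c))
                labels.append(f"{label}[{c}]")
                owners.append(label)
    if not cols:
        raise DesignError("empty model specification")
    X = np.column_stack(cols)
    if not np.isfinite(X).all():
        bad = [labels[j] for j in np.flatnonzero(~np.isfinite(X).all(axis=0))]
        raise DesignError(f"non-finite values in design columns {bad}")
    # reject columns constant within every stratum (no within-set contrast)
    n_groups = int(strata_codes.max()) + 1
    sizes_arr = np.bincount(strata_codes)
    if (sizes_arr == sizes_arr[0]).all():
        spread = np.ptp(X.reshape(n_groups, sizes_arr[0], -1), axis=1).max(axis=0)
        for j in np.flatnonzero(np.isclose(spread, 0.0)):
            raise DesignError(
                f"column {labels[j]!r} is constant within every stratum"
            )
    else:
        for j in range(X.shape[1]):
            v = X[:, j]
            hi = np.full(n_groups, -np.inf)
            lo = np.full(n_groups, np.inf)
            np.maximum.at(hi, strata_codes, v)
            np.minimum.at(lo, strata_codes, v)
            if np.allclose(hi, lo):
                raise DesignError(
                    f"column {labels[j]!r} is constant within every stratum"
                )
    sizes = np.bincount(strata_codes)
    return DesignData(X=X, column_labels=labels, column_terms=owners,
                      strata=strata_codes, case=case, group_sizes=sizes)


# ---------------------------------------------------------------------------
# likelihood


def _uniform_size(design: DesignData):
    sizes = design.group_sizes
    return int(sizes[0]) if (sizes == sizes[0]).all() else None


def _softmax_parts(beta, design: DesignData):
    s = design.X @ beta
    g = _uniform_size(design)
    if g is not None:  # rows are stratum-contiguous: reshape fast path
        S = s.reshape(design.n_strata, g)
        m = S.max(axis=1)
        ex = np.exp(S - m[:, None])
        denom = ex.sum(axis=1)
        lse = m + np.log(denom)
        w = (ex / denom[:, None]).reshape(-1)
        return s, lse, w
    m = np.full(design.n_strata, -np.inf)
    np.maximum.at(m, design.strata, s)
    ex = np.exp(s - m[design.strata])
    denom = np.bincount(design.strata, weights=ex,
                        minlength=design.n_strata)
    lse = m + np.log(denom)
    w = ex / denom[design.strata]
    return s, lse, w


def clogit_nll_grad(beta, design: DesignData):
    """Negative conditional log-likelihood and its gradient."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape[0] != design.X.shape[1]:
        raise DesignError("beta length does not match design columns")
    s, lse, w = _softmax_parts(beta, design)
    nll = float(lse.sum() - s[design.case].sum())
    grad = design.X.T @ w - design.X[design.case].sum(axis=0)
    return nll, grad


def clogit_hessian(beta, design: DesignData):
    _, _, w = _softmax_parts(np.asarray(beta, dtype=float), design)
    Xw = design.X * w[:, None]
    g = _uniform_size(design)
    if g is not None:
        mu = Xw.reshape(design.n_strata, g, -1).sum(axis=1)
    else:
        mu = np.zeros((design.n_strata, design.X.shape[1]))
        np.add.at(mu, design.strata, Xw)
    return design.X.T @ Xw - mu.T @ mu


def _check_rank(design: DesignData):
    # rank within strata: center each column by its stratum mean first
    means = np.zeros((design.n_strata, design.X.shape[1]))
    np.add.at(means, design.strata, design.X)
    means /= design.group_sizes[:, None]
    Xc = design.X - means[design.strata]
    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xc.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < design.X.shape[1]:
        bad = [design.column_labels[j] for j in piv[rank:]]
        raise RankDeficiencyError(bad)


def subset_design(design: DesignData, keep_terms) -> DesignData:
    """Column subset of an existing design (same strata and case rows)."""
    keep = set(keep_terms)
    idx = [j for j, t in enumerate(design.column_terms) if t in keep]
    return DesignData(
        X=design.X[:, idx],
        column_labels=[design.column_labels[j] for j in idx],
        column_terms=[design.column_terms[j] for j in idx],
        strata=design.strata, case=design.case,
        group_sizes=design.group_sizes,
    )


def fit_clogit(design: DesignData, fish_id=None, terms=None,
               max_iter: int = 100, grad_tol: float = 1e-8,
               separation_threshold: float = 15.0,
               check_rank: bool = True, start=None) -> FittedModel:
    """Newton optimization of the conditional logistic likelihood.

    Starts from zero unless a warm `start` is given (the likelihood is
    convex, so the optimum does not depend on the start)."""
    if check_rank:
        _check_rank(design)
    p = design.X.shape[1]
    beta = np.zeros(p) if start is None else np.asarray(start, dtype=float).copy()
    nll, grad = clogit_nll_grad(beta, design)
    converged = False
    for _ in range(max_iter):
        if np.linalg.norm(grad, np.inf) < grad_tol:
            converged = True
            break
        H = clogit_hessian(beta, design)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            step = grad
        t = 1.0
        for _ in range(40):  # backtracking: convexity guarantees descent
            new_beta = beta - t * step
            new_nll, new_grad = clogit_nll_grad(new_beta, design)
            if new_nll <= nll + 1e-12:
                break
            t *= 0.5
        beta, nll, grad = new_beta, new_nll, new_grad
    else:
        if np.linalg.norm(grad, np.inf) < 1e-4:
            converged = True
    H = clogit_hessian(beta, design)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    separation = [design.column_labels[j]
                  for j in np.flatnonzero(np.abs(beta) > separation_threshold)]
    loglik = -nll
    aic = 2.0 * p + 2.0 * nll
    model = FittedModel(
        fish_id=fish_id, terms=list(terms if terms is not None else
                                    dict.fromkeys(design.column_terms)),
        column_labels=list(design.column_labels), beta=beta, cov=cov, se=se,
        loglik=loglik, aic=aic, concordance=np.nan,
        n_strata=design.n_strata, converged=converged, separation=separation,
    )
    model.concordance = model_concordance(model, design)
    return model


def empty_model(design_like, fish_id=None) -> FittedModel:
    """Null (no-term) model: uniform choice within every stratum."""
    sizes = np.asarray(design_like.group_sizes)
    nll = float(np.log(sizes).sum())
    return FittedModel(fish_id=fish_id, terms=[], column_labels=[],
                       beta=np.zeros(0), cov=np.zeros((0, 0)), se=np.zeros(0),
                       loglik=-nll, aic=2.0 * nll, concordance=0.5,
                       n_strata=len(sizes), converged=True,
                       notes="empty model (all terms removed)")


def model_concordance(model: FittedModel, design: DesignData) -> float:
    """Within-stratum case-vs-control ranking, ties counted one half."""
    if model.beta.size == 0:
        return 0.5
    s = design.X @ model.beta
    case_score = np.zeros(design.n_strata)
    case_score[design.strata[design.case]] = s[design.case]
    ctrl = ~design.case
    diff = s[ctrl] - case_score[design.strata[ctrl]]
    wins = float((diff < 0).sum())
    ties = float((diff == 0).sum())
    return (wins + 0.5 * ties) / float(len(diff))


# ---------------------------------------------------------------------------
# backward stepwise selection


def retain_complex(current_aic: float, candidate_aic: float,
                   delta: float = 2.0) -> bool:
    """The retention rule: keep the more complex model only when its AIC is
    at least `delta` units lower than the simpler candidate's."""
    return current_aic <= candidate_aic - delta


def backward_stepwise(steps: pd.DataFrame, spec: ModelSpec, delta: float = 2.0,
                      fish_id=None, enforce_hierarchy: bool = False,
                      separation_threshold: float = 15.0):
    """AIC backward elimination with the delta-AIC retention rule.

    Each round evaluates every single-term deletion and takes the one with
    the lowest AIC; the more complex current model is retained (and the
    search stops) only when its AIC is at least `delta` units lower than the
    best simpler candidate.  Ties between deletions are broken toward
    removing the earlier-listed term.  TOD indicator columns are removed as
    a block with their owning term.
    """
    current_terms = list(spec.terms)
    full_design = build_design(steps, ModelSpec(list(spec.terms), spec.reference_tod))
    current = fit_clogit(full_design, fish_id=fish_id, terms=current_terms,
                         separation_threshold=separation_threshold)
    history = []
    while current_terms:
        best = None
        for term in current_terms:
            if enforce_hierarchy and _has_dependents(term, current_terms):
                continue
            cand_terms = [t for t in current_terms if t != term]
            if cand_terms:
                # columns of a full-rank design stay full-rank when subset;
                # warm-start from the current fit's coefficients
                sub = subset_design(full_design, cand_terms)
                cur_coef = current.coef()
                warm = np.array([cur_coef.get(lbl, 0.0)
                                 for lbl in sub.column_labels])
                cand = fit_clogit(sub, fish_id=fish_id, terms=cand_terms,
                                  separation_threshold=separation_threshold,
                                  check_rank=False, start=warm)
            else:
                cand = empty_model(full_design, fish_id=fish_id)
            if best is None or cand.aic < best[1].aic:  # strict: earlier wins ties
                best = (term, cand)
        if best is None:
            break
        removed, simpler = best
        if retain_complex(current.aic, simpler.aic, delta):
            break  # complex model at least delta lower: retain it
        history.append(dict(removed=removed, aic_before=current.aic,
                            aic_after=simpler.aic))
        current = simpler
        current_terms = list(current.terms)
    return current, history


def _has_dependents(term, terms):
    fac = set(term_factors(term))
    if len(fac) > 1:
        return False
    f = next(iter(fac))
    return any(f in term_factors(t) and t != term for t in terms)


# ---------------------------------------------------------------------------
# correlation screen


def correlation_screen(table: pd.DataFrame, columns=None,
                       threshold: float = 0.5) -> pd.DataFrame:
    """Pairwise Pearson correlations with the start/end-pair exemption.

    Pairs with |r| >= threshold are flagged, except the same covariate
    measured at the start and end of a step, which is reported but exempt.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    if len(columns) < 2:
        raise EstimationError("need at least two columns to screen")
    rows = []
    for i in range(len(columns)):
        for j in range(i + 1, len(columns)):
            a, b = columns[i], columns[j]
            va = table[a].to_numpy(dtype=float)
            vb = table[b].to_numpy(dtype=float)
            ok = np.isfinite(va) & np.isfinite(vb)
            if ok.sum() < 3 or np.std(va[ok]) == 0 or np.std(vb[ok]) == 0:
                rows.append(dict(col_a=a, col_b=b, r=np.nan, flagged=False,
                                 exempt=False, note="undefined (constant column)"))
                continue
            r = float(np.corrcoef(va[ok], vb[ok])[0, 1])
            exempt = _same_covariate_pair(a, b)
            rows.append(dict(col_a=a, col_b=b, r=r,
                             flagged=bool(abs(r) >= threshold and not exempt),
                             exempt=exempt, note=""))
    return pd.DataFrame(rows)


def _same_covariate_pair(a: str, b: str) -> bool:
    def split(name):
        for suffix in ("_start", "_end", " (start)", " (end)"):
            if name.endswith(suffix):
                return name[: -len(suffix)]
        return None

    ra, rb = split(a), split(b)
    return ra is not None and ra == rb and a != b
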