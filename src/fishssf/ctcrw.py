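"""Continuous-time correlated random walk (CTCRW) track regularization.

Positions follow an integrated Ornstein-Uhlenbeck velocity process per
coordinate: dv = -b v dt + s dW, dx = v dt, observed with isotropic Gaussian
measurement error.  Both coordinates share the parameters (b, s, tau).  The
model is fitted per track segment by maximum likelihood via the Kalman
prediction-error decomposition, then a Rauch-Tung-Striebel smoother predicts
positions on the regular output grid.

The measurement SD is floored (default 0.1 m) so that noise-free input cannot
drive the error variance to zero and destabilise the filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, log, pi

import numpy as np
from scipy.optimize import minimize

from .errors import EstimationError


def _transition(beta: float, sigma2: float, dt: float):
    """State transition (Phi) and process covariance (Q) for one time gap."""
    eb = exp(-beta * dt)
    phi01 = (1.0 - eb) / beta
    qvv = sigma2 / (2.0 * beta) * (1.0 - eb * eb)
    qxx = sigma2 / beta**2 * (dt - 2.0 * (1.0 - eb) / beta + (1.0 - eb * eb) / (2.0 * beta))
    qxv = sigma2 / (2.0 * beta**2) * (1.0 - 2.0 * eb + eb * eb)
    return (1.0, phi01, 0.0, eb), (qxx, qxv, qxv, qvv)


def _nll_scalar(times, obs, beta, sigma2, tau2):
    """Prediction-error NLL with plain-float state (fast path for fitting)."""
    n = len(times)
    first = 0
    while not np.isfinite(obs[first]):
        first += 1
    m0, m1 = float(obs[first]), 0.0
    stat_v = sigma2 / (2.0 * beta)
    p00 = tau2 * 10.0 + 1.0
    p01 = 0.0
    p11 = max(stat_v * 10.0, 1.0)
    nll = 0.0
    log2pi = log(2.0 * pi)
    prev_t = times[0]
    for k in range(n):
        dt = times[k] - prev_t
        if dt > 0:
            eb = exp(-beta * dt)
            b_ = (1.0 - eb) / beta
            qvv = sigma2 / (2.0 * beta) * (1.0 - eb * eb)
            qxx = sigma2 / beta**2 * (
                dt - 2.0 * (1.0 - eb) / beta + (1.0 - eb * eb) / (2.0 * beta)
            )
            qxv = sigma2 / (2.0 * beta**2) * (1.0 - 2.0 * eb + eb * eb)
            m0 = m0 + b_ * m1
            m1 = eb * m1
            n00 = p00 + 2.0 * b_ * p01 + b_ * b_ * p11 + qxx
            n01 = eb * (p01 + b_ * p11) + qxv
            n11 = eb * eb * p11 + qvv
            p00, p01, p11 = n00, n01, n11
        prev_t = times[k]
        y = obs[k]
        if y == y:  # not NaN
            S = p00 + tau2
            resid = y - m0
            nll += 0.5 * (log2pi + log(S) + resid * resid / S)
            k0 = p00 / S
            k1 = p01 / S
            m0 += k0 * resid
            m1 += k1 * resid
            n00 = p00 - k0 * p00
            n01 = p01 - k0 * p01
            n11 = p11 - k1 * p01
            p00, p01, p11 = n00, n01, n11
    return nll


def _kalman(times, obs, beta, sigma2, tau2, smooth_times=None):
    """Scalar 2-state Kalman filter (+RTS smoother when smooth_times given).

    Returns the NLL when smooth_times is None, else smoothed positions at
    smooth_times.  `obs` may contain NaN at pure-prediction times.
    """
    n = len(times)
    mx = obs[np.isfinite(obs)][0]
    m = np.array([mx, 0.0])
    stat_v = sigma2 / (2.0 * beta)
    P = np.array([[tau2 * 10.0 + 1.0, 0.0], [0.0, max(stat_v * 10.0, 1.0)]])
    nll = 0.0
    store = smooth_times is not None
    if store:
        pred_m = np.empty((n, 2)); pred_P = np.empty((n, 2, 2))
        filt_m = np.empty((n, 2)); filt_P = np.empty((n, 2, 2))
        phis = np.empty((n, 4))
    prev_t = times[0]
    for k in range(n):
        dt = times[k] - prev_t
        if dt > 0:
            (a, b_, c, d), (qxx, qxv, _, qvv) = _transition(beta, sigma2, dt)
            m = np.array([a * m[0] + b_ * m[1], d * m[1]])
            p00 = P[0, 0] + 2 * b_ * P[0, 1] + b_ * b_ * P[1, 1] + qxx
            p01 = d * (P[0, 1] + b_ * P[1, 1]) + qxv
            p11 = d * d * P[1, 1] + qvv
            P = np.array([[p00, p01], [p01, p11]])
            phi = (a, b_, c, d)
        else:
            phi = (1.0, 0.0, 0.0, 1.0)
        prev_t = times[k]
        if store:
            pred_m[k] = m; pred_P[k] = P; phis[k] = phi
        y = obs[k]
        if np.isfinite(y):
            S = P[0, 0] + tau2
            resid = y - m[0]
            nll += 0.5 * (log(2.0 * pi * S) + resid * resid / S)
            K = P[:, 0] / S
            m = m + K * resid
            P = P - np.outer(K, P[0, :])
            P = 0.5 * (P + P.T)
        if store:
            filt_m[k] = m; filt_P[k] = P
    if not store:
        return nll
    # RTS smoother
    sm = filt_m.copy(); sP = filt_P.copy()
    for k in range(n - 2, -1, -1):
        a, b_, c, d = phis[k + 1]
        Phi = np.array([[a, b_], [c, d]])
        C = filt_P[k] @ Phi.T @ np.linalg.inv(pred_P[k + 1])
        sm[k] = filt_m[k] + C @ (sm[k + 1] - pred_m[k + 1])
        sP[k] = filt_P[k] + C @ (sP[k + 1] - pred_P[k + 1]) @ C.T
    idx = np.searchsorted(times, smooth_times)
    return sm[idx, 0]


@dataclass
class CTCRWFit:
    beta: float
    sigma: float
    tau: float
    nll: float
    converged: bool


def fit_ctcrw(times, xs, ys, measurement_floor=0.1):
    """ML fit of (beta, sigma, tau) shared across the two coordinates."""
    times = np.asarray(times, dtype=float)
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if len(times) < 4:
        raise EstimationError("need at least 4 observations to fit a CTCRW")
    dts = np.diff(times)
    if np.any(dts <= 0):
        raise EstimationError("observation times must be strictly increasing")
    speed = np.hypot(np.diff(xs), np.diff(ys)) / dts
    s_guess = max(float(np.std(speed)), 1e-3)
    floor2 = measurement_floor**2

    def unpack(p):
        beta = exp(np.clip(p[0], -7.0, 4.0))
        sigma2 = exp(np.clip(p[1], -20.0, 10.0))
        tau2 = floor2 + exp(np.clip(p[2], -20.0, 8.0))
        return beta, sigma2, tau2

    def nll(p):
        beta, sigma2, tau2 = unpack(p)
        try:
            return _nll_scalar(times, xs, beta, sigma2, tau2) + _nll_scalar(
                times, ys, beta, sigma2, tau2
            )
        except (FloatingPointError, OverflowError, ValueError):
            return 1e12

    p0 = np.array([log(1.0 / max(np.mean(dts), 1e-2)), 2.0 * log(s_guess), 2.0 * log(max(measurement_floor, 1e-2))])
    res = minimize(nll, p0, method="Nelder-Mead",
                   options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-6})
    beta, sigma2, tau2 = unpack(res.x)
    return CTCRWFit(beta=beta, sigma=sigma2**0.5, tau=tau2**0.5,
                    nll=float(res.fun), converged=bool(res.success))


def predict_ctcrw(fit: CTCRWFit, times, xs, ys, grid_times):
    """Smoothed positions at grid_times (which need not coincide with obs)."""
    times = np.asarray(times, dtype=float)
    grid = np.asarray(grid_times, dtype=float)
    all_t = np.unique(np.concatenate([times, grid]))
    obs_x = np.full(all_t.shape, np.nan)
    obs_y = np.full(all_t.shape, np.nan)
    pos = np.searchsorted(all_t, times)
    obs_x[pos] = xs
    obs_y[pos] = ys
    gx = _kalman(all_t, obs_x, fit.beta, fit.sigma**2, fit.tau**2, smooth_times=grid)
    gy = _kalman(all_t, obs_y, fit.beta, fit.sigma**2, fit.tau**2, smooth_times=grid)
    return gx, gy
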