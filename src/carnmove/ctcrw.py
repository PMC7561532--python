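"""Continuous-time correlated random walk (integrated OU) imputation.

The velocity follows an Ornstein-Uhlenbeck process
``dv = -beta v dt + sigma dW`` and the position integrates it; observed
positions carry Gaussian measurement noise with SD ``tau``. The x and y
axes are treated as independent with shared parameters. The exact
discrete-time transition over a slot of length ``dt`` is Gaussian with

    a    = exp(-beta dt)
    Phi  = [[1, (1-a)/beta], [0, a]]
    Qvv  = sigma^2 (1 - a^2) / (2 beta)
    Qxv  = sigma^2 (1 - a)^2 / (2 beta^2)
    Qxx  = sigma^2 / beta^2 (dt - 2(1-a)/beta + (1-a^2)/(2 beta))

so the likelihood is computed exactly by Kalman filtering and missing
slots are filled by single draws from the Kalman (RTS) smoothing
distribution. The measurement SD is floored at 1 m: GPS noise is never
truly zero and the floor regularizes the likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .preprocess import Burst

__all__ = ["CtcrwParams", "fit_ctcrw", "impute_missing", "kalman_loglik"]

TAU_FLOOR_M = 1.0
BETA_BOUNDS = (1e-3, 50.0)


@dataclass
class CtcrwParams:
    """Fitted CTCRW parameters (per hour / meter units)."""

    beta: float  # velocity autocorrelation rate, 1/h
    sigma: float  # velocity diffusion scale, m/h^1.5
    tau: float  # measurement SD, m (>= 1)
    loglik: float
    beta_at_bound: bool = False

    def validate(self) -> None:
        if not (self.beta > 0 and self.sigma > 0 and np.isfinite(self.loglik)):
            raise ValueError("invalid CTCRW parameters")


def _transition(beta: float, sigma: float, dt: float):
    a = np.exp(-beta * dt)
    phi = np.array([[1.0, (1.0 - a) / beta], [0.0, a]])
    s2 = sigma**2
    qvv = s2 * (1.0 - a * a) / (2.0 * beta)
    qxv = s2 * (1.0 - a) ** 2 / (2.0 * beta**2)
    qxx = s2 / beta**2 * (dt - 2.0 * (1.0 - a) / beta + (1.0 - a * a) / (2.0 * beta))
    q = np.array([[qxx, qxv], [qxv, qvv]])
    return phi, q


def _initial_state(z0: float, beta: float, sigma: float, tau: float):
    mean = np.array([z0, 0.0])
    cov = np.array([[tau**2, 0.0], [0.0, sigma**2 / (2.0 * beta)]])
    return mean, cov


def _filter(z: np.ndarray, observed: np.ndarray, beta, sigma, tau, dt):
    """Kalman filter one axis over a regular slot grid.

    ``z`` has one entry per slot (NaN where unobserved). The state prior
    at slot 0 conditions on the first observation, which must exist;
    the likelihood accumulates over the remaining observations.
    """
    T = len(z)
    phi, q = _transition(beta, sigma, dt)
    f00, f01, f11 = phi[0, 0], phi[0, 1], phi[1, 1]  # phi[1,0] == 0
    qxx, qxv, qvv = q[0, 0], q[0, 1], q[1, 1]
    r = tau * tau
    m0, p0 = _initial_state(z[0], beta, sigma, tau)
    pred_m = np.zeros((T, 2))
    pred_p = np.zeros((T, 2, 2))
    filt_m = np.zeros((T, 2))
    filt_p = np.zeros((T, 2, 2))
    mx, mv = m0[0], m0[1]
    pxx, pxv, pvv = p0[0, 0], p0[0, 1], p0[1, 1]
    pred_m[0] = filt_m[0] = m0
    pred_p[0] = filt_p[0] = p0
    loglik = 0.0
    log2pi = np.log(2.0 * np.pi)
    zv = z
    obs = observed
    for t in range(1, T):
        # predict (scalar-unrolled symmetric 2x2 propagation)
        nmx = f00 * mx + f01 * mv
        nmv = f11 * mv
        a = f00 * pxx + f01 * pxv
        b = f00 * pxv + f01 * pvv
        npxx = a * f00 + b * f01 + qxx
        npxv = b * f11 + qxv
        npvv = f11 * pvv * f11 + qvv
        mx, mv, pxx, pxv, pvv = nmx, nmv, npxx, npxv, npvv
        pred_m[t, 0], pred_m[t, 1] = mx, mv
        pred_p[t, 0, 0], pred_p[t, 0, 1] = pxx, pxv
        pred_p[t, 1, 0], pred_p[t, 1, 1] = pxv, pvv
        if obs[t]:
            s = pxx + r
            innov = zv[t] - mx
            loglik += -0.5 * (log2pi + np.log(s) + innov * innov / s)
            kx = pxx / s
            kv = pxv / s
            mx += kx * innov
            mv += kv * innov
            pvv -= kv * pxv
            pxv -= kx * pxv
            pxx -= kx * pxx
        filt_m[t, 0], filt_m[t, 1] = mx, mv
        filt_p[t, 0, 0], filt_p[t, 0, 1] = pxx, pxv
        filt_p[t, 1, 0], filt_p[t, 1, 1] = pxv, pvv
    return loglik, pred_m, pred_p, filt_m, filt_p, phi


def _smooth(pred_m, pred_p, filt_m, filt_p, phi):
    """RTS smoother; returns smoothing means and covariances."""
    T = len(pred_m)
    sm = filt_m.copy()
    sp = filt_p.copy()
    for t in range(T - 2, -1, -1):
        c = filt_p[t] @ phi.T @ np.linalg.inv(pred_p[t + 1])
        sm[t] = filt_m[t] + c @ (sm[t + 1] - pred_m[t + 1])
        sp[t] = filt_p[t] + c @ (sp[t + 1] - pred_p[t + 1]) @ c.T
    return sm, sp


def kalman_loglik(
    x: np.ndarray, y: np.ndarray, observed: np.ndarray, beta, sigma, tau, dt
) -> float:
    """Joint log-likelihood of both axes under shared parameters."""
    lx = _filter(x, observed, beta, sigma, tau, dt)[0]
    ly = _filter(y, observed, beta, sigma, tau, dt)[0]
    return lx + ly


def fit_ctcrw(burst: Burst, n_starts: int = 4, min_observed: int = 20) -> CtcrwParams:
    """Maximum-likelihood CTCRW fit to one burst.

    Bounded L-BFGS on (log beta, log sigma, log tau) from several
    starting points; raises on universal optimizer failure, carrying the
    best parameters found so far in the exception.
    """
    df = burst.fixes
    observed = (~df["missing"].astype(bool)).to_numpy()
    if observed.sum() < min_observed:
        raise ValueError(f"burst has {observed.sum()} observed fixes < {min_observed}")
    x = df["x"].to_numpy(dtype=float)
    y = df["y"].to_numpy(dtype=float)
    dt = burst.interval_h
    # trim to first observed slot: the prior conditions on it
    first = int(np.argmax(observed))
    x, y, observed = x[first:], y[first:], observed[first:]

    step = np.hypot(np.diff(x[observed]), np.diff(y[observed]))
    speed_scale = max(np.nanmedian(step) / dt, 10.0)

    def nll(theta):
        beta, sigma, tau = np.exp(theta)
        tau = max(tau, TAU_FLOOR_M)
        ll = kalman_loglik(x, y, observed, beta, sigma, tau, dt)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [
        (np.log(BETA_BOUNDS[0]), np.log(BETA_BOUNDS[1])),
        (np.log(1e-2), np.log(1e6)),
        (np.log(TAU_FLOOR_M), np.log(1e4)),
    ]
    rng = np.random.default_rng(0)
    starts = [np.array([np.log(0.5), np.log(speed_scale), np.log(10.0)])]
    for _ in range(n_starts - 1):
        starts.append(
            np.array(
                [
                    rng.uniform(np.log(0.05), np.log(5.0)),
                    np.log(speed_scale) + rng.uniform(-1.5, 1.5),
                    rng.uniform(np.log(2.0), np.log(100.0)),
                ]
            )
        )
    best = None
    for s0 in starts:
        res = minimize(nll, s0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    beta, sigma, tau = np.exp(best.x)
    tau = max(tau, TAU_FLOOR_M)
    params = CtcrwParams(
        beta=float(beta),
        sigma=float(sigma),
        tau=float(tau),
        loglik=-float(best.fun),
        beta_at_bound=bool(np.isclose(beta, BETA_BOUNDS[1], rtol=1e-3)),
    )
    if not best.success and not np.isfinite(best.fun):
        err = RuntimeError("CTCRW optimizer failed to converge")
        err.best_params = params
        raise err
    params.validate()
    return params


def impute_missing(burst: Burst, params: CtcrwParams, seed: int = 0) -> Burst:
    """Fill missing slots with single draws from the smoothing law.

    Observed fixes are untouched; filled fixes get ``source='imputed'``.
    Each missing slot receives one independent draw from its marginal
    smoothing distribution per axis (single imputation). Deterministic
    under the seed.
    """
    df = burst.fixes.copy().reset_index(drop=True)
    observed = (~df["missing"].astype(bool)).to_numpy()
    if observed.all():
        return Burst(burst.animal_id, df, burst.interval_h)
    rng = np.random.default_rng(seed)
    out_xy = {}
    for col in ("x", "y"):
        z = df[col].to_numpy(dtype=float)
        _, pm, pp, fm, fp, phi = _filter(z, observed, params.beta, params.sigma, params.tau, burst.interval_h)
        sm, sp = _smooth(pm, pp, fm, fp, phi)
        draws = sm[:, 0] + np.sqrt(np.maximum(sp[:, 0, 0], 0.0)) * rng.standard_normal(len(z))
        out_xy[col] = np.where(observed, z, draws)
    df["x"] = out_xy["x"]
    df["y"] = out_xy["y"]
    df.loc[~observed, "source"] = "imputed"
    df["missing"] = False
    return Burst(burst.animal_id, df, burst.interval_h)
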