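"""Hidden Markov movement models on step length / turning angle series.

Each latent state emits step lengths from a gamma distribution
(parametrized by mean ``mu`` and SD ``s``; internally shape
``(mu/s)^2`` and scale ``s^2/mu``) and turning angles from a wrapped
Cauchy distribution (location ``m``, concentration ``rho`` in [0, 1)).
States are interpreted, in ascending step-length order, as encamped,
foraging, and traveling (plus searching in 4-state models).

Fitting maximizes the forward-algorithm likelihood by bounded
quasi-Newton (L-BFGS-B) on working-scale parameters — log means, log
SDs, turn locations, logit concentrations, and multinomial-logit
transition rows — with the exact gradient obtained from the
forward-backward smoothing quantities (Fisher's identity). A Cartesian
grid of starting values guards against local optima. Model choice
follows three sequential criteria: biological plausibility (ordered,
well-separated state means), predictive power (mean maximum posterior
> 0.85), then AIC among the survivors.

Missing turning angles (sequence starts, gaps, zero-length previous
steps) contribute only their step-length likelihood. Step lengths at or
below 1 m — below GPS noise — are treated as left-censored: they
contribute the gamma probability of the interval [0, 1 m] rather than a
point density. This keeps the likelihood proper where the gamma density
is degenerate (x = 0) and avoids the point-mass artifact that flooring
sub-resolution lengths to a single value would create, which otherwise
rewards spurious extra states during model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.special import digamma, gammainc, gammaln

__all__ = [
    "MovementModel",
    "Decoding",
    "gamma_logpdf",
    "wrapped_cauchy_logpdf",
    "forward_loglik",
    "fit_hmm",
    "multistart_fit",
    "default_start_grid",
    "viterbi",
    "state_posteriors",
    "predictive_power",
    "aic",
    "select_model",
]

LOG_FLOOR = -1e30
STEP_FLOOR_M = 1.0


# ---------------------------------------------------------------------------
# emission densities


def gamma_logpdf(x, mu, s):
    """Gamma log-density in mean/SD parametrization.

    Degenerate evaluations (x = 0 with non-exponential shape) are
    floored at ``LOG_FLOOR`` instead of +/-inf.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.asarray(mu) <= 0) or np.any(np.asarray(s) <= 0):
        raise ValueError("gamma mean and SD must be positive")
    shape = (mu / s) ** 2
    scale = s**2 / mu
    safe_x = np.where(x > 0, x, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -shape * np.log(scale) - gammaln(shape) + (shape - 1.0) * np.log(safe_x) - x / scale
    # x = 0: finite only in the exponential case (shape == 1)
    at_zero, exp_case, out = np.broadcast_arrays(x == 0, np.isclose(shape, 1.0), out)
    out = np.where(at_zero & ~exp_case, LOG_FLOOR, out)
    out = np.where(np.isfinite(out), out, LOG_FLOOR)
    return out


def wrapped_cauchy_logpdf(theta, m, rho):
    """Wrapped Cauchy log-density on (-pi, pi]."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho < 0) or np.any(rho >= 1):
        raise ValueError("wrapped Cauchy concentration must lie in [0, 1)")
    theta = np.asarray(theta, dtype=float)
    denom = 1.0 + rho**2 - 2.0 * rho * np.cos(theta - m)
    return np.log1p(-(rho**2)) - np.log(2.0 * np.pi) - np.log(denom)


# ---------------------------------------------------------------------------
# model container


@dataclass
class MovementModel:
    """A fitted N-state movement HMM, states sorted by ascending mean."""

    mu: np.ndarray  # per-state step-length mean, m
    s: np.ndarray  # per-state step-length SD, m
    m: np.ndarray  # per-state turn location, radians
    rho: np.ndarray  # per-state turn concentration, [0, 1)
    gamma: np.ndarray  # transition matrix, rows sum to 1
    delta: np.ndarray  # initial distribution
    loglik: float = np.nan

    def __post_init__(self):
        for name in ("mu", "s", "m", "rho", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.gamma = np.asarray(self.gamma, dtype=float)
        if not np.allclose(self.gamma.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.delta.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")
        if np.any(self.mu <= 0):
            raise ValueError("state means must be positive")
        if np.any((self.rho < 0) | (self.rho >= 1)):
            raise ValueError("concentrations must lie in [0, 1)")

    @property
    def n_states(self) -> int:
        return len(self.mu)

    @property
    def k(self) -> int:
        """Parameter count: 4 emission per state + N(N-1) transition + (N-1) initial."""
        n = self.n_states
        return 4 * n + n * (n - 1) + (n - 1)

    def canonical(self) -> "MovementModel":
        """Relabel states by ascending step-length mean."""
        order = np.argsort(self.mu, kind="stable")
        return MovementModel(
            mu=self.mu[order],
            s=self.s[order],
            m=self.m[order],
            rho=self.rho[order],
            gamma=self.gamma[np.ix_(order, order)],
            delta=self.delta[order],
            loglik=self.loglik,
        )

    def to_json(self) -> str:
        payload = {
            "mu": self.mu.tolist(),
            "s": self.s.tolist(),
            "m": self.m.tolist(),
            "rho": self.rho.tolist(),
            "gamma": self.gamma.tolist(),
            "delta": self.delta.tolist(),
            "loglik": self.loglik,
            "k": self.k,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "MovementModel":
        d = json.loads(text)
        return cls(
            mu=d["mu"], s=d["s"], m=d["m"], rho=d["rho"],
            gamma=d["gamma"], delta=d["delta"], loglik=d["loglik"],
        )


@dataclass
class Decoding:
    """Viterbi path plus smoothing probabilities (1-based state labels)."""

    path: np.ndarray
    posteriors: np.ndarray
    max_posterior: np.ndarray = field(init=False)

    def __post_init__(self):
        self.max_posterior = self.posteriors.max(axis=1)


# ---------------------------------------------------------------------------
# sequences: steps tables -> (lengths, angles) arrays per burst


def _sequences(steps: pd.DataFrame) -> list[tuple[np.ndarray, np.ndarray]]:
    if "burst_id" in steps.columns:
        groups = [g for _, g in steps.groupby("burst_id", sort=False)]
    else:
        groups = [steps]
    out = []
    for g in groups:
        lengths = np.maximum(g["length"].to_numpy(dtype=float), STEP_FLOOR_M)
        angles = g["turn_angle"].to_numpy(dtype=float)
        out.append((lengths, angles))
    return out


def _gamma_logcdf_floor(mu, s):
    """log P(X <= STEP_FLOOR_M) under gamma(mean mu, SD s), per state."""
    shape = (np.asarray(mu) / np.asarray(s)) ** 2
    scale = np.asarray(s) ** 2 / np.asarray(mu)
    p = gammainc(shape, STEP_FLOOR_M / scale)
    return np.where(p > 0, np.log(np.maximum(p, 1e-300)), LOG_FLOOR)


def _emission_logs(model_arrays, lengths, angles):
    """(T, N) emission log-density matrix.

    NaN angles contribute the step-length term only; lengths at or
    below the 1 m resolution floor are left-censored (interval
    probability instead of density).
    """
    mu, s, m, rho = model_arrays
    logb = gamma_logpdf(np.maximum(lengths, STEP_FLOOR_M)[:, None], mu[None, :], s[None, :])
    censored = lengths <= STEP_FLOOR_M
    if censored.any():
        logb[censored] = _gamma_logcdf_floor(mu, s)[None, :]
    has_angle = ~np.isnan(angles)
    if has_angle.any():
        wc = wrapped_cauchy_logpdf(angles[has_angle, None], m[None, :], rho[None, :])
        logb[has_angle] += wc
    return logb


# ---------------------------------------------------------------------------
# numba recursions (scaled linear-space forward/backward, log-space Viterbi)


@njit(cache=True)
def _forward_nb(b_scaled, gamma, delta):
    T, N = b_scaled.shape
    alpha = np.zeros((T, N))
    logc = 0.0
    a = delta * b_scaled[0]
    c = a.sum()
    alpha[0] = a / c
    logc += np.log(c)
    for t in range(1, T):
        a = (alpha[t - 1] @ gamma) * b_scaled[t]
        c = a.sum()
        alpha[t] = a / c
        logc += np.log(c)
    return logc, alpha


@njit(cache=True)
def _backward_nb(b_scaled, gamma):
    T, N = b_scaled.shape
    beta = np.zeros((T, N))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        v = gamma @ (b_scaled[t + 1] * beta[t + 1])
        beta[t] = v / v.sum()
    return beta


@njit(cache=True)
def _viterbi_nb(logb, loggamma, logdelta):
    T, N = logb.shape
    score = logdelta + logb[0]
    back = np.zeros((T, N), dtype=np.int64)
    for t in range(1, T):
        new = np.empty(N)
        for j in range(N):
            best = -1e300
            arg = 0
            for i in range(N):
                v = score[i] + loggamma[i, j]
                if v > best:
                    best = v
                    arg = i
            new[j] = best + logb[t, j]
            back[t, j] = arg
        score = new
    path = np.zeros(T, dtype=np.int64)
    path[T - 1] = np.argmax(score)
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1, path[t + 1]]
    return path


def _scale(logb):
    mx = logb.max(axis=1)
    return np.exp(logb - mx[:, None]), mx


# ---------------------------------------------------------------------------
# likelihood and analytic gradient on the working scale


def _n_params(n: int) -> int:
    return 4 * n + n * (n - 1) + (n - 1)


def _unpack(theta: np.ndarray, n: int):
    i = 0
    logmu = theta[i : i + n]; i += n
    logs = theta[i : i + n]; i += n
    m = theta[i : i + n]; i += n
    urho = theta[i : i + n]; i += n
    ugam = theta[i : i + n * (n - 1)].reshape(n, n - 1); i += n * (n - 1)
    udel = theta[i : i + n - 1]
    mu = np.exp(logmu)
    s = np.exp(logs)
    rho = 1.0 / (1.0 + np.exp(-urho))
    gam_logits = np.concatenate([np.zeros((n, 1)), ugam], axis=1)
    gam = np.exp(gam_logits - gam_logits.max(axis=1, keepdims=True))
    gam /= gam.sum(axis=1, keepdims=True)
    del_logits = np.concatenate([[0.0], udel])
    delta = np.exp(del_logits - del_logits.max())
    delta /= delta.sum()
    return mu, s, m, rho, gam, delta


def _pack(mu, s, m, rho, gamma, delta) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    rho = np.asarray(rho, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    delta = np.asarray(delta, dtype=float)
    eps = 1e-10
    ugam = np.log(gamma[:, 1:] + eps) - np.log(gamma[:, :1] + eps)
    udel = np.log(delta[1:] + eps) - np.log(delta[0] + eps)
    urho = np.log(rho + eps) - np.log(1.0 - rho + eps)
    return np.concatenate([np.log(mu), np.log(s), m, urho, ugam.ravel(), udel])


def _loglik_and_grad(theta: np.ndarray, sequences, n: int):
    mu, s, m, rho, gam, delta = _unpack(theta, n)
    shape = (mu / s) ** 2
    scale = s**2 / mu
    total_ll = 0.0
    g_logmu = np.zeros(n)
    g_logs = np.zeros(n)
    g_m = np.zeros(n)
    g_urho = np.zeros(n)
    xi_total = np.zeros((n, n))
    gamma1_total = np.zeros(n)
    n_seq = 0
    for lengths, angles in sequences:
        logb = _emission_logs((mu, s, m, rho), lengths, angles)
        b_scaled, mx = _scale(logb)
        logc, alpha = _forward_nb(b_scaled, gam, delta)
        beta = _backward_nb(b_scaled, gam)
        total_ll += logc + mx.sum()
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        # transition smoothing counts
        num = alpha[:-1, :, None] * gam[None, :, :] * (b_scaled[1:] * beta[1:])[:, None, :]
        num_sum = num.sum(axis=(1, 2))
        xi_total += (num / num_sum[:, None, None]).sum(axis=0)
        gamma1_total += post[0]
        n_seq += 1

        x = np.maximum(lengths, STEP_FLOOR_M)[:, None]
        dl_dshape = -np.log(scale)[None, :] - digamma(shape)[None, :] + np.log(x)
        dl_dscale = (-shape / scale)[None, :] + x / (scale**2)[None, :]
        dlogmu = dl_dshape * (2.0 * shape)[None, :] + dl_dscale * (-scale)[None, :]
        dlogs = dl_dshape * (-2.0 * shape)[None, :] + dl_dscale * (2.0 * scale)[None, :]
        cens = lengths <= STEP_FLOOR_M
        if cens.any():
            # censored terms: central differences of the log interval
            # probability on the working scale (no closed form in shape)
            h = 1e-6
            d_mu = (
                _gamma_logcdf_floor(mu * np.exp(h), s) - _gamma_logcdf_floor(mu * np.exp(-h), s)
            ) / (2.0 * h)
            d_s = (
                _gamma_logcdf_floor(mu, s * np.exp(h)) - _gamma_logcdf_floor(mu, s * np.exp(-h))
            ) / (2.0 * h)
            dlogmu[cens] = d_mu[None, :]
            dlogs[cens] = d_s[None, :]
        g_logmu += (post * dlogmu).sum(axis=0)
        g_logs += (post * dlogs).sum(axis=0)

        has_angle = ~np.isnan(angles)
        if has_angle.any():
            th = angles[has_angle, None]
            denom = 1.0 + (rho**2)[None, :] - 2.0 * rho[None, :] * np.cos(th - m[None, :])
            dm = 2.0 * rho[None, :] * np.sin(th - m[None, :]) / denom
            drho = (-2.0 * rho / (1.0 - rho**2))[None, :] - (
                2.0 * rho[None, :] - 2.0 * np.cos(th - m[None, :])
            ) / denom
            w = post[has_angle]
            g_m += (w * dm).sum(axis=0)
            g_urho += (w * drho).sum(axis=0) * rho * (1.0 - rho)

    # transition-row logits (reference column 0)
    row_tot = xi_total.sum(axis=1, keepdims=True)
    g_gam_full = xi_total - row_tot * gam
    g_ugam = g_gam_full[:, 1:].ravel()
    g_del_full = gamma1_total - n_seq * delta
    g_udel = g_del_full[1:]

    grad = np.concatenate([g_logmu, g_logs, g_m, g_urho, g_ugam, g_udel])
    return total_ll, grad


def forward_loglik(model: MovementModel, steps: pd.DataFrame) -> float:
    """Forward-algorithm log-likelihood, summed over bursts."""
    total = 0.0
    for lengths, angles in _sequences(steps):
        logb = _emission_logs((model.mu, model.s, model.m, model.rho), lengths, angles)
        b_scaled, mx = _scale(logb)
        logc, _ = _forward_nb(b_scaled, model.gamma, model.delta)
        total += logc + mx.sum()
    return float(total)


# ---------------------------------------------------------------------------
# fitting


_BOUND_LOGMU = (np.log(0.5), np.log(5e4))
_BOUND_LOGS = (np.log(0.5), np.log(5e4))
_BOUND_M = (-2.0 * np.pi, 2.0 * np.pi)
_BOUND_U = (-12.0, 12.0)


def _bounds(n: int):
    return (
        [_BOUND_LOGMU] * n
        + [_BOUND_LOGS] * n
        + [_BOUND_M] * n
        + [_BOUND_U] * n
        + [_BOUND_U] * (n * (n - 1))
        + [_BOUND_U] * (n - 1)
    )


def fit_hmm(
    steps: pd.DataFrame,
    n_states: int,
    start: MovementModel | np.ndarray | None = None,
    maxiter: int = 300,
) -> MovementModel:
    """Local maximum-likelihood fit from one starting point.

    ``start`` may be a MovementModel or a packed working-scale vector;
    by default states are spread over the observed length quantiles.
    The returned model's log-likelihood is never below the start's.
    """
    sequences = _sequences(steps)
    if isinstance(start, MovementModel):
        theta0 = _pack(start.mu, start.s, start.m, start.rho, start.gamma, start.delta)
    elif start is not None:
        theta0 = np.asarray(start, dtype=float)
    else:
        lengths = np.concatenate([l for l, _ in sequences])
        qs = np.quantile(lengths, np.linspace(0.2, 0.9, n_states))
        theta0 = _start_vector(qs, qs, 0.5, n_states)

    def negll(theta):
        ll, grad = _loglik_and_grad(theta, sequences, n_states)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(theta)
        return -ll, -grad

    res = minimize(
        negll,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=_bounds(n_states),
        options={"maxiter": maxiter, "maxfun": 4 * maxiter},
    )
    ll0 = _loglik_and_grad(theta0, sequences, n_states)[0]
    if -res.fun < ll0 - 1e-9:
        # L-BFGS must not end below its start; fall back to the start
        res.x, res.fun = theta0, -ll0
    if not np.isfinite(res.fun):
        err = RuntimeError("HMM optimizer failed")
        err.start = theta0
        err.trace = res
        raise err
    mu, s, m, rho, gam, delta = _unpack(res.x, n_states)
    model = MovementModel(mu, s, _wrap_angles(m), rho, gam, delta, loglik=float(-res.fun))
    return model.canonical()


def _wrap_angles(m):
    return np.pi - (np.pi - np.asarray(m)) % (2.0 * np.pi)


def _start_vector(means, sds, rho, n: int) -> np.ndarray:
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    gam = np.full((n, n), 0.1 / max(n - 1, 1))
    np.fill_diagonal(gam, 0.9)
    delta = np.full(n, 1.0 / n)
    return _pack(means, sds, np.zeros(n), np.full(n, rho), gam, delta)


def default_start_grid(n_states: int, mean_pool=(5.0, 50.0, 200.0, 500.0, 1500.0), rhos=(0.2, 0.7)):
    """Cartesian starting grid: ordered mean subsets crossed with rho values."""
    from itertools import combinations

    grid = []
    for means in combinations(mean_pool, n_states):
        for rho in rhos:
            grid.append(_start_vector(np.array(means), np.array(means), rho, n_states))
    return grid


def multistart_fit(
    steps: pd.DataFrame,
    n_states: int,
    start_grid=None,
    screen_iter: int = 20,
    n_refine: int = 2,
) -> MovementModel:
    """Best-by-likelihood fit over a grid of starting values.

    Every start is first run for ``screen_iter`` quasi-Newton iterations;
    the ``n_refine`` most promising are then run to convergence and the
    winner (ties broken by grid order) is returned with its grid
    provenance attached as ``.n_starts``.
    """
    if start_grid is None:
        start_grid = default_start_grid(n_states)
    if len(start_grid) == 0:
        raise ValueError("empty starting grid")
    screened = []
    failures = []
    for idx, theta0 in enumerate(start_grid):
        try:
            mdl = fit_hmm(steps, n_states, start=theta0, maxiter=screen_iter)
            screened.append((mdl.loglik, idx, mdl))
        except RuntimeError as exc:
            failures.append((idx, exc))
    if not screened:
        raise RuntimeError(f"all {len(start_grid)} starts failed: {failures}")
    screened.sort(key=lambda t: (-t[0], t[1]))
    best = None
    for ll, idx, _ in screened[:n_refine]:
        mdl = fit_hmm(steps, n_states, start=np.asarray(start_grid[idx], dtype=float))
        if best is None or mdl.loglik > best.loglik + 1e-9:
            best = mdl
    best.n_starts = len(start_grid)
    return best


# ---------------------------------------------------------------------------
# decoding and selection


def viterbi(model: MovementModel, steps: pd.DataFrame) -> np.ndarray:
    """Most probable joint state path (1-based), concatenated over bursts."""
    paths = []
    logdelta = np.log(model.delta + 1e-300)
    loggamma = np.log(model.gamma + 1e-300)
    for lengths, angles in _sequences(steps):
        logb = _emission_logs((model.mu, model.s, model.m, model.rho), lengths, angles)
        paths.append(_viterbi_nb(logb, loggamma, logdelta) + 1)
    return np.concatenate(paths)


def state_posteriors(model: MovementModel, steps: pd.DataFrame) -> Decoding:
    """Forward-backward smoothing probabilities plus the Viterbi path."""
    posts = []
    for lengths, angles in _sequences(steps):
        logb = _emission_logs((model.mu, model.s, model.m, model.rho), lengths, angles)
        b_scaled, _ = _scale(logb)
        _, alpha = _forward_nb(b_scaled, model.gamma, model.delta)
        beta = _backward_nb(b_scaled, model.gamma)
        post = alpha * beta
        post /= post.sum(axis=1, keepdims=True)
        posts.append(post)
    return Decoding(path=viterbi(model, steps), posteriors=np.vstack(posts))


def predictive_power(decoding: Decoding) -> float:
    """Mean over steps of the maximum posterior state probability."""
    return float(decoding.max_posterior.mean())


def aic(model: MovementModel) -> float:
    return -2.0 * model.loglik + 2.0 * model.k


def select_model(
    candidates: dict[int, MovementModel],
    decodings: dict[int, Decoding],
    min_mean_ratio: float = 3.0,
    predictive_threshold: float = 0.85,
) -> tuple[MovementModel, dict]:
    """Apply the three sequential selection criteria.

    1. biological plausibility: consecutive state step-length means
       differ by at least ``min_mean_ratio`` (states are mean-ordered);
    2. predictive power: mean max posterior above the threshold;
    3. minimum AIC among the survivors.

    Raises (with the full criteria report attached) if nothing survives.
    """
    report = {}
    survivors = []
    for n, model in sorted(candidates.items()):
        ratios = model.mu[1:] / model.mu[:-1]
        plausible = bool(np.all(ratios >= min_mean_ratio))
        power = predictive_power(decodings[n])
        predictive = power > predictive_threshold
        entry = {
            "n_states": n,
            "mean_ratios": ratios.tolist(),
            "plausible": plausible,
            "predictive_power": power,
            "predictive": predictive,
            "aic": aic(model),
        }
        report[n] = entry
        if plausible and predictive:
            survivors.append(n)
    if not survivors:
        err = RuntimeError("no candidate passed plausibility and predictive-power filters")
        err.report = report
        raise err
    chosen = min(survivors, key=lambda n: report[n]["aic"])
    for n in report:
        report[n]["selected"] = n == chosen
    return candidates[chosen], report
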