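"""Integrated step selection analysis (iSSA).

Each observed ("used") step is matched with ten random steps drawn from
the pooled empirical step-length and turn-angle distributions of all
individuals, sharing the used step's start point and previous bearing.
Every candidate is characterized by the landscape covariates at its
endpoint plus two movement covariates — the natural log of step length
and the cosine of the turning angle — and a conditional logistic
regression is fitted separately to each temporal-behavior dataset
(season x light x movement state), maximizing the stratified partial
likelihood (a softmax over the 11 candidates per stratum) by
Newton-Raphson with the analytic gradient and Hessian. Standard errors
come from the inverse observed information; a coefficient is flagged
significant when 2 SE < |beta|. Variance inflation factors are computed
by OLS of each covariate on the others over all candidate rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import COVARIATE_NAMES, sample_covariates
from .landscape import LandscapeStack

__all__ = [
    "SelectionFit",
    "empirical_distributions",
    "generate_random_steps",
    "build_strata",
    "partition_steps",
    "fit_clogit",
    "null_loglik",
    "vif",
    "significance_flags",
]

N_RANDOM_DEFAULT = 10
DEFAULT_MODEL_TERMS = COVARIATE_NAMES + ["log_sl", "cos_ta"]
VIF_SENTINEL = 1e6


@dataclass
class SelectionFit:
    """Conditional-logistic fit for one season x light x behavior dataset."""

    dataset_key: tuple
    covariates: list
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n_strata: int
    vif: np.ndarray | None = None
    separation: np.ndarray | None = None

    @property
    def significant(self) -> np.ndarray:
        return significance_flags(self)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "beta": self.beta,
                "se": self.se,
                "significant": self.significant,
                "vif": self.vif if self.vif is not None else np.nan,
                "n_strata": self.n_strata,
            }
        )


def empirical_distributions(steps: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pooled empirical step-length and turn-angle samples, all animals."""
    lengths = steps["length"].to_numpy(dtype=float)
    lengths = lengths[np.isfinite(lengths)]
    angles = steps["turn_angle"].to_numpy(dtype=float)
    angles = angles[np.isfinite(angles)]
    if len(lengths) == 0 or len(angles) == 0:
        raise ValueError("empty empirical distributions")
    return lengths, angles


def generate_random_steps(
    start: tuple[float, float],
    prev_bearing: float,
    distributions: tuple[np.ndarray, np.ndarray],
    n: int = N_RANDOM_DEFAULT,
    rng: np.random.Generator | None = None,
    bounds: tuple | None = None,
    max_attempts: int = 100,
) -> pd.DataFrame:
    """Draw ``n`` random candidate steps from the empirical distributions.

    Each candidate resamples an independent (length, turn angle) pair;
    the endpoint follows from the previous bearing plus the turn.
    Candidates landing outside ``bounds`` (xmin, ymin, xmax, ymax) are
    redrawn up to ``max_attempts`` times, then an error is raised.
    """
    rng = rng or np.random.default_rng()
    lengths_pool, angles_pool = distributions
    x0, y0 = start
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
        if not (xmin <= x0 < xmax and ymin <= y0 < ymax):
            raise ValueError(f"stratum start ({x0:.1f}, {y0:.1f}) outside landscape")
    rows = []
    for _ in range(n):
        for attempt in range(max_attempts):
            length = float(rng.choice(lengths_pool))
            turn = float(rng.choice(angles_pool))
            bearing = prev_bearing + turn
            ex = x0 + length * np.cos(bearing)
            ey = y0 + length * np.sin(bearing)
            if bounds is None or (xmin <= ex < xmax and ymin <= ey < ymax):
                rows.append({"length": length, "turn_angle": turn, "x_end": ex, "y_end": ey})
                break
        else:
            raise RuntimeError("could not place a random step inside the landscape")
    return pd.DataFrame(rows)


def build_strata(
    steps: pd.DataFrame,
    stack: LandscapeStack,
    distributions: tuple[np.ndarray, np.ndarray] | None = None,
    n_random: int = N_RANDOM_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Used/available strata with covariates, long format.

    ``steps`` needs length, turn_angle, bearing, endpoints, and the
    season / light / state labels. Strata whose used step lacks a
    defined turning angle, or that touch imputed fixes, are dropped
    (cos turn angle is a model covariate; imputed steps are excluded
    from selection analysis). Returns one row per candidate with
    ``case`` = 1 for the used step and a shared ``stratum`` id.
    """
    rng = np.random.default_rng(seed)
    if distributions is None:
        distributions = empirical_distributions(steps)
    usable = steps[~steps["turn_angle"].isna()]
    if "imputed" in usable.columns:
        usable = usable[~usable["imputed"].astype(bool)]
    bounds = stack.bounds
    pad = stack.cellsize
    bounds = (bounds[0] + pad, bounds[1] + pad, bounds[2] - pad, bounds[3] - pad)
    parts = []
    for stratum_id, (_, row) in enumerate(usable.iterrows()):
        prev_bearing = row["bearing"] - row["turn_angle"]
        rand = generate_random_steps(
            (row["x_start"], row["y_start"]),
            prev_bearing,
            distributions,
            n=n_random,
            rng=rng,
            bounds=bounds,
        )
        cand = pd.concat(
            [
                pd.DataFrame(
                    [
                        {
                            "length": row["length"],
                            "turn_angle": row["turn_angle"],
                            "x_end": row["x_end"],
                            "y_end": row["y_end"],
                        }
                    ]
                ),
                rand,
            ],
            ignore_index=True,
        )
        cand["case"] = [1] + [0] * n_random
        cand["stratum"] = stratum_id
        for col in ("season", "light", "state"):
            if col in row.index:
                cand[col] = row[col]
        parts.append(cand)
    if not parts:
        return pd.DataFrame()
    strata = pd.concat(parts, ignore_index=True)
    cov = sample_covariates(stack, strata[["x_end", "y_end"]].to_numpy())
    strata = pd.concat([strata.reset_index(drop=True), cov.reset_index(drop=True)], axis=1)
    strata["log_sl"] = np.log(np.maximum(strata["length"].to_numpy(), 1.0))
    strata["cos_ta"] = np.cos(strata["turn_angle"].to_numpy())
    return strata


STATE_NAMES = {1: "encamped", 2: "foraging", 3: "traveling", 4: "searching"}


def partition_steps(strata: pd.DataFrame) -> dict[tuple, pd.DataFrame]:
    """Split strata rows into season x light x behavior datasets."""
    out = {}
    for (season, light, state), grp in strata.groupby(["season", "light", "state"], sort=True):
        key = (str(season), str(light), STATE_NAMES.get(int(state), str(state)))
        out[key] = grp.reset_index(drop=True)
    return out


def _stratum_arrays(dataset: pd.DataFrame, covariates: list[str]):
    """(n_strata, K, p) design tensor and used-candidate index per stratum."""
    groups = list(dataset.groupby("stratum", sort=True))
    K = len(groups[0][1])
    X = np.empty((len(groups), K, len(covariates)))
    used = np.empty(len(groups), dtype=int)
    for g, (_, grp) in enumerate(groups):
        if len(grp) != K:
            raise ValueError("unequal candidate counts across strata")
        X[g] = grp[covariates].to_numpy(dtype=float)
        used[g] = int(np.argmax(grp["case"].to_numpy()))
    return X, used


def null_loglik(n_strata: int, n_candidates: int = N_RANDOM_DEFAULT + 1) -> float:
    """Partial log-likelihood of the null model (beta = 0)."""
    return n_strata * np.log(1.0 / n_candidates)


def _partial_loglik(X, used, beta):
    eta = X @ beta
    mx = eta.max(axis=1)
    lse = mx + np.log(np.exp(eta - mx[:, None]).sum(axis=1))
    return float(eta[np.arange(len(used)), used].sum() - lse.sum())


def fit_clogit(
    dataset: pd.DataFrame,
    covariates: list[str] | None = None,
    min_strata: int = 20,
    max_iter: int = 60,
    tol: float = 1e-10,
    ridge: float = 1e-8,
    dataset_key: tuple = (),
) -> SelectionFit:
    """Newton-Raphson conditional-logistic fit of one dataset.

    Raises when a covariate has no within-stratum contrast anywhere
    (naming it) or when there are fewer than ``min_strata`` strata.
    Coefficients running away (|beta| > 15 on standardized-scale data)
    are flagged as separation with an infinite-SE marker rather than an
    error. The Newton iteration uses step halving, so the partial
    likelihood increases monotonically.
    """
    covariates = list(covariates) if covariates is not None else list(DEFAULT_MODEL_TERMS)
    n_strata = dataset["stratum"].nunique()
    if n_strata < min_strata:
        raise ValueError(f"{n_strata} strata < required {min_strata}")
    X, used = _stratum_arrays(dataset, covariates)
    # within-stratum contrast check
    spread = np.ptp(X, axis=1).max(axis=0)
    dead = [c for c, s in zip(covariates, spread) if s == 0]
    if dead:
        raise ValueError(f"no within-stratum contrast for covariates: {dead}")

    p = X.shape[2]
    beta = np.zeros(p)
    ll = _partial_loglik(X, used, beta)
    n = len(used)
    idx = np.arange(n)
    for _ in range(max_iter):
        eta = X @ beta
        eta -= eta.max(axis=1, keepdims=True)
        w = np.exp(eta)
        w /= w.sum(axis=1, keepdims=True)
        xbar = np.einsum("gk,gkp->gp", w, X)
        grad = (X[idx, used] - xbar).sum(axis=0)
        info = np.einsum("gk,gkp,gkq->pq", w, X, X) - np.einsum("gp,gq->pq", xbar, xbar)
        info = info + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular information matrix; collinear columns among {covariates}"
            ) from exc
        # step halving: never decrease the partial likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new = _partial_loglik(X, used, cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        moved = np.abs(scale * step).max()
        beta = beta + scale * step
        ll = _partial_loglik(X, used, beta)
        if moved < tol or np.abs(grad).max() < 1e-8:
            break
    cov_beta = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))
    separation = np.abs(beta) > 15.0
    se = np.where(separation, np.inf, se)
    fit = SelectionFit(
        dataset_key=dataset_key,
        covariates=covariates,
        beta=beta,
        se=se,
        loglik=ll,
        n_strata=n,
        separation=separation,
    )
    fit.vif = vif(dataset, covariates)
    return fit


def vif(dataset: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    """Variance inflation factors over all candidate rows.

    VIF_j = 1 / (1 - R^2_j) from OLS of covariate j on the others (with
    intercept); perfect collinearity reports the 1e6 sentinel.
    """
    Z = dataset[list(covariates)].to_numpy(dtype=float)
    n, p = Z.shape
    out = np.empty(p)
    for j in range(p):
        yj = Z[:, j]
        Xj = np.column_stack([np.ones(n), np.delete(Z, j, axis=1)])
        coef, *_ = np.linalg.lstsq(Xj, yj, rcond=None)
        resid = yj - Xj @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        if ss_tot == 0:
            out[j] = VIF_SENTINEL
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        out[j] = VIF_SENTINEL if r2 >= 1.0 - 1e-9 else 1.0 / (1.0 - r2)
    return out


def significance_flags(fit: SelectionFit) -> np.ndarray:
    """True where 2 SE < |beta| (strict inequality)."""
    return 2.0 * fit.se < np.abs(fit.beta)


def results_long(fits: dict[tuple, SelectionFit]) -> pd.DataFrame:
    """Long-format results table across datasets."""
    rows = []
    for key, fit in fits.items():
        for j, cov in enumerate(fit.covariates):
            rows.append(
                {
                    "season": key[0],
                    "light": key[1],
                    "behavior": key[2],
                    "covariate": cov,
                    "beta": fit.beta[j],
                    "se": fit.se[j],
                    "significant": bool(fit.significant[j]),
                    "vif": fit.vif[j] if fit.vif is not None else np.nan,
                    "n_strata": fit.n_strata,
                }
            )
    return pd.DataFrame(rows)
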