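"""Synthetic landscapes and movement tracks with known ground truth.

The generator emulates the study system the pipeline is built for: a
rugged temperate landscape (forested / open / wetland cover with sparse
anthropogenic features, low-elevation lowlands against a > 300 m
plateau, a handful of linear corridors) and collared-canid movement — a
three-state Markov switching walk whose states are, in ascending
step-length order, encamped, foraging, and traveling, with gamma step
lengths and wrapped-Cauchy turning angles, an optional habitat-selection
bias, a 2-h fix schedule, and missing fixes.

Habitat selection is generated with an importance-sampling scheme: at
every step, ``n_candidates`` endpoints are drawn from the movement
kernel of the current state and one is chosen with probability
proportional to ``exp(beta . z(endpoint))``, where ``z`` are the
landscape covariates. As ``n_candidates`` grows this converges to the
step-selection density the iSSA estimates, so the selection
coefficients are recoverable by conditional logistic regression.
Candidate endpoints falling off the landscape are reflected back across
the boundary (never an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, box

from .landscape import ANTHROPOGENIC, FOREST, OPEN, WETLAND, LandscapeStack
from .raster import Raster

__all__ = [
    "LandscapeSpec",
    "TrackSpec",
    "make_landscape",
    "simulate_track",
    "sample_wrapped_cauchy",
    "drop_fixes",
]

#: order in which cumulative class proportions are assigned to the
#: smoothed random field
_CLASS_ORDER = ("forest", "open", "wetland", "anthropogenic")
_CLASS_CODE = {"forest": FOREST, "open": OPEN, "wetland": WETLAND, "anthropogenic": ANTHROPOGENIC}


class InvalidSpecError(ValueError):
    """Raised when a generator spec violates its invariants."""


@dataclass
class LandscapeSpec:
    """Parameters of a synthetic landscape.

    ``class_proportions`` maps forest/open/wetland/anthropogenic to target
    area fractions (must sum to 1). ``relief_amplitude`` is the total
    elevation range in meters; ``plateau_threshold`` the elevation that
    separates lowland from plateau regimes (300 m in the study system).
    """

    grid_size: int = 512
    cell_size: float = 10.0
    class_proportions: dict = field(
        default_factory=lambda: {"forest": 0.55, "open": 0.25, "wetland": 0.15, "anthropogenic": 0.05}
    )
    relief_amplitude: float = 500.0
    plateau_threshold: float = 300.0
    corridor_count: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.grid_size <= 0 or self.cell_size <= 0:
            raise InvalidSpecError("grid size and cell size must be positive")
        total = sum(self.class_proportions.get(c, 0.0) for c in _CLASS_ORDER)
        if not np.isclose(total, 1.0, atol=1e-8):
            raise InvalidSpecError(f"class proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise InvalidSpecError("class proportions must be nonnegative")


@dataclass
class TrackSpec:
    """Parameters of a simulated movement track.

    Per-state arrays are ordered encamped, foraging, traveling; step-length
    means must be strictly increasing in that order. ``selection_coefs``
    maps covariate names (see :mod:`carnmove.covariates`) to log-selection
    strengths; empty means selection-free movement.
    """

    step_means: tuple = (7.0, 198.0, 1426.0)
    step_sds: tuple = (7.0, 150.0, 800.0)
    turn_concentrations: tuple = (0.3, 0.2, 0.8)
    turn_locations: tuple = (np.pi, 0.0, 0.0)
    transition_matrix: np.ndarray = field(
        default_factory=lambda: np.array(
            [[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]]
        )
    )
    fix_interval_h: float = 2.0
    duration_days: float = 60.0
    missingness: float = 0.085
    selection_coefs: dict = field(default_factory=dict)
    n_candidates: int = 50
    start: tuple | None = None
    start_time: str = "2013-01-01T00:00:00Z"
    seed: int = 0

    @property
    def n_states(self) -> int:
        return len(self.step_means)

    def validate(self) -> None:
        gamma = np.asarray(self.transition_matrix, dtype=float)
        if gamma.shape != (self.n_states, self.n_states):
            raise InvalidSpecError("transition matrix shape mismatch")
        if not np.allclose(gamma.sum(axis=1), 1.0, atol=1e-8):
            raise InvalidSpecError("transition matrix rows must sum to 1")
        means = np.asarray(self.step_means, dtype=float)
        if np.any(np.diff(means) <= 0):
            raise InvalidSpecError("step-length means must increase encamped -> traveling")
        if not 0.0 <= self.missingness <= 0.25:
            raise InvalidSpecError("missingness must lie in [0, 0.25]")
        if any(not 0 <= r < 1 for r in self.turn_concentrations):
            raise InvalidSpecError("turn concentrations must lie in [0, 1)")


def _smooth_field(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Gaussian random field: white noise smoothed at scale ``sigma`` cells."""
    noise = rng.standard_normal((n, n))
    f = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    f = f - f.min()
    rng_span = f.max() - f.min()
    return f / rng_span if rng_span > 0 else np.zeros_like(f)


def make_landscape(spec: LandscapeSpec) -> LandscapeStack:
    """Generate a co-registered land-cover / DEM / corridor stack.

    Land cover is produced by thresholding a smoothed Gaussian random
    field at the cumulative class proportions, which yields contiguous
    patches with near-exact class frequencies. The DEM is a
    low-frequency field rescaled to ``[0, relief_amplitude]`` with a
    sigmoid plateau along the x-axis, so elevations span both sides of
    the plateau threshold whenever the amplitude exceeds it. Corridors
    are random straight chords of the domain. Fully deterministic given
    the spec (including its seed).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size

    # land cover: quantile thresholds on a smoothed field
    patch_scale = max(2.0, n / 32.0)
    fcover = _smooth_field(rng, n, patch_scale)
    order = np.argsort(fcover, axis=None)
    cover = np.empty(n * n, dtype=int)
    start = 0
    ncells = n * n
    cum = 0.0
    for cname in _CLASS_ORDER:
        cum += spec.class_proportions.get(cname, 0.0)
        stop = int(round(cum * ncells))
        cover[order[start:stop]] = _CLASS_CODE[cname]
        start = stop
    cover[order[start:]] = _CLASS_CODE[_CLASS_ORDER[-1]]
    cover = cover.reshape(n, n)

    # DEM: low-frequency relief + plateau sigmoid along x
    base = _smooth_field(rng, n, max(4.0, n / 8.0))
    xs = np.linspace(-6.0, 6.0, n)
    plateau = 1.0 / (1.0 + np.exp(-xs))[None, :]
    dem = 0.4 * base + 0.6 * plateau
    dem = dem - dem.min()
    span = dem.max()
    if span > 0:
        dem = dem / span
    dem = dem * spec.relief_amplitude

    cellsize = spec.cell_size
    landcover = Raster(cover, cellsize)
    dem_raster = Raster(dem, cellsize)

    # corridors: random chords clipped to the domain box
    extent = n * cellsize
    domain = box(0, 0, extent, extent)
    corridors = []
    for _ in range(spec.corridor_count):
        theta = rng.uniform(0, np.pi)
        cx, cy = rng.uniform(0.1 * extent, 0.9 * extent, size=2)
        dx, dy = np.cos(theta), np.sin(theta)
        big = 4.0 * extent
        line = LineString([(cx - big * dx, cy - big * dy), (cx + big * dx, cy + big * dy)])
        clipped = line.intersection(domain)
        if not clipped.is_empty and clipped.geom_type == "LineString":
            corridors.append(clipped)

    return LandscapeStack(landcover=landcover, dem=dem_raster, corridors=corridors)


def sample_wrapped_cauchy(rng: np.random.Generator, m: float, rho: float, size=None) -> np.ndarray:
    """Draw wrapped-Cauchy angles by the inverse-CDF construction."""
    u = rng.uniform(0.0, 1.0, size=size)
    theta = m + 2.0 * np.arctan(((1.0 - rho) / (1.0 + rho)) * np.tan(np.pi * (u - 0.5)))
    return _wrap_angle(theta)


def _wrap_angle(theta):
    """Wrap to (-pi, pi]."""
    out = np.mod(-np.asarray(theta) + np.pi, 2.0 * np.pi)
    return np.pi - out


def _reflect(value: float, lo: float, hi: float) -> float:
    """Mirror a coordinate back into [lo, hi] (repeatedly if needed)."""
    if not np.isfinite(hi - lo):
        return value
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def simulate_track(
    track_spec: TrackSpec, landscape: LandscapeStack | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate one animal's track; returns (fixes, true state labels).

    States evolve as a Markov chain; each step draws its length from the
    state's gamma distribution and its turning angle from the state's
    wrapped-Cauchy distribution. With nonzero ``selection_coefs`` (and a
    landscape), endpoints are importance-sampled toward preferred
    habitat (see module docstring). True states are 1-based, ordered by
    ascending step-length mean.
    """
    track_spec.validate()
    if track_spec.selection_coefs and landscape is None:
        raise InvalidSpecError("selection coefficients require a landscape")
    rng = np.random.default_rng(track_spec.seed)
    n_steps = int(round(track_spec.duration_days * 24.0 / track_spec.fix_interval_h))
    gamma = np.asarray(track_spec.transition_matrix, dtype=float)
    n_states = track_spec.n_states

    if landscape is not None:
        xmin, ymin, xmax, ymax = landscape.bounds
        # stay clear of the outer cell ring so covariates stay sampleable
        pad = landscape.cellsize
        xmin, ymin, xmax, ymax = xmin + pad, ymin + pad, xmax - pad, ymax - pad
    else:
        xmin = ymin = -np.inf
        xmax = ymax = np.inf

    if track_spec.start is not None:
        x, y = track_spec.start
    elif landscape is not None:
        x, y = 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)
    else:
        x, y = 0.0, 0.0

    # stationary distribution of the chain for the initial state
    eigvals, eigvecs = np.linalg.eig(gamma.T)
    k = int(np.argmin(np.abs(eigvals - 1.0)))
    statdist = np.real(eigvecs[:, k])
    statdist = np.abs(statdist) / np.abs(statdist).sum()
    state = rng.choice(n_states, p=statdist)

    shapes = (np.asarray(track_spec.step_means) / np.asarray(track_spec.step_sds)) ** 2
    scales = np.asarray(track_spec.step_sds) ** 2 / np.asarray(track_spec.step_means)

    sel_names = list(track_spec.selection_coefs)
    sel_betas = np.array([track_spec.selection_coefs[c] for c in sel_names])
    if sel_names:
        from .covariates import sample_covariate_matrix  # deferred: avoids import cycle

    bearing = rng.uniform(-np.pi, np.pi)
    xs = [x]
    ys = [y]
    states = [state]
    m_cand = track_spec.n_candidates
    for _ in range(n_steps):
        state = rng.choice(n_states, p=gamma[state])
        if sel_names:
            lengths = rng.gamma(shapes[state], scales[state], size=m_cand)
            turns = sample_wrapped_cauchy(
                rng, track_spec.turn_locations[state], track_spec.turn_concentrations[state], m_cand
            )
            bearings = bearing + turns
            cx = x + lengths * np.cos(bearings)
            cy = y + lengths * np.sin(bearings)
            cx = np.array([_reflect(v, xmin, xmax) for v in cx])
            cy = np.array([_reflect(v, ymin, ymax) for v in cy])
            zmat = sample_covariate_matrix(landscape, cx, cy, sel_names)
            logw = zmat @ sel_betas
            w = np.exp(logw - logw.max())
            pick = rng.choice(m_cand, p=w / w.sum())
            nx, ny = cx[pick], cy[pick]
            bearing = np.arctan2(ny - y, nx - x)
        else:
            length = rng.gamma(shapes[state], scales[state])
            turn = float(
                sample_wrapped_cauchy(
                    rng,
                    track_spec.turn_locations[state],
                    track_spec.turn_concentrations[state],
                )
            )
            bearing = _wrap_angle(bearing + turn)
            nx = _reflect(x + length * np.cos(bearing), xmin, xmax)
            ny = _reflect(y + length * np.sin(bearing), ymin, ymax)
        x, y = float(nx), float(ny)
        xs.append(x)
        ys.append(y)
        states.append(state)

    t0 = pd.Timestamp(track_spec.start_time)
    times = t0 + pd.to_timedelta(
        np.arange(n_steps + 1) * track_spec.fix_interval_h, unit="h"
    )
    fixes = pd.DataFrame(
        {
            "id": "sim",
            "timestamp": times,
            "x": xs,
            "y": ys,
            "source": "observed",
            "missing": False,
        }
    )
    true_states = np.asarray(states) + 1
    fixes["true_state"] = true_states
    if track_spec.missingness > 0:
        fixes = drop_fixes(fixes, track_spec.missingness, max_gap=4, seed=int(rng.integers(2**31)))
    return fixes, true_states


def drop_fixes(
    fixes: pd.DataFrame, missingness_rate: float, max_gap: int = 4, seed: int = 0
) -> pd.DataFrame:
    """Mark fixes missing at random, never more than ``max_gap`` in a row.

    The first and last fixes are always retained so the track span is
    preserved. Deterministic given the seed; a rate of 0 returns the
    input unchanged.
    """
    if not 0.0 <= missingness_rate <= 0.25:
        raise InvalidSpecError("missingness rate must lie in [0, 0.25]")
    if missingness_rate == 0.0:
        return fixes
    rng = np.random.default_rng(seed)
    out = fixes.copy().reset_index(drop=True)
    n = len(out)
    missing = np.zeros(n, dtype=bool)
    run = 0
    for i in range(n):
        if i in (0, n - 1):
            run = 0
            continue
        if run < max_gap and rng.uniform() < missingness_rate:
            missing[i] = True
            run += 1
        else:
            run = 0
    out.loc[missing, ["x", "y"]] = np.nan
    out["missing"] = out["missing"].to_numpy() | missing
    return out
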