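"""The nine landscape covariates of the global step-selection model.

At a point these are: binary forest / open cover at the local (10 m
cell) scale; forest and open proportions within 500 m; forest-open edge
density within 50 m (m of shared forest|open cell boundary per m^2 of
circle); Simpson diversity of forest / open / wetland within 500 m;
linear-corridor density within 100 m and 500 m (km of corridor inside
the circle — length per neighborhood, matching the km/100 m and
km/500 m units); elevation in hundreds of meters; and slope in radians
(Horn's 3x3 gradient).

Focal statistics use cell-center-in-circle membership (inclusive) and,
at raster edges, the available cells only. Per-point primitives accept
arbitrary coordinates; the bulk sampler ``sample_covariates`` evaluates
raster-aligned statistics at the center of the containing cell using
cached FFT-convolution focal rasters, which agrees exactly with the
primitives at cell centers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .landscape import COVER_CLASSES, FOREST, OPEN, WETLAND, LandscapeStack
from .raster import Raster

__all__ = [
    "COVARIATE_NAMES",
    "reclass_landcover",
    "focal_proportion",
    "edge_density",
    "simpson_diversity",
    "slope_from_dem",
    "corridor_density",
    "sample_covariates",
    "sample_covariate_matrix",
]

COVARIATE_NAMES = [
    "forest10",
    "open10",
    "forest500",
    "open500",
    "edge50",
    "simpson500",
    "corridor100",
    "corridor500",
    "elev100",
    "slope",
]


def reclass_landcover(raw: Raster, mapping: dict) -> Raster:
    """Collapse a raw land-cover raster into the four analysis classes.

    ``mapping`` sends every raw code to a class name ("forest", "open",
    "wetland", "anthropogenic") or directly to a class code.
    """
    vals = raw.values.astype(int)
    codes = np.unique(vals)
    unmapped = [int(c) for c in codes if c not in mapping]
    if unmapped:
        raise ValueError(f"unmapped land-cover codes: {unmapped}")
    out = np.zeros_like(vals)
    for code in codes:
        target = mapping[code]
        if isinstance(target, str):
            target = COVER_CLASSES[target]
        out[vals == code] = target
    return raw.like(out)


# ---------------------------------------------------------------------------
# per-point focal primitives


def _window_mask(raster: Raster, x: float, y: float, radius: float):
    """Rows/cols of cells whose centers lie within ``radius`` of (x, y)."""
    xs, ys = raster.cell_centers()
    half = int(np.ceil(radius / raster.cellsize)) + 1
    r0, c0 = raster.index_of(x, y)
    rows = np.arange(max(0, r0 - half), min(raster.nrows, r0 + half + 1))
    cols = np.arange(max(0, c0 - half), min(raster.ncols, c0 + half + 1))
    cx = xs[cols][None, :]
    cy = ys[rows][:, None]
    inside = np.hypot(cx - x, cy - y) <= radius + 1e-9
    return rows, cols, inside


def focal_proportion(class_raster: Raster, class_code: int, radius: float, x: float, y: float) -> float:
    """Fraction of in-circle cells equal to ``class_code``."""
    rows, cols, inside = _window_mask(class_raster, x, y, radius)
    window = class_raster.values[np.ix_(rows, cols)]
    n = inside.sum()
    if n == 0:
        raise ValueError("no raster cells within the focal circle")
    return float(np.sum((window == class_code) & inside) / n)


def edge_density(class_raster: Raster, radius: float, x: float, y: float) -> float:
    """Forest-open shared cell-boundary length per unit circle area.

    An edge between two 4-adjacent cells counts when one cell is forest,
    the other open, and both cell centers lie inside the circle; each
    counted edge contributes one cell-size of boundary length. Edges to
    wetland or anthropogenic cells never count.
    """
    rows, cols, inside = _window_mask(class_raster, x, y, radius)
    w = class_raster.values[np.ix_(rows, cols)]
    cell = class_raster.cellsize
    fo_h = ((w[:, :-1] == FOREST) & (w[:, 1:] == OPEN)) | ((w[:, :-1] == OPEN) & (w[:, 1:] == FOREST))
    fo_v = ((w[:-1, :] == FOREST) & (w[1:, :] == OPEN)) | ((w[:-1, :] == OPEN) & (w[1:, :] == FOREST))
    both_h = inside[:, :-1] & inside[:, 1:]
    both_v = inside[:-1, :] & inside[1:, :]
    length = (np.sum(fo_h & both_h) + np.sum(fo_v & both_v)) * cell
    return float(length / (np.pi * radius**2))


def simpson_diversity(class_raster: Raster, radius: float, x: float, y: float) -> float:
    """Simpson diversity 1 - sum(p_i^2) over forest, open, wetland.

    Proportions are renormalized over the three natural classes;
    anthropogenic cells are excluded from the denominator.
    """
    rows, cols, inside = _window_mask(class_raster, x, y, radius)
    w = class_raster.values[np.ix_(rows, cols)]
    counts = np.array([np.sum((w == c) & inside) for c in (FOREST, OPEN, WETLAND)], dtype=float)
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts / total
    return float(1.0 - np.sum(p**2))


def slope_from_dem(dem: Raster) -> Raster:
    """Slope raster (radians) from Horn's 3x3 finite differences."""
    z = np.pad(dem.values.astype(float), 1, mode="edge")
    cell = dem.cellsize
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cell)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cell)
    return dem.like(np.arctan(np.hypot(dzdx, dzdy)))


def _segments(lines) -> tuple[np.ndarray, np.ndarray]:
    """Decompose LineStrings into (start, end) vertex arrays."""
    starts, ends = [], []
    for line in lines:
        coords = np.asarray(line.coords)
        starts.append(coords[:-1])
        ends.append(coords[1:])
    if not starts:
        return np.zeros((0, 2)), np.zeros((0, 2))
    return np.vstack(starts), np.vstack(ends)


def _chord_lengths(a: np.ndarray, b: np.ndarray, center: np.ndarray, radius: float) -> np.ndarray:
    """Length of each segment a->b inside the circle (closed form)."""
    d = b - a
    f = a - center[None, :]
    dd = np.einsum("ij,ij->i", d, d)
    t_lo = np.zeros(len(a))
    t_hi = np.zeros(len(a))
    nz = dd > 0
    bq = np.einsum("ij,ij->i", f, d)
    cq = np.einsum("ij,ij->i", f, f) - radius**2
    disc = bq**2 - dd * cq
    ok = nz & (disc >= 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(ok, (-bq - sq) / dd, 0.0)
        t2 = np.where(ok, (-bq + sq) / dd, 0.0)
    t_lo = np.clip(t1, 0.0, 1.0)
    t_hi = np.clip(t2, 0.0, 1.0)
    return np.where(ok, (t_hi - t_lo) * np.sqrt(dd), 0.0)


def corridor_density(lines, radius: float, x: float, y: float) -> float:
    """Total corridor length (km) inside the circle of given radius.

    Reported as length per neighborhood (not per unit area), matching
    the km/100 m and km/500 m covariate units.
    """
    a, b = _segments(lines)
    if len(a) == 0:
        return 0.0
    return float(_chord_lengths(a, b, np.array([x, y]), radius).sum() / 1000.0)


# ---------------------------------------------------------------------------
# bulk sampling with cached convolution rasters


def _disk_kernel(radius: float, cellsize: float) -> np.ndarray:
    half = int(np.ceil(radius / cellsize))
    di, dj = np.mgrid[-half : half + 1, -half : half + 1]
    return (np.hypot(di, dj) * cellsize <= radius + 1e-9).astype(float)


def _focal_raster(stack: LandscapeStack, class_code: int, radius: float) -> np.ndarray:
    key = ("prop", class_code, radius)
    if key not in stack._cache:
        kernel = _disk_kernel(radius, stack.cellsize)
        ind = (stack.landcover.values == class_code).astype(float)
        num = fftconvolve(ind, kernel, mode="same")
        den = fftconvolve(np.ones_like(ind), kernel, mode="same")
        stack._cache[key] = np.clip(num / den, 0.0, 1.0)
        stack._cache[("propcount", class_code, radius)] = num
        stack._cache[("count", radius)] = den
    return stack._cache[key]


def _edge_raster(stack: LandscapeStack, radius: float) -> np.ndarray:
    """Forest-open edge-density raster evaluated at every cell center.

    Edge indicators live on the half-step grids between cell pairs; the
    count at center cell (r, c) is the cross-correlation of each
    indicator grid with a pair-membership kernel K(di, dj) = 1 iff both
    flanking cell centers at offsets (di, dj) and (di, dj+1) — or
    (di+1, dj) for vertical pairs — fall inside the disk. With both
    arrays anchored at the first cell of the pair, the full-mode
    convolution with the flipped kernel gives the count at index
    (r + h, c + h), h being the kernel half-width.
    """
    key = ("edge", radius)
    if key not in stack._cache:
        cell = stack.cellsize
        v = stack.landcover.values
        n, m = v.shape
        fo_h = (
            ((v[:, :-1] == FOREST) & (v[:, 1:] == OPEN))
            | ((v[:, :-1] == OPEN) & (v[:, 1:] == FOREST))
        ).astype(float)
        fo_v = (
            ((v[:-1, :] == FOREST) & (v[1:, :] == OPEN))
            | ((v[:-1, :] == OPEN) & (v[1:, :] == FOREST))
        ).astype(float)
        h = max(int(np.ceil(radius / cell)), 1)
        di, dj = np.mgrid[-h - 1 : h + 2, -h - 1 : h + 2]
        disk = np.hypot(di, dj) * cell <= radius + 1e-9
        core = slice(1, 2 * h + 2)  # offsets -h..h within the padded disk
        k_h = (disk[core, core] & disk[core, 2 : 2 * h + 3]).astype(float)
        k_v = (disk[core, core] & disk[2 : 2 * h + 3, core]).astype(float)
        counts = np.zeros((n, m), dtype=float)
        if fo_h.any():
            c_full = fftconvolve(fo_h, k_h[::-1, ::-1], mode="full")
            counts += c_full[h : h + n, h : h + m]
        if fo_v.any():
            c_full = fftconvolve(fo_v, k_v[::-1, ::-1], mode="full")
            counts += c_full[h : h + n, h : h + m]
        stack._cache[key] = np.round(counts) * cell / (np.pi * radius**2)
    return stack._cache[key]


def sample_covariates(stack: LandscapeStack, points: np.ndarray) -> pd.DataFrame:
    """All nine covariates at each point (rows align with ``points``).

    Raster-aligned focal statistics (proportions, edge density, Simpson)
    are evaluated at the containing cell's center; corridor densities
    are exact at the point. Points outside the raster raise an error
    naming the first offending point.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    x, y = points[:, 0], points[:, 1]
    row, col = stack.landcover.index_of(x, y)  # raises outside

    lc = stack.landcover.values[row, col]
    pf500 = _focal_raster(stack, FOREST, 500.0)[row, col]
    po500 = _focal_raster(stack, OPEN, 500.0)[row, col]
    pw500 = _focal_raster(stack, WETLAND, 500.0)[row, col]
    edge = _edge_raster(stack, 50.0)[row, col]
    with np.errstate(divide="ignore", invalid="ignore"):
        tot = pf500 + po500 + pw500
        simpson = np.where(
            tot > 0,
            1.0 - ((pf500 / tot) ** 2 + (po500 / tot) ** 2 + (pw500 / tot) ** 2),
            0.0,
        )
    if "slope" not in stack._cache:
        stack._cache["slope"] = slope_from_dem(stack.dem)
    slope = stack._cache["slope"].values[row, col]
    elev = stack.dem.values[row, col]

    a, b = _segments(stack.corridors)
    corr100 = np.zeros(len(points))
    corr500 = np.zeros(len(points))
    if len(a):
        for i, (px, py) in enumerate(points):
            center = np.array([px, py])
            corr100[i] = _chord_lengths(a, b, center, 100.0).sum() / 1000.0
            corr500[i] = _chord_lengths(a, b, center, 500.0).sum() / 1000.0

    return pd.DataFrame(
        {
            "forest10": (lc == FOREST).astype(float),
            "open10": (lc == OPEN).astype(float),
            "forest500": pf500,
            "open500": po500,
            "edge50": edge,
            "simpson500": simpson,
            "corridor100": corr100,
            "corridor500": corr500,
            "elev100": elev / 100.0,
            "slope": slope,
        }
    )


def sample_covariate_matrix(stack: LandscapeStack, x, y, names) -> np.ndarray:
    """Covariate matrix (n points x len(names)) for the named covariates."""
    pts = np.column_stack([np.asarray(x, dtype=float), np.asarray(y, dtype=float)])
    df = sample_covariates(stack, pts)
    return df[list(names)].to_numpy()
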