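"""Landscape covariates: focal statistics, terrain, corridor density."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from carnmove.covariates import (
    corridor_density,
    edge_density,
    focal_proportion,
    reclass_landcover,
    sample_covariates,
    simpson_diversity,
    slope_from_dem,
)
from carnmove.landscape import ANTHROPOGENIC, FOREST, OPEN, WETLAND, LandscapeStack
from carnmove.raster import Raster


def _raster(values, cellsize=10.0):
    return Raster(np.asarray(values), cellsize)


def _uniform(code, n=120, cellsize=10.0):
    return _raster(np.full((n, n), code), cellsize)


def _center(raster):
    xmin, ymin, xmax, ymax = raster.bounds
    return 0.5 * (xmin + xmax), 0.5 * (ymin + ymax)


# ---------------------------------------------------------------------------
# reclassification


def test_reclass_identity():
    r = _raster(np.array([[FOREST, OPEN], [WETLAND, ANTHROPOGENIC]]))
    out = reclass_landcover(r, {c: c for c in (FOREST, OPEN, WETLAND, ANTHROPOGENIC)})
    assert np.array_equal(out.values, r.values)


def test_reclass_ten_class_grouping_conserves_counts():
    rng = np.random.default_rng(0)
    raw = _raster(rng.integers(1, 11, size=(50, 50)))
    mapping = {
        1: "forest", 2: "forest", 3: "forest",        # alder, Acadian, boreal
        4: "open", 5: "open", 6: "open", 7: "open",   # barren, intolerant, fern, grass
        8: "wetland", 9: "wetland",
        10: "anthropogenic",
    }
    out = reclass_landcover(raw, mapping)
    n_forest_raw = int(np.isin(raw.values, [1, 2, 3]).sum())
    assert int((out.values == FOREST).sum()) == n_forest_raw
    assert out.values.size == raw.values.size


def test_reclass_unmapped_code_errors():
    raw = _raster(np.array([[1, 99]]))
    with pytest.raises(ValueError, match="99"):
        reclass_landcover(raw, {1: "forest"})


# ---------------------------------------------------------------------------
# focal proportions


def test_focal_proportion_uniform():
    r = _uniform(FOREST)
    x, y = _center(r)
    for radius in (50, 200, 500):
        assert focal_proportion(r, FOREST, radius, x, y) == 1.0
        assert focal_proportion(r, OPEN, radius, x, y) == 0.0


def test_focal_proportion_half_plane():
    vals = np.full((200, 200), FOREST)
    vals[:, 100:] = OPEN
    r = _raster(vals)
    x = 100 * 10.0  # on the class boundary
    y = 100 * 10.0
    p = focal_proportion(r, FOREST, 500.0, x, y)
    assert abs(p - 0.5) < 0.02


def test_focal_proportions_sum_to_one():
    rng = np.random.default_rng(1)
    vals = rng.choice([FOREST, OPEN, WETLAND, ANTHROPOGENIC], size=(150, 150))
    r = _raster(vals)
    x, y = _center(r)
    total = sum(
        focal_proportion(r, c, 300.0, x, y) for c in (FOREST, OPEN, WETLAND, ANTHROPOGENIC)
    )
    assert total == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# edge density


def test_edge_density_uniform_is_zero():
    r = _uniform(FOREST)
    x, y = _center(r)
    assert edge_density(r, 50.0, x, y) == 0.0


def _enumerate_edge_density(raster, radius, x, y):
    """Direct enumeration oracle: loop over all 4-adjacent cell pairs."""
    xs, ys = raster.cell_centers()
    v = raster.values
    total = 0.0
    for i in range(v.shape[0]):
        for j in range(v.shape[1]):
            for di, dj in ((0, 1), (1, 0)):
                i2, j2 = i + di, j + dj
                if i2 >= v.shape[0] or j2 >= v.shape[1]:
                    continue
                pair = {v[i, j], v[i2, j2]}
                if pair != {FOREST, OPEN}:
                    continue
                if (
                    np.hypot(xs[j] - x, ys[i] - y) <= radius + 1e-9
                    and np.hypot(xs[j2] - x, ys[i2] - y) <= radius + 1e-9
                ):
                    total += raster.cellsize
    return total / (np.pi * radius**2)


def test_edge_density_vertical_boundary_matches_enumeration():
    vals = np.full((40, 40), FOREST)
    vals[:, 20:] = OPEN
    r = _raster(vals)
    x, y = 200.0, 200.0  # on the boundary between columns 19 and 20
    got = edge_density(r, 50.0, x, y)
    want = _enumerate_edge_density(r, 50.0, x, y)
    assert got == pytest.approx(want)
    assert got > 0


def test_edge_density_random_matches_enumeration():
    rng = np.random.default_rng(2)
    vals = rng.choice([FOREST, OPEN, WETLAND], size=(40, 40))
    r = _raster(vals)
    got = edge_density(r, 50.0, 195.0, 210.0)
    want = _enumerate_edge_density(r, 50.0, 195.0, 210.0)
    assert got == pytest.approx(want)


def test_forest_wetland_boundary_not_an_edge():
    vals = np.full((40, 40), FOREST)
    vals[:, 20:] = WETLAND
    r = _raster(vals)
    assert edge_density(r, 50.0, 200.0, 200.0) == 0.0


# ---------------------------------------------------------------------------
# Simpson diversity


def test_simpson_uniform_forest_is_zero():
    r = _uniform(FOREST)
    x, y = _center(r)
    assert simpson_diversity(r, 500.0, x, y) == pytest.approx(0.0)


def test_simpson_exact_thirds():
    # stripes of exactly one third each within a square window; use a
    # large radius so the clipped circle covers the whole (small) raster
    vals = np.zeros((30, 30), dtype=int)
    vals[:10] = FOREST
    vals[10:20] = OPEN
    vals[20:] = WETLAND
    r = _raster(vals)
    x, y = _center(r)
    assert simpson_diversity(r, 10_000.0, x, y) == pytest.approx(2.0 / 3.0)


def test_simpson_hand_computed_mixture():
    # 50 / 30 / 20 cells of forest / open / wetland -> 1 - 0.38 = 0.62
    vals = np.array([FOREST] * 50 + [OPEN] * 30 + [WETLAND] * 20).reshape(10, 10)
    r = _raster(vals)
    x, y = _center(r)
    assert simpson_diversity(r, 10_000.0, x, y) == pytest.approx(0.62)


def test_simpson_ignores_anthropogenic():
    vals = np.array([FOREST] * 50 + [ANTHROPOGENIC] * 50).reshape(10, 10)
    r = _raster(vals)
    x, y = _center(r)
    assert simpson_diversity(r, 10_000.0, x, y) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# terrain


def test_slope_flat_dem_is_zero():
    dem = _raster(np.full((50, 50), 250.0))
    assert np.allclose(slope_from_dem(dem).values, 0.0)


def test_slope_unit_plane_is_quarter_pi():
    n = 30
    xs = np.arange(n) * 10.0
    dem = _raster(np.tile(xs, (n, 1)))  # z = x, 1 m rise per 1 m
    slope = slope_from_dem(dem).values
    assert np.allclose(slope[1:-1, 1:-1], np.pi / 4)


def test_slope_gentle_plane_matches_arctan():
    n = 30
    xs = np.arange(n) * 10.0 * 0.1
    dem = _raster(np.tile(xs, (n, 1)))  # z = 0.1 x
    slope = slope_from_dem(dem).values
    assert np.allclose(slope[1:-1, 1:-1], np.arctan(0.1))
    assert slope[5, 5] == pytest.approx(0.0997, abs=1e-4)


# ---------------------------------------------------------------------------
# corridor density


def test_corridor_density_no_lines():
    assert corridor_density([], 100.0, 0.0, 0.0) == 0.0


def test_corridor_density_diameter_chord():
    line = LineString([(-10_000, 0), (10_000, 0)])
    assert corridor_density([line], 100.0, 0.0, 0.0) == pytest.approx(0.2, abs=1e-9)
    assert corridor_density([line], 500.0, 0.0, 0.0) == pytest.approx(1.0, abs=1e-9)


def test_corridor_density_matches_shapely_clipping():
    rng = np.random.default_rng(3)
    lines = [
        LineString(rng.uniform(-800, 800, size=(3, 2)))
        for _ in range(5)
    ]
    for radius in (100.0, 500.0):
        got = corridor_density(lines, radius, 50.0, -30.0)
        circle = Point(50.0, -30.0).buffer(radius, quad_segs=512)
        want = sum(line.intersection(circle).length for line in lines) / 1000.0
        assert got == pytest.approx(want, abs=1e-4)


# ---------------------------------------------------------------------------
# bulk sampler


def _pure_forest_stack(n=150, cellsize=10.0):
    landcover = _raster(np.full((n, n), FOREST), cellsize)
    dem = _raster(np.full((n, n), 350.0), cellsize)
    return LandscapeStack(landcover=landcover, dem=dem, corridors=[])


def test_sample_covariates_pure_forest_flat():
    stack = _pure_forest_stack()
    x, y = _center(stack.landcover)
    row = sample_covariates(stack, [[x, y]]).iloc[0]
    assert row["forest10"] == 1.0 and row["open10"] == 0.0
    assert row["forest500"] == pytest.approx(1.0)
    assert row["edge50"] == 0.0
    assert row["simpson500"] == pytest.approx(0.0)
    assert row["corridor100"] == 0.0 and row["corridor500"] == 0.0
    assert row["slope"] == 0.0
    assert row["elev100"] == pytest.approx(3.5)  # 350 m -> 3.5


def test_sample_covariates_deterministic():
    stack = _pure_forest_stack()
    pts = [[700.0, 700.0], [300.0, 900.0]]
    a = sample_covariates(stack, pts)
    b = sample_covariates(stack, pts)
    assert a.equals(b)


def test_sample_covariates_outside_raster_errors():
    stack = _pure_forest_stack()
    with pytest.raises(ValueError, match="outside"):
        sample_covariates(stack, [[-50.0, 100.0]])


def test_bulk_sampler_agrees_with_pointwise_primitives(small_landscape):
    """The convolution fast path equals the per-point primitives when
    evaluated at cell centers."""
    stack = small_landscape
    xs, ys = stack.landcover.cell_centers()
    rng = np.random.default_rng(4)
    rows = rng.integers(55, 75, size=6)
    cols = rng.integers(55, 75, size=6)
    pts = np.column_stack([xs[cols], ys[rows]])
    bulk = sample_covariates(stack, pts)
    for k, (x, y) in enumerate(pts):
        assert bulk["forest500"].iloc[k] == pytest.approx(
            focal_proportion(stack.landcover, FOREST, 500.0, x, y), abs=1e-9
        )
        assert bulk["open500"].iloc[k] == pytest.approx(
            focal_proportion(stack.landcover, OPEN, 500.0, x, y), abs=1e-9
        )
        assert bulk["edge50"].iloc[k] == pytest.approx(
            edge_density(stack.landcover, 50.0, x, y), abs=1e-9
        )
        assert bulk["corridor100"].iloc[k] == pytest.approx(
            corridor_density(stack.corridors, 100.0, x, y), abs=1e-9
        )


def test_covariates_finite_everywhere(small_landscape):
    rng = np.random.default_rng(5)
    xmin, ymin, xmax, ymax = small_landscape.bounds
    pts = np.column_stack(
        [rng.uniform(xmin, xmax - 1e-6, 200), rng.uniform(ymin, ymax - 1e-6, 200)]
    )
    df = sample_covariates(small_landscape, pts)
    assert np.isfinite(df.to_numpy()).all()
    assert (df["forest500"] >= 0).all() and (df["forest500"] <= 1).all()
    assert (df["simpson500"] <= 2.0 / 3.0 + 1e-9).all()
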