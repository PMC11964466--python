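"""LEC computation, interpolation, isopleth extraction and the ODI rule."""

import numpy as np
import pytest
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import box

import colognepop as cp
from colognepop.core_area import (
    CoreAreaParams,
    DegenerateInputError,
    IsoplethCurve,
    LecGrid,
    LecSample,
    NoOdiError,
    build_core_areas,
    compute_lec,
    default_levels,
    extract_isopleths,
    interpolate_lec,
    select_odi,
)
from colognepop.records import StudyConfig
from colognepop.synthetic import SiteSimConfig, generate_sites

KM = 1000.0


# --------------------------------------------------------------------- LEC

def test_lec_square_symmetry():
    """Four sites at the corners of a 2x2 km square: the single interior
    Voronoi vertex sits at the centre with radius sqrt(2) km."""
    xy = np.array([[0, 0], [2, 0], [2, 2], [0, 2]]) * KM
    window = box(0, 0, 2 * KM, 2 * KM)
    samples = compute_lec(xy, window)
    interior = [s for s in samples if s.origin == "voronoi_vertex"]
    assert len(interior) == 1
    assert (interior[0].cx, interior[0].cy) == (KM, KM)
    assert interior[0].radius_km == pytest.approx(np.sqrt(2), abs=1e-9)


def test_lec_no_site_strictly_inside_any_circle(square_window, rng):
    xy = rng.uniform(0, 100 * KM, (25, 2))
    tree = cKDTree(xy)
    for s in compute_lec(xy, square_window):
        d, _ = tree.query([s.cx, s.cy])
        assert d / KM >= s.radius_km - 1e-9


def test_lec_matches_brute_force_grid_search(square_window, rng):
    """The largest Voronoi-based empty-circle radius agrees with exhaustive
    search over a 0.1 km candidate grid within one grid diagonal."""
    xy = rng.uniform(0, 100 * KM, (20, 2))
    samples = compute_lec(xy, square_window)
    vmax = max(s.radius_km for s in samples)

    cell = 0.1 * KM
    g = np.arange(0, 100 * KM + cell / 2, cell)
    gx, gy = np.meshgrid(g, g)
    d, _ = cKDTree(xy).query(np.column_stack([gx.ravel(), gy.ravel()]), workers=-1)
    bmax = d.max() / KM
    assert abs(vmax - bmax) <= 0.1 * np.sqrt(2)


def test_lec_degenerate_inputs(square_window):
    with pytest.raises(DegenerateInputError):
        compute_lec(np.array([[KM, KM]]), square_window)
    collinear = np.array([[1, 1], [2, 2], [3, 3], [4, 4]]) * KM
    with pytest.raises(DegenerateInputError, match="collinear"):
        compute_lec(collinear, square_window, region="flatland")


# ------------------------------------------------------------- interpolation

def test_idw_constant_field(square_window):
    samples = [LecSample(x * KM, y * KM, 5.0, "voronoi_vertex")
               for x in (0, 50, 100) for y in (0, 50, 100)]
    grid = interpolate_lec(samples, 2.0, square_window)
    vals = grid.values[grid.mask]
    assert np.allclose(vals, 5.0)


def test_idw_symmetric_midpoint(square_window):
    """Two samples r=2 and r=4 at equal distance: the midpoint averages to 3."""
    samples = [LecSample(0, 0, 2.0, "voronoi_vertex"),
               LecSample(10 * KM, 0, 4.0, "voronoi_vertex")]
    grid = interpolate_lec(samples, 1.0, box(0, 0, 10 * KM, 2 * KM))
    ix = int(np.argmin(np.abs(grid.x - 5 * KM)))
    iy = int(np.argmin(np.abs(grid.y - 0)))
    dx = abs(grid.x[ix] - 5 * KM)
    # the cell centre must be exactly equidistant for the symmetry argument
    assert abs((grid.x[ix] - 0) - (10 * KM - grid.x[ix])) < 1e-6
    assert grid.values[iy, ix] == pytest.approx(3.0, abs=1e-9)


def test_idw_exact_hit_returns_sample_value(square_window, rng):
    samples = [LecSample(float(x), float(y), float(v), "voronoi_vertex")
               for (x, y), v in zip(rng.uniform(10 * KM, 90 * KM, (5, 2)),
                                    rng.uniform(1, 20, 5))]
    grid = interpolate_lec(samples, 1.0, square_window)
    s = samples[0]
    # move a grid cell centre onto the sample by constructing a window whose
    # bounds align the lattice with it
    ix = int(np.argmin(np.abs(grid.x - s.cx)))
    iy = int(np.argmin(np.abs(grid.y - s.cy)))
    # nearest cell is within half a cell; interpolate there directly instead
    shifted = [LecSample(grid.x[ix], grid.y[iy], s.radius_km, "voronoi_vertex")] + samples[1:]
    grid2 = interpolate_lec(shifted, 1.0, square_window)
    assert grid2.values[iy, ix] == pytest.approx(s.radius_km, abs=1e-12)


def test_idw_requires_samples(square_window):
    with pytest.raises(ValueError):
        interpolate_lec([], 1.0, square_window)


# ---------------------------------------------------------------- isopleths

def _radial_grid(square_window, cell_km=1.0):
    cell = cell_km * KM
    xs = np.arange(0 - cell, 100 * KM + 1.5 * cell, cell)
    gx, gy = np.meshgrid(xs, xs)
    vals = np.hypot(gx - 50 * KM, gy - 50 * KM) / KM
    mask = shapely.intersects_xy(square_window, gx.ravel(), gy.ravel()).reshape(gx.shape)
    return LecGrid(x=xs, y=xs, values=vals, mask=mask, cell_km=cell_km,
                   window=square_window)


def test_isopleth_constant_grid_thresholds(square_window):
    samples = [LecSample(x * KM, y * KM, 5.0, "voronoi_vertex")
               for x in (0, 50, 100) for y in (0, 50, 100)]
    grid = interpolate_lec(samples, 2.0, square_window)
    curve, _ = extract_isopleths(grid, [4.0, 5.0, 6.0])
    assert curve.area_km2[0] == 0.0
    window_km2 = square_window.area / KM**2
    assert curve.area_km2[1] == pytest.approx(window_km2, rel=1e-6)
    assert curve.area_km2[2] == pytest.approx(window_km2, rel=1e-6)


def test_isopleth_disc_area_closed_form(square_window):
    """On the radial field f = distance from the window centre, the level-L
    isopleth encloses pi*L^2 within 2% while the disc fits in the window."""
    grid = _radial_grid(square_window)
    levels = [10.0, 20.0, 40.0]
    curve, _ = extract_isopleths(grid, levels)
    for L, a in zip(levels, curve.area_km2):
        assert a == pytest.approx(np.pi * L**2, rel=0.02)


def test_isopleth_nesting_and_monotonicity(square_window, rng):
    xy = rng.uniform(0, 100 * KM, (40, 2))
    samples = compute_lec(xy, square_window)
    grid = interpolate_lec(samples, 2.0, square_window)
    levels = default_levels(samples, 2.0)
    curve, geoms = extract_isopleths(grid, levels, xy)
    assert (np.diff(curve.area_km2) >= -1e-9).all()
    assert (np.diff(curve.capture) >= 0).all()
    assert ((curve.capture >= 0) & (curve.capture <= 1)).all()
    for l1, l2 in zip(levels[:-1], levels[1:]):
        inner, outer = geoms[float(l1)], geoms[float(l2)]
        if not inner.is_empty:
            assert inner.difference(outer.buffer(1.0)).area < 1e-6 * max(inner.area, 1)


def test_isopleth_discretisation_stability(square_window):
    """Halving the cell size changes the enclosed area of a smooth field
    by < 5%."""
    a = []
    for cell in (2.0, 1.0):
        grid = _radial_grid(square_window, cell)
        curve, _ = extract_isopleths(grid, [30.0])
        a.append(curve.area_km2[0])
    assert abs(a[1] - a[0]) / a[0] < 0.05


def test_levels_must_ascend(square_window):
    grid = _radial_grid(square_window)
    with pytest.raises(ValueError):
        extract_isopleths(grid, [3.0, 2.0])


# ----------------------------------------------------------------- ODI rule

def _curve(increments, captures):
    areas = np.cumsum(increments).astype(float)
    return IsoplethCurve(levels=np.arange(1.0, len(increments) + 1),
                         area_km2=areas, capture=np.array(captures))


def test_odi_first_peak_with_sufficient_capture():
    curve = _curve([5, 6, 40, 7, 5], [0.30, 0.55, 0.78, 0.90, 1.0])
    res = select_odi(curve)
    assert res.level_km == 3.0
    assert not res.fallback


def test_odi_fallback_when_increments_keep_rising():
    curve = _curve([5, 10, 20, 40, 80], [0.30, 0.50, 0.60, 0.75, 0.90])
    res = select_odi(curve)
    assert res.level_km == 4.0
    assert res.fallback


def test_odi_error_when_capture_unreachable():
    curve = _curve([5, 6, 40, 7, 5], [0.1, 0.2, 0.3, 0.4, 0.65])
    with pytest.raises(NoOdiError):
        select_odi(curve)


def test_odi_plateau_counts_as_candidate():
    # increments flat within 10% after level 2; capture crosses at level 3
    curve = _curve([10, 100, 102, 104, 100], [0.2, 0.5, 0.75, 0.9, 1.0])
    res = select_odi(curve)
    assert res.level_km == 3.0
    assert not res.fallback


# ------------------------------------------------------------- full pipeline

def _two_cluster_sites(seed):
    window = box(0, 0, 500 * KM, 500 * KM)
    cfg = SiteSimConfig(
        window=window,
        parent_xy_m=[(150 * KM, 150 * KM), (350 * KM, 350 * KM)],
        mu=120, sigma_km=15.0, background_per_km2=3e-4, seed=seed,
    )
    sites, truth = generate_sites(cfg)
    return window, sites, truth


def test_pipeline_capture_postcondition():
    window, sites, _ = _two_cluster_sites(seed=0)
    cores = build_core_areas(sites, StudyConfig(window=window),
                             CoreAreaParams(cell_km=5.0))
    assert cores.capture >= 0.70
    assert cores.total_area_km2 > 0


def test_pipeline_recovers_two_clusters():
    from shapely.ops import unary_union

    window, sites, truth = _two_cluster_sites(seed=1)
    cores = build_core_areas(sites, StudyConfig(window=window),
                             CoreAreaParams(cell_km=5.0))
    got, want = cores.geometry(), unary_union(truth)
    jac = got.intersection(want).area / got.union(want).area
    assert jac >= 0.5


def test_pipeline_runs_per_calibration_region():
    window, sites, _ = _two_cluster_sites(seed=2)
    cfg = StudyConfig(
        window=window,
        calibration_regions={
            "west": box(0, 0, 250 * KM, 500 * KM),
            "east": box(250 * KM, 0, 500 * KM, 500 * KM),
        },
    )
    cores = build_core_areas(sites, cfg, CoreAreaParams(cell_km=5.0))
    assert set(cores.regions) == {"west", "east"}
    total = sum(r.area_km2 for r in cores.regions.values())
    assert cores.total_area_km2 == pytest.approx(total)
    assert cores.capture >= 0.70


def test_uniform_pattern_yields_non_informative_core():
    """A homogeneous Poisson pattern has no densification to delineate: the
    selected isoline captures the required share only by enclosing a large
    share of the window."""
    window = box(0, 0, 300 * KM, 300 * KM)
    fractions = []
    for seed in (1, 2, 3):
        cfg = SiteSimConfig(window=window, kappa_per_km2=0.0,
                            background_per_km2=2e-3, seed=seed)
        sites, _ = generate_sites(cfg)
        cores = build_core_areas(sites, StudyConfig(window=window),
                                 CoreAreaParams(cell_km=5.0))
        assert cores.capture >= 0.70
        fractions.append(cores.total_area_km2 / (window.area / KM**2))
    assert min(fractions) >= 0.40


def test_pipeline_error_names_region():
    window = box(0, 0, 100 * KM, 100 * KM)
    cfg = StudyConfig(window=window, calibration_regions={"empty": window})
    with pytest.raises(DegenerateInputError, match="empty"):
        build_core_areas([], cfg, CoreAreaParams(cell_km=5.0))
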