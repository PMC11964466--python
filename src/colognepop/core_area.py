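"""Core Area delineation: Largest-Empty-Circle field, interpolation, isopleths
and the optimally-describing-isoline (ODI) rule.

The pipeline per calibration region is

    sites -> Voronoi-based LEC samples -> IDW grid -> sub-level-set isopleths
          -> first increment peak/plateau capturing >= 70% of sites

The LEC radius at a Voronoi vertex is the distance to its defining nearest
sites and is an inverse measure of local site density; small radii mean dense
occupation. Isopleths of the interpolated radius field therefore enclose
regions of elevated density, and the selected isoline's interior is the Core
Area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy.spatial import QhullError, Voronoi, cKDTree
from shapely.geometry import LineString, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .records import SiteRecord, StudyConfig

KM = 1000.0


class DegenerateInputError(ValueError):
    """Fewer than 3 distinct non-collinear sites: no Voronoi diagram exists."""


class NoOdiError(ValueError):
    """No isopleth level captures the required fraction of sites."""


@dataclass(frozen=True)
class LecSample:
    cx: float
    cy: float
    radius_km: float
    origin: str  # "voronoi_vertex" | "window_boundary"


@dataclass
class LecGrid:
    """Interpolated LEC radius on a regular grid (values in km, masked outside
    the window)."""

    x: np.ndarray  # cell-centre x coordinates, metres
    y: np.ndarray
    values: np.ndarray  # (ny, nx), km; NaN where masked
    mask: np.ndarray  # True inside the window
    cell_km: float
    window: BaseGeometry


@dataclass
class IsoplethCurve:
    """Per-level enclosed area and site capture; the machine twin of the
    areal-increase diagrams used to pick the ODI."""

    levels: np.ndarray  # km, ascending
    area_km2: np.ndarray
    capture: np.ndarray

    def increments(self) -> np.ndarray:
        return np.diff(self.area_km2, prepend=0.0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"level_km": self.levels, "area_km2": self.area_km2, "capture": self.capture}
        )


@dataclass
class OdiResult:
    level_km: float
    area_km2: float
    capture: float
    fallback: bool


@dataclass
class RegionCoreArea:
    region: str
    odi_level_km: float
    geometry: BaseGeometry
    area_km2: float
    n_sites: int
    n_captured: int
    fallback: bool
    curve: IsoplethCurve


@dataclass
class CoreAreaSet:
    regions: dict[str, RegionCoreArea] = field(default_factory=dict)
    n_duplicates_removed: int = 0

    @property
    def total_area_km2(self) -> float:
        return sum(r.area_km2 for r in self.regions.values())

    @property
    def n_sites(self) -> int:
        return sum(r.n_sites for r in self.regions.values())

    @property
    def n_captured(self) -> int:
        return sum(r.n_captured for r in self.regions.values())

    @property
    def capture(self) -> float:
        return self.n_captured / self.n_sites if self.n_sites else 0.0

    def geometry(self) -> BaseGeometry:
        return unary_union([r.geometry for r in self.regions.values()])

    def areas_by_region(self, estimate_regions: Mapping[str, BaseGeometry]) -> dict[str, float]:
        """Split the merged Core Areas over estimate-region polygons (km²)."""
        merged = self.geometry()
        return {
            name: merged.intersection(poly).area / KM**2
            for name, poly in estimate_regions.items()
        }


def _site_xy(sites: Sequence[SiteRecord] | np.ndarray) -> np.ndarray:
    if isinstance(sites, np.ndarray):
        return np.asarray(sites, dtype=float).reshape(-1, 2)
    return np.array([(s.x, s.y) for s in sites], dtype=float).reshape(-1, 2)


def dedupe_xy(xy: np.ndarray) -> tuple[np.ndarray, int]:
    """Drop exact coordinate duplicates (order-preserving); return count removed."""
    seen: set[tuple[float, float]] = set()
    keep = []
    for i, (x, y) in enumerate(xy):
        if (x, y) not in seen:
            seen.add((x, y))
            keep.append(i)
    return xy[keep], len(xy) - len(keep)


def _collinear(xy: np.ndarray, tol: float = 1e-9) -> bool:
    if len(xy) < 3:
        return True
    p0 = xy[0]
    d = xy - p0
    cross = np.abs(d[1:, 0, None] * d[1:, 1] - d[1:, 1, None] * d[1:, 0])
    scale = max(np.abs(d).max(), 1.0)
    return bool((cross <= tol * scale**2).all())


def compute_lec(
    sites: Sequence[SiteRecord] | np.ndarray,
    window: BaseGeometry,
    region: str = "",
) -> list[LecSample]:
    """Largest-Empty-Circle samples: Voronoi vertices inside the window plus
    points where Voronoi edges cross the window boundary.

    The radius at every sample is the distance to the nearest site, so by
    construction no site lies strictly inside the circle.
    """
    xy, _ = dedupe_xy(_site_xy(sites))
    tag = f" in region {region!r}" if region else ""
    if len(xy) < 3:
        raise DegenerateInputError(f"need >= 3 distinct sites{tag}, got {len(xy)}")
    if _collinear(xy):
        raise DegenerateInputError(f"sites are collinear{tag}: Voronoi diagram is degenerate")
    try:
        vor = Voronoi(xy)
    except QhullError as e:  # pragma: no cover - collinearity is caught above
        raise DegenerateInputError(f"degenerate site configuration{tag}: {e}") from e

    tree = cKDTree(xy)
    samples: list[LecSample] = []
    shapely.prepare(window)

    verts = vor.vertices
    if len(verts):
        inside = shapely.contains_xy(window, verts[:, 0], verts[:, 1])
        dists, _ = tree.query(verts[inside])
        for (vx, vy), d in zip(verts[inside], np.atleast_1d(dists)):
            samples.append(LecSample(float(vx), float(vy), float(d) / KM, "voronoi_vertex"))

    # boundary samples: clip each (possibly unbounded) Voronoi ridge to the
    # window boundary so coastal density is not extrapolated from the interior;
    # window vertices complete the candidate set (a constrained LEC centre is
    # a Voronoi vertex, an edge/boundary crossing, or a window corner)
    boundary = window.boundary
    polys = getattr(window, "geoms", [window])
    for poly in polys:
        rings = [poly.exterior, *poly.interiors]
        for ring in rings:
            for cx, cy in ring.coords[:-1]:
                d, _ = tree.query([cx, cy])
                samples.append(LecSample(float(cx), float(cy), float(d) / KM, "window_boundary"))
    center = xy.mean(axis=0)
    span = 10.0 * max(window.bounds[2] - window.bounds[0], window.bounds[3] - window.bounds[1])
    for (p1, p2), (v1, v2) in zip(vor.ridge_points, vor.ridge_vertices):
        if v1 == -1 and v2 == -1:
            continue
        if -1 in (v1, v2):
            vfin = verts[v2 if v1 == -1 else v1]
            t = xy[p2] - xy[p1]
            t = t / np.linalg.norm(t)
            n = np.array([-t[1], t[0]])
            midpoint = (xy[p1] + xy[p2]) / 2
            if np.dot(midpoint - center, n) < 0:
                n = -n
            seg = LineString([vfin, vfin + n * span])
        else:
            seg = LineString([verts[v1], verts[v2]])
        cross = seg.intersection(boundary)
        if cross.is_empty:
            continue
        pts = getattr(cross, "geoms", [cross])
        for pt in pts:
            if pt.geom_type != "Point":
                continue
            d, _ = tree.query([pt.x, pt.y])
            samples.append(LecSample(float(pt.x), float(pt.y), float(d) / KM, "window_boundary"))
    return samples


def interpolate_lec(
    samples: Sequence[LecSample],
    cell_km: float,
    window: BaseGeometry,
    power: float = 2.0,
) -> LecGrid:
    """Inverse-distance-weighted (power 2) LEC radius on a regular grid.

    A cell centre coinciding with a sample (within 1e-6 m) takes that
    sample's value exactly. Values are extrapolated one ring of cells beyond
    the window so isopleth polygons cross the boundary smoothly and are then
    clipped to the window; the mask marks cells inside the window proper.
    """
    if not samples:
        raise ValueError("need at least one LEC sample")
    cell = cell_km * KM
    minx, miny, maxx, maxy = window.bounds
    xs = np.arange(minx - cell, maxx + 1.5 * cell, cell)
    ys = np.arange(miny - cell, maxy + 1.5 * cell, cell)
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.intersects_xy(window, gx.ravel(), gy.ravel()).reshape(gx.shape)
    if not mask.any():
        raise ValueError("no grid cell centre falls inside the window")
    halo = window.buffer(1.6 * cell)
    compute = shapely.intersects_xy(halo, gx.ravel(), gy.ravel()).reshape(gx.shape)

    sxy = np.array([(s.cx, s.cy) for s in samples])
    sval = np.array([s.radius_km for s in samples])
    values = np.full(gx.shape, np.nan)
    pts = np.column_stack([gx[compute], gy[compute]])
    out = np.empty(len(pts))
    chunk = 4096
    for i in range(0, len(pts), chunk):
        block = pts[i : i + chunk]
        d = np.hypot(block[:, 0, None] - sxy[None, :, 0], block[:, 1, None] - sxy[None, :, 1])
        hit = d < 1e-6
        w = 1.0 / np.maximum(d, 1e-6) ** power
        est = (w * sval).sum(axis=1) / w.sum(axis=1)
        rows_with_hit = hit.any(axis=1)
        if rows_with_hit.any():
            est[rows_with_hit] = sval[hit.argmax(axis=1)[rows_with_hit]]
        out[i : i + chunk] = est
    values[compute] = out
    return LecGrid(x=xs, y=ys, values=values, mask=mask, cell_km=cell_km, window=window)


def _filled_polygons(grid: LecGrid, level: float) -> BaseGeometry:
    """Sub-level-set {radius <= level} as polygons, clipped to the window."""
    import contourpy

    z = np.ma.masked_invalid(grid.values)
    gen = contourpy.contour_generator(
        x=grid.x, y=grid.y, z=z, fill_type=contourpy.FillType.OuterOffset
    )
    lo = min(float(np.nanmin(grid.values)), level) - 1.0
    # a site/level tie or float noise at a constant field must fall inside
    upper = level + 1e-9 * max(1.0, abs(level))
    points_list, offsets_list = gen.filled(lo, upper)
    polys = []
    for pts, offs in zip(points_list, offsets_list):
        rings = [pts[offs[i] : offs[i + 1]] for i in range(len(offs) - 1)]
        if len(rings[0]) < 4:
            continue
        poly = Polygon(rings[0], [r for r in rings[1:] if len(r) >= 4])
        if not poly.is_valid:
            poly = poly.buffer(0)
        polys.append(poly)
    if not polys:
        return Polygon()
    return unary_union(polys).intersection(grid.window)


def extract_isopleths(
    grid: LecGrid,
    levels: Sequence[float],
    sites: Sequence[SiteRecord] | np.ndarray | None = None,
) -> tuple[IsoplethCurve, dict[float, BaseGeometry]]:
    """Isopleth polygons and the (area, capture) curve over ascending levels.

    Sites lying exactly on an isoline count as captured.
    """
    levels = np.asarray(levels, dtype=float)
    if len(levels) and (np.diff(levels) < 0).any():
        raise ValueError("levels must be ascending")
    xy = _site_xy(sites) if sites is not None and len(sites) else np.empty((0, 2))
    areas, caps, geoms = [], [], {}
    for lv in levels:
        geom = _filled_polygons(grid, float(lv))
        geoms[float(lv)] = geom
        areas.append(geom.area / KM**2)
        if len(xy):
            shapely.prepare(geom)
            caps.append(float(shapely.intersects_xy(geom, xy[:, 0], xy[:, 1]).mean()))
        else:
            caps.append(0.0)
    curve = IsoplethCurve(levels=levels, area_km2=np.array(areas), capture=np.array(caps))
    return curve, geoms


def select_odi(
    curve: IsoplethCurve,
    min_capture: float = 0.70,
    plateau_tol: float = 0.10,
) -> OdiResult:
    """Pick the optimally describing isoline.

    The ODI is the smallest level at which the areal-increment sequence has
    peaked or flattened — the next increment does not exceed the current one
    by more than ``plateau_tol`` (relative) — and which captures at least
    ``min_capture`` of the sites. A local maximum is the strict case
    (the next increment falls); a plateau is the tolerant case (it stays
    within ``plateau_tol``). If no peak or plateau reaches the capture
    threshold, the smallest level that does is returned with the
    ``fallback`` flag set; if none does, :class:`NoOdiError` is raised.
    The last level can never be confirmed as a peak.
    """
    if len(curve.levels) == 0:
        raise ValueError("empty isopleth curve")
    inc = curve.increments()
    n = len(inc)
    candidate = np.zeros(n, dtype=bool)
    for i in range(n - 1):
        if inc[i] > 0 and inc[i + 1] <= inc[i] * (1.0 + plateau_tol):
            candidate[i] = True
    ok = curve.capture >= min_capture
    hits = np.flatnonzero(candidate & ok)
    if len(hits):
        i = int(hits[0])
        return OdiResult(float(curve.levels[i]), float(curve.area_km2[i]),
                         float(curve.capture[i]), fallback=False)
    reachable = np.flatnonzero(ok)
    if len(reachable):
        i = int(reachable[0])
        return OdiResult(float(curve.levels[i]), float(curve.area_km2[i]),
                         float(curve.capture[i]), fallback=True)
    raise NoOdiError(
        f"site capture never reaches {min_capture:.0%} (max {curve.capture.max():.0%})"
    )


@dataclass
class CoreAreaParams:
    cell_km: float = 10.0
    level_step_km: float = 1.0
    min_capture: float = 0.70
    plateau_tol: float = 0.10
    levels: Sequence[float] | None = None  # overrides the automatic ladder


def default_levels(samples: Sequence[LecSample], step_km: float) -> np.ndarray:
    """Level ladder: step_km increments up to the 95th percentile of radii."""
    radii = np.array([s.radius_km for s in samples])
    top = float(np.percentile(radii, 95))
    return np.arange(step_km, max(top, step_km) + step_km, step_km)


def build_core_areas(
    sites: Sequence[SiteRecord],
    cfg: StudyConfig,
    params: CoreAreaParams | None = None,
) -> CoreAreaSet:
    """Run the full Core-Area pipeline independently per calibration region.

    Each calibration region gets its own LEC field, interpolation, isopleth
    curve and ODI; the resulting polygons are reported per region and can be
    merged or split over estimate regions afterwards.
    """
    params = params or CoreAreaParams()
    regions = dict(cfg.calibration_regions) or {"window": cfg.window}
    result = CoreAreaSet()
    for name, poly in regions.items():
        region_window = poly.intersection(cfg.window)
        in_region = [
            s for s in sites if shapely.intersects_xy(region_window, s.x, s.y)
        ]
        xy = _site_xy(in_region)
        xy_unique, ndup = dedupe_xy(xy)
        result.n_duplicates_removed += ndup
        try:
            samples = compute_lec(xy_unique, region_window, region=name)
            grid = interpolate_lec(samples, params.cell_km, region_window)
            levels = (
                np.asarray(params.levels, dtype=float)
                if params.levels is not None
                else default_levels(samples, params.level_step_km)
            )
            curve, geoms = extract_isopleths(grid, levels, xy_unique)
            odi = select_odi(curve, params.min_capture, params.plateau_tol)
        except (DegenerateInputError, NoOdiError, ValueError) as e:
            raise type(e)(f"region {name!r}: {e}") from e
        geom = geoms[odi.level_km]
        n_captured = int(shapely.intersects_xy(geom, xy_unique[:, 0], xy_unique[:, 1]).sum())
        result.regions[name] = RegionCoreArea(
            region=name,
            odi_level_km=odi.level_km,
            geometry=geom,
            area_km2=geom.area / KM**2,
            n_sites=len(xy_unique),
            n_captured=n_captured,
            fallback=odi.fallback,
            curve=curve,
        )
    return result
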