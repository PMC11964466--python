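"""Synthetic site patterns and raw-material assemblages with known ground truth.

Site patterns are drawn from a Thomas process (Poisson parents, Poisson
offspring counts, Gaussian offspring displacement) superposed on a uniform
Poisson background — the simplest generative model of the "areas of high
activity vs areas of little or no activity" structure the Core-Area analysis
assumes. Ground truth for recovery experiments is the disc of radius 3σ
around each parent, which holds ≈99% of that cluster's offspring mass.

All intensities are per km²; coordinates are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .records import ATTRIBUTION_FLAGS, SiteRecord

KM = 1000.0


@dataclass
class SiteSimConfig:
    """Thomas-process site simulation parameters.

    kappa_per_km2: parent (cluster-centre) intensity per km².
    mu: mean offspring per parent.
    sigma_km: Gaussian offspring spread.
    background_per_km2: uniform Poisson background intensity.
    parent_xy_m: optional fixed parent locations (metres) instead of a
        Poisson draw — used for controlled recovery experiments.
    phase_mix: sampling probabilities for the five attribution flags.
    """

    window: BaseGeometry
    kappa_per_km2: float = 0.0
    mu: float = 50.0
    sigma_km: float = 15.0
    background_per_km2: float = 0.0
    parent_xy_m: Sequence[tuple[float, float]] | None = None
    phase_mix: dict[str, float] = field(
        default_factory=lambda: {
            "GI1DA": 0.49, "GS1": 0.28, "FP_GENERIC": 0.12,
            "FP_PB_GENERIC": 0.07, "GS1_PB": 0.04,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kappa_per_km2, self.mu, self.sigma_km, self.background_per_km2) < 0:
            raise ValueError("intensities, mu and sigma must be non-negative")
        p = np.array([self.phase_mix.get(f, 0.0) for f in ATTRIBUTION_FLAGS])
        if (p < 0).any() or not np.isclose(p.sum(), 1.0):
            raise ValueError("phase_mix must be a probability vector over the five flags")


@dataclass
class RawMatSimConfig:
    """Raw-material assemblage simulation parameters.

    Each assemblage receives 1..k sources at exponential-tailed distances
    (mean ``distance_scale_km``); share percentages are Dirichlet with
    symmetric concentration ``share_concentration``. In a fraction
    ``noise_share_fraction`` of assemblages one extra trace material is
    forced below 1% to exercise the share filter, and a fraction
    ``single_piece_fraction`` of sources are flagged as single pieces.
    """

    n_sources_range: tuple[int, int] = (1, 5)
    distance_scale_km: float = 40.0
    share_concentration: float = 1.0
    noise_share_fraction: float = 0.10
    single_piece_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.distance_scale_km <= 0:
            raise ValueError("distance_scale_km must be positive")
        lo, hi = self.n_sources_range
        if not (1 <= lo <= hi):
            raise ValueError("n_sources_range must be 1 <= lo <= hi")


def _poisson_in_window(rng: np.random.Generator, window: BaseGeometry,
                       intensity_per_km2: float) -> np.ndarray:
    """Homogeneous Poisson points inside a polygon, via bounding-box rejection."""
    minx, miny, maxx, maxy = window.bounds
    bbox_km2 = (maxx - minx) * (maxy - miny) / KM**2
    n = rng.poisson(intensity_per_km2 * bbox_km2)
    if n == 0:
        return np.empty((0, 2))
    pts = np.column_stack([
        rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n)
    ])
    import shapely
    keep = shapely.contains_xy(window, pts[:, 0], pts[:, 1])
    return pts[keep]


def generate_sites(
    cfg: SiteSimConfig,
) -> tuple[list[SiteRecord], list[BaseGeometry]]:
    """Draw a clustered site pattern; return records plus truth discs (3σ)."""
    if cfg.window.area <= 0:
        raise ValueError("window area must be positive")
    rng = np.random.default_rng(cfg.seed)
    import shapely

    if cfg.parent_xy_m is not None:
        parents = np.asarray(cfg.parent_xy_m, dtype=float).reshape(-1, 2)
    else:
        parents = _poisson_in_window(rng, cfg.window, cfg.kappa_per_km2)

    pts: list[np.ndarray] = []
    for px, py in parents:
        n_off = rng.poisson(cfg.mu)
        if n_off == 0:
            continue
        off = rng.normal((px, py), cfg.sigma_km * KM, size=(n_off, 2))
        keep = shapely.contains_xy(cfg.window, off[:, 0], off[:, 1])
        pts.append(off[keep])
    pts.append(_poisson_in_window(rng, cfg.window, cfg.background_per_km2))
    xy = np.vstack(pts) if pts else np.empty((0, 2))

    flags = list(ATTRIBUTION_FLAGS)
    probs = np.array([cfg.phase_mix.get(f, 0.0) for f in flags])
    chosen = rng.choice(len(flags), size=len(xy), p=probs)
    records = [
        SiteRecord(
            id=f"syn{i:05d}", x=float(x), y=float(y), region="sim",
            attributions=frozenset({flags[c]}),
            evidence="surface" if rng.random() < 0.5 else "excavation",
        )
        for i, ((x, y), c) in enumerate(zip(xy, chosen))
    ]
    truth = [
        Point(px, py).buffer(3 * cfg.sigma_km * KM).intersection(cfg.window)
        for px, py in parents
    ]
    return records, truth


def generate_raw_materials(
    sites: Sequence[SiteRecord], cfg: RawMatSimConfig
) -> pd.DataFrame:
    """Simulate raw-material sources and share percentages per assemblage."""
    if not sites:
        raise ValueError("sites must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.n_sources_range
    rows = []
    for s in sites:
        k = int(rng.integers(lo, hi + 1))
        noisy = rng.random() < cfg.noise_share_fraction
        dists = rng.exponential(cfg.distance_scale_km * KM, size=k)
        angles = rng.uniform(0, 2 * np.pi, size=k)
        shares = rng.dirichlet(np.full(k, cfg.share_concentration)) * 100.0
        if noisy:
            # carve a trace material (<1%) out of the largest share
            trace = rng.uniform(0.05, 0.95)
            j = int(np.argmax(shares))
            shares[j] -= trace
            dists = np.append(dists, rng.exponential(cfg.distance_scale_km * KM))
            angles = np.append(angles, rng.uniform(0, 2 * np.pi))
            shares = np.append(shares, trace)
        for d, a, share in zip(dists, angles, shares):
            rows.append({
                "assemblage_id": s.id, "site_id": s.id,
                "source_x": s.x + d * np.cos(a), "source_y": s.y + d * np.sin(a),
                "share_percent": float(max(share, 1e-9)),
                "attributions": ";".join(sorted(s.attributions)),
                "single_piece": bool(rng.random() < cfg.single_piece_fraction),
            })
    return pd.DataFrame(rows)
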