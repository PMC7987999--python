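"""Continuous Bayesian phylogeography under a Brownian random walk.

Internal-node locations are sampled exactly from their conditional Gaussian
given the tip coordinates on the dated tree: an upward (pruning) pass
accumulates each subtree's conditional mean and variance, the diffusion
variance is drawn from its conjugate posterior (scaled inverse chi-square
under the log-uniform prior), and a downward pass samples every node given
its parent.  All algebra runs on a local km plane centred on the tip
centroid; reported distances use the haversine formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union
from skimage import measure

from .chronology import PosteriorTrace, hpd_interval
from .geo import LocalProjection, haversine_km
from .trees import Node, Tree

__all__ = [
    "GeoSample",
    "HPDRegion",
    "prune_recent_same_population",
    "infer_locations",
    "hpd_region_2d",
    "diffusion_rate",
]


@dataclass
class GeoSample:
    """Per-posterior-state locations for every node of the tree."""

    node_names: tuple[str, ...]       # all nodes, preorder (root first)
    lat: np.ndarray                   # (S, N) degrees
    lon: np.ndarray                   # (S, N)
    sigma2: np.ndarray                # (S,) km^2/year diffusion variance per axis
    tip_names: tuple[str, ...]
    branch_parent: np.ndarray         # (B,) indices into node arrays
    branch_child: np.ndarray          # (B,)
    branch_duration: np.ndarray       # (S, B) years
    projection: LocalProjection = field(repr=False, default=None)

    @property
    def n_states(self) -> int:
        return len(self.sigma2)

    def node_locations(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.node_names.index(name)
        return self.lat[:, i], self.lon[:, i]

    def root_locations(self) -> tuple[np.ndarray, np.ndarray]:
        return self.lat[:, 0], self.lon[:, 0]


def prune_recent_same_population(
    tree: Tree,
    tip_populations: dict[str, str],
    threshold_years: float = 1000.0,
    tip_missing: dict[str, float] | None = None,
) -> Tree:
    """Thin cherries of same-population tips coalescing within the last
    ~``threshold_years``.

    From each such pair the tip with more missing data is removed (ties:
    the later by sample ID); applied repeatedly until stable.
    """
    tip_missing = tip_missing or {}
    tree = tree.copy()
    while True:
        victim = None
        for node in tree.postorder():
            if node.is_leaf or node.age >= threshold_years:
                continue
            tips = [c for c in node.children if c.is_leaf]
            for i in range(len(tips)):
                for j in range(i + 1, len(tips)):
                    a, b = tips[i], tips[j]
                    if tip_populations.get(a.name) != tip_populations.get(b.name):
                        continue
                    ma = tip_missing.get(a.name, 0.0)
                    mb = tip_missing.get(b.name, 0.0)
                    if ma > mb:
                        victim = a.name
                    elif mb > ma:
                        victim = b.name
                    else:
                        victim = max(a.name, b.name)
                    break
                if victim:
                    break
            if victim:
                break
        if victim is None:
            return tree
        tree = tree.prune_leaves([victim])


def infer_locations(
    tree: Tree,
    tip_locations: dict[str, tuple[float, float]],
    n_states: int = 500,
    trace: PosteriorTrace | None = None,
    jitter_km: float = 1.0,
    seed: int = 0,
) -> GeoSample:
    """Sample internal-node locations under homogeneous Brownian diffusion.

    For each posterior state (node ages drawn from ``trace`` when given,
    otherwise the tree's own ages), the diffusion variance is drawn from its
    conjugate posterior and node locations from the exact conditional
    Gaussian given the tips.  Coincident tip coordinates are jittered by up
    to ``jitter_km``.  Deterministic given the seed.
    """
    tips = tree.leaves()
    missing = [t.name for t in tips if t.name not in tip_locations]
    if missing:
        raise ValueError(f"tips without coordinates: {missing}")
    rng = np.random.default_rng(seed)

    lat0 = float(np.mean([tip_locations[t.name][0] for t in tips]))
    lon0 = float(np.mean([tip_locations[t.name][1] for t in tips]))
    proj = LocalProjection(lat0, lon0)
    coords: dict[str, np.ndarray] = {}
    seen: set[tuple[float, float]] = set()
    for t in tips:
        lat, lon = tip_locations[t.name]
        x, y = proj.to_plane(lat, lon)
        xy = np.array([float(x), float(y)])
        if (round(xy[0], 6), round(xy[1], 6)) in seen and jitter_km > 0:
            xy = xy + rng.uniform(-jitter_km, jitter_km, size=2)
        seen.add((round(xy[0], 6), round(xy[1], 6)))
        coords[t.name] = xy

    nodes = list(tree.preorder())
    name_of = [n.name for n in nodes]
    idx = {id(n): i for i, n in enumerate(nodes)}
    S = n_states if trace is None else trace.n_states
    if trace is not None:
        n_states = S
    N = len(nodes)
    out_xy = np.empty((S, N, 2))
    sigma2 = np.empty(S)
    branch_parent = np.array([idx[id(n.parent)] for n in nodes if n.parent is not None])
    branch_child = np.array([idx[id(n)] for n in nodes if n.parent is not None])
    durations = np.empty((S, len(branch_parent)))

    post = [n for n in tree.postorder()]
    for st in range(S):
        ages = {n.name: n.age for n in nodes}
        if trace is not None:
            for nm in trace.node_names:
                ages[nm] = float(trace.ages[st % trace.n_states, trace.node_names.index(nm)])
        # branch durations for this state (floored to keep messages proper)
        tau = {}
        for n in nodes:
            if n.parent is not None:
                tau[id(n)] = max(ages[n.parent.name] - ages[n.name], 1e-9)

        # upward pass: subtree-conditional mean/variance (variance in sigma^2 units)
        mean_up: dict[int, np.ndarray] = {}
        var_up: dict[int, float] = {}
        ss = 0.0
        n_contrasts = 0
        for n in post:
            if n.is_leaf:
                mean_up[id(n)] = coords[n.name]
                var_up[id(n)] = 0.0
            else:
                msgs = [(mean_up[id(c)], var_up[id(c)] + tau[id(c)]) for c in n.children]
                m0, v0 = msgs[0]
                for m1, v1 in msgs[1:]:
                    d = m1 - m0
                    ss += float(d @ d) / (v0 + v1)
                    n_contrasts += 1
                    w = v1 / (v0 + v1)
                    m0 = m0 * w + m1 * (1 - w)
                    v0 = v0 * v1 / (v0 + v1)
                mean_up[id(n)] = m0
                var_up[id(n)] = v0

        # conjugate draw of the per-axis diffusion variance:
        # contrasts are iid N(0, sigma^2) per axis after standardisation
        if n_contrasts:
            shape = n_contrasts  # 2 axes x n_contrasts / 2
            sig2 = (ss / 2.0) / rng.gamma(shape)
        else:
            sig2 = 1e-6
        sigma2[st] = sig2

        # downward pass
        xy = np.empty((N, 2))
        root = nodes[0]
        xy[0] = rng.normal(mean_up[id(root)], math.sqrt(max(var_up[id(root)], 0.0) * sig2))
        for n in nodes[1:]:
            i = idx[id(n)]
            p = idx[id(n.parent)]
            if n.is_leaf:
                xy[i] = coords[n.name]
                continue
            vu = var_up[id(n)]
            tv = tau[id(n)]
            v = 1.0 / (1.0 / max(vu, 1e-12) + 1.0 / tv) if vu > 0 else 0.0
            mean = (
                (mean_up[id(n)] / max(vu, 1e-12) + xy[p] / tv) * v
                if vu > 0 else mean_up[id(n)]
            )
            xy[i] = rng.normal(mean, math.sqrt(max(v, 0.0) * sig2))
        out_xy[st] = xy
        durations[st] = [tau[id(n)] for n in nodes if n.parent is not None]

    lat, lon = proj.to_latlon(out_xy[:, :, 0], out_xy[:, :, 1])
    return GeoSample(
        node_names=tuple(name_of),
        lat=lat,
        lon=lon,
        sigma2=sigma2,
        tip_names=tuple(t.name for t in tips),
        branch_parent=branch_parent,
        branch_child=branch_child,
        branch_duration=durations,
        projection=proj,
    )


@dataclass
class HPDRegion:
    """Smallest-area density region holding >= ``level`` posterior mass."""

    level: float
    polygons: MultiPolygon
    area_km2: float
    _grid_lat: np.ndarray = field(repr=False, default=None)
    _grid_lon: np.ndarray = field(repr=False, default=None)
    _included: np.ndarray = field(repr=False, default=None)

    def contains(self, lat: float, lon: float) -> bool:
        """Whether a point falls in the region (by grid-cell membership)."""
        gi = np.argmin(np.abs(self._grid_lat - lat))
        gj = np.argmin(np.abs(self._grid_lon - lon))
        if (np.abs(self._grid_lat - lat).min() > (self._grid_lat[1] - self._grid_lat[0])
                or np.abs(self._grid_lon - lon).min() > (self._grid_lon[1] - self._grid_lon[0])):
            return False
        return bool(self._included[gi, gj])

    def to_geojson(self) -> dict:
        geoms = []
        polys = (self.polygons.geoms if isinstance(self.polygons, MultiPolygon)
                 else [self.polygons])
        for p in polys:
            geoms.append({
                "type": "Polygon",
                "coordinates": [[[float(x), float(y)] for x, y in p.exterior.coords]],
            })
        return {
            "type": "Feature",
            "properties": {"level": self.level, "area_km2": self.area_km2},
            "geometry": {"type": "GeometryCollection", "geometries": geoms}
            if len(geoms) != 1 else geoms[0],
        }


def hpd_region_2d(
    lat_samples,
    lon_samples,
    level: float = 0.80,
    grid_cells: int = 200,
    min_samples: int = 100,
) -> HPDRegion:
    """Gaussian-KDE highest-density region of 2-D location samples.

    The density is evaluated on a ``grid_cells`` x ``grid_cells`` lat/lon
    grid; the region is the smallest set of cells whose mass reaches
    ``level``, contoured into polygons.  The area is the km^2 sum of the
    included cells.
    """
    from scipy.stats import gaussian_kde

    lat = np.asarray(lat_samples, dtype=float)
    lon = np.asarray(lon_samples, dtype=float)
    if len(lat) < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {len(lat)}")

    spread = max(lat.std(), lon.std())
    pad = max(3.0 * spread / max(1, len(lat)) ** 0.1, 1e-6)
    glat = np.linspace(lat.min() - pad, lat.max() + pad, grid_cells)
    glon = np.linspace(lon.min() - pad, lon.max() + pad, grid_cells)
    if np.ptp(lat) < 1e-12 and np.ptp(lon) < 1e-12:
        # all samples identical: single-cell region at that point
        included = np.zeros((grid_cells, grid_cells), dtype=bool)
        gi = np.argmin(np.abs(glat - lat[0]))
        gj = np.argmin(np.abs(glon - lon[0]))
        included[gi, gj] = True
        dlat = glat[1] - glat[0]
        dlon = glon[1] - glon[0]
        area = _cell_area_km2(glat[gi], dlat, dlon)
        poly = Point(lon[0], lat[0]).buffer(max(dlat, dlon) / 2.0, quad_segs=4)
        return HPDRegion(level=level, polygons=MultiPolygon([poly]),
                         area_km2=area, _grid_lat=glat, _grid_lon=glon,
                         _included=included)

    kde = gaussian_kde(np.vstack([lat, lon]))
    mlat, mlon = np.meshgrid(glat, glon, indexing="ij")
    dens = kde(np.vstack([mlat.ravel(), mlon.ravel()])).reshape(mlat.shape)
    mass = dens / dens.sum()
    if level >= 1.0:
        threshold = 0.0
        included = np.ones_like(dens, dtype=bool)
    else:
        order = np.argsort(mass.ravel())[::-1]
        cum = np.cumsum(mass.ravel()[order])
        k = int(np.searchsorted(cum, level)) + 1
        k = min(k, mass.size)
        threshold = dens.ravel()[order[k - 1]]
        included = dens >= threshold

    dlat = glat[1] - glat[0]
    dlon = glon[1] - glon[0]
    area = float(sum(_cell_area_km2(glat[i], dlat, dlon)
                     for i, j in zip(*np.nonzero(included))))

    polys = []
    for ring in measure.find_contours(dens, threshold):
        ring_lat = np.interp(ring[:, 0], np.arange(grid_cells), glat)
        ring_lon = np.interp(ring[:, 1], np.arange(grid_cells), glon)
        if len(ring_lat) >= 4:
            poly = Polygon(zip(ring_lon, ring_lat))
            if poly.is_valid and poly.area > 0:
                polys.append(poly)
    if not polys:
        cells = [Polygon([
            (glon[j] - dlon / 2, glat[i] - dlat / 2), (glon[j] + dlon / 2, glat[i] - dlat / 2),
            (glon[j] + dlon / 2, glat[i] + dlat / 2), (glon[j] - dlon / 2, glat[i] + dlat / 2),
        ]) for i, j in zip(*np.nonzero(included))]
        merged = unary_union(cells)
        polys = list(merged.geoms) if isinstance(merged, MultiPolygon) else [merged]
    merged = unary_union(polys)
    if isinstance(merged, Polygon):
        merged = MultiPolygon([merged])
    return HPDRegion(level=level, polygons=merged, area_km2=area,
                     _grid_lat=glat, _grid_lon=glon, _included=included)


def _cell_area_km2(lat: float, dlat: float, dlon: float) -> float:
    return abs(dlat) * 110.574 * abs(dlon) * 111.320 * math.cos(math.radians(lat))


def diffusion_rate(geo_sample: GeoSample, tree: Tree | None = None) -> np.ndarray:
    """Posterior samples of the tree-wide dispersal rate, km/year.

    Per posterior state: sum of great-circle parent-child displacements
    divided by the total branch time.
    """
    total_time = geo_sample.branch_duration.sum(axis=1)
    if np.any(total_time <= 0):
        raise ValueError("zero total tree time")
    dist = haversine_km(
        geo_sample.lat[:, geo_sample.branch_parent],
        geo_sample.lon[:, geo_sample.branch_parent],
        geo_sample.lat[:, geo_sample.branch_child],
        geo_sample.lon[:, geo_sample.branch_child],
    )
    return dist.sum(axis=1) / total_time


def summarize_rate(rates: np.ndarray, prob: float = 0.95) -> dict:
    lo, hi = hpd_interval(rates, prob)
    return {"rate_median": float(np.median(rates)), "rate_hpd": (lo, hi)}
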