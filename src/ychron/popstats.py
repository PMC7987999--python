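"""Y-STR gene diversity, branch frequency tables, and spatial surfaces.

Gene diversity is Nei's unbiased estimator D = n/(n-1) * (1 - sum p_i^2)
over exact 8-locus haplotype identity — equivalently, the bias-corrected
probability that two randomly drawn haplotypes differ.  Spatial surfaces
use ordinary kriging with a linear variogram (no nugget) or inverse-
distance weighting as a light-weight alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "str_gene_diversity",
    "branch_frequency_table",
    "SurfaceGrid",
    "interpolate_surface",
]

STR_DIVERSITY_LOCI = ("DYS19", "DYS389I", "DYS389II", "DYS390",
                      "DYS391", "DYS392", "DYS393", "DYS439")


def str_gene_diversity(haplotypes: pd.DataFrame | np.ndarray) -> float:
    """Nei's unbiased gene diversity of STR haplotypes.

    ``haplotypes`` is a samples x loci table of integer repeat counts with
    no missing entries; identity is exact equality across all loci.
    """
    h = np.asarray(haplotypes)
    n = h.shape[0]
    if n < 2:
        raise ValueError("gene diversity needs at least 2 haplotypes")
    if np.any(~np.isfinite(h.astype(float))):
        raise ValueError("missing locus values are not allowed")
    _, counts = np.unique(h, axis=0, return_counts=True)
    p = counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p ** 2)))


def branch_frequency_table(
    assignments: dict[str, str],
    population_labels: dict[str, str],
    level_branches: list[str] | None = None,
    tree=None,
) -> pd.DataFrame:
    """Per-population branch counts and percentages, with a totals row.

    ``assignments`` maps sample -> branch name.  When ``level_branches`` and
    a tree are given, each sample is attributed to the listed ancestor
    branch containing its assignment; the level branches must be disjoint
    clades.  Row percentages are relative to each population's classified
    samples.
    """
    if level_branches and tree is not None:
        sets = tree.leaf_sets()
        nodes = {n.name: sets[id(n)] for n in tree.postorder()}
        clades = []
        for b in level_branches:
            if b not in nodes:
                raise ValueError(f"unknown level branch {b!r}")
            clades.append(nodes[b])
        for i in range(len(clades)):
            for j in range(i + 1, len(clades)):
                if clades[i] & clades[j]:
                    raise ValueError(
                        f"level branches overlap: {level_branches[i]} / {level_branches[j]}"
                    )
        lifted = {}
        for sample, br in assignments.items():
            target = None
            if br in nodes:
                members = nodes[br]
                for lb, cl in zip(level_branches, clades):
                    if members <= cl:
                        target = lb
                        break
            lifted[sample] = target if target is not None else "other"
        assignments = lifted

    df = pd.DataFrame({
        "sample": list(assignments),
        "branch": [assignments[s] for s in assignments],
        "population": [population_labels.get(s, "?") for s in assignments],
    })
    counts = df.pivot_table(index="population", columns="branch", values="sample",
                            aggfunc="count", fill_value=0)
    counts.loc["total"] = counts.sum(axis=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    out = pd.concat({"count": counts, "percent": pct.round(2)}, axis=1)
    return out


@dataclass
class SurfaceGrid:
    """Regular lon/lat grid of interpolated values."""

    lat: np.ndarray      # (ny,)
    lon: np.ndarray      # (nx,)
    values: np.ndarray   # (ny, nx)
    method: str

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, index=self.lat, columns=self.lon)
        df.index.name = "lat\\lon"
        df.to_csv(path, sep="\t")

    def to_ascii_grid(self, path) -> None:
        """ESRI ASCII grid (row order north to south)."""
        ny, nx = self.values.shape
        cell = float(self.lon[1] - self.lon[0]) if nx > 1 else 1.0
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.lon[0] - cell / 2}\n")
            fh.write(f"yllcorner {self.lat[0] - cell / 2}\n")
            fh.write(f"cellsize {cell}\nNODATA_value -9999\n")
            for row in self.values[::-1]:
                fh.write(" ".join("-9999" if not np.isfinite(v) else f"{v:.6g}"
                                  for v in row) + "\n")

    def value_at(self, lat: float, lon: float) -> float:
        i = int(np.argmin(np.abs(self.lat - lat)))
        j = int(np.argmin(np.abs(self.lon - lon)))
        return float(self.values[i, j])


def _dedupe_points(lat, lon, values):
    pts: dict[tuple[float, float], list[float]] = {}
    for la, lo, v in zip(lat, lon, values):
        pts.setdefault((float(la), float(lo)), []).append(float(v))
    out_lat, out_lon, out_val = [], [], []
    warned = False
    for (la, lo), vs in pts.items():
        if len(vs) > 1 and len(set(vs)) > 1 and not warned:
            warnings.warn("duplicate coordinates with different values: averaging",
                          stacklevel=3)
            warned = True
        out_lat.append(la)
        out_lon.append(lo)
        out_val.append(float(np.mean(vs)))
    return np.array(out_lat), np.array(out_lon), np.array(out_val)


def kriging_weights(coords: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Ordinary-kriging weights with a linear variogram gamma(h) = h.

    Solves the (k+1) x (k+1) system [[Gamma, 1], [1', 0]] [w, m] = [g, 1]
    where Gamma_ij = |x_i - x_j| and g_i = |x_i - target|.
    """
    k = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = d
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    b = np.zeros(k + 1)
    b[:k] = np.linalg.norm(coords - target[None, :], axis=1)
    b[k] = 1.0
    sol = np.linalg.solve(A, b)
    return sol[:k]


def interpolate_surface(
    lat,
    lon,
    values,
    grid_lat: np.ndarray | None = None,
    grid_lon: np.ndarray | None = None,
    n_grid: int = 100,
    method: str = "ordinary_kriging",
    idw_power: float = 2.0,
    max_reach_deg: float | None = None,
) -> SurfaceGrid:
    """Interpolate point data onto a regular lat/lon grid.

    ``method`` is ``"ordinary_kriging"`` (linear variogram, exact at data
    points) or ``"idw"`` (inverse-distance weighting, power 2 by default,
    also exact at data points).  Duplicate coordinates with differing
    values are averaged with a warning.  Cells farther than
    ``max_reach_deg`` from every datum are left NaN.
    """
    lat, lon, values = _dedupe_points(np.asarray(lat, float), np.asarray(lon, float),
                                      np.asarray(values, float))
    if method == "ordinary_kriging":
        if len(lat) < 3:
            raise ValueError("kriging needs at least 3 points")
        span = np.ptp(lat) * np.ptp(lon)
        if span == 0:
            raise ValueError("kriging needs non-collinear points")
    if grid_lat is None:
        pad = 0.05 * max(np.ptp(lat), 1e-6)
        grid_lat = np.linspace(lat.min() - pad, lat.max() + pad, n_grid)
    if grid_lon is None:
        pad = 0.05 * max(np.ptp(lon), 1e-6)
        grid_lon = np.linspace(lon.min() - pad, lon.max() + pad, n_grid)

    coords = np.stack([lat, lon], axis=1)
    out = np.full((len(grid_lat), len(grid_lon)), np.nan)
    for i, gla in enumerate(grid_lat):
        for j, glo in enumerate(grid_lon):
            target = np.array([gla, glo])
            d = np.linalg.norm(coords - target[None, :], axis=1)
            if max_reach_deg is not None and d.min() > max_reach_deg:
                continue
            hit = np.argmin(d)
            if d[hit] < 1e-12:
                out[i, j] = values[hit]
                continue
            if method == "idw":
                w = 1.0 / d ** idw_power
                out[i, j] = float(np.sum(w * values) / np.sum(w))
            elif method == "ordinary_kriging":
                w = kriging_weights(coords, target)
                out[i, j] = float(w @ values)
            else:
                raise ValueError(f"unknown method {method!r}")
    return SurfaceGrid(lat=np.asarray(grid_lat), lon=np.asarray(grid_lon),
                       values=out, method=method)
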