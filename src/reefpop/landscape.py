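"""Habitat rasters, least-cost distances and range-expansion origin mapping.

The seascape is a coded integer grid (0 land, 1 open sea, 2 seamount,
3 reef). Each habitat code carries a permeability; movement cost between two
adjacent marine cells is the step length (cell size, times sqrt(2) on
diagonals) multiplied by the mean of the two cells' resistances
(resistance = 1 / permeability). Land is impassable. Least-cost (LC)
distances are shortest paths on the resulting 8-connected graph.

Two inference procedures sit on top:

* ``optimize_permeability`` searches reef/seamount permeabilities (open sea
  fixed at 1, land at 0, and seamount <= reef per the habitat-quality
  ordering) maximizing the Pearson correlation between pairwise LC
  distances and linearized genetic distances F_ST/(1-F_ST).
* ``origin_map`` treats every marine cell as a candidate range-expansion
  origin and maps the correlation between per-site genetic diversity and
  the LC distance from that cell; the most negative cell is the inferred
  origin (diversity decays away from an expansion origin).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import ConfigError, DegenerateInputError, DimensionError

__all__ = [
    "LAND",
    "SEA",
    "SEAMOUNT",
    "REEF",
    "HabitatRaster",
    "PermeabilityConfig",
    "CostSurface",
    "OriginMap",
    "read_ascii_grid",
    "write_ascii_grid",
    "build_cost_surface",
    "lc_distance",
    "lc_distance_matrix",
    "optimize_permeability",
    "origin_map",
]

LAND, SEA, SEAMOUNT, REEF = 0, 1, 2, 3

COARSE_GRID = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)


@dataclass(frozen=True)
class HabitatRaster:
    """Coded habitat grid. Row 0 is the northernmost row (ESRI convention)."""

    codes: np.ndarray
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: int = -9999

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes, dtype=np.int64)
        if codes.ndim != 2:
            raise DimensionError("raster codes must be 2-D")
        object.__setattr__(self, "codes", codes)
        if not self.marine_mask().any():
            raise DegenerateInputError("raster holds no marine cell")

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def marine_mask(self) -> np.ndarray:
        return (self.codes != LAND) & (self.codes != self.nodata)


@dataclass(frozen=True)
class PermeabilityConfig:
    """Habitat permeabilities; land and open sea are fixed by convention."""

    p_reef: float = 1.0
    p_seamount: float = 1.0
    p_sea: float = field(default=1.0, init=False)
    p_land: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not (1.0 <= self.p_reef <= 100.0):
            raise ConfigError("p_reef must lie in [1, 100]")
        if not (1.0 <= self.p_seamount <= self.p_reef):
            raise ConfigError("p_seamount must lie in [1, p_reef]")

    def permeability(self) -> np.ndarray:
        """Permeability indexed by habitat code."""
        return np.array([self.p_land, self.p_sea, self.p_seamount, self.p_reef])


class CostSurface:
    """Weighted 8-connected graph over the marine cells of a raster."""

    def __init__(self, raster: HabitatRaster, graph, marine: np.ndarray):
        self.raster = raster
        self.graph = graph  # csr matrix over all nrows*ncols nodes
        self.marine = marine

    def node(self, cell: tuple[int, int]) -> int:
        r, c = cell
        nrows, ncols = self.raster.shape
        if not (0 <= r < nrows and 0 <= c < ncols):
            raise IndexError(f"cell {cell} outside raster {self.raster.shape}")
        if not self.marine[r, c]:
            raise ConfigError(f"cell {cell} is not marine")
        return r * ncols + c


def read_ascii_grid(path: str | os.PathLike, cls=HabitatRaster):
    """ESRI ASCII grid reader (integer or float body depending on cls)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        body = np.loadtxt(fh)
    body = np.atleast_2d(body)
    if body.shape != (int(header["nrows"]), int(header["ncols"])):
        raise DimensionError("ASCII grid body does not match header dimensions")
    kwargs = dict(
        cellsize=header.get("cellsize", 1.0),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
    )
    if cls is HabitatRaster:
        return HabitatRaster(codes=body.astype(np.int64), nodata=int(header.get("nodata_value", -9999)), **kwargs)
    return cls(values=body, nodata=header.get("nodata_value", -9999.0), **kwargs)


def _write_grid(values: np.ndarray, path, cellsize, xll, yll, nodata, fmt) -> None:
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {xll}\nyllcorner {yll}\ncellsize {cellsize}\n")
        fh.write(f"NODATA_value {nodata}\n")
        for row in values:
            fh.write(" ".join(fmt % v for v in row) + "\n")


def write_ascii_grid(raster, path: str | os.PathLike) -> None:
    if isinstance(raster, HabitatRaster):
        _write_grid(raster.codes, path, raster.cellsize, raster.xllcorner,
                    raster.yllcorner, raster.nodata, "%d")
    else:  # OriginMap or any float grid object
        vals = np.where(np.isnan(raster.values), raster.nodata, raster.values)
        _write_grid(vals, path, raster.cellsize, raster.xllcorner,
                    raster.yllcorner, raster.nodata, "%.6g")


_STEPS = [(-1, 0, 1.0), (0, -1, 1.0), (-1, -1, np.sqrt(2)), (-1, 1, np.sqrt(2))]


def build_cost_surface(
    raster: HabitatRaster,
    perm: PermeabilityConfig,
    diagonal: bool = True,
    conductance_mean: bool = False,
) -> CostSurface:
    """Edge-weighted marine graph.

    Default edge weight is step length times the mean of the two cells'
    resistances; ``conductance_mean=True`` instead averages permeabilities
    and inverts (the alternative transition-layer convention).
    """
    codes = raster.codes
    marine = raster.marine_mask()
    nrows, ncols = codes.shape
    p = perm.permeability()
    with np.errstate(divide="ignore"):
        resist = np.where(marine, 1.0 / p[np.clip(codes, 0, 3)], np.inf)
        conduct = np.where(marine, p[np.clip(codes, 0, 3)], 0.0)
    rows_l: list[np.ndarray] = []
    cols_l: list[np.ndarray] = []
    w_l: list[np.ndarray] = []
    idx = np.arange(nrows * ncols).reshape(nrows, ncols)
    steps = _STEPS if diagonal else _STEPS[:2]
    for dr, dc, step in steps:
        r0 = slice(max(0, -dr), nrows - max(0, dr))
        c0 = slice(max(0, -dc), ncols - max(0, dc))
        r1 = slice(max(0, dr), nrows - max(0, -dr))
        c1 = slice(max(0, dc), ncols - max(0, -dc))
        ok = marine[r0, c0] & marine[r1, c1]
        if conductance_mean:
            cm = (conduct[r0, c0] + conduct[r1, c1]) / 2.0
            w = np.where(cm > 0, step * raster.cellsize / np.where(cm > 0, cm, 1.0), np.inf)
        else:
            w = step * raster.cellsize * (resist[r0, c0] + resist[r1, c1]) / 2.0
        rows_l.append(idx[r0, c0][ok])
        cols_l.append(idx[r1, c1][ok])
        w_l.append(w[ok])
    if not any(len(r) for r in rows_l):
        if marine.sum() <= 1:
            g = coo_matrix((nrows * ncols, nrows * ncols)).tocsr()
            return CostSurface(raster, g, marine)
    rows = np.concatenate(rows_l)
    cols = np.concatenate(cols_l)
    w = np.concatenate(w_l)
    g = coo_matrix((w, (rows, cols)), shape=(nrows * ncols, nrows * ncols)).tocsr()
    return CostSurface(raster, g, marine)


def lc_distance(surface: CostSurface, source: tuple[int, int], targets=None) -> np.ndarray:
    """Least-cost distances from one marine cell.

    With ``targets=None`` returns the full (nrows, ncols) distance field
    (inf for unreachable or land cells); otherwise a vector over the target
    cells in order.
    """
    src = surface.node(source)
    dist = dijkstra(surface.graph, directed=False, indices=src)
    if targets is None:
        return dist.reshape(surface.raster.shape)
    return np.array([dist[surface.node(t)] for t in targets])


def lc_distance_matrix(surface: CostSurface, cells) -> np.ndarray:
    """Symmetric matrix of pairwise LC distances between marine cells."""
    nodes = [surface.node(c) for c in cells]
    dist = dijkstra(surface.graph, directed=False, indices=nodes)
    D = dist[:, nodes]
    return (D + D.T) / 2.0  # symmetrize away float jitter


def _linearize_fst(fst: np.ndarray) -> np.ndarray:
    f = np.clip(np.asarray(fst, dtype=float), 0.0, None)
    if np.any(f >= 1.0):
        raise ConfigError("F_ST >= 1 cannot be linearized")
    return f / (1.0 - f)


def _pair_objective(D: np.ndarray, G: np.ndarray) -> float:
    iu = np.triu_indices(D.shape[0], k=1)
    x = D[iu]
    y = G[iu]
    if not np.all(np.isfinite(x)):
        raise DegenerateInputError("sites are not all mutually reachable")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("constant distances: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _site_cells(sites) -> list[tuple[int, int]]:
    return [(int(r), int(c)) for r, c in zip(sites["row"], sites["col"])]


def optimize_permeability(
    raster: HabitatRaster,
    sites,
    gdist: np.ndarray,
    objective: str = "fst_lin",
    coarse: tuple = COARSE_GRID,
    refine_step: float = 0.01,
    diagonal: bool = True,
) -> tuple[PermeabilityConfig, list[tuple[float, float, float]]]:
    """Grid-search reef/seamount permeabilities maximizing distance correlation.

    ``sites`` is a SiteTable DataFrame (columns row, col); ``gdist`` the
    matching square genetic-distance matrix (F_ST by default, linearized
    internally unless ``objective='fst'``). A coarse logarithmic pass over
    ``coarse`` x ``coarse`` (seamount <= reef) is refined by repeated 9-point
    zooming around the optimum down to ``refine_step``. Ties prefer the
    lexicographically smallest (p_reef, p_seamount).

    Returns the best configuration and the full evaluation profile as
    (p_reef, p_seamount, r) triples.
    """
    gdist = np.asarray(gdist, dtype=float)
    if len(sites) < 4:
        raise ConfigError("need at least 4 sites to fit permeabilities")
    if gdist.shape != (len(sites), len(sites)):
        raise DimensionError("genetic distance matrix does not match site table")
    G = _linearize_fst(gdist) if objective == "fst_lin" else np.asarray(gdist, dtype=float)
    cells = _site_cells(sites)

    cache: dict[tuple[float, float], float] = {}

    def evaluate(pr: float, ps: float) -> float:
        key = (round(pr, 6), round(ps, 6))
        if key not in cache:
            surf = build_cost_surface(raster, PermeabilityConfig(pr, ps), diagonal=diagonal)
            cache[key] = _pair_objective(lc_distance_matrix(surf, cells), G)
        return cache[key]

    best = (-np.inf, np.inf, np.inf)  # (r, p_reef, p_seamount) with tie order
    profile: list[tuple[float, float, float]] = []

    def consider(pr: float, ps: float) -> None:
        nonlocal best
        r = evaluate(pr, ps)
        profile.append((pr, ps, r))
        if r > best[0] or (r == best[0] and (pr, ps) < (best[1], best[2])):
            best = (r, pr, ps)

    for pr in coarse:
        for ps in coarse:
            if ps <= pr:
                consider(float(pr), float(ps))
    # zoom refinement: bracket each coordinate by its coarse neighbors
    lo_r, hi_r = _bracket(best[1], coarse)
    lo_s, hi_s = _bracket(best[2], coarse)
    while max(hi_r - lo_r, hi_s - lo_s) > 8 * refine_step:
        for pr in np.linspace(lo_r, hi_r, 9):
            for ps in np.linspace(lo_s, hi_s, 9):
                if 1.0 <= ps <= pr <= 100.0:
                    consider(float(pr), float(ps))
        span_r = (hi_r - lo_r) / 4.0
        span_s = (hi_s - lo_s) / 4.0
        lo_r, hi_r = max(1.0, best[1] - span_r), min(100.0, best[1] + span_r)
        lo_s, hi_s = max(1.0, best[2] - span_s), min(100.0, best[2] + span_s)
    for pr in np.arange(max(1.0, best[1] - 4 * refine_step), min(100.0, best[1] + 4 * refine_step) + refine_step / 2, refine_step):
        for ps in np.arange(max(1.0, best[2] - 4 * refine_step), min(100.0, best[2] + 4 * refine_step) + refine_step / 2, refine_step):
            if 1.0 <= ps <= pr <= 100.0:
                consider(round(float(pr), 6), round(float(ps), 6))
    return PermeabilityConfig(best[1], best[2]), profile


def _bracket(x: float, grid: tuple) -> tuple[float, float]:
    g = sorted(grid)
    lo = max([v for v in g if v <= x], default=g[0])
    hi = min([v for v in g if v >= x], default=g[-1])
    below = [v for v in g if v < lo]
    above = [v for v in g if v > hi]
    return (below[-1] if below else lo), (above[0] if above else hi)


@dataclass(frozen=True)
class OriginMap:
    """Grid of Pearson correlations r(theta_pi, LC distance from cell)."""

    values: np.ndarray  # NaN where undefined
    cellsize: float = 1.0
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    nodata: float = -9999.0

    @property
    def argmin(self) -> tuple[int, int]:
        v = np.where(np.isnan(self.values), np.inf, self.values)
        flat = int(np.argmin(v))
        return np.unravel_index(flat, self.values.shape)


def origin_map(
    raster: HabitatRaster,
    sites,
    perm: PermeabilityConfig,
    diversity_col: str = "theta_pi",
    diagonal: bool = True,
) -> OriginMap:
    """Correlation map between per-site diversity and LC distance from each
    marine cell; the argmin (most negative r) is the inferred RE origin."""
    if len(sites) < 3:
        raise ConfigError("need at least 3 sites for an origin correlation map")
    theta = np.asarray(sites[diversity_col], dtype=float)
    if np.std(theta) == 0:
        raise DegenerateInputError("constant diversity across sites: map undefined")
    surf = build_cost_surface(raster, perm, diagonal=diagonal)
    cells = _site_cells(sites)
    nodes = [surf.node(c) for c in cells]
    D = dijkstra(surf.graph, directed=False, indices=nodes)  # k x ncells
    nrows, ncols = raster.shape
    k = len(nodes)
    finite = np.isfinite(D).all(axis=0)
    marine = surf.marine.ravel()
    ok = finite & marine
    x = theta - theta.mean()
    sx = np.sqrt((x**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        Dm = np.where(np.isfinite(D), D, 0.0)
        Dc = Dm - Dm.mean(axis=0, keepdims=True)
        sy = np.sqrt((Dc**2).sum(axis=0))
        r = (x @ Dc) / (sx * sy)
    r[~ok | (sy == 0)] = np.nan
    vals = r.reshape(nrows, ncols)
    if np.all(np.isnan(vals)):
        raise DegenerateInputError("no marine cell reaches all sites")
    return OriginMap(values=vals, cellsize=raster.cellsize,
                     xllcorner=raster.xllcorner, yllcorner=raster.yllcorner)
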