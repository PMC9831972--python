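"""Seeded generators for every input the pipeline consumes.

These produce the statistical structure the analysis assumes, without any
real data: archipelago habitat rasters (sea background, reef patches,
seamount speckle, land masses), per-site diversity values carrying a planted
range-expansion decay away from a chosen origin cell, and pairwise F_ST
matrices carrying a planted isolation-by-distance slope. Demographic
datasets (folded SFS, two-population genotypes) come from the coalescent
simulator (:mod:`reefpop.coalsim`), which is the pipeline's main synthetic
engine.

The diversity decay is phenomenological (linear in least-cost distance plus
Gaussian noise) rather than a spatially explicit expansion simulation: the
origin-mapping method only assumes a monotone decay, so this is the minimal
structure that can validate it. Every generator is a pure function of its
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError
from .landscape import (
    LAND,
    REEF,
    SEA,
    SEAMOUNT,
    HabitatRaster,
    PermeabilityConfig,
    build_cost_surface,
    lc_distance,
    lc_distance_matrix,
)

__all__ = [
    "ArchipelagoSpec",
    "PlantedOrigin",
    "make_archipelago_raster",
    "make_planted_origin_data",
    "make_ibd_fst",
    "make_demo_dataset",
]


@dataclass(frozen=True)
class ArchipelagoSpec:
    """Recipe for a synthetic island/reef seascape."""

    shape: tuple[int, int] = (60, 80)
    n_reef_patches: int = 8
    patch_radius: tuple[int, int] = (2, 4)
    seamount_density: float = 0.01
    n_land_masses: int = 3
    land_size: tuple[int, int] = (4, 10)
    n_sites: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape[0] < 20 or self.shape[1] < 20:
            raise ConfigError("raster must be at least 20x20")
        if self.n_sites > self.n_reef_patches:
            raise ConfigError("cannot place more sites than reef patches")


@dataclass(frozen=True)
class PlantedOrigin:
    """Linear diversity decay away from a planted range-expansion origin."""

    origin: tuple[int, int]
    a: float = 2.0e-3  # diversity at the origin
    b: float = 1.0e-5  # decay per LC distance unit
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ConfigError("decay intercept a must be positive")
        if self.b <= 0:
            raise ConfigError("decay slope b must be positive")


def _disk(codes: np.ndarray, center: tuple[int, int], radius: int, value: int) -> None:
    nrows, ncols = codes.shape
    r0, c0 = center
    rr, cc = np.ogrid[:nrows, :ncols]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    codes[mask] = value


def make_archipelago_raster(spec: ArchipelagoSpec) -> tuple[HabitatRaster, list[tuple[int, int]]]:
    """Sea background + land masses + reef patches + seamount speckle.

    Returns the raster and one candidate site cell per reef patch (the patch
    center), guaranteed mutually reachable through marine cells; the layout
    is re-drawn (bounded retries) if land masses sever connectivity.
    """
    base = np.random.SeedSequence(spec.seed)
    for attempt, child in enumerate(base.spawn(30)):
        gen = np.random.default_rng(child)
        nrows, ncols = spec.shape
        codes = np.full((nrows, ncols), SEA, dtype=np.int64)
        for _ in range(spec.n_land_masses):
            h = int(gen.integers(spec.land_size[0], spec.land_size[1] + 1))
            w = int(gen.integers(spec.land_size[0], spec.land_size[1] + 1))
            r = int(gen.integers(0, nrows - h))
            c = int(gen.integers(0, ncols - w))
            codes[r : r + h, c : c + w] = LAND
        sm = gen.random((nrows, ncols)) < spec.seamount_density
        codes[sm & (codes == SEA)] = SEAMOUNT
        centers: list[tuple[int, int]] = []
        for _ in range(spec.n_reef_patches):
            for _try in range(200):
                r = int(gen.integers(2, nrows - 2))
                c = int(gen.integers(2, ncols - 2))
                if codes[r, c] != LAND and all(abs(r - rr) + abs(c - cc) > 6 for rr, cc in centers):
                    rad = int(gen.integers(spec.patch_radius[0], spec.patch_radius[1] + 1))
                    disk = np.zeros_like(codes, dtype=bool)
                    rr_, cc_ = np.ogrid[:nrows, :ncols]
                    disk = (rr_ - r) ** 2 + (cc_ - c) ** 2 <= rad**2
                    codes[disk & (codes != LAND)] = REEF
                    centers.append((r, c))
                    break
        if len(centers) < spec.n_reef_patches:
            continue
        raster = HabitatRaster(codes=codes)
        sites = centers[: spec.n_sites]
        surf = build_cost_surface(raster, PermeabilityConfig(1.0, 1.0))
        try:
            D = lc_distance_matrix(surf, sites)
        except ConfigError:
            continue
        if np.all(np.isfinite(D)):
            return raster, sites
    raise DegenerateInputError("could not generate a connected archipelago (30 attempts)")


def make_planted_origin_data(
    raster: HabitatRaster,
    planted: PlantedOrigin,
    site_cells: list[tuple[int, int]],
    perm: PermeabilityConfig = PermeabilityConfig(1.0, 1.0),
) -> pd.DataFrame:
    """Site table whose theta_pi decays linearly with LC distance from the
    planted origin: theta_i = max(0, a - b d_i + N(0, sd))."""
    surf = build_cost_surface(raster, perm)
    d = lc_distance(surf, planted.origin, targets=site_cells)
    if not np.all(np.isfinite(d)):
        raise DegenerateInputError("planted origin cannot reach every site")
    gen = np.random.default_rng(planted.seed)
    noise = gen.normal(0.0, planted.noise_sd, size=len(site_cells)) if planted.noise_sd > 0 else 0.0
    theta = np.maximum(0.0, planted.a - planted.b * d + noise)
    return pd.DataFrame({
        "id": [f"site{i}" for i in range(len(site_cells))],
        "row": [r for r, _ in site_cells],
        "col": [c for _, c in site_cells],
        "theta_pi": theta,
        "n": 10,
    })


def make_ibd_fst(
    dist: np.ndarray,
    slope: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """F_ST matrix with a planted isolation-by-distance signal.

    Inverts the Rousset linearization: x = max(0, c d + eps), F = x/(1+x).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ConfigError("distance matrix must be square")
    gen = np.random.default_rng(seed)
    x = slope * D
    if noise_sd > 0:
        eps = gen.normal(0.0, noise_sd, size=D.shape)
        eps = (eps + eps.T) / 2.0
        x = x + eps
    x = np.clip(x, 0.0, None)
    F = x / (1.0 + x)
    np.fill_diagonal(F, 0.0)
    if np.any(F >= 1.0):
        raise ConfigError("planted slope too steep: F_ST reaches 1")
    return (F + F.T) / 2.0


def make_demo_dataset(outdir, seed: int = 0, n_dip: int = 6, n_loci: int = 200,
                      abc_nsim: int = 40, td_nsim: int = 100) -> dict:
    """Emit a complete, internally consistent demo dataset directory.

    Contents: an archipelago raster (.asc), a site table with planted-origin
    diversity decay, per-site folded SFS simulated under a stepping-stone
    history, per-site 012 genotype matrices, a planted-IBD F_ST matrix, and
    a ready-to-run pipeline config (config.yaml). Small by design; sizes are
    configurable through the keyword arguments.
    """
    from pathlib import Path

    import yaml

    from . import io as rio
    from .coalsim import DemographicModel, SampleSpec, simulate_sfs, simulate_two_deme_genotypes

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    s_rast, s_orig, s_sfs, s_geno, s_fst = [int(c.generate_state(1)[0] % (2**31 - 1))
                                            for c in ss.spawn(5)]
    spec = ArchipelagoSpec(seed=s_rast)
    raster, cells = make_archipelago_raster(spec)
    from .landscape import write_ascii_grid

    write_ascii_grid(raster, out / "raster.asc")
    planted = PlantedOrigin(origin=cells[0], a=2.0e-3, b=5e-6, noise_sd=5e-5, seed=s_orig)
    sites = make_planted_origin_data(raster, planted, cells)
    sites["n"] = n_dip
    rio.write_site_table(sites, out / "sites.tsv")

    surf = build_cost_surface(raster, PermeabilityConfig(1.0, 1.0))
    D = lc_distance_matrix(surf, cells)
    F = make_ibd_fst(D, slope=2e-4, noise_sd=0.0, seed=s_fst)
    rio.write_distance_matrix(F, list(sites["id"]), out / "fst.tsv")

    sst = DemographicModel(kind="SST", N=2000, m=5e-3, T_col=2e5, N_anc=20000)
    gen = np.random.default_rng(s_sfs)
    (out / "sfs").mkdir(exist_ok=True)
    for sid in sites["id"]:
        sfs = simulate_sfs(sst, SampleSpec(deme=(4, 4), n_dip=n_dip),
                           n_loci=n_loci, locus_len=100, rng=gen)
        rio.write_sfs(sfs, out / "sfs" / f"{sid}.sfs")

    ggen = np.random.default_rng(s_geno)
    (out / "geno").mkdir(exist_ok=True)
    ids = list(sites["id"])
    for a in range(0, len(ids), 2):
        if a + 1 >= len(ids):
            break
        HA, HB = simulate_two_deme_genotypes(
            sst, (4, 4), (4, 6), n_dip_each=n_dip, n_loci=n_loci // 4,
            locus_len=100, rng=ggen)
        for sid, H in ((ids[a], HA), (ids[a + 1], HB)):
            G = H[0::2] + H[1::2]
            rio.write_012(G, out / "geno" / f"{sid}.tsv")

    config = {
        "seed": seed,
        "outdir": "results",
        "stages": ["diversity", "permeability", "origin", "abc", "popstruct"],
        "sfs": {sid: f"sfs/{sid}.sfs" for sid in sites["id"]},
        "genotypes": {sid: f"geno/{sid}.tsv" for sid in ids[: 2 * (len(ids) // 2)]},
        "raster": "raster.asc",
        "site_table": "sites.tsv",
        "fst_matrix": "fst.tsv",
        "diversity": {"td_nsim": td_nsim},
        "abc": {"nsim_per_model": abc_nsim, "n_trees": 100, "n_loci": n_loci},
        "landscape": {"objective": "fst_lin", "refine_step": 0.5},
    }
    (out / "config.yaml").write_text(yaml.safe_dump(config, sort_keys=False))
    return {"outdir": str(out), "planted_origin": cells[0], "sites": sites}
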