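"""Structured-coalescent simulation of the three demographic scenarios.

Three meta-population histories are supported, all viewed backward in time:

* **NS** (no structure): one panmictic population whose diploid size switches
  instantaneously from ``N_mod`` to ``N_anc`` at ``T_c`` generations.
* **FIM** (finite island model): a grid of demes of equal diploid size ``N``,
  every deme exchanging migrants with every other; all demes merge into one
  ancestral pool of size ``N_anc`` at ``T_col`` generations.
* **SST** (stepping stone): like FIM but migration is restricted to the four
  lattice neighbors (non-toroidal by default; each lineage's total emigration
  rate stays ``m``, renormalized over its 2-4 available neighbors).

Conventions follow the standard diploid coalescent: a pair of lineages in a
deme of diploid size ``N`` coalesces at rate ``1/(2N)`` per generation, and
``Nm`` is the expected number of diploid migrants per deme per generation.
Mutations follow the infinite-sites model on independent non-recombining
loci (default 100 bp each). The default mutation rate is 1.93e-8 per site
per generation and the generation time 10 years (metadata only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import _engine
from .errors import ConfigError, SampleSizeError
from .sfs import FoldedSFS, fold_sfs

__all__ = [
    "DemographicModel",
    "SampleSpec",
    "Genealogy",
    "simulate_genealogy",
    "drop_mutations",
    "simulate_sfs",
    "simulate_two_deme_genotypes",
    "simulate_two_deme_counts",
]

DEFAULT_MU = 1.93e-8
DEFAULT_GEN_TIME = 10.0
DEFAULT_GRID = (10, 10)
DEFAULT_DEME = (4, 4)  # near-center cell of the default 10x10 grid


@dataclass(frozen=True)
class DemographicModel:
    """Parameter bundle for one of the NS / FIM / SST scenarios."""

    kind: Literal["NS", "FIM", "SST"]
    mu: float = DEFAULT_MU
    gen_time: float = DEFAULT_GEN_TIME
    # NS
    N_mod: float | None = None
    N_anc: float | None = None
    T_c: float | None = None
    # FIM / SST
    grid: tuple[int, int] = DEFAULT_GRID
    N: float | None = None
    m: float | None = None
    T_col: float | None = None
    torus: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("NS", "FIM", "SST"):
            raise ConfigError(f"unknown model kind {self.kind!r}")
        if self.mu < 0:
            raise ConfigError("mu must be non-negative")
        if self.kind == "NS":
            for name in ("N_mod", "N_anc", "T_c"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ConfigError(f"NS model requires {name} > 0")
            if self.N_mod < 1 or self.N_anc < 1:
                raise ConfigError("population sizes must be >= 1")
        else:
            for name in ("N", "N_anc", "T_col"):
                v = getattr(self, name)
                if v is None or v <= 0:
                    raise ConfigError(f"{self.kind} model requires {name} > 0")
            if self.m is None or not (0.0 <= self.m <= 1.0):
                raise ConfigError("migration probability m must lie in [0, 1]")
            r, c = self.grid
            if r < 1 or c < 1:
                raise ConfigError("grid dimensions must be >= 1")

    @property
    def n_demes(self) -> int:
        return self.grid[0] * self.grid[1]

    @property
    def Nm(self) -> float | None:
        if self.kind == "NS":
            return None
        return self.N * self.m


@dataclass(frozen=True)
class SampleSpec:
    """Where and how many diploid individuals are sampled."""

    deme: tuple[int, int] | str = "panmictic"
    n_dip: int = 10

    def __post_init__(self) -> None:
        if self.n_dip < 1:
            raise SampleSizeError("n_dip must be >= 1")


class Genealogy:
    """A single coalescent tree over ``n`` sampled lineages.

    Internally stored as the time-ordered coalescence events; exposes node
    times (generations, tips at 0), parent pointers, branch lengths and the
    number of sampled descendants below each node.
    """

    def __init__(self, n: int, times: np.ndarray, child1: np.ndarray, child2: np.ndarray):
        self.n = int(n)
        self.event_times = np.asarray(times, dtype=float)
        self.child1 = np.asarray(child1, dtype=np.int64)
        self.child2 = np.asarray(child2, dtype=np.int64)
        nn = 2 * self.n - 1 if self.n > 1 else 1
        self.node_times = np.zeros(nn)
        self.parent = np.full(nn, -1, dtype=np.int64)
        self.n_descendants = np.ones(nn, dtype=np.int64)
        for e in range(len(self.event_times)):
            w = self.n + e
            self.node_times[w] = self.event_times[e]
            self.parent[self.child1[e]] = w
            self.parent[self.child2[e]] = w
            self.n_descendants[w] = (
                self.n_descendants[self.child1[e]] + self.n_descendants[self.child2[e]]
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_times)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        bl = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        bl[has_parent] = self.node_times[self.parent[has_parent]] - self.node_times[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.node_times[self.root]) if self.n > 1 else 0.0

    def leaf_sets(self) -> list[set[int]]:
        """Set of sampled leaves below each node."""
        sets: list[set[int]] = [{i} for i in range(self.n)]
        for e in range(len(self.event_times)):
            sets.append(sets[self.child1[e]] | sets[self.child2[e]])
        return sets


def _lattice_neighbors(grid: tuple[int, int], torus: bool) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = grid
    d = rows * cols
    nbr = np.zeros((d, 4), dtype=np.int64)
    cnt = np.zeros(d, dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if torus:
                    rr %= rows
                    cc %= cols
                elif not (0 <= rr < rows and 0 <= cc < cols):
                    continue
                j = rr * cols + cc
                if j == i:  # degenerate 1-wide torus
                    continue
                nbr[i, cnt[i]] = j
                cnt[i] += 1
    return nbr, cnt


_EMPTY_NBR = np.zeros((1, 4), dtype=np.int64)
_EMPTY_CNT = np.zeros(1, dtype=np.int64)


def _deme_index(model: DemographicModel, deme: tuple[int, int]) -> int:
    r, c = deme
    rows, cols = model.grid
    if not (0 <= r < rows and 0 <= c < cols):
        raise IndexError(f"deme {deme} outside {rows}x{cols} grid")
    return r * cols + c


def _check_spec(model: DemographicModel, spec: SampleSpec) -> None:
    if model.kind == "NS":
        if spec.deme != "panmictic":
            raise ConfigError("NS model takes a panmictic sample, not a deme")
    else:
        if spec.deme == "panmictic":
            raise ConfigError(f"{model.kind} model requires a sampled deme (row, col)")


def _engine_seed(rng) -> int:
    return int(np.random.default_rng(rng).integers(1, 2**31 - 1))


def _sim_events(model: DemographicModel, n: int, deme_idx: int, seed: int, naive: bool = False):
    if model.kind == "NS":
        return _engine.sim_genealogy_ns(n, model.N_mod, model.N_anc, model.T_c, seed)
    init = np.full(n, deme_idx, dtype=np.int64)
    island = model.kind == "FIM"
    if island:
        nbr, cnt = _EMPTY_NBR, _EMPTY_CNT
    else:
        nbr, cnt = _lattice_neighbors(model.grid, model.torus)
    return _engine.sim_genealogy_struct(
        init, model.n_demes, model.N, model.m, model.T_col, model.N_anc, nbr, cnt, island,
        seed, naive,
    )


def simulate_genealogy(
    model: DemographicModel,
    spec: SampleSpec,
    rng: int | np.random.Generator | None = None,
    n_haploid: int | None = None,
    naive: bool = False,
) -> Genealogy:
    """Simulate one genealogy of ``2 * spec.n_dip`` (or ``n_haploid``) lineages.

    ``naive=True`` routes structured models through the plain one-event-at-a-
    time kernel (slow; kept as an internal cross-validation oracle).
    """
    _check_spec(model, spec)
    n = n_haploid if n_haploid is not None else 2 * spec.n_dip
    if n < 1:
        raise SampleSizeError("need at least one lineage")
    if n == 1:
        return Genealogy(1, np.empty(0), np.empty(0, np.int64), np.empty(0, np.int64))
    deme_idx = 0 if model.kind == "NS" else _deme_index(model, spec.deme)
    t, a, b = _sim_events(model, n, deme_idx, _engine_seed(rng), naive)
    return Genealogy(n, t, a, b)


def drop_mutations(
    g: Genealogy,
    mu: float,
    locus_len: int = 100,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Infinite-sites mutations on a genealogy: one derived-allele count per site.

    Each branch receives Poisson(mu * locus_len * branch_length) mutations;
    a mutation on the branch above node v segregates at frequency
    ``n_descendants[v]``, always in 1..n-1.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    gen = np.random.default_rng(rng)
    bl = g.branch_lengths()
    nmut = gen.poisson(mu * locus_len * bl)
    return np.repeat(g.n_descendants, nmut)


def simulate_sfs(
    model: DemographicModel,
    spec: SampleSpec,
    n_loci: int = 1000,
    locus_len: int = 100,
    rng: int | np.random.Generator | None = None,
    n_haploid: int | None = None,
) -> FoldedSFS:
    """Simulate one dataset: independent genealogies per locus, aggregated
    into a folded SFS with ``L = n_loci * locus_len``."""
    _check_spec(model, spec)
    if n_loci < 1 or locus_len < 1:
        raise ConfigError("n_loci and locus_len must be >= 1")
    n = n_haploid if n_haploid is not None else 2 * spec.n_dip
    if n < 2:
        raise SampleSizeError("need at least two lineages for an SFS")
    seed = _engine_seed(rng)
    mu_len = model.mu * locus_len
    if model.kind == "NS":
        xi = _engine.sim_sfs_ns(n, model.N_mod, model.N_anc, model.T_c, mu_len, n_loci, seed)
    else:
        deme_idx = _deme_index(model, spec.deme)
        init = np.full(n, deme_idx, dtype=np.int64)
        island = model.kind == "FIM"
        nbr, cnt = (_EMPTY_NBR, _EMPTY_CNT) if island else _lattice_neighbors(model.grid, model.torus)
        xi = _engine.sim_sfs_struct(
            init, model.n_demes, model.N, model.m, model.T_col, model.N_anc,
            nbr, cnt, island, mu_len, n_loci, seed,
        )
    return FoldedSFS(n=n, eta=fold_sfs(xi, n), L=n_loci * locus_len)


def _two_deme_init(model, demeA, demeB, n_dip_each):
    if model.kind == "NS":
        raise ConfigError("two-deme sampling requires a structured (FIM/SST) model")
    ia, ib = _deme_index(model, demeA), _deme_index(model, demeB)
    if ia == ib:
        raise ConfigError("the two sampled demes must be distinct")
    nA = 2 * n_dip_each
    init = np.concatenate([np.full(nA, ia, np.int64), np.full(nA, ib, np.int64)])
    island = model.kind == "FIM"
    nbr, cnt = (_EMPTY_NBR, _EMPTY_CNT) if island else _lattice_neighbors(model.grid, model.torus)
    return init, nA, island, nbr, cnt


def simulate_two_deme_counts(
    model: DemographicModel,
    demeA: tuple[int, int],
    demeB: tuple[int, int],
    n_dip_each: int,
    n_loci: int = 50,
    locus_len: int = 100,
    rng: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-site derived-allele counts in two sampled demes (fast path).

    Returns ``(countsA, countsB, nA, nB)`` where the count arrays have one
    entry per segregating site of the joint sample. Sufficient for any
    allele-frequency statistic (e.g. Hudson F_ST) without materializing
    haplotype matrices.
    """
    init, nA, island, nbr, cnt = _two_deme_init(model, demeA, demeB, n_dip_each)
    aA, aB, nm = _engine.sim_two_pop_branch_counts(
        init, nA, model.n_demes, model.N, model.m, model.T_col, model.N_anc,
        nbr, cnt, island, model.mu * locus_len, n_loci, _engine_seed(rng),
    )
    return np.repeat(aA, nm), np.repeat(aB, nm), nA, nA


def simulate_two_deme_genotypes(
    model: DemographicModel,
    demeA: tuple[int, int],
    demeB: tuple[int, int],
    n_dip_each: int,
    n_loci: int = 50,
    locus_len: int = 100,
    rng: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Joint simulation of two sampled demes, returning one binary haplotype
    matrix per population over the union of segregating sites."""
    init, nA, island, nbr, cnt = _two_deme_init(model, demeA, demeB, n_dip_each)
    gen = np.random.default_rng(rng)
    n = len(init)
    cols: list[np.ndarray] = []
    for _ in range(n_loci):
        seed = int(gen.integers(1, 2**31 - 1))
        t, a, b = _engine.sim_genealogy_struct(
            init, model.n_demes, model.N, model.m, model.T_col, model.N_anc,
            nbr, cnt, island, seed, False,
        )
        g = Genealogy(n, t, a, b)
        bl = g.branch_lengths()
        nmut = gen.poisson(model.mu * locus_len * bl)
        if nmut.sum() == 0:
            continue
        leaf_sets = g.leaf_sets()
        for v in np.nonzero(nmut)[0]:
            col = np.zeros(n, dtype=np.int8)
            col[list(leaf_sets[v])] = 1
            cols.extend([col] * int(nmut[v]))
    H = np.stack(cols, axis=1) if cols else np.zeros((n, 0), dtype=np.int8)
    return H[:nA], H[nA:]
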