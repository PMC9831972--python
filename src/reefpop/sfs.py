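"""Folded site-frequency-spectrum statistics.

The folded SFS is the central exchange object of the pipeline: a histogram
``eta[j]`` of minor-allele counts ``j = 1..floor(n/2)`` over ``n`` sampled
haploid sequences, together with the total number of surveyed sites ``L``
(monomorphic sites included, so that per-site diversities are comparable
across datasets with different amounts of invariant sequence).

From the folded SFS alone this module computes the three classic diversity
statistics:

* ``theta_pi`` — mean pairwise nucleotide difference per site,
* ``theta_w`` — Watterson's estimator (segregating sites over the harmonic
  number), per site,
* ``tajimas_d`` — the normalized difference of the two, whose sign separates
  expansion-like (negative, excess rare variants) from structure- or
  bottleneck-like (positive) genealogies.

Significance of Tajima's D is assessed by parametric simulation of a
constant-size panmictic coalescent whose scaled mutation rate matches the
observed ``theta_pi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    DimensionError,
    SampleSizeError,
    UndefinedStatisticError,
)

__all__ = [
    "FoldedSFS",
    "DiversityStats",
    "fold_sfs",
    "sfs_from_haplotypes",
    "theta_pi",
    "theta_w",
    "tajimas_d",
    "td_significance",
    "diversity_stats",
    "tajima_constants",
]


@dataclass(frozen=True)
class FoldedSFS:
    """Folded site frequency spectrum.

    Parameters
    ----------
    n
        Haploid sample size (number of sequences), at least 2.
    eta
        Integer counts of sites with minor-allele count ``j``, indexed
        ``j = 1..floor(n/2)`` (so ``eta[0]`` is the singleton class).
    L
        Total number of surveyed sites, monomorphic included.
    """

    n: int
    eta: np.ndarray
    L: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise SampleSizeError(f"need n >= 2 haploid sequences, got {self.n}")
        eta = np.asarray(self.eta, dtype=np.int64)
        if eta.ndim != 1 or len(eta) != self.n // 2:
            raise DimensionError(
                f"eta must have length floor(n/2) = {self.n // 2}, got {eta.shape}"
            )
        if np.any(eta < 0):
            raise ValueError("eta entries must be non-negative")
        if self.L <= 0:
            raise ValueError(f"L must be a positive integer, got {self.L}")
        if eta.sum() > self.L:
            raise ValueError("sum(eta) exceeds total site count L")
        object.__setattr__(self, "eta", eta)

    @property
    def S(self) -> int:
        """Number of segregating sites."""
        return int(self.eta.sum())


@dataclass(frozen=True)
class DiversityStats:
    """Per-site diversity summary for one sampling site."""

    theta_pi: float
    theta_w: float
    tajimas_d: float
    p_value: float | None = field(default=None)

    def __post_init__(self) -> None:
        if self.theta_pi < 0 or self.theta_w < 0:
            raise ValueError("per-site diversities must be non-negative")
        if self.p_value is not None and not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must lie in (0, 1], got {self.p_value}")


def fold_sfs(xi, n: int) -> FoldedSFS | np.ndarray:
    """Fold an unfolded spectrum ``xi`` (derived counts 1..n-1) into minor-allele classes.

    ``eta_j = xi_j + xi_{n-j}`` for ``j < n/2``; the middle class
    ``j = n/2`` (even ``n``) is copied as-is. Returns the eta count vector.
    """
    xi = np.asarray(xi)
    if xi.ndim != 1 or len(xi) != n - 1:
        raise DimensionError(f"xi must have length n-1 = {n - 1}, got {xi.shape}")
    if np.any(xi < 0):
        raise ValueError("xi entries must be non-negative")
    half = n // 2
    eta = np.zeros(half, dtype=np.int64)
    for j in range(1, half + 1):
        if j < n - j:
            eta[j - 1] = xi[j - 1] + xi[n - j - 1]
        else:  # middle class of an even sample
            eta[j - 1] = xi[j - 1]
    return eta


def sfs_from_haplotypes(H, L: int | None = None) -> FoldedSFS:
    """Build a FoldedSFS from a binary haplotype x site matrix.

    Columns are sites (monomorphic columns allowed: they add nothing to eta
    but count toward ``L``). ``L`` defaults to the number of columns and may
    be larger to account for invariant sequence not present in the matrix.
    """
    H = np.asarray(H)
    if H.ndim != 2:
        raise DimensionError("H must be a 2-D haplotype x site matrix")
    n, m = H.shape
    if n < 2:
        raise SampleSizeError(f"need at least 2 haplotypes, got {n}")
    if not np.isin(H, (0, 1)).all():
        raise ValueError("H entries must be 0/1")
    if L is None:
        L = m
    if L < m:
        raise ValueError(f"L = {L} smaller than number of columns {m}")
    counts = H.sum(axis=0)
    minor = np.minimum(counts, n - counts)
    half = n // 2
    eta = np.bincount(minor[minor > 0], minlength=half + 1)[1 : half + 1]
    return FoldedSFS(n=n, eta=eta, L=L)


def _pi_total(sfs: FoldedSFS) -> float:
    """Total (not per-site) mean pairwise difference: sum_j j(n-j) eta_j / C(n,2)."""
    n = sfs.n
    j = np.arange(1, n // 2 + 1, dtype=np.float64)
    return float((j * (n - j) * sfs.eta).sum() / (n * (n - 1) / 2))


def theta_pi(sfs: FoldedSFS) -> float:
    """Per-site mean pairwise difference computed directly from the folded SFS.

    Because ``j (n-j)`` is symmetric under ``j -> n-j``, the folded spectrum
    carries exactly the information needed and the formula is exact.
    """
    if sfs.L == 0:
        raise ZeroDivisionError("L must be positive")
    return _pi_total(sfs) / sfs.L


def theta_w(sfs: FoldedSFS) -> float:
    """Per-site Watterson estimator: S / a_{n-1} / L."""
    a1 = sum(1.0 / i for i in range(1, sfs.n))
    return sfs.S / a1 / sfs.L


def tajima_constants(n: int) -> dict[str, float]:
    """The 1989 normalization constants a1, a2, b1, b2, c1, c2, e1, e2."""
    if n < 2:
        raise SampleSizeError("n must be >= 2")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(sfs: FoldedSFS) -> float:
    """Tajima's D from the folded SFS, using total (not per-site) pi and S."""
    S = sfs.S
    if S == 0:
        raise UndefinedStatisticError("Tajima's D is undefined with no segregating sites")
    c = tajima_constants(sfs.n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    if var <= 0:  # n < 4: the 1989 normalization degenerates
        raise UndefinedStatisticError(
            f"Tajima's D variance is zero for n = {sfs.n}; need n >= 4")
    return (_pi_total(sfs) - S / c["a1"]) / math.sqrt(var)


def _tajimas_d_from_xi(xi: np.ndarray, n: int) -> np.ndarray:
    """Vectorized Tajima's D over rows of unfolded count matrices.

    Rows with S == 0 yield NaN.
    """
    xi = np.atleast_2d(xi).astype(np.float64)
    i = np.arange(1, n)
    pi_tot = (xi * (i * (n - i))).sum(axis=1) / (n * (n - 1) / 2)
    S = xi.sum(axis=1)
    c = tajima_constants(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = c["e1"] * S + c["e2"] * S * (S - 1)
        d = (pi_tot - S / c["a1"]) / np.sqrt(var)
    d[S == 0] = np.nan
    return d


def td_significance(
    sfs: FoldedSFS,
    nsim: int = 1000,
    rng: int | np.random.Generator | None = None,
    n_loci: int = 1,
    locus_len: int | None = None,
) -> float:
    """Two-tailed simulation p-value for Tajima's D.

    Simulates ``nsim`` datasets under a constant-size panmictic coalescent
    with matched ``n`` and ``L``, mutation-parameterized so that the per-site
    scaled rate ``4*N*mu`` equals the observed ``theta_pi``. The null's locus
    structure should mirror the observed data (``n_loci`` independent
    non-recombining loci; default a single locus spanning L sites, the
    maximally conservative choice since fewer loci inflate the genealogical
    variance of the null). Monomorphic simulated datasets (TD undefined) are
    dropped; the two-tailed p uses the (1+x)/(1+m) correction over the m
    retained simulations, capped at 1.
    """
    from . import _engine

    if sfs.S == 0:
        raise UndefinedStatisticError("observed TD undefined: no segregating sites")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    gen = np.random.default_rng(rng)
    d_obs = tajimas_d(sfs)
    tp = theta_pi(sfs)
    if locus_len is None:
        locus_len = max(1, sfs.L // n_loci)
    # Arbitrary reference size; only 4*N*mu per site matters for the null.
    N = 1000.0
    mu_len = tp / (4.0 * N) * locus_len
    seed = int(gen.integers(1, 2**31 - 1))
    xi = _engine.sim_sfs_ns_batch(sfs.n, N, N, 1.0, mu_len, n_loci, nsim, seed)
    sims = _tajimas_d_from_xi(xi, sfs.n)
    sims = sims[~np.isnan(sims)]
    if sims.size == 0:
        raise DegenerateInputError("all simulated null datasets were monomorphic")
    m = len(sims)
    p_lo = (1 + int((sims <= d_obs).sum())) / (1 + m)
    p_hi = (1 + int((sims >= d_obs).sum())) / (1 + m)
    return min(1.0, 2.0 * min(p_lo, p_hi))


def diversity_stats(
    sfs: FoldedSFS,
    nsim: int | None = 1000,
    rng: int | np.random.Generator | None = None,
) -> DiversityStats:
    """Compute the per-site diversity summary; ``nsim=None`` skips the TD p-value."""
    tp = theta_pi(sfs)
    tw = theta_w(sfs)
    if sfs.S == 0:
        raise UndefinedStatisticError("no segregating sites: TD undefined")
    td = tajimas_d(sfs)
    p = td_significance(sfs, nsim=nsim, rng=rng) if nsim else None
    return DiversityStats(theta_pi=tp, theta_w=tw, tajimas_d=td, p_value=p)
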