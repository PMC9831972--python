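"""Population-structure statistics: Hudson F_ST, permutation tests, Mantel
correlation and isolation-by-distance fits.

F_ST follows Hudson's nucleotide form, ``1 - Hw/Hb``: Hw is the average of
the two within-population mean pairwise differences and Hb the mean pairwise
difference between populations, totalled over sites. Slightly negative
estimates are possible by sampling noise and are reported raw; they are
clamped to zero only inside the ``F_ST/(1-F_ST)`` linearization used for
isolation by distance.

Significance testing is permutational throughout, with the standard
``(1 + #extreme)/(1 + n_perm)`` correction: diploid individuals (haplotype
pairs) are shuffled between population labels for F_ST; rows/columns of the
second matrix are jointly permuted for the Mantel test (one-sided, positive
association, matching the directional isolation-by-distance hypothesis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DimensionError, SampleSizeError, UndefinedStatisticError

__all__ = [
    "FstResult",
    "MantelResult",
    "hudson_fst",
    "nei_fst",
    "fst_perm_test",
    "pairwise_fst_matrix",
    "mantel",
    "ibd_fit",
]


@dataclass(frozen=True)
class FstResult:
    fst: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")
        if self.fst > 1.0:
            raise ValueError("F_ST cannot exceed 1")


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValueError("correlation must lie in [-1, 1]")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("permutation p must lie in (0, 1]")


def _check_pair(HA: np.ndarray, HB: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    HA = np.asarray(HA)
    HB = np.asarray(HB)
    if HA.ndim != 2 or HB.ndim != 2 or HA.shape[1] != HB.shape[1]:
        raise DimensionError("haplotype matrices must share the same site columns")
    if HA.shape[0] < 2 or HB.shape[0] < 2:
        raise SampleSizeError("need >= 2 haplotypes per population")
    return HA, HB


def _pi_within(H: np.ndarray) -> float:
    """Mean pairwise difference within a haplotype matrix, totalled over sites."""
    n = H.shape[0]
    c = H.sum(axis=0)
    return float((c * (n - c)).sum() / (n * (n - 1) / 2))


def _pi_between(HA: np.ndarray, HB: np.ndarray) -> float:
    nA, nB = HA.shape[0], HB.shape[0]
    cA = HA.sum(axis=0)
    cB = HB.sum(axis=0)
    return float((cA * (nB - cB) + cB * (nA - cA)).sum() / (nA * nB))


def hudson_fst(HA: np.ndarray, HB: np.ndarray) -> float:
    """Hudson's nucleotide F_ST = 1 - Hw/Hb between two haplotype matrices."""
    HA, HB = _check_pair(HA, HB)
    hw = (_pi_within(HA) + _pi_within(HB)) / 2.0
    hb = _pi_between(HA, HB)
    if hb == 0:
        raise UndefinedStatisticError("no between-population diversity: F_ST undefined")
    return 1.0 - hw / hb


def hudson_fst_from_counts(cA, cB, nA: int, nB: int) -> float:
    """Hudson F_ST from per-site derived-allele counts (no matrices needed)."""
    cA = np.asarray(cA, dtype=float)
    cB = np.asarray(cB, dtype=float)
    piA = (cA * (nA - cA)).sum() / (nA * (nA - 1) / 2)
    piB = (cB * (nB - cB)).sum() / (nB * (nB - 1) / 2)
    hb = (cA * (nB - cB) + cB * (nA - cA)).sum() / (nA * nB)
    if hb == 0:
        raise UndefinedStatisticError("no between-population diversity: F_ST undefined")
    return float(1.0 - (piA + piB) / 2.0 / hb)


def nei_fst(HA: np.ndarray, HB: np.ndarray) -> float:
    """Nei-style G_ST: 1 - mean within-heterozygosity / total heterozygosity."""
    HA, HB = _check_pair(HA, HB)
    pA = HA.mean(axis=0)
    pB = HB.mean(axis=0)
    hs = pA * (1 - pA) + pB * (1 - pB)  # mean within-pop heterozygosity per site
    pT = (pA + pB) / 2.0
    ht = 2.0 * pT * (1 - pT)
    if ht.sum() == 0:
        raise UndefinedStatisticError("no diversity: G_ST undefined")
    return float(1.0 - hs.sum() / ht.sum())


def fst_perm_test(
    HA: np.ndarray,
    HB: np.ndarray,
    n_perm: int = 1000,
    rng: int | np.random.Generator | None = None,
    estimator=hudson_fst,
) -> FstResult:
    """One-sided permutation test of F_ST > 0, shuffling diploid individuals.

    Rows are haplotypes; consecutive row pairs (0,1), (2,3), ... are treated
    as one diploid individual and move together between labels.
    """
    HA, HB = _check_pair(HA, HB)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if HA.shape[0] % 2 or HB.shape[0] % 2:
        raise DimensionError("haplotype counts must be even (diploid pairs)")
    gen = np.random.default_rng(rng)
    obs = estimator(HA, HB)
    pooled = np.vstack([HA, HB])
    n_indA = HA.shape[0] // 2
    n_ind = pooled.shape[0] // 2
    count = 0
    for _ in range(n_perm):
        order = gen.permutation(n_ind)
        rows = np.column_stack([2 * order, 2 * order + 1]).ravel()
        P = pooled[rows]
        if estimator(P[: 2 * n_indA], P[2 * n_indA :]) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return FstResult(fst=obs, p_value=p, n_permutations=n_perm)


def pairwise_fst_matrix(populations: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Symmetric Hudson F_ST matrix over populations plus the overall F_ST.

    Overall F_ST pools the mean within-population diversity against the mean
    between-population diversity over all pairs.
    """
    k = len(populations)
    if k < 2:
        raise SampleSizeError("need >= 2 populations")
    F = np.zeros((k, k))
    hw = [_pi_within(np.asarray(H)) for H in populations]
    hbs = []
    for i in range(k):
        for j in range(i + 1, k):
            hb = _pi_between(populations[i], populations[j])
            hbs.append(hb)
            if hb == 0:
                raise UndefinedStatisticError(f"populations {i},{j} share no diversity")
            F[i, j] = F[j, i] = 1.0 - (hw[i] + hw[j]) / 2.0 / hb
    overall = 1.0 - float(np.mean(hw)) / float(np.mean(hbs))
    return F, overall


def _lower(M: np.ndarray) -> np.ndarray:
    iu = np.tril_indices(M.shape[0], k=-1)
    return M[iu]


def _check_square(M: np.ndarray) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DimensionError("distance matrix must be square")
    return M


def mantel(
    A: np.ndarray,
    B: np.ndarray,
    n_perm: int = 1000,
    rng: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the lower triangles; the null permutes
    rows and columns of B jointly; p is one-sided for positive association
    with the (1+x)/(1+n) correction.
    """
    A = _check_square(A)
    B = _check_square(B)
    if A.shape != B.shape:
        raise DimensionError("matrices must have the same shape")
    if A.shape[0] < 3:
        raise SampleSizeError("need >= 3 sites")
    a = _lower(A)
    b = _lower(B)
    if np.std(a) == 0 or np.std(b) == 0:
        raise DegenerateInputError("constant lower triangle: r undefined")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    gen = np.random.default_rng(rng)
    n = A.shape[0]
    count = 0
    for _ in range(n_perm):
        order = gen.permutation(n)
        bp = _lower(B[np.ix_(order, order)])
        if np.corrcoef(a, bp)[0, 1] >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return MantelResult(r=r_obs, p_value=p, n_permutations=n_perm)


def ibd_fit(fst_matrix: np.ndarray, dist_matrix: np.ndarray) -> tuple[float, float, float]:
    """OLS of linearized F_ST/(1-F_ST) on distance over the lower triangle.

    Negative F_ST entries are clamped to zero before linearization. Returns
    (slope, intercept, Pearson r).
    """
    F = _check_square(fst_matrix)
    D = _check_square(dist_matrix)
    if F.shape != D.shape:
        raise DimensionError("matrices must match")
    y_f = np.clip(_lower(F), 0.0, None)
    if np.any(y_f >= 1.0):
        raise ValueError("F_ST >= 1 cannot be linearized")
    y = y_f / (1.0 - y_f)
    x = _lower(D)
    if len(x) < 3:
        raise SampleSizeError("need >= 3 pairs")
    if np.std(x) == 0:
        raise DegenerateInputError("constant distances: IBD fit undefined")
    slope, intercept = np.polyfit(x, y, 1)
    r = float(np.corrcoef(x, y)[0, 1]) if np.std(y) > 0 else 0.0
    return float(slope), float(intercept), r
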