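"""Readers and writers for the plain-text exchange formats.

Formats
-------
* Folded SFS dialect: line 1 ``n=<haploid size> L=<total sites>``, line 2 the
  whitespace-separated counts ``eta_1 .. eta_floor(n/2)``. Round-trips
  bit-exactly.
* 012 genotype TSV: rows are diploid individuals, columns are sites, header
  row carries site ids, first column the individual id. Cells in {0,1,2}
  count the non-reference alleles; any other value marks a missing call.
* Minimal VCF: biallelic SNPs, GT field only (cyvcf2-backed).
* Square distance-matrix TSV with matching header row/column of site ids;
  ``inf`` cells allowed.
* Site table TSV: columns ``id, row, col, theta_pi, n``.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .errors import DimensionError
from .sfs import FoldedSFS

__all__ = [
    "read_sfs",
    "write_sfs",
    "read_012",
    "write_012",
    "read_vcf_genotypes",
    "genotypes_to_haplotypes",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_site_table",
    "write_site_table",
]


def write_sfs(sfs: FoldedSFS, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(f"n={sfs.n} L={sfs.L}\n")
        fh.write(" ".join(str(int(x)) for x in sfs.eta) + "\n")


def read_sfs(path: str | os.PathLike) -> FoldedSFS:
    with open(path) as fh:
        header = fh.readline().split()
        fields = dict(kv.split("=") for kv in header)
        eta = np.array([int(x) for x in fh.readline().split()], dtype=np.int64)
    return FoldedSFS(n=int(fields["n"]), eta=eta, L=int(fields["L"]))


def write_012(G: np.ndarray, path: str | os.PathLike, site_ids=None, indiv_ids=None) -> None:
    G = np.asarray(G)
    n, m = G.shape
    site_ids = site_ids if site_ids is not None else [f"s{j}" for j in range(m)]
    indiv_ids = indiv_ids if indiv_ids is not None else [f"i{i}" for i in range(n)]
    df = pd.DataFrame(G, index=indiv_ids, columns=site_ids)
    df.to_csv(path, sep="\t", index_label="id")


def read_012(path: str | os.PathLike, drop_missing: bool = True) -> pd.DataFrame:
    """Read a 012 matrix; by default drop any site with a missing call."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    valid = df.isin((0, 1, 2)).all(axis=0)
    if drop_missing:
        df = df.loc[:, valid]
    return df


def read_vcf_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Diploid 012 genotype matrix from a VCF (biallelic SNPs, GT only).

    Sites with any missing genotype or more than two alleles are dropped,
    matching the pipeline's no-imputation policy.
    """
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path), gts012=True)
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for var in vcf:
        if not var.is_snp or len(var.ALT) != 1:
            continue
        g = var.gt_types  # 0/1/2, 3 = missing under gts012
        if (g == 3).any():
            continue
        cols[f"{var.CHROM}:{var.POS}"] = g.astype(np.int8).copy()
    vcf.close()
    return pd.DataFrame(cols, index=samples)


def genotypes_to_haplotypes(G: np.ndarray, rng=None) -> np.ndarray:
    """Expand diploid 012 genotypes to a 2n x sites pseudo-haplotype matrix.

    Homozygotes split deterministically; heterozygous sites place the single
    alternate allele on a random one of the two haplotypes (phase unknown).
    """
    G = np.asarray(G)
    gen = np.random.default_rng(rng)
    n, m = G.shape
    H = np.zeros((2 * n, m), dtype=np.int8)
    H[0::2] = (G >= 1).astype(np.int8)
    H[1::2] = (G == 2).astype(np.int8)
    het = G == 1
    flip = gen.random((n, m)) < 0.5
    swap = het & flip
    a = H[0::2].copy()
    H[0::2][swap] = H[1::2][swap]
    H[1::2][swap] = a[swap]
    return H


def write_distance_matrix(D: np.ndarray, ids, path: str | os.PathLike) -> None:
    pd.DataFrame(np.asarray(D, dtype=float), index=ids, columns=ids).to_csv(
        path, sep="\t", index_label="id"
    )


def read_distance_matrix(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.columns = df.columns.astype(str)
    df.index = df.index.astype(str)
    if df.shape[0] != df.shape[1] or list(df.index) != list(df.columns):
        raise DimensionError("distance matrix must be square with matching ids")
    return df


def write_site_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["id", "row", "col", "theta_pi", "n"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DimensionError(f"site table missing columns {missing}")
    df[cols].to_csv(path, sep="\t", index=False)


def read_site_table(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["id"] = df["id"].astype(str)
    if df["id"].duplicated().any():
        raise ValueError("site ids must be unique")
    return df
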