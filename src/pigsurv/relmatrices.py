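"""Relationship matrices for single-step genomic evaluation.

Implements the pedigree numerator relationship matrix A (tabular method,
inbreeding included) and its sparse inverse (Henderson's rules), the
VanRaden genomic relationship matrix G, the rescaled G* whose average
diagonal and off-diagonal match the pedigree block A11, the blend
G_omega = (1-omega) G* + omega A11, and the single-step H matrix for an
arbitrary genotyped subset — both the dense block form and the sparse
inverse H^-1 = A^-1 + [[G_omega^-1 - A11^-1, 0], [0, 0]] used in the
mixed-model equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "RelationshipMatrix",
    "build_A",
    "build_A_inverse",
    "build_G",
    "adjust_G",
    "blend_G",
    "build_H",
    "build_H_inverse",
]


@dataclass
class RelationshipMatrix:
    """Symmetric relationship matrix with an ordered ID index."""

    values: np.ndarray
    ids: np.ndarray
    kind: str  # one of {"A", "A11", "G", "G*", "Gw", "H"}

    def loc(self, ids: np.ndarray) -> np.ndarray:
        """Sub-matrix for ``ids`` (in the given order)."""
        pos = pd.Index(self.ids).get_indexer(ids)
        if (pos < 0).any():
            raise KeyError("requested ids not in matrix index")
        return self.values[np.ix_(pos, pos)]


def _parent_rows(pedigree: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of sire and dam (-1 for unknown); validates ordering."""
    ids = pedigree["id"].to_numpy()
    idx = pd.Index(ids)
    sire = idx.get_indexer(pedigree["sire"].to_numpy())
    dam = idx.get_indexer(pedigree["dam"].to_numpy())
    known_s = pedigree["sire"].to_numpy() != 0
    known_d = pedigree["dam"].to_numpy() != 0
    if (known_s & (sire < 0)).any() or (known_d & (dam < 0)).any():
        raise ValueError("pedigree references a parent that is not listed")
    rows = np.arange(len(pedigree))
    if (sire >= rows).any() or (dam >= rows).any():
        raise ValueError("pedigree must list parents before their offspring")
    sire[~known_s] = -1
    dam[~known_d] = -1
    return sire, dam


def build_A(pedigree: pd.DataFrame) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    The pedigree must be sorted so parents precede offspring.  The diagonal
    is 1 + F with F the inbreeding coefficient.
    """
    sire, dam = _parent_rows(pedigree)
    n = len(pedigree)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, :i] = 0.5 * (A[s, :i] + A[d, :i])
            A[i, i] = 1.0 + 0.5 * A[s, d]
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(A, pedigree["id"].to_numpy(), "A")


def build_A_inverse(
    pedigree: pd.DataFrame, inbreeding: np.ndarray | None = None
) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules, accounting for inbreeding.

    ``inbreeding`` is the vector of F coefficients in pedigree order; when
    omitted it is computed from the tabular A (fine at desk scale).
    """
    sire, dam = _parent_rows(pedigree)
    n = len(pedigree)
    if inbreeding is None:
        inbreeding = np.diag(build_A(pedigree).values) - 1.0
    F = np.concatenate([inbreeding, [0.0]])  # F[-1] = 0 for unknown parents
    both = (sire >= 0) & (dam >= 0)
    one = (sire >= 0) ^ (dam >= 0)
    d = np.ones(n)
    d[both] = 0.5 - 0.25 * (F[sire[both]] + F[dam[both]])
    p_one = np.where(sire >= 0, sire, dam)
    d[one] = 0.75 - 0.25 * F[p_one[one]]
    b = 1.0 / d
    rows, cols, vals = [], [], []

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        add(i, i, b[i])
        for p in (sire[i], dam[i]):
            if p >= 0:
                add(i, p, -0.5 * b[i])
                add(p, i, -0.5 * b[i])
                add(p, p, 0.25 * b[i])
        if sire[i] >= 0 and dam[i] >= 0:
            add(sire[i], dam[i], 0.25 * b[i])
            add(dam[i], sire[i], 0.25 * b[i])
    return sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def build_G(
    dosages: np.ndarray,
    ids: np.ndarray,
    allele_freqs: np.ndarray | None = None,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    G = Z Z' / (2 sum_j p_j (1 - p_j)) with Z the dosage matrix centred at
    twice the allele frequency.  Frequencies default to those observed in
    the genotyped set itself; monomorphic markers are dropped.
    """
    dosages = np.asarray(dosages, dtype=float)
    if dosages.shape[0] < 2:
        raise ValueError("need at least 2 genotyped individuals")
    if allele_freqs is None:
        allele_freqs = dosages.mean(axis=0) / 2.0
    allele_freqs = np.asarray(allele_freqs, dtype=float)
    poly = (allele_freqs > 0.0) & (allele_freqs < 1.0)
    if not poly.any():
        raise ValueError("all markers are monomorphic; G undefined")
    p = allele_freqs[poly]
    Z = dosages[:, poly] - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    G = (Z @ Z.T) / denom
    return RelationshipMatrix(G, np.asarray(ids), "G")


def _avg_diag_offdiag(M: np.ndarray) -> tuple[float, float]:
    n = M.shape[0]
    dmean = float(np.trace(M) / n)
    omean = float((M.sum() - np.trace(M)) / (n * (n - 1)))
    return dmean, omean


def adjust_G(G: RelationshipMatrix, A11: np.ndarray) -> RelationshipMatrix:
    """Rescale G to G* = beta G + alpha so that its average diagonal and
    average off-diagonal equal those of the pedigree block A11."""
    gd, go = _avg_diag_offdiag(G.values)
    ad, ao = _avg_diag_offdiag(A11)
    if abs(gd - go) < 1e-12:
        raise ValueError("Avg.diag(G) equals Avg.offdiag(G); system singular")
    beta, alpha = np.linalg.solve([[gd, 1.0], [go, 1.0]], [ad, ao])
    return RelationshipMatrix(beta * G.values + alpha, G.ids, "G*")


def blend_G(
    Gstar: RelationshipMatrix, A11: np.ndarray, omega: float = 0.2
) -> RelationshipMatrix:
    """G_omega = (1 - omega) G* + omega A11; omega > 0 guarantees PD."""
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega must be in [0,1]")
    return RelationshipMatrix(
        (1.0 - omega) * Gstar.values + omega * A11, Gstar.ids, "Gw"
    )


def build_H(
    A: RelationshipMatrix, Gw: RelationshipMatrix
) -> RelationshipMatrix:
    """Dense single-step H by the block formula (testing oracle).

    With genotyped block 1 and non-genotyped block 2 of A:

        H11 = Gw
        H12 = Gw A11^-1 A12
        H22 = A21 A11^-1 Gw A11^-1 A12 + A22 - A21 A11^-1 A12

    The result is indexed in A's original ID order.
    """
    idx = pd.Index(A.ids)
    g_pos = idx.get_indexer(Gw.ids)
    if (g_pos < 0).any():
        raise KeyError("genotyped ids missing from A")
    n_pos = np.setdiff1d(np.arange(len(A.ids)), g_pos)
    A11 = A.values[np.ix_(g_pos, g_pos)]
    A12 = A.values[np.ix_(g_pos, n_pos)]
    A22 = A.values[np.ix_(n_pos, n_pos)]
    A11inv_A12 = np.linalg.solve(A11, A12)
    H = np.empty_like(A.values)
    H11 = Gw.values
    H12 = Gw.values @ A11inv_A12
    H22 = A11inv_A12.T @ Gw.values @ A11inv_A12 + A22 - A12.T @ A11inv_A12
    H[np.ix_(g_pos, g_pos)] = H11
    H[np.ix_(g_pos, n_pos)] = H12
    H[np.ix_(n_pos, g_pos)] = H12.T
    H[np.ix_(n_pos, n_pos)] = H22
    return RelationshipMatrix(H, A.ids, "H")


def build_H_inverse(
    A_inv: sp.spmatrix,
    ids: np.ndarray,
    Gw: RelationshipMatrix,
    A11: np.ndarray,
    jitter: float = 1e-8,
) -> sp.csr_matrix:
    """Sparse H^-1 = A^-1 + [[Gw^-1 - A11^-1, 0],[0, 0]] on the genotyped block.

    ``A11`` must be A restricted to ``Gw.ids`` in the same order.  If Gw is
    numerically singular, ``jitter`` is added to its diagonal once.
    """
    idx = pd.Index(np.asarray(ids))
    g_pos = idx.get_indexer(Gw.ids)
    if (g_pos < 0).any():
        raise KeyError("genotyped ids missing from pedigree index")
    try:
        Gw_inv = np.linalg.inv(Gw.values)
    except np.linalg.LinAlgError:
        Gw_inv = np.linalg.inv(Gw.values + jitter * np.eye(len(Gw.ids)))
    corr = Gw_inv - np.linalg.inv(A11)
    ii, jj = np.meshgrid(g_pos, g_pos, indexing="ij")
    corr_sp = sp.coo_matrix(
        (corr.ravel(), (ii.ravel(), jj.ravel())), shape=A_inv.shape
    )
    return (A_inv + corr_sp).tocsr()
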