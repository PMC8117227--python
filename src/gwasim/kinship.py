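"""Relationship matrices for pedigree, genomic and single-step models.

Covers the numerator relationship matrix A (tabular method, plus a sparse
Henderson inverse with Meuwissen-Luo inbreeding for large pedigrees), the two
genomic relationship matrices used in practice (VanRaden's first method with
2p centering, and the marker-sample-mean / k construction used by EMMAX-style
software), the blending G = lambda*G0 + beta*I against singularity, the base
tuning of G to A22, the genetic-base scalar delta, and the single-step
combined inverse H^-1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not a or callable(a[0]) is False else wrap(a[0])

__all__ = [
    "KinshipSet",
    "build_A",
    "inbreeding",
    "build_A_inverse",
    "subset_A22",
    "A22_from_pedigree",
    "relationship_block",
    "build_G_vanraden",
    "build_G_gemma",
    "blend_G",
    "tune_G_to_A22",
    "build_Hinv",
    "compute_delta",
]

LAMBDA_BLEND = 0.95
BETA_BLEND = 0.05


@dataclass
class KinshipSet:
    """All relationship matrices one scenario needs, with their scalars."""

    A: np.ndarray | None = None
    A22: np.ndarray | None = None
    G0: np.ndarray | None = None
    G: np.ndarray | None = None
    Hinv: object = None  # dense ndarray or scipy sparse
    lambda_blend: float = LAMBDA_BLEND
    beta_blend: float = BETA_BLEND
    delta: float = 1.0
    n: int = 0


# ---------------------------------------------------------------------------
# pedigree relationships
# ---------------------------------------------------------------------------


def _parents(pedigree):
    s = np.asarray(pedigree.sire, dtype=np.int64)
    d = np.asarray(pedigree.dam, dtype=np.int64)
    idx = np.arange(s.size)
    if np.any(s[s >= 0] >= idx[s >= 0]) or np.any(d[d >= 0] >= idx[d >= 0]):
        raise ValueError("pedigree must be topologically ordered (parents first)")
    return s, d


def build_A(pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular (recursive) method.

    Row i is 0.5*(row(sire) + row(dam)); the diagonal is 1 + F where F is half
    the parents' relationship.  O(n^2) memory -- meant for desk-scale
    pedigrees; use :func:`build_A_inverse` / :func:`A22_from_pedigree` beyond.
    """
    s, d = _parents(pedigree)
    n = s.size
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        row = A[i, :i]
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[si, di] if (si >= 0 and di >= 0) else 0.0)
    return A


@njit(cache=True)
def _inbreeding_rec(sire, dam):  # pragma: no cover - exercised via inbreeding()
    """Inbreeding from the ancestor decomposition 1 + F_i = sum_j L_ij^2 D_j.

    L_ij is the expected genome fraction animal i derives from ancestor j and
    D_j the Mendelian-sampling variance scalar (Meuwissen & Luo 1992 recursion
    in its simple backward-sweep form).
    """
    n = sire.size
    F = np.zeros(n)
    D = np.zeros(n)
    L = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            F[i] = 0.0
            continue
        for k in range(i + 1):
            L[k] = 0.0
        L[i] = 1.0
        acc = 0.0
        for k in range(i, -1, -1):
            lk = L[k]
            if lk != 0.0:
                acc += lk * lk * D[k]
                if sire[k] >= 0:
                    L[sire[k]] += 0.5 * lk
                if dam[k] >= 0:
                    L[dam[k]] += 0.5 * lk
        F[i] = acc - 1.0
    return F


def inbreeding(pedigree) -> np.ndarray:
    """Per-animal inbreeding coefficients F (diagonal of A minus one)."""
    s, d = _parents(pedigree)
    return _inbreeding_rec(s, d)


def build_A_inverse(pedigree, F: np.ndarray | None = None) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding accounted for."""
    s, d = _parents(pedigree)
    n = s.size
    if F is None:
        F = inbreeding(pedigree)
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    dii = np.where(
        both, 0.5 - 0.25 * (Fs + Fd), np.where(one, 0.75 - 0.25 * (Fs + Fd), 1.0)
    )
    w = 1.0 / dii
    rows, cols, vals = [], [], []
    i = np.arange(n)
    rows.append(i); cols.append(i); vals.append(w)
    for p in (s, d):
        k = p >= 0
        rows.append(i[k]); cols.append(p[k]); vals.append(-0.5 * w[k])
        rows.append(p[k]); cols.append(i[k]); vals.append(-0.5 * w[k])
        rows.append(p[k]); cols.append(p[k]); vals.append(0.25 * w[k])
    k = both
    rows.append(s[k]); cols.append(d[k]); vals.append(0.25 * w[k])
    rows.append(d[k]); cols.append(s[k]); vals.append(0.25 * w[k])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return Ainv.tocsr()


def _chol_factors(pedigree, F: np.ndarray | None = None):
    """Sparse Cholesky structure of A: A = T^-1 D T^-T with T = I - P.

    P holds 0.5 at the parent positions, so T is unit lower triangular; D is
    the Mendelian-sampling variance diagonal.  Lets any block of A be read
    off with two triangular solves instead of an LU factorization.
    """
    s, d = _parents(pedigree)
    n = s.size
    if F is None:
        F = inbreeding(pedigree)
    i = np.arange(n)
    rows, cols, vals = [i], [i], [np.ones(n)]
    for p in (s, d):
        k = p >= 0
        rows.append(i[k]); cols.append(p[k]); vals.append(np.full(int(k.sum()), -0.5))
    T = sp.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    Fs = np.where(s >= 0, F[np.maximum(s, 0)], 0.0)
    Fd = np.where(d >= 0, F[np.maximum(d, 0)], 0.0)
    both = (s >= 0) & (d >= 0)
    one = (s >= 0) ^ (d >= 0)
    D = np.where(both, 0.5 - 0.25 * (Fs + Fd),
                 np.where(one, 0.75 - 0.25 * (Fs + Fd), 1.0))
    return T, D


def _A_columns(pedigree, idx: np.ndarray) -> np.ndarray:
    """Columns of A for the given animals, via the triangular factors."""
    T, D = _chol_factors(pedigree)
    n = T.shape[0]
    E = np.zeros((n, idx.size))
    E[idx, np.arange(idx.size)] = 1.0
    W = spla.spsolve_triangular(T.T.tocsr(), E, lower=False)
    return spla.spsolve_triangular(T, D[:, None] * W, lower=True)


def subset_A22(A: np.ndarray, genotyped_index) -> np.ndarray:
    """Principal submatrix of A for the genotyped animals."""
    idx = np.asarray(genotyped_index)
    if idx.size == 0:
        raise ValueError("empty genotyped index")
    if idx.min() < 0 or idx.max() >= A.shape[0]:
        raise ValueError("genotyped index out of bounds")
    return A[np.ix_(idx, idx)]


def A22_from_pedigree(pedigree, genotyped_index) -> np.ndarray:
    """A22 without forming dense A: solve sparse A^-1 X = E on the index."""
    idx = np.asarray(genotyped_index)
    if idx.size == 0:
        raise ValueError("empty genotyped index")
    n = len(pedigree.sire)
    if n <= 3000:
        return subset_A22(build_A(pedigree), idx)
    A22 = _A_columns(pedigree, idx)[idx]
    return 0.5 * (A22 + A22.T)


def relationship_block(pedigree, rows, cols) -> np.ndarray:
    """A[rows, cols] rectangular block via sparse solves (mate allocation)."""
    rows = np.asarray(rows)
    cols = np.asarray(cols)
    n = len(pedigree.sire)
    if n <= 3000:
        A = build_A(pedigree)
        return A[np.ix_(rows, cols)]
    return _A_columns(pedigree, rows)[cols].T


# ---------------------------------------------------------------------------
# genomic relationships
# ---------------------------------------------------------------------------


def build_G_vanraden(dosages: np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden's first G: MM'/(2 sum p(1-p)), M centered by 2p.

    Frequencies default to the current sample of genotyped animals."""
    X = np.asarray(dosages, dtype=np.float64)
    p = X.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, float)
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all SNPs monomorphic: VanRaden denominator is zero")
    M = X - 2.0 * p
    return (M @ M.T) / denom


def build_G_gemma(dosages: np.ndarray) -> np.ndarray:
    """Centered marker covariance G = (1/k) sum_i (x_i - xbar_i)(x_i - xbar_i)'."""
    X = np.asarray(dosages, dtype=np.float64)
    k = X.shape[1]
    if k == 0:
        raise ValueError("no SNPs")
    M = X - X.mean(axis=0)
    return (M @ M.T) / k


def blend_G(G0: np.ndarray, lam: float = LAMBDA_BLEND, beta: float = BETA_BLEND) -> np.ndarray:
    """G = lambda*G0 + beta*I; the identity bump keeps G invertible."""
    G = lam * np.asarray(G0, dtype=np.float64).copy()
    G[np.diag_indices_from(G)] += beta
    return G


def tune_G_to_A22(G: np.ndarray, A22: np.ndarray):
    """Rescale G so its mean diagonal and mean off-diagonal match A22's.

    Solves a + b*mean_diag(G) = mean_diag(A22) and the off-diagonal analogue;
    returns (a*J + b*G, a, b).  This aligns the genetic base of G (centered at
    current allele frequencies) with the pedigree base.
    """
    G = np.asarray(G, float)
    A22 = np.asarray(A22, float)
    if G.shape != A22.shape:
        raise ValueError("G and A22 dimensions differ")
    n = G.shape[0]
    dg, da = np.mean(np.diag(G)), np.mean(np.diag(A22))
    if n > 1:
        og = (G.sum() - np.trace(G)) / (n * (n - 1))
        oa = (A22.sum() - np.trace(A22)) / (n * (n - 1))
    else:
        og, oa = 0.0, 0.0
    if np.isclose(dg, og):
        raise ValueError("degenerate tuning system: mean diag equals mean off-diag of G")
    b = (da - oa) / (dg - og)
    a = da - b * dg
    return a + b * G, a, b


def compute_delta(A22: np.ndarray, G: np.ndarray) -> float:
    """Genetic-base adjustment delta = 1 - (0.5/n^2) (sum A22 - sum G)."""
    A22 = np.asarray(A22, float)
    G = np.asarray(G, float)
    if A22.shape != G.shape:
        raise ValueError("A22 and G dimensions differ")
    n = A22.shape[0]
    return 1.0 - 0.5 / n**2 * (A22.sum() - G.sum())


def build_Hinv(Ainv, A22inv: np.ndarray, Ginv: np.ndarray, genotyped_index):
    """Single-step H^-1 = A^-1 + scatter(G^-1 - A22^-1) on the genotyped block.

    ``Ainv`` may be dense or scipy-sparse; the result matches its format.
    """
    idx = np.asarray(genotyped_index)
    corr = np.asarray(Ginv) - np.asarray(A22inv)
    if idx.size and corr.shape != (idx.size, idx.size):
        raise ValueError("G^-1 / A22^-1 dimensions inconsistent with genotyped index")
    if sp.issparse(Ainv):
        if idx.size == 0:
            return Ainv.copy()
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        C = sp.coo_matrix((corr.ravel(), (ii.ravel(), jj.ravel())), shape=Ainv.shape)
        return (Ainv + C.tocsr()).tocsr()
    H = np.array(Ainv, dtype=float, copy=True)
    if idx.size:
        H[np.ix_(idx, idx)] += corr
    return H
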