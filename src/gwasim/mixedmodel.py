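"""Animal-model machinery: mixed-model equations, REML, EBV and reliabilities.

The single-trait animal model is y = X b + Z a + e with a ~ N(0, K sigma2_a)
and e ~ N(0, I sigma2_e), where K is a relationship matrix (A, G or H).
Henderson's mixed-model equations

    [ X'X      X'Z            ] [ b ]   [ X'y ]
    [ Z'X  Z'Z + K^-1 (se/sa) ] [ a ] = [ Z'y ]

yield BLUE/BLUP solutions; the animal block of the inverse coefficient matrix
times sigma2_e is the prediction-error (co)variance of a-hat, which feeds the
SNP-effect variances of the association layer and the EBV reliabilities of the
deregression step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import kinship

__all__ = [
    "VarianceComponents",
    "MMESolution",
    "solve_mme",
    "reml_estimate",
    "reliability",
    "parent_average",
    "pedigree_blup",
    "records_design",
]


@dataclass(frozen=True)
class VarianceComponents:
    """Additive and residual variances with their provenance."""

    sigma2_a: float
    sigma2_e: float
    source: str = "true-simulation"  # or "REML"

    def __post_init__(self):
        if self.sigma2_a <= 0 or self.sigma2_e <= 0:
            raise ValueError("variance components must be strictly positive")

    @property
    def ratio(self) -> float:
        """Shrinkage ratio sigma2_e / sigma2_a entering the MME."""
        return self.sigma2_e / self.sigma2_a

    @property
    def heritability(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class MMESolution:
    """Solutions of one mixed-model-equation system."""

    fixed: np.ndarray
    a: np.ndarray
    vc: VarianceComponents
    c22: np.ndarray | None = None  # raw inverse-coefficient block (animal part)
    c22_index: np.ndarray | None = None
    pev: np.ndarray | None = field(default=None, repr=False)

    @property
    def mu(self) -> float:
        return float(self.fixed[0])


def records_design(record_animal: np.ndarray, n_animals: int) -> sp.csr_matrix:
    """Incidence matrix Z mapping records to animal effects."""
    r = np.asarray(record_animal)
    return sp.csr_matrix(
        (np.ones(r.size), (np.arange(r.size), r)), shape=(r.size, n_animals)
    )


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Z,
    Kinv,
    vc: VarianceComponents,
    c22_index=None,
    full_c22: bool = False,
) -> MMESolution:
    """Assemble and solve Henderson's MME.

    ``Kinv`` is the inverse relationship matrix (A^-1, G^-1 or H^-1), dense or
    sparse; the sparse path factorizes once and extracts requested C22 columns
    by unit-vector solves, so prediction-error variances for a subset of
    animals (e.g. only genotyped sires) stay cheap on large pedigrees.
    """
    y = np.asarray(y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    q = Kinv.shape[0]
    sparse_path = sp.issparse(Kinv) or sp.issparse(Z)
    Zs = sp.csr_matrix(Z) if not sp.issparse(Z) else Z.tocsr()
    if Zs.shape != (n, q):
        raise ValueError("Z dimensions inconsistent with y and Kinv")

    if full_c22 and c22_index is None:
        c22_index = np.arange(q)
    lam = vc.ratio
    XtX = X.T @ X
    XtZ = Zs.T.dot(X).T  # p x q
    ZtZ = Zs.T @ Zs
    rhs = np.concatenate([X.T @ y, Zs.T @ y])

    if sparse_path:
        K = Kinv.tocsr() if sp.issparse(Kinv) else sp.csr_matrix(Kinv)
        C = sp.bmat(
            [[sp.csr_matrix(XtX), sp.csr_matrix(XtZ)],
             [sp.csr_matrix(XtZ.T), ZtZ + lam * K]],
            format="csc",
        )
        c22 = idx = pev = None
        if c22_index is None:
            # solutions only: the SPD system yields to Jacobi-preconditioned CG
            # far faster than a sparse LU of the pedigree-ordered matrix
            M = sp.diags(1.0 / np.maximum(C.diagonal(), 1e-300))
            sol, info = spla.cg(C.tocsr(), rhs, rtol=1e-12, atol=0.0,
                                M=M, maxiter=20 * C.shape[0])
            if info != 0:
                raise np.linalg.LinAlgError(
                    f"MME conjugate-gradient solve failed (info={info})"
                )
        else:
            try:
                lu = spla.splu(C, permc_spec="MMD_AT_PLUS_A")
            except RuntimeError as err:  # singular
                raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {err}")
            sol = lu.solve(rhs)
            idx = np.asarray(c22_index)
            E = np.zeros((p + q, idx.size))
            E[p + idx, np.arange(idx.size)] = 1.0
            cols = lu.solve(E)
            c22 = cols[p + idx]
            c22 = 0.5 * (c22 + c22.T)
            pev = np.diag(c22) * vc.sigma2_e
        return MMESolution(sol[:p], sol[p:], vc, c22, idx, pev)

    C = np.empty((p + q, p + q))
    C[:p, :p] = XtX
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    C[p:, p:] = ZtZ.toarray() + lam * np.asarray(Kinv)
    try:
        lu_piv = la.lu_factor(C)
    except la.LinAlgError as err:
        raise np.linalg.LinAlgError(f"singular MME coefficient matrix: {err}")
    if not np.all(np.isfinite(np.diag(lu_piv[0]))) or np.any(
        np.abs(np.diag(lu_piv[0])) < 1e-12
    ):
        raise np.linalg.LinAlgError("singular MME coefficient matrix")
    sol = la.lu_solve(lu_piv, rhs)
    c22 = idx = pev = None
    if full_c22 or c22_index is not None:
        idx = np.arange(q) if full_c22 else np.asarray(c22_index)
        E = np.zeros((p + q, idx.size))
        E[p + idx, np.arange(idx.size)] = 1.0
        cols = la.lu_solve(lu_piv, E)
        c22 = cols[p + idx]
        c22 = 0.5 * (c22 + c22.T)
        pev = np.diag(c22) * vc.sigma2_e
    return MMESolution(sol[:p], sol[p:], vc, c22, idx, pev)


# ---------------------------------------------------------------------------
# REML
# ---------------------------------------------------------------------------


def reml_estimate(
    y: np.ndarray,
    X: np.ndarray | None = None,
    K: np.ndarray | None = None,
    Z=None,
    Kinv=None,
    bounds=(1e-6, 1e6),
) -> VarianceComponents:
    """Exact REML for one genetic random effect by spectral profiling.

    ``K`` is the genetic covariance structure among the *records*
    (Z K_animals Z'); alternatively pass ``Z`` and ``Kinv`` and it is formed
    explicitly (dense -- desk scale only).  The restricted likelihood is
    profiled on the variance ratio gamma = sigma2_a/sigma2_e using the
    eigendecomposition of the projected kinship, then maximized by a grid
    bracket plus bounded scalar refinement; with a single decomposition this
    is exact and cannot fail to converge.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 records for REML")
    if X is None:
        X = np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != n:
        X = X.T
    p = X.shape[1]
    if K is None:
        if Z is None or Kinv is None:
            raise ValueError("supply K, or Z and Kinv")
        Kd = np.linalg.inv(Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv))
        Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
        K = Zd @ Kd @ Zd.T
    K = np.asarray(K, float)

    # project out fixed effects, keep the n-p informative contrasts
    Q, _ = np.linalg.qr(X, mode="complete")
    T = Q[:, p:]  # n x (n-p), T'X = 0
    S = T.T @ K @ T
    S = 0.5 * (S + S.T)
    theta, U = np.linalg.eigh(S)
    theta = np.maximum(theta, 0.0)
    eta = U.T @ (T.T @ y)
    m = n - p
    eta2 = eta**2
    if eta2.sum() <= 0:
        # degenerate records (e.g. all equal): boundary without crashing
        return VarianceComponents(1e-12, 1e-12, source="REML")

    def neg_restricted_ll(log_gamma):
        g = 10.0**log_gamma
        denom = theta * g + 1.0
        rss = float(np.sum(eta2 / denom))
        return 0.5 * (m * np.log(rss) + np.sum(np.log(denom)))

    lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
    grid = np.linspace(lo, hi, 121)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    from scipy.optimize import minimize_scalar

    a, b = grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(neg_restricted_ll, bounds=(a, b), method="bounded")
    gamma = 10.0**res.x
    denom = theta * gamma + 1.0
    sigma2_e = float(np.sum(eta2 / denom)) / m
    sigma2_a = gamma * sigma2_e
    return VarianceComponents(max(sigma2_a, 1e-12), max(sigma2_e, 1e-12), source="REML")


# ---------------------------------------------------------------------------
# reliabilities, parent average, pedigree BLUP
# ---------------------------------------------------------------------------


def reliability(pev: np.ndarray, sigma2_a: float, diag_K: np.ndarray) -> np.ndarray:
    """rel = 1 - PEV / (diag(K) * sigma2_a); diag(K) carries the inbreeding."""
    pev = np.asarray(pev, float)
    diag_K = np.asarray(diag_K, float)
    denom = diag_K * sigma2_a
    if np.any(denom <= 0):
        raise ValueError("zero or negative genetic variance in reliability")
    return 1.0 - pev / denom


def parent_average(pedigree, ebv: np.ndarray) -> np.ndarray:
    """PA = (EBV_sire + EBV_dam)/2, unknown parents contributing 0."""
    ebv = np.asarray(ebv, float)
    s = np.asarray(pedigree.sire)
    d = np.asarray(pedigree.dam)
    es = np.where(s >= 0, ebv[np.maximum(s, 0)], 0.0)
    ed = np.where(d >= 0, ebv[np.maximum(d, 0)], 0.0)
    return 0.5 * (es + ed)


def pedigree_blup(
    pedigree,
    y: np.ndarray,
    record_animal: np.ndarray,
    vc: VarianceComponents,
    c22_index=None,
) -> MMESolution:
    """Animal-model BLUP on a pedigree: sparse Henderson A^-1, mean as the
    only fixed effect.  Used for in-simulation selection and for the EBV /
    reliabilities feeding deregressed proofs."""
    n_animals = len(pedigree.sire)
    Z = records_design(record_animal, n_animals)
    Ainv = kinship.build_A_inverse(pedigree)
    X = np.ones((len(y), 1))
    return solve_mme(y, X, Z, Ainv, vc, c22_index=c22_index)
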