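"""The four association-mapping methods, on a common per-SNP output.

* ``ssa_nocor``  -- single-SNP least squares, no relatedness correction.
* ``emmax``      -- per-SNP generalized least squares with a genomic kinship
                    random effect; variance components estimated once on the
                    null (no-SNP) model and held fixed across SNPs.
* ``gblup_gwas`` -- fit GBLUP once, back-solve all SNP effects from the
                    breeding values, with prediction-error variances from the
                    animal block of the inverse MME.
* ``ssgwas``     -- the same back-solving applied to a single-step model whose
                    H matrix merges pedigree and genomic information, so
                    phenotypes of non-genotyped relatives contribute.

All methods report effect, standard error and a two-sided p-value from the
standard normal reference p = 2(1 - Phi(|effect/se|)), so cross-method
comparisons are like-for-like.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm

from . import kinship
from .kinship import BETA_BLEND, LAMBDA_BLEND
from .mixedmodel import VarianceComponents, records_design, reml_estimate, solve_mme

__all__ = ["ssa_nocor", "emmax", "gblup_gwas", "ssgwas", "pvalue_from_effect"]

_TINY_VAR = 1e-30


def pvalue_from_effect(effect, sd):
    """Two-sided normal p-value, p = 2(1 - Phi(|effect/sd|))."""
    effect = np.asarray(effect, float)
    sd = np.asarray(sd, float)
    if np.any(sd <= 0):
        raise ValueError("standard error must be positive")
    return 2.0 * norm.sf(np.abs(effect) / sd)


def _result(panel, effect, se, pvalue, flag, method) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "snp_id": panel.map["snp_id"].to_numpy(),
            "chrom": panel.map["chrom"].to_numpy(),
            "pos_cM": panel.map["pos_cM"].to_numpy(),
            "effect": effect,
            "se": se,
            "pvalue": np.clip(pvalue, 0.0, 1.0),
            "flag": flag,
        }
    )
    out.attrs["method"] = method
    return out


# ---------------------------------------------------------------------------
# SSA-NoCor
# ---------------------------------------------------------------------------


def ssa_nocor(y: np.ndarray, panel) -> pd.DataFrame:
    """Per-SNP ordinary least squares of y on {1, x_i}.

    SNPs monomorphic among the phenotyped animals have no defined effect and
    are flagged with p = 1.
    """
    y = np.asarray(y, float).ravel()
    X = panel.dosages.astype(np.float64)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("phenotypes and panel rows misaligned")
    xm = X.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", X, X) - n * xm**2
    sxy = yc @ X
    syy = float(yc @ yc)
    mono = sxx <= 0
    sxx_safe = np.where(mono, 1.0, sxx)
    b = sxy / sxx_safe
    rss = np.maximum(syy - b * sxy, 0.0)
    dof = max(n - 2, 1)
    se = np.sqrt(rss / dof / sxx_safe)
    se_safe = np.where(se > 0, se, 1.0)
    p = pvalue_from_effect(b, se_safe)
    p[se <= 0] = np.where(b[se <= 0] == 0, 1.0, 0.0)
    b[mono] = 0.0
    se[mono] = np.nan
    p[mono] = 1.0
    flag = np.where(mono, "monomorphic", "")
    return _result(panel, b, se, p, flag, "SSA-NoCor")


# ---------------------------------------------------------------------------
# EMMAX
# ---------------------------------------------------------------------------


def emmax(y: np.ndarray, panel, G: np.ndarray | None = None,
          vc: VarianceComponents | None = None) -> pd.DataFrame:
    """Per-SNP GLS under V = G sigma2_a + I sigma2_e, components fixed from
    the null model (the defining EMMAX approximation).

    ``G`` defaults to the marker-sample-mean kinship of the panel itself
    (:func:`gwasim.kinship.build_G_gemma`).
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if panel.dosages.shape[0] != n:
        raise ValueError("phenotypes and panel rows misaligned")
    if G is None:
        G = kinship.build_G_gemma(panel.dosages)
    if vc is None:
        vc = reml_estimate(y, K=G)

    w, U = np.linalg.eigh(G)
    var = np.maximum(w * vc.sigma2_a + vc.sigma2_e, 1e-12)
    scale = 1.0 / np.sqrt(var)
    # rotate records into the eigenbasis and whiten: OLS there == GLS
    yt = scale * (U.T @ y)
    onet = scale * (U.T @ np.ones(n))
    Xt = scale[:, None] * (U.T @ panel.dosages.astype(np.float64))

    a = float(onet @ onet)
    bvec = onet @ Xt
    c = np.einsum("ij,ij->j", Xt, Xt)
    s1y = float(onet @ yt)
    sxy = yt @ Xt
    det = a * c - bvec**2
    bad = det <= 1e-12 * np.maximum(a * c, 1e-300)
    det_safe = np.where(bad, 1.0, det)
    beta = (a * sxy - bvec * s1y) / det_safe
    se = np.sqrt(a / det_safe)
    p = pvalue_from_effect(beta, np.where(se > 0, se, 1.0))
    beta[bad] = 0.0
    se[bad] = np.nan
    p[bad] = 1.0
    flag = np.where(bad, "monomorphic", "")
    out = _result(panel, beta, se, p, flag, "EMMAX")
    out.attrs["vc"] = vc
    return out


# ---------------------------------------------------------------------------
# shared back-solving core (GBLUP-GWAS and ssGWAS)
# ---------------------------------------------------------------------------


def _backsolve(panel, a_hat, pev_block, G, vc, coef, sqrt_lambda=False):
    """SNP effects and variances from breeding values of genotyped animals.

    effect = coef * (1/(2 sum pq)) * M' G^-1 a_hat
    Var    = [coef/(2 sum pq)]^2 * M' G^-1 (G sigma2_a - PEV) G^-1 M  (diagonal)

    ``coef`` is lambda (blending weight) for GBLUP-GWAS and lambda*delta for
    ssGWAS; ``sqrt_lambda`` selects the sqrt(lambda) variant of the printed
    scaling ambiguity.
    """
    X = panel.dosages.astype(np.float64)
    p = X.mean(axis=0) / 2.0
    spq = 2.0 * np.sum(p * (1.0 - p))
    if spq <= 0:
        raise ValueError("monomorphic panel: back-solving scale undefined")
    if sqrt_lambda:
        coef = np.sqrt(coef)
    s = coef / spq
    M = X - 2.0 * p
    Ginv = np.linalg.inv(G)
    W = Ginv @ M  # n_genotyped x k
    effect = s * (W.T @ a_hat)
    D = G * vc.sigma2_a - pev_block
    var = s**2 * np.einsum("ij,ij->j", W, D @ W)
    clamped = var <= 0
    if np.any(clamped):
        warnings.warn(
            f"{int(clamped.sum())} SNP-effect variances were non-positive "
            "(floating-point cancellation) and were clamped",
            stacklevel=3,
        )
        var = np.where(clamped, _TINY_VAR, var)
    se = np.sqrt(var)
    pval = pvalue_from_effect(effect, se)
    flag = np.where(clamped, "variance_clamped", "")
    return effect, se, pval, flag


def gblup_gwas(
    y: np.ndarray,
    panel,
    vc: VarianceComponents | None = None,
    lam: float = LAMBDA_BLEND,
    beta: float = BETA_BLEND,
    G: np.ndarray | None = None,
    sqrt_lambda: bool = False,
) -> pd.DataFrame:
    """GBLUP fit once, then all SNP effects back-solved simultaneously.

    Every phenotyped animal must be genotyped (rows of ``panel`` align with
    ``y``).  G is VanRaden's matrix blended with the identity
    (lam*G0 + beta*I) unless supplied.
    """
    y = np.asarray(y, float).ravel()
    n = y.size
    if panel.dosages.shape[0] != n:
        raise ValueError("GBLUP-GWAS requires genotypes for every phenotyped animal")
    if G is None:
        G = kinship.blend_G(kinship.build_G_vanraden(panel.dosages), lam, beta)
    if vc is None:
        vc = reml_estimate(y, K=G)
    Ginv = np.linalg.inv(G)
    sol = solve_mme(y, np.ones((n, 1)), sp.identity(n, format="csr"),
                    Ginv, vc, full_c22=True)
    pev_block = sol.c22 * vc.sigma2_e
    effect, se, pval, flag = _backsolve(
        panel, sol.a, pev_block, G, vc, coef=lam, sqrt_lambda=sqrt_lambda
    )
    out = _result(panel, effect, se, pval, flag, "GBLUP-GWAS")
    out.attrs["vc"] = vc
    out.attrs["gebv"] = sol.a
    return out


def ssgwas(
    y: np.ndarray,
    record_animal: np.ndarray,
    pedigree,
    panel,
    vc: VarianceComponents,
    lam: float = LAMBDA_BLEND,
    beta: float = BETA_BLEND,
    tune: bool = True,
    sqrt_lambda: bool = False,
) -> pd.DataFrame:
    """Single-step GWAS: H^-1 merges pedigree and genomic relationships, so
    ``y`` may contain records of non-genotyped animals.

    ``record_animal`` holds the 0-based pedigree index of each record.  The
    genomic matrix is built on the genotyped animals (VanRaden, blended,
    optionally tuned to A22), delta corrects any remaining genetic-base
    difference, and SNP effects are back-solved from the genotyped animals'
    GEBV with variances from the genotyped block of the inverse MME.
    """
    y = np.asarray(y, float).ravel()
    record_animal = np.asarray(record_animal)
    n_animals = len(pedigree.sire)
    gidx = np.flatnonzero(np.asarray(pedigree.genotyped))
    if gidx.size == 0:
        raise ValueError("no genotyped animals in pedigree")
    panel_rows = {int(i) - 1: r for r, i in enumerate(panel.ids)}
    try:
        order = np.array([panel_rows[int(i)] for i in gidx])
    except KeyError as err:
        raise ValueError(f"pedigree/genotype index mismatch: animal {err} has no genotypes")
    dos = panel.dosages[order]
    aligned = type(panel)(ids=gidx + 1, dosages=dos, map=panel.map)

    G0 = kinship.build_G_vanraden(dos)
    G = kinship.blend_G(G0, lam, beta)
    A22 = kinship.A22_from_pedigree(pedigree, gidx)
    if tune:
        G, _, _ = kinship.tune_G_to_A22(G, A22)
    delta = kinship.compute_delta(A22, G)
    Ginv = np.linalg.inv(G)
    A22inv = np.linalg.inv(A22)

    sparse = n_animals > 3000
    Ainv = kinship.build_A_inverse(pedigree)
    if not sparse:
        Ainv = Ainv.toarray()
    Hinv = kinship.build_Hinv(Ainv, A22inv, Ginv, gidx)
    Z = records_design(record_animal, n_animals)
    sol = solve_mme(y, np.ones((y.size, 1)), Z, Hinv, vc, c22_index=gidx)
    a22 = sol.a[gidx]
    pev_block = sol.c22 * vc.sigma2_e
    effect, se, pval, flag = _backsolve(
        aligned, a22, pev_block, G, vc, coef=lam * delta, sqrt_lambda=sqrt_lambda
    )
    out = _result(aligned, effect, se, pval, flag, "ssGWAS")
    out.attrs["vc"] = vc
    out.attrs["delta"] = delta
    out.attrs["gebv"] = a22
    return out
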