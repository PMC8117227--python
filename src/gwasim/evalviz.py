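"""Results layer: significance windows, ROC, LD decay, PCA and Ne.

A significant SNP (Bonferroni 0.05/n) counts as a true positive when it lies
within +/-2 cM of a same-chromosome QTN (boundary inclusive) and as a false
positive otherwise; counts are per significant SNP, matching how association
scans are usually summarized.  ROC curves use the same window as the truth
label over the full p-value sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinship

__all__ = [
    "EvalSummary",
    "InbreedingTrend",
    "bonferroni_threshold",
    "classify_tp_fp",
    "roc_curve",
    "ld_decay",
    "pca_of_G",
    "ne_from_rate",
    "effective_population_size",
    "manhattan_data",
]

WINDOW_CM = 2.0


@dataclass
class EvalSummary:
    method: str
    threshold: float
    tp: int
    fp: int
    window_cM: float = WINDOW_CM
    replicate: int | None = None
    classification: np.ndarray = field(default=None, repr=False)  # 'tp'/'fp'/''

    @property
    def n_significant(self) -> int:
        return self.tp + self.fp


@dataclass
class InbreedingTrend:
    """Per-generation mean inbreeding, its rate of change, and Ne."""

    table: pd.DataFrame  # generation, F, delta_F
    ne: float  # nan when mean delta_F <= 0


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n."""
    if n_snps < 1:
        raise ValueError("need at least one SNP")
    return alpha / n_snps


def _dist_to_qtn(assoc: pd.DataFrame, qtn: pd.DataFrame) -> np.ndarray:
    """Distance (cM) from each SNP to the nearest same-chromosome QTN."""
    if not set(assoc["chrom"]).issubset(set(qtn["chrom"])):
        raise ValueError("chromosome mismatch between association map and QTN registry")
    dist = np.full(len(assoc), np.inf)
    for c, grp in qtn.groupby("chrom"):
        on = assoc["chrom"].to_numpy() == c
        if on.any():
            d = np.abs(
                assoc.loc[on, "pos_cM"].to_numpy()[:, None]
                - grp["pos_cM"].to_numpy()[None, :]
            )
            dist[on] = d.min(axis=1)
    return dist


def classify_tp_fp(
    assoc: pd.DataFrame,
    qtn: pd.DataFrame,
    threshold: float,
    window_cM: float = WINDOW_CM,
    replicate: int | None = None,
) -> EvalSummary:
    """Count significant SNPs inside (TP) and outside (FP) the QTN windows."""
    dist = _dist_to_qtn(assoc, qtn)
    sig = assoc["pvalue"].to_numpy() < threshold
    near = dist <= window_cM
    cls = np.where(sig & near, "tp", np.where(sig, "fp", ""))
    return EvalSummary(
        method=assoc.attrs.get("method", "?"),
        threshold=threshold,
        tp=int((sig & near).sum()),
        fp=int((sig & ~near).sum()),
        window_cM=window_cM,
        replicate=replicate,
        classification=cls,
    )


def roc_curve(assoc: pd.DataFrame, qtn: pd.DataFrame, window_cM: float = WINDOW_CM):
    """ROC over the p-value sweep; returns (points DataFrame, area).

    Positives are SNPs within the QTN window.  The trapezoidal area equals
    the Mann-Whitney statistic of p-values between the two label groups.
    """
    dist = _dist_to_qtn(assoc, qtn)
    label = dist <= window_cM
    n_pos, n_neg = int(label.sum()), int((~label).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need both positive and negative SNPs")
    order = np.argsort(assoc["pvalue"].to_numpy(), kind="stable")
    lab = label[order]
    tpr = np.concatenate([[0.0], np.cumsum(lab) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(~lab) / n_neg])
    area = float(np.trapezoid(tpr, fpr))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr}), area


def ld_decay(
    panel,
    max_dist_cM: float = 50.0,
    bin_width: float = 1.0,
    max_pairs_per_chrom: int = 20_000,
    seed=None,
) -> pd.DataFrame:
    """Mean r^2 between SNP pairs binned by map distance.

    r^2 is the squared Pearson correlation of allele dosages.  Pairs are
    sampled per chromosome to bound cost; pairs with a monomorphic member are
    skipped.
    """
    rng = np.random.default_rng(seed)
    X = panel.dosages.astype(np.float64)
    chrom = panel.map["chrom"].to_numpy()
    pos = panel.map["pos_cM"].to_numpy()
    sd = X.std(axis=0)
    edges = np.arange(0.0, max_dist_cM + bin_width, bin_width)
    sums = np.zeros(edges.size - 1)
    counts = np.zeros(edges.size - 1, dtype=int)
    Xc = X - X.mean(axis=0)
    n = X.shape[0]
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size < 2:
            continue
        i = idx[rng.integers(0, idx.size, max_pairs_per_chrom)]
        j = idx[rng.integers(0, idx.size, max_pairs_per_chrom)]
        keep = (i != j) & (sd[i] > 0) & (sd[j] > 0)
        i, j = i[keep], j[keep]
        d = np.abs(pos[i] - pos[j])
        keep = d <= max_dist_cM
        i, j, d = i[keep], j[keep], d[keep]
        r = np.einsum("ij,ij->j", Xc[:, i], Xc[:, j]) / (n * sd[i] * sd[j])
        b = np.clip(np.digitize(d, edges) - 1, 0, edges.size - 2)
        np.add.at(sums, b, r**2)
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {
            "dist_lo_cM": edges[:-1],
            "dist_hi_cM": edges[1:],
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def pca_of_G(G: np.ndarray, n_pc: int = 2):
    """Principal components of a genomic relationship matrix.

    Returns (scores for the leading ``n_pc`` axes, variance-explained
    fractions for all axes).  Scores are eigenvectors scaled by the square
    root of their eigenvalue, the usual PCA-of-kinship display.
    """
    G = np.asarray(G, float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    w, U = np.linalg.eigh(G)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    wpos = np.maximum(w, 0.0)
    total = wpos.sum()
    varexp = wpos / total if total > 0 else wpos
    scores = U[:, :n_pc] * np.sqrt(wpos[:n_pc])
    return scores, varexp


def ne_from_rate(delta_f: float) -> float:
    """Closed form Ne = 1/(2 delta_F); NaN for a non-positive rate."""
    return 1.0 / (2.0 * delta_f) if delta_f > 0 else np.nan


def effective_population_size(pedigree) -> InbreedingTrend:
    """Ne from the realized per-generation rate of inbreeding.

    Per generation, delta_F_n = (F_n - F_{n-1}) / (1 - F_{n-1}); the averaged
    rate is the geometric mean of the survival fractions (1 - delta_F_n),
    which telescopes to 1 - ((1-F_T)/(1-F_1))^(1/(T-1)).  The endpoint form
    is used because per-generation mean F fluctuates strongly at small census
    sizes and single differences can even be negative; on a constant-rate
    trajectory both definitions coincide.  The founder-to-first-offspring
    transition is excluded (with non-inbred founders it cannot produce
    inbreeding).  Ne = 1/(2 rate), NaN when the rate is not positive.
    """
    F = kinship.inbreeding(pedigree)
    gen = np.asarray(pedigree.generation)
    gens = np.unique(gen)
    if gens.size < 2:
        raise ValueError("need at least two generations to compute delta F")
    meanF = np.array([F[gen == g].mean() for g in gens])
    dF = (meanF[1:] - meanF[:-1]) / (1.0 - meanF[:-1])
    table = pd.DataFrame(
        {"generation": gens, "F": meanF, "delta_F": np.concatenate([[np.nan], dF])}
    )
    if gens.size > 2:
        start, m = 1, gens.size - 2
    else:
        start, m = 0, 1
    ratio = (1.0 - meanF[-1]) / (1.0 - meanF[start])
    rate = 1.0 - ratio ** (1.0 / m) if ratio > 0 else np.nan
    ne = ne_from_rate(rate) if np.isfinite(rate) else np.nan
    return InbreedingTrend(table=table, ne=ne)


def manhattan_data(assoc: pd.DataFrame) -> pd.DataFrame:
    """-log10 p against cumulative map position (plotting convenience)."""
    out = assoc[["chrom", "pos_cM", "pvalue"]].copy()
    offset = 0.0
    cum = np.empty(len(out))
    for c, grp in out.groupby("chrom", sort=True):
        cum[grp.index] = grp["pos_cM"] + offset
        offset += grp["pos_cM"].max()
    out["cum_pos_cM"] = cum
    out["neglog10p"] = -np.log10(np.clip(out["pvalue"], 1e-300, None))
    return out
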