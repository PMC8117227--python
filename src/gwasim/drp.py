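"""Deregressed proofs: sire pseudo-phenotypes from daughter records.

For sex-limited traits the genotyped animals (sires) have no phenotype of
their own; their EBV carry daughter information but are shrunken toward the
parent average.  Deregression removes the PA contribution and the shrinkage:

    DE_PA   = rel_PA / (1 - rel_PA)
    DE_prog = rel_EBV / (1 - rel_EBV) - DE_PA
    DRP     = PA + (EBV - PA) * (DE_prog + DE_PA + 1) / DE_prog

where DE are daughter equivalents and rel the reliabilities of EBV and PA.
Animals without progeny information beyond the parent average
(DE_prog <= 0) have no defined DRP and are excluded with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .mixedmodel import parent_average

__all__ = ["compute_drp"]


def compute_drp(ebv: np.ndarray, rel: np.ndarray, pedigree, animals=None) -> pd.DataFrame:
    """Deregress proofs for the requested animals (default: genotyped ones).

    ``ebv`` and ``rel`` are per-animal vectors over the whole pedigree
    (reliability may be NaN for animals where it was not computed).  PA
    reliability is (rel_sire + rel_dam)/4 with missing parents contributing 0.
    Returns one row per animal with a defined DRP; columns follow the
    drp.tsv layout (id, pa, ebv, ebv_rel, pa_rel, de_prog, de_pa, drp, weight).
    """
    ebv = np.asarray(ebv, float)
    rel = np.asarray(rel, float)
    if animals is None:
        animals = np.flatnonzero(np.asarray(pedigree.genotyped))
    animals = np.asarray(animals)

    pa_all = parent_average(pedigree, ebv)
    s = np.asarray(pedigree.sire)
    d = np.asarray(pedigree.dam)
    rel_fill = np.nan_to_num(rel, nan=0.0)
    rs = np.where(s >= 0, rel_fill[np.maximum(s, 0)], 0.0)
    rd = np.where(d >= 0, rel_fill[np.maximum(d, 0)], 0.0)
    pa_rel_all = (rs + rd) / 4.0

    rows = []
    n_excluded = 0
    for i in animals:
        ebv_rel = rel[i]
        pa_rel = pa_rel_all[i]
        if not np.isfinite(ebv_rel) or not (0.0 <= ebv_rel < 1.0) or not (0.0 <= pa_rel < 1.0):
            n_excluded += 1
            continue
        de_pa = pa_rel / (1.0 - pa_rel)
        de_prog = ebv_rel / (1.0 - ebv_rel) - de_pa
        if de_prog <= 0:
            n_excluded += 1
            continue
        pa = pa_all[i]
        drp = pa + (ebv[i] - pa) * (de_prog + de_pa + 1.0) / de_prog
        rows.append(
            dict(id=i + 1, pa=pa, ebv=ebv[i], ebv_rel=ebv_rel, pa_rel=pa_rel,
                 de_prog=de_prog, de_pa=de_pa, drp=drp, weight=de_prog)
        )
    if n_excluded:
        warnings.warn(
            f"{n_excluded} animals excluded from deregression "
            "(no progeny information beyond parent average)",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["id", "pa", "ebv", "ebv_rel", "pa_rel",
                                       "de_prog", "de_pa", "drp", "weight"])
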