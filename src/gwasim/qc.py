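"""Genotype quality control applied before association analysis.

Three rules, in order: drop monomorphic SNPs, drop SNPs with minor allele
frequency strictly below ``maf_min``, and drop SNPs whose observed
heterozygote frequency deviates from the Hardy-Weinberg expectation 2pq by
strictly more than ``dev_max``.  Thresholds are strict inequalities, so a
locus at exactly MAF 0.05 or deviation 0.15 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QcReport", "qc_filter"]


@dataclass
class QcReport:
    n_input: int
    removed_monomorphic: int
    removed_maf: int
    removed_deviation: int
    retained_index: np.ndarray

    @property
    def n_retained(self) -> int:
        return self.retained_index.size

    def __post_init__(self):
        removed = self.removed_monomorphic + self.removed_maf + self.removed_deviation
        assert removed + self.n_retained == self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": ["monomorphic", "maf", "frequency_deviation", "retained"],
                "count": [
                    self.removed_monomorphic,
                    self.removed_maf,
                    self.removed_deviation,
                    self.n_retained,
                ],
            }
        )


def qc_filter(panel, maf_min: float = 0.05, dev_max: float = 0.15, mode: str = "hwe"):
    """Filter a genotype panel; returns (filtered panel, QcReport).

    ``mode='hwe'`` tests |observed heterozygote frequency - 2pq|; the
    alternative ``mode='freq'`` compares the observed allele frequency against
    0.5 (the founder frequency), kept behind this flag because the rule's
    published wording is ambiguous.
    """
    X = panel.dosages
    p = X.mean(axis=0) / 2.0
    alive = np.ones(p.size, bool)

    mono = (p == 0.0) | (p == 1.0)
    n_mono = int(mono.sum())
    alive &= ~mono

    maf = np.minimum(p, 1.0 - p)
    low = alive & (maf < maf_min)
    n_maf = int(low.sum())
    alive &= ~low

    if mode == "hwe":
        het = (X == 1).mean(axis=0)
        dev = np.abs(het - 2.0 * p * (1.0 - p))
    elif mode == "freq":
        dev = np.abs(p - 0.5)
    else:
        raise ValueError(f"unknown deviation mode {mode!r}")
    bad = alive & (dev > dev_max)
    n_dev = int(bad.sum())
    alive &= ~bad

    if not alive.any():
        report = QcReport(p.size, n_mono, n_maf, n_dev, np.flatnonzero(alive))
        raise ValueError(f"quality control removed every SNP: {report.to_frame().to_dict('records')}")
    keep = np.flatnonzero(alive)
    return panel.subset_snps(keep), QcReport(p.size, n_mono, n_maf, n_dev, keep)
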