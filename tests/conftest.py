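"""Shared fixtures: miniature simulated scenarios and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from gwasim import simdata
from gwasim.simdata import GenomeSpec, GenotypePanel, Pedigree

#: small genome: 29 chromosomes x 20 SNPs + 1 QTN, full 100 cM maps
TINY_GENOME = GenomeSpec(n_snps=580)


def make_panel(dosages, chrom=None, pos=None) -> GenotypePanel:
    """Panel from a raw dosage matrix with a default 1-cM-spaced map."""
    dosages = np.asarray(dosages, dtype=np.int8)
    k = dosages.shape[1]
    if chrom is None:
        chrom = np.ones(k, int)
    if pos is None:
        pos = np.arange(k, dtype=float)
    gmap = pd.DataFrame(
        {"snp_id": [f"snp{i + 1}" for i in range(k)], "chrom": chrom, "pos_cM": pos}
    )
    return GenotypePanel(
        ids=np.arange(1, dosages.shape[0] + 1), dosages=dosages, map=gmap
    )


def make_pedigree(sire, dam, sex=None, generation=None, genotyped=None, phenotyped=None):
    sire = np.asarray(sire)
    dam = np.asarray(dam)
    n = sire.size
    if sex is None:
        # assign sexes consistent with parent usage
        sex = np.array(["F"] * n)
        sex[np.unique(sire[sire >= 0])] = "M"
    if generation is None:
        generation = np.zeros(n, int)
        for i in range(n):
            ps = [p for p in (sire[i], dam[i]) if p >= 0]
            generation[i] = 1 + max((generation[p] for p in ps), default=-1)
    return Pedigree(
        sire=sire,
        dam=dam,
        sex=np.asarray(sex),
        generation=np.asarray(generation),
        genotyped=np.zeros(n, bool) if genotyped is None else np.asarray(genotyped),
        phenotyped=np.zeros(n, bool) if phenotyped is None else np.asarray(phenotyped),
    )


def random_pedigree(n, n_founders, rng, force_both_parents=True):
    """Random topologically ordered pedigree for oracle comparisons."""
    sire = np.full(n, -1)
    dam = np.full(n, -1)
    sex = np.array(["M", "F"] * ((n + 1) // 2))[:n]
    rng.shuffle(sex)
    if not (sex[:n_founders] == "M").any() or not (sex[:n_founders] == "F").any():
        sex[0], sex[1] = "M", "F"
    for i in range(n_founders, n):
        males = np.flatnonzero(sex[:i] == "M")
        females = np.flatnonzero(sex[:i] == "F")
        sire[i] = rng.choice(males)
        dam[i] = rng.choice(females)
    return make_pedigree(sire, dam, sex=sex)


def kinship_oracle(sire, dam):
    """Numerator relationships by direct recursion on Wright's definition."""
    n = len(sire)
    memo = {}

    def a(i, j):
        if i < 0 or j < 0:
            return 0.0
        if i > j:
            i, j = j, i
        if (i, j) in memo:
            return memo[(i, j)]
        if i == j:
            val = 1.0 + 0.5 * a(sire[i], dam[i])
        else:
            # j is the later-born: relationship through j's parents
            val = 0.5 * (a(i, sire[j]) + a(i, dam[j]))
        memo[(i, j)] = val
        return val

    return np.array([[a(i, j) for j in range(n)] for i in range(n)])


@pytest.fixture(scope="session")
def tiny_fish():
    """Full fish breeding design on a thin 580-SNP panel (fast)."""
    return simdata.simulate_scenario(
        "fish", seed=7, genome=TINY_GENOME, trajectory=((0, 80), (10, 60))
    )


@pytest.fixture(scope="session")
def tiny_fish_gwas_inputs(tiny_fish):
    """Aligned (y, panel) for the genotyped-with-phenotype animals."""
    sim = tiny_fish
    ped = sim.pedigree
    both = np.flatnonzero(ped.genotyped & ped.phenotyped)
    lookup = {int(i): r for r, i in enumerate(sim.panel.ids)}
    rows = np.array([lookup[int(i) + 1] for i in both])
    panel = sim.panel.subset_animals(rows)
    y = sim.phenotypes.set_index("id")["value"].loc[both + 1].to_numpy()
    return y, panel, sim
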