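"""Forward-in-time breeding-population simulator.

Emulates QMSim-style two-phase simulations: a long historical phase of random
union of gametes that builds linkage disequilibrium and mutation--drift
equilibrium, followed by species-specific recent populations (fish, beef
cattle, dairy cattle) with the selection and mating designs used in livestock
association studies.  Output is a pedigree, a SNP panel with a genetic map,
a QTN registry and a phenotype table -- the inputs of every downstream stage.

Genome model: biallelic loci on ``n_chromosomes`` chromosomes, evenly spaced
SNPs plus one causal QTN per chromosome at the chromosome midpoint.  Meiosis
follows the Haldane model (Poisson crossovers, no interference), implemented
as independent Bernoulli recombination events between adjacent loci with
probability (1 - exp(-2d/100))/2 for map distance d in cM, which is exactly
equivalent for loci observed at fixed positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import kinship, mixedmodel

__all__ = [
    "GenomeSpec",
    "TraitSpec",
    "Pedigree",
    "GenotypePanel",
    "SimOutput",
    "simulate_historical",
    "meiosis",
    "simulate_recent",
    "assign_qtn_effects",
    "write_scenario",
    "read_scenario",
    "write_plink",
    "FISH_GENOME",
    "CATTLE_GENOME",
    "scale_genome",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSpec:
    """Genome layout: chromosomes, marker panel and causal loci.

    SNPs are evenly spaced; the i-th SNP of a chromosome with ``n`` SNPs sits
    at (i + 0.25) * length / n cM, an offset grid that never coincides with
    the QTN at the chromosome midpoint.
    """

    n_chromosomes: int = 29
    chrom_length_cM: float = 100.0
    n_snps: int = 35_000
    n_qtn_per_chrom: int = 1
    mutation_rate: float = 2.5e-5
    founder_freq: float = 0.5

    def loci(self) -> "Loci":
        """All loci (SNP + QTN) sorted by chromosome and position."""
        chroms, pos, is_qtn = [], [], []
        base, extra = divmod(self.n_snps, self.n_chromosomes)
        for c in range(self.n_chromosomes):
            n_c = base + (1 if c < extra else 0)
            p_snp = (np.arange(n_c) + 0.25) * self.chrom_length_cM / n_c
            p_qtn = np.full(self.n_qtn_per_chrom, self.chrom_length_cM / 2.0)
            p = np.concatenate([p_snp, p_qtn])
            q = np.concatenate(
                [np.zeros(n_c, bool), np.ones(self.n_qtn_per_chrom, bool)]
            )
            order = np.argsort(p, kind="stable")
            chroms.append(np.full(n_c + self.n_qtn_per_chrom, c + 1))
            pos.append(p[order])
            is_qtn.append(q[order])
        return Loci(
            chrom=np.concatenate(chroms).astype(np.int16),
            pos_cM=np.concatenate(pos),
            is_qtn=np.concatenate(is_qtn),
        )


@dataclass(frozen=True)
class Loci:
    """Concrete locus table derived from a :class:`GenomeSpec`."""

    chrom: np.ndarray
    pos_cM: np.ndarray
    is_qtn: np.ndarray

    def __post_init__(self):
        d = np.diff(self.pos_cM)
        same = np.diff(self.chrom) == 0
        if np.any(d[same] < 0):
            raise ValueError("locus positions must be non-decreasing within chromosome")

    @property
    def n(self) -> int:
        return self.chrom.size

    @property
    def snp_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtn)

    @property
    def qtn_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtn)

    def switch_probs(self) -> np.ndarray:
        """Per-locus probability that a gamete switches source haplotype.

        Entry 0 of every chromosome is 0.5 (independent assortment); within a
        chromosome the Haldane map function gives the recombination fraction
        between adjacent loci.
        """
        q = np.empty(self.n)
        d = np.diff(self.pos_cM)
        q[1:] = 0.5 * (1.0 - np.exp(-2.0 * np.maximum(d, 0.0) / 100.0))
        q[0] = 0.5
        q[1:][np.diff(self.chrom) != 0] = 0.5
        return q

    def recomb_model(self):
        """(chromosome-start indices, per-interval crossover intensities).

        Intensities are Morgans between adjacent loci; crossover counts per
        interval are Poisson with these means, and the source haplotype flips
        with the parity of the count (Haldane: no interference).  Cached on
        first use.
        """
        if not hasattr(self, "_recomb"):
            starts = np.flatnonzero(
                np.concatenate([[True], np.diff(self.chrom) != 0])
            )
            lam = np.diff(self.pos_cM) / 100.0
            lam[np.diff(self.chrom) != 0] = 0.0
            lam = np.concatenate([[0.0], np.maximum(lam, 0.0)])
            object.__setattr__(self, "_recomb", (starts, lam))
        return self._recomb

    def snp_map(self) -> pd.DataFrame:
        i = self.snp_index
        return pd.DataFrame(
            {
                "snp_id": [f"snp{j + 1}" for j in range(i.size)],
                "chrom": self.chrom[i].astype(int),
                "pos_cM": self.pos_cM[i],
            }
        )


@dataclass(frozen=True)
class TraitSpec:
    """Single polygenic trait controlled entirely by the QTN.

    ``heritability`` is the ratio of QTN variance to total variance among the
    founders of the recent population; the residual variance is fixed at 1.
    """

    heritability: float = 0.25
    overall_mean: float = 1.0
    qtn_effect_shape: float = 0.40
    sex_limited: bool = False

    def __post_init__(self):
        if not 0.0 < self.heritability < 1.0:
            raise ValueError("heritability must be in (0, 1)")

    @property
    def genetic_variance(self) -> float:
        """Target Var(TBV) for residual variance 1."""
        return self.heritability / (1.0 - self.heritability)


@dataclass
class Pedigree:
    """Topologically ordered pedigree with analysis flags.

    Parents are stored as 0-based row indices, -1 for unknown.  Animal ids in
    text output are 1-based (0 = unknown parent).
    """

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray  # 'M' / 'F'
    generation: np.ndarray
    genotyped: np.ndarray
    phenotyped: np.ndarray

    def __post_init__(self):
        n = self.n
        for arr in (self.dam, self.sex, self.generation, self.genotyped, self.phenotyped):
            if len(arr) != n:
                raise ValueError("pedigree columns must have equal length")
        self.validate()

    @property
    def n(self) -> int:
        return len(self.sire)

    @property
    def ids(self) -> np.ndarray:
        return np.arange(1, self.n + 1)

    def validate(self) -> None:
        idx = np.arange(self.n)
        for par, want in ((self.sire, "M"), (self.dam, "F")):
            known = par >= 0
            if np.any(par[known] >= idx[known]):
                raise ValueError("pedigree not topologically ordered: parent after offspring")
            if np.any(self.sex[par[known]] != want):
                raise ValueError(f"parent sex inconsistent: expected {want}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": np.where(self.sire >= 0, self.sire + 1, 0),
                "dam": np.where(self.dam >= 0, self.dam + 1, 0),
                "sex": self.sex,
                "generation": self.generation,
                "genotyped": self.genotyped.astype(int),
                "phenotyped": self.phenotyped.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Pedigree":
        return cls(
            sire=df["sire"].to_numpy(int) - 1,
            dam=df["dam"].to_numpy(int) - 1,
            sex=df["sex"].to_numpy(str),
            generation=df["generation"].to_numpy(int),
            genotyped=df["genotyped"].to_numpy(int).astype(bool),
            phenotyped=df["phenotyped"].to_numpy(int).astype(bool),
        )


@dataclass
class GenotypePanel:
    """Allele-dosage matrix {0,1,2} for a set of animals plus its genetic map."""

    ids: np.ndarray  # 1-based animal ids, aligned with dosage rows
    dosages: np.ndarray  # (n_animals, n_snps) int8
    map: pd.DataFrame  # snp_id, chrom, pos_cM

    def __post_init__(self):
        if self.dosages.shape != (len(self.ids), len(self.map)):
            raise ValueError("dosage matrix shape inconsistent with ids/map")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def allele_freqs(self) -> np.ndarray:
        return self.dosages.mean(axis=0) / 2.0

    def subset_snps(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            ids=self.ids,
            dosages=self.dosages[:, keep],
            map=self.map.iloc[keep].reset_index(drop=True),
        )

    def subset_animals(self, rows: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(ids=self.ids[rows], dosages=self.dosages[rows], map=self.map)


@dataclass
class SimOutput:
    """Everything one replicate of a scenario produces."""

    pedigree: Pedigree
    panel: GenotypePanel
    phenotypes: pd.DataFrame  # id, value, tbv (phenotyped animals only)
    qtn: pd.DataFrame  # chrom, pos_cM, effect, founder_freq
    genome: GenomeSpec
    trait: TraitSpec
    tbv: np.ndarray = field(repr=False, default=None)  # all animals, validation only


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

FISH_GENOME = GenomeSpec(n_snps=35_000)
CATTLE_GENOME = GenomeSpec(n_snps=65_000)

#: documented scale-down divisors for desk-scale runs
SNP_DIVISOR = 10
SIZE_DIVISOR = 10
FISH_HIST_GEN_DIVISOR = 4
#: cattle historical generations shrink with population size so the cumulative
#: drift sum(1/2N) -- and with it the terminal allele-frequency spectrum and
#: LD level -- is preserved
CATTLE_HIST_GEN_DIVISOR = 10


def scale_genome(genome: GenomeSpec, divisor: int = SNP_DIVISOR) -> GenomeSpec:
    return replace(genome, n_snps=genome.n_snps // divisor)


# ---------------------------------------------------------------------------
# gamete formation
# ---------------------------------------------------------------------------


def _gametes(hap: np.ndarray, parents: np.ndarray, loci: Loci, rng,
             chunk: int = 4000) -> np.ndarray:
    """Vectorized meiosis: one gamete per entry of ``parents``.

    hap: (2n, L) uint8 haplotypes, rows 2i / 2i+1 belong to individual i.
    Crossovers are drawn as sparse Poisson events (tens per gamete) rather
    than per-interval Bernoulli draws, so cost scales with the map length,
    not the marker count.
    """
    parents = np.asarray(parents)
    m = parents.size
    L = loci.n
    starts, lam = loci.recomb_model()
    lam_tot = lam.sum()
    if lam_tot > 0:
        cum = np.cumsum(lam)
        cum /= cum[-1]
    out = np.empty((m, L), dtype=np.uint8)
    for lo_i in range(0, m, chunk):
        sl = slice(lo_i, min(lo_i + chunk, m))
        mc = sl.stop - sl.start
        events = np.zeros((mc, L), dtype=np.int8)
        # independent assortment: each chromosome starts from a random haplotype
        events[:, starts] = rng.integers(0, 2, size=(mc, starts.size), dtype=np.int8)
        n_ev = rng.poisson(lam_tot * mc) if lam_tot > 0 else 0
        if n_ev:
            pos = np.searchsorted(cum, rng.random(n_ev))
            gi = rng.integers(0, mc, n_ev)
            np.add.at(events, (gi, pos), 1)
        # int8 cumsum may wrap mod 256; parity is preserved by an even modulus
        parity = np.cumsum(events, axis=1, dtype=np.int8)
        parity &= 1
        p = parents[sl]
        h0 = hap[2 * p]
        h0 ^= (h0 ^ hap[2 * p + 1]) & parity.view(np.uint8)
        out[sl] = h0
    return out


def meiosis(hap_pair: np.ndarray, loci: Loci, rng: np.random.Generator) -> np.ndarray:
    """One gamete from a parental haplotype pair (2, L) under the Haldane model."""
    hap_pair = np.asarray(hap_pair)
    if hap_pair.shape != (2, loci.n):
        raise ValueError("hap_pair must have shape (2, n_loci)")
    return _gametes(hap_pair, np.zeros(1, dtype=np.intp), loci, rng)[0]


def _mutate(hap: np.ndarray, rate: float, rng) -> None:
    """Recurrent mutation: allele flips at the given per-locus rate, in place."""
    if rate <= 0:
        return
    size = hap.size
    n_flips = rng.binomial(size, rate)
    if n_flips:
        idx = rng.integers(0, size, size=n_flips)
        np.bitwise_xor.at(hap.reshape(-1), idx, 1)


# ---------------------------------------------------------------------------
# historical phase
# ---------------------------------------------------------------------------


def _trajectory_sizes(size_trajectory) -> np.ndarray:
    """Per-generation sizes by linear interpolation between (gen, size) anchors."""
    anchors = sorted(size_trajectory)
    if not anchors:
        raise ValueError("size_trajectory must be non-empty")
    gens = np.array([g for g, _ in anchors], dtype=float)
    sizes = np.array([s for _, s in anchors], dtype=float)
    if np.any(sizes < 2):
        raise ValueError("population sizes must be >= 2")
    grid = np.arange(0, int(gens[-1]) + 1)
    return np.maximum(np.round(np.interp(grid, gens, sizes)).astype(int), 2)


def simulate_historical(
    genome: GenomeSpec,
    size_trajectory,
    prop_male: float = 0.5,
    seed=None,
) -> np.ndarray:
    """Random-mating historical phase; returns final-generation haplotypes.

    Generation 0 is founded at exactly ``founder_freq`` per locus (allele
    counts are exact, their placement random).  Each later generation is a
    random union of gametes from the previous one with separate sexes
    (``prop_male`` males) and recurrent mutation.
    """
    rng = np.random.default_rng(seed)
    loci = genome.loci()
    sizes = _trajectory_sizes(size_trajectory)
    n0 = sizes[0]

    # exact founder frequency: fixed allele counts, random placement
    n_ones = int(round(2 * n0 * genome.founder_freq))
    hap = np.zeros((2 * n0, loci.n), dtype=np.uint8)
    hap[:n_ones] = 1
    hap = rng.permuted(hap, axis=0)

    for n_next in sizes[1:]:
        n_cur = hap.shape[0] // 2
        n_male = int(round(prop_male * n_cur))
        if n_male < 1 or n_cur - n_male < 1:
            raise ValueError(
                f"historical generation with {n_cur} individuals has no "
                f"{'males' if n_male < 1 else 'females'} (prop_male={prop_male})"
            )
        sex_perm = rng.permutation(n_cur)
        males, females = sex_perm[:n_male], sex_perm[n_male:]
        sires = males[rng.integers(0, males.size, n_next)]
        dams = females[rng.integers(0, females.size, n_next)]
        new = np.empty((2 * n_next, loci.n), dtype=np.uint8)
        new[0::2] = _gametes(hap, sires, loci, rng)
        new[1::2] = _gametes(hap, dams, loci, rng)
        _mutate(new, genome.mutation_rate, rng)
        hap = new
    return hap


# ---------------------------------------------------------------------------
# QTN effects and phenotypes
# ---------------------------------------------------------------------------


def assign_qtn_effects(
    genome: GenomeSpec,
    trait: TraitSpec,
    founder_qtn_dosages: np.ndarray,
    seed=None,
) -> np.ndarray:
    """Gamma-distributed QTN effects with random sign, scaled to the target h².

    Raw magnitudes are gamma(shape) draws; the vector is rescaled so the
    variance of the founders' total QTN value equals h²/(1-h²) times the unit
    residual variance.
    """
    rng = np.random.default_rng(seed)
    q = np.asarray(founder_qtn_dosages, dtype=np.float64)
    n_qtn = q.shape[1]
    raw = rng.gamma(trait.qtn_effect_shape, 1.0, size=n_qtn)
    raw *= rng.choice([-1.0, 1.0], size=n_qtn)
    tbv = q @ raw
    v = tbv.var()
    if v <= 1e-12 * (np.abs(tbv).max() ** 2 + 1e-300):
        raise ValueError("all QTN monomorphic among founders; cannot scale effects")
    return raw * np.sqrt(trait.genetic_variance / v)


# ---------------------------------------------------------------------------
# recent populations
# ---------------------------------------------------------------------------


class _Population:
    """Growing pedigree + haplotype store used while breeding a recent design."""

    def __init__(self, loci: Loci, founder_hap: np.ndarray, founder_sex: np.ndarray, rng):
        self.loci = loci
        self.rng = rng
        n0 = founder_hap.shape[0] // 2
        self.hap = [founder_hap]
        self.sire = list(np.full(n0, -1))
        self.dam = list(np.full(n0, -1))
        self.sex = list(founder_sex)
        self.generation = list(np.zeros(n0, dtype=int))
        # one residual per animal, drawn at birth, so in-simulation selection
        # and the final phenotype table see the same record
        self.resid = [rng.standard_normal(n0)]
        self._hap_cat = None

    @property
    def n(self) -> int:
        return len(self.sire)

    def haplotypes(self) -> np.ndarray:
        if self._hap_cat is None or self._hap_cat.shape[0] != 2 * self.n:
            self._hap_cat = np.concatenate(self.hap, axis=0)
        return self._hap_cat

    def breed(self, sires: np.ndarray, dams: np.ndarray, generation: int,
              mutation_rate: float) -> np.ndarray:
        """One offspring per (sire, dam) pair; returns new animal indices.

        Sexes alternate via random permutation so each batch is half male."""
        m = sires.size
        hap = self.haplotypes()
        new = np.empty((2 * m, self.loci.n), dtype=np.uint8)
        new[0::2] = _gametes(hap, np.asarray(sires), self.loci, self.rng)
        new[1::2] = _gametes(hap, np.asarray(dams), self.loci, self.rng)
        _mutate(new, mutation_rate, self.rng)
        idx = np.arange(self.n, self.n + m)
        sexes = np.where(np.arange(m) < m // 2, "M", "F")
        sexes = self.rng.permuted(sexes)
        self.hap.append(new)
        self.sire.extend(sires)
        self.dam.extend(dams)
        self.sex.extend(sexes)
        self.generation.extend([generation] * m)
        self.resid.append(self.rng.standard_normal(m))
        return idx

    def residuals(self) -> np.ndarray:
        return np.concatenate(self.resid)

    def pedigree(self, genotyped: np.ndarray, phenotyped: np.ndarray) -> Pedigree:
        return Pedigree(
            sire=np.asarray(self.sire, dtype=np.int64),
            dam=np.asarray(self.dam, dtype=np.int64),
            sex=np.asarray(self.sex),
            generation=np.asarray(self.generation, dtype=np.int64),
            genotyped=genotyped,
            phenotyped=phenotyped,
        )

    def dosages(self, animal_idx: np.ndarray, locus_idx: np.ndarray) -> np.ndarray:
        hap = self.haplotypes()
        a = np.asarray(animal_idx)
        return (hap[2 * a][:, locus_idx] + hap[2 * a + 1][:, locus_idx]).astype(np.int8)

    def ebv(self, y: np.ndarray, record_idx: np.ndarray, h2: float) -> np.ndarray:
        """Pedigree-BLUP breeding values with the true variance ratio."""
        ped = self.pedigree(
            genotyped=np.zeros(self.n, bool), phenotyped=np.zeros(self.n, bool)
        )
        vc = mixedmodel.VarianceComponents(
            sigma2_a=h2 / (1 - h2), sigma2_e=1.0, source="true-simulation"
        )
        sol = mixedmodel.pedigree_blup(ped, y, record_idx, vc)
        return sol.a


def _select_founders(hap_pool: np.ndarray, n_male: int, n_female: int, rng):
    """Draw distinct individuals from a historical pool and assign sexes."""
    n_pool = hap_pool.shape[0] // 2
    if n_pool < n_male + n_female:
        raise ValueError(
            f"founder pool of {n_pool} smaller than required {n_male + n_female}"
        )
    pick = rng.choice(n_pool, size=n_male + n_female, replace=False)
    rows = np.empty(2 * pick.size, dtype=np.intp)
    rows[0::2], rows[1::2] = 2 * pick, 2 * pick + 1
    sex = np.array(["M"] * n_male + ["F"] * n_female)
    return hap_pool[rows].copy(), sex


def _phenotypes(pop: _Population, effects, trait: TraitSpec):
    """TBV for all animals and their (birth-time) phenotypes."""
    qtn_dos = pop.dosages(np.arange(pop.n), pop.loci.qtn_index).astype(np.float64)
    tbv = qtn_dos @ effects
    y = trait.overall_mean + tbv + pop.residuals()
    return tbv, y


def _finalize(pop, genotyped_idx, phenotyped_idx, genome, trait, effects,
              founder_freq_qtn, rng) -> SimOutput:
    n = pop.n
    genotyped = np.zeros(n, bool)
    genotyped[genotyped_idx] = True
    phenotyped = np.zeros(n, bool)
    phenotyped[phenotyped_idx] = True
    if trait.sex_limited:
        phenotyped &= np.asarray(pop.sex) == "F"
    tbv, y = _phenotypes(pop, effects, trait)
    ped = pop.pedigree(genotyped, phenotyped)
    gidx = np.flatnonzero(genotyped)
    loci = pop.loci
    panel = GenotypePanel(
        ids=gidx + 1,
        dosages=pop.dosages(gidx, loci.snp_index),
        map=loci.snp_map(),
    )
    pidx = np.flatnonzero(phenotyped)
    phen = pd.DataFrame({"id": pidx + 1, "value": y[pidx], "tbv": tbv[pidx]})
    qtn = pd.DataFrame(
        {
            "chrom": loci.chrom[loci.qtn_index].astype(int),
            "pos_cM": loci.pos_cM[loci.qtn_index],
            "effect": effects,
            "founder_freq": founder_freq_qtn,
        }
    )
    return SimOutput(
        pedigree=ped, panel=panel, phenotypes=phen, qtn=qtn,
        genome=genome, trait=trait, tbv=tbv,
    )


def _init_design(founders, genome, trait, n_male, n_female, rng):
    """Found the recent population and draw scaled QTN effects."""
    hap, sex = _select_founders(founders, n_male, n_female, rng)
    loci = genome.loci()
    pop = _Population(loci, hap, sex, rng)
    qtn_dos = pop.dosages(np.arange(pop.n), loci.qtn_index)
    effects = assign_qtn_effects(genome, trait, qtn_dos, rng)
    founder_freq = qtn_dos.mean(axis=0) / 2.0
    return pop, effects, founder_freq


def _simulate_fish(founders, genome, trait, rng, *, n_sires=20, n_dams=20,
                   random_gens=5, offspring_per_female=2, litter=100,
                   genotyped_line_count=1000) -> SimOutput:
    """Fish design: random nucleus then one 20x20 generation with litter 100.

    Analysis animals are the final line plus its parents; both sexes are
    phenotyped, and the parents plus half of the line are genotyped.
    """
    pop, effects, qf = _init_design(founders, genome, trait, n_sires, n_dams, rng)
    cur = np.arange(pop.n)
    for g in range(1, random_gens + 1):
        males = cur[np.asarray(pop.sex)[cur] == "M"]
        females = cur[np.asarray(pop.sex)[cur] == "F"]
        # each dam is mated to one randomly drawn sire: litters are full sibs
        mate = males[rng.integers(0, males.size, females.size)]
        dams = np.repeat(females, offspring_per_female)
        sires = np.repeat(mate, offspring_per_female)
        cur = pop.breed(sires, dams, g, genome.mutation_rate)
    # new line: 20 males x 20 females from generation 5, litter 100
    males = cur[np.asarray(pop.sex)[cur] == "M"]
    females = cur[np.asarray(pop.sex)[cur] == "F"]
    parents_m = rng.choice(males, size=n_sires, replace=False)
    parents_f = rng.choice(females, size=n_dams, replace=False)
    mate = parents_m[rng.integers(0, parents_m.size, parents_f.size)]
    dams = np.repeat(parents_f, litter)
    sires = np.repeat(mate, litter)
    line = pop.breed(sires, dams, random_gens + 1, genome.mutation_rate)
    parents = np.concatenate([parents_m, parents_f])
    phenotyped = np.concatenate([parents, line])
    genotyped = np.concatenate(
        [parents, rng.choice(line, size=min(genotyped_line_count, line.size), replace=False)]
    )
    return _finalize(pop, genotyped, phenotyped, genome, trait, effects, qf, rng)


def _simulate_beef(founders, genome, trait, rng, *, n_sires=20, n_dams=1000,
                   random_gens=5, n_lines=5, line_sires=1, line_dams=50,
                   line_gens=2, pooled_gens=5) -> SimOutput:
    """Beef design: random phase, five EBV-stratified lines, pooled random line.

    Lines are founded from EBV strata of the last random generation (top
    sires/dams ranked and split), bred with within-line truncation selection,
    then pooled and randomly mated.  Genotyped: last generation + parents.
    """
    pop, effects, qf = _init_design(founders, genome, trait, n_sires, n_dams, rng)
    h2 = trait.heritability
    sex = lambda idx, s: idx[np.asarray(pop.sex)[idx] == s]  # noqa: E731

    cur = np.arange(pop.n)
    for g in range(1, random_gens + 1):
        females = sex(cur, "F")
        mate = sex(cur, "M")[rng.integers(0, sex(cur, "M").size, females.size)]
        dams, sires = np.repeat(females, 2), np.repeat(mate, 2)
        cur = pop.breed(sires, dams, g, genome.mutation_rate)
        if g < random_gens:
            cur = np.concatenate([
                rng.choice(sex(cur, "M"), n_sires, replace=False),
                rng.choice(sex(cur, "F"), n_dams, replace=False),
            ])

    def current_records():
        females = np.flatnonzero((np.asarray(pop.sex) == "F") & (np.asarray(pop.sire) >= 0))
        qtn_dos = pop.dosages(females, pop.loci.qtn_index).astype(float)
        y = trait.overall_mean + qtn_dos @ effects + pop.residuals()[females]
        return females, y

    # line formation from EBV strata
    females, y = current_records()
    ebv = pop.ebv(y, females, h2)
    males_c, females_c = sex(cur, "M"), sex(cur, "F")
    top_m = males_c[np.argsort(-ebv[males_c])][: n_lines * line_sires]
    top_f = females_c[np.argsort(-ebv[females_c])][: n_lines * line_dams]
    lines = [
        (top_m[j * line_sires:(j + 1) * line_sires],
         top_f[j * line_dams:(j + 1) * line_dams])
        for j in range(n_lines)
    ]
    g = random_gens
    for _ in range(line_gens):
        g += 1
        new_lines = []
        offspring = []
        for sires_l, dams_l in lines:
            mate = sires_l[rng.integers(0, sires_l.size, dams_l.size)]
            d, s = np.repeat(dams_l, 2), np.repeat(mate, 2)
            offspring.append(pop.breed(s, d, g, genome.mutation_rate))
        females, y = current_records()
        ebv = pop.ebv(y, females, h2)
        for off in offspring:
            m, f = sex(off, "M"), sex(off, "F")
            new_lines.append((
                m[np.argsort(-ebv[m])][:line_sires],
                f[np.argsort(-ebv[f])][:line_dams],
            ))
        lines = new_lines

    # pool the lines and mate randomly
    pool_m = np.concatenate([s for s, _ in lines])
    pool_f = np.concatenate([d for _, d in lines])
    cur_m, cur_f = pool_m, pool_f
    for _ in range(pooled_gens):
        g += 1
        mate = cur_m[rng.integers(0, cur_m.size, cur_f.size)]
        dams, sires = np.repeat(cur_f, 2), np.repeat(mate, 2)
        off = pop.breed(sires, dams, g, genome.mutation_rate)
        last_parents = np.concatenate([cur_m, cur_f])
        cur_m = rng.choice(sex(off, "M"), pool_m.size, replace=False)
        cur_f = rng.choice(sex(off, "F"), pool_f.size, replace=False)
        last = off

    genotyped = np.concatenate([last, last_parents])
    phenotyped = np.flatnonzero(np.asarray(pop.sire) >= 0)  # recent-born; females kept in _finalize
    return _finalize(pop, genotyped, phenotyped, genome, trait, effects, qf, rng)


def _simulate_dairy(founders, genome, trait, rng, *, n_sires=100, n_dams=1000,
                    n_gens=10, genotyped_gen=7) -> SimOutput:
    """Dairy design: 10 generations of EBV selection with inbreeding-minimizing
    mate allocation; only sires used in the genotyping generation are
    genotyped, and each has ~10 phenotyped daughters."""
    pop, effects, qf = _init_design(founders, genome, trait, n_sires, n_dams, rng)
    h2 = trait.heritability
    sex_arr = lambda: np.asarray(pop.sex)  # noqa: E731

    cur_m = np.flatnonzero(sex_arr() == "M")
    cur_f = np.flatnonzero(sex_arr() == "F")
    genotyped_sires = None
    for g in range(1, n_gens + 1):
        pairs = _min_inbreeding_allocation(pop, cur_m, cur_f, rng)
        dams = np.repeat(pairs[:, 1], 2)
        sires = np.repeat(pairs[:, 0], 2)
        off = pop.breed(sires, dams, g, genome.mutation_rate)
        if g == genotyped_gen + 1:
            # the sires that produced this generation were born in generation g-1
            genotyped_sires = np.unique(pairs[:, 0])
        if g < n_gens:
            females = np.flatnonzero((sex_arr() == "F") & (np.asarray(pop.sire) >= 0))
            qtn_dos = pop.dosages(females, pop.loci.qtn_index).astype(float)
            y = trait.overall_mean + qtn_dos @ effects + pop.residuals()[females]
            ebv = pop.ebv(y, females, h2)
            m, f = off[sex_arr()[off] == "M"], off[sex_arr()[off] == "F"]
            cur_m = m[np.argsort(-ebv[m])][:n_sires]
            cur_f = f[np.argsort(-ebv[f])][:n_dams]
    if genotyped_sires is None:  # short runs: genotype the last sires used
        genotyped_sires = np.unique(sires)
    phenotyped = np.flatnonzero(np.asarray(pop.sire) >= 0)
    return _finalize(pop, genotyped_sires, phenotyped, genome, trait, effects, qf, rng)


def _min_inbreeding_allocation(pop: _Population, sires, dams, rng) -> np.ndarray:
    """Greedy mate allocation minimizing parent kinship.

    Each dam (random order) is assigned to the candidate sire with the lowest
    pedigree relationship among those below quota (dams/sires per sire)."""
    ped = pop.pedigree(np.zeros(pop.n, bool), np.zeros(pop.n, bool))
    rel = kinship.relationship_block(ped, np.asarray(sires), np.asarray(dams))
    quota = int(np.ceil(dams.size / sires.size))
    count = np.zeros(len(sires), dtype=int)
    pairs = np.empty((dams.size, 2), dtype=np.int64)
    order = rng.permutation(dams.size)
    for k, j in enumerate(order):
        open_ = count < quota
        i = np.flatnonzero(open_)[np.argmin(rel[open_, j])]
        count[i] += 1
        pairs[k] = (sires[i], dams[j])
    return pairs


_DESIGNS = {"fish": _simulate_fish, "beef": _simulate_beef, "dairy": _simulate_dairy}


def simulate_recent(design: str, founders: np.ndarray, genome: GenomeSpec,
                    trait: TraitSpec, seed=None, **kwargs) -> SimOutput:
    """Run one recent-population design on a founder haplotype pool."""
    if design not in _DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {sorted(_DESIGNS)}")
    rng = np.random.default_rng(seed)
    return _DESIGNS[design](founders, genome, trait, rng, **kwargs)


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioPreset:
    """Bundled genome + trait + historical trajectory + recent design."""

    design: str
    genome: GenomeSpec
    trait: TraitSpec
    trajectory: tuple
    prop_male: float = 0.5
    recent_kwargs: dict = field(default_factory=dict)


def preset(species: str, scaled: bool = True) -> ScenarioPreset:
    """Study presets; ``scaled`` applies the documented desk-scale divisors.

    The fish recent design is already desk-scale (2040 animals, 1040
    genotyped), so scaling touches only its historical phase and it keeps the
    full 35,000-SNP panel; the large-fish design divided by 10 coincides with
    these sizes.  Cattle presets scale population sizes and the SNP panel by
    10 and the historical generations by the same factor as the sizes, which
    preserves the cumulative drift and hence the allele-frequency spectrum.
    """
    if species == "fish":
        traj = ((0, 500), (50, 310)) if scaled else ((0, 5000), (200, 3100))
        # the fish recent design is desk-scale, so the full printed SNP panel
        # is kept: thinning it would lengthen the QTN-to-nearest-SNP distance
        # and change the tagging power the study measures
        genome = FISH_GENOME
        return ScenarioPreset(
            design="fish", genome=genome,
            trait=TraitSpec(heritability=0.25, sex_limited=False),
            trajectory=traj, prop_male=0.32,
        )
    if species == "beef":
        traj = ((0, 100), (100, 5000), (200, 2300)) if scaled else \
               ((0, 1000), (1000, 50_000), (2000, 23_000))
        genome = scale_genome(CATTLE_GENOME) if scaled else CATTLE_GENOME
        kw = {} if scaled else dict(n_sires=200, n_dams=10_000, line_sires=10, line_dams=500)
        return ScenarioPreset(
            design="beef", genome=genome,
            trait=TraitSpec(heritability=0.30, sex_limited=True),
            trajectory=traj, recent_kwargs=kw,
        )
    if species == "dairy":
        traj = ((0, 100), (100, 5000), (200, 2300)) if scaled else \
               ((0, 1000), (1000, 50_000), (2000, 23_000))
        genome = scale_genome(CATTLE_GENOME) if scaled else CATTLE_GENOME
        kw = {} if scaled else dict(n_sires=1000, n_dams=20_000)
        return ScenarioPreset(
            design="dairy", genome=genome,
            trait=TraitSpec(heritability=0.35, sex_limited=True),
            trajectory=traj, recent_kwargs=kw,
        )
    raise ValueError(f"unknown species {species!r}")


def simulate_scenario(
    species: str,
    seed,
    scaled: bool = True,
    genome: GenomeSpec | None = None,
    trajectory=None,
    **overrides,
) -> SimOutput:
    """Historical phase + recent design for a species preset.

    The scenario seed is expanded into independent substreams for the two
    stages, so each is reproducible on its own.  ``genome``/``trajectory``
    and recent-design keyword overrides allow miniature versions of a preset
    for fast exploratory runs.
    """
    p = preset(species, scaled=scaled)
    genome = genome if genome is not None else p.genome
    trajectory = trajectory if trajectory is not None else p.trajectory
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(2)
    founders = simulate_historical(genome, trajectory, p.prop_male, seed=ss[0])
    kwargs = dict(p.recent_kwargs)
    kwargs.update(overrides)
    return simulate_recent(p.design, founders, genome, p.trait, seed=ss[1], **kwargs)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_scenario(sim: SimOutput, directory) -> None:
    """Emit pedigree/genotypes/map/phenotypes/qtn TSVs (lossless round-trip)."""
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    if sim.pedigree.n == 0:
        raise ValueError("empty pedigree")
    sim.pedigree.to_frame().to_csv(d / "pedigree.tsv", sep="\t", index=False)
    geno = pd.DataFrame(sim.panel.dosages, columns=sim.panel.map["snp_id"])
    geno.insert(0, "id", sim.panel.ids)
    geno.to_csv(d / "genotypes.tsv", sep="\t", index=False)
    sim.panel.map.to_csv(d / "map.tsv", sep="\t", index=False)
    sim.phenotypes.to_csv(d / "phenotypes.tsv", sep="\t", index=False)
    sim.qtn.to_csv(d / "qtn.tsv", sep="\t", index=False)


def read_scenario(directory):
    """Read back what :func:`write_scenario` wrote.

    Returns (pedigree, panel, phenotypes, qtn)."""
    from pathlib import Path

    d = Path(directory)
    ped = Pedigree.from_frame(pd.read_csv(d / "pedigree.tsv", sep="\t"))
    gmap = pd.read_csv(d / "map.tsv", sep="\t")
    geno = pd.read_csv(d / "genotypes.tsv", sep="\t")
    panel = GenotypePanel(
        ids=geno["id"].to_numpy(),
        dosages=geno.drop(columns="id").to_numpy(np.int8),
        map=gmap,
    )
    phen = pd.read_csv(d / "phenotypes.tsv", sep="\t")
    qtn = pd.read_csv(d / "qtn.tsv", sep="\t")
    return ped, panel, phen, qtn


def write_plink(sim: SimOutput, prefix) -> None:
    """PLINK .ped/.map export (alleles 1/2, cM in the genetic-distance column)."""
    from pathlib import Path

    prefix = Path(prefix)
    ped = sim.pedigree
    m = sim.panel.map
    with open(f"{prefix}.map", "w") as fh:
        for _, row in m.iterrows():
            fh.write(f"{row.chrom}\t{row.snp_id}\t{row.pos_cM}\t0\n")
    id2row = {i: r for r, i in enumerate(sim.panel.ids)}
    sex_code = {"M": 1, "F": 2}
    with open(f"{prefix}.ped", "w") as fh:
        for i in sim.panel.ids:
            r = id2row[i]
            j = i - 1
            sire = ped.sire[j] + 1 if ped.sire[j] >= 0 else 0
            dam = ped.dam[j] + 1 if ped.dam[j] >= 0 else 0
            dos = sim.panel.dosages[r]
            a = np.where(dos >= 1, 2, 1)
            b = np.where(dos == 2, 2, 1)
            alleles = " ".join(f"{x} {y}" for x, y in zip(a, b))
            fh.write(f"1 {i} {sire} {dam} {sex_code[ped.sex[j]]} -9 {alleles}\n")
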