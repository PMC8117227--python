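"""Simulator tests: genome layout, meiosis, historical phase, designs, I/O."""

import numpy as np
import pytest

from gwasim import evalviz, simdata
from gwasim.simdata import GenomeSpec, TraitSpec

from conftest import TINY_GENOME, make_panel


class TestGenomeSpec:
    def test_loci_layout_invariants(self):
        loci = TINY_GENOME.loci()
        assert loci.n == 580 + 29
        for c in range(1, 30):
            on = loci.chrom == c
            pos = loci.pos_cM[on]
            assert np.all(np.diff(pos) > 0)
            assert pos.min() >= 0 and pos.max() <= 100.0
            qtn = loci.pos_cM[on & loci.is_qtn]
            assert qtn == pytest.approx([50.0])
        # QTN positions never collide with panel SNPs
        snp_pos = set(zip(loci.chrom[loci.snp_index], loci.pos_cM[loci.snp_index]))
        qtn_pos = set(zip(loci.chrom[loci.qtn_index], loci.pos_cM[loci.qtn_index]))
        assert not snp_pos & qtn_pos

    def test_snp_count_split_evenly(self):
        loci = GenomeSpec(n_snps=35_000).loci()
        counts = np.bincount(loci.chrom[loci.snp_index])[1:]
        assert counts.sum() == 35_000
        assert counts.max() - counts.min() <= 1


class TestHistorical:
    def test_no_evolution_keeps_exact_founder_freq(self):
        genome = GenomeSpec(n_snps=58, mutation_rate=0.0)
        hap = simdata.simulate_historical(genome, [(0, 40)], seed=0)
        assert hap.shape == (80, 58 + 29)
        np.testing.assert_allclose(hap.mean(axis=0), 0.5)

    def test_allele_frequency_conserved_in_expectation(self):
        genome = GenomeSpec(n_snps=580, mutation_rate=0.0)
        hap0 = simdata.simulate_historical(genome, [(0, 200)], seed=1)
        hap5 = simdata.simulate_historical(genome, [(0, 200), (5, 200)], seed=1)
        drift = hap5.mean(axis=0) - hap0.mean(axis=0)
        assert abs(drift.mean()) < 0.005  # zero-mean drift across many loci

    def test_mutation_flip_count_matches_binomial_expectation(self):
        rng = np.random.default_rng(3)
        rate = 1e-3
        flips = []
        for _ in range(10):
            hap = np.zeros((200, 500), dtype=np.uint8)
            simdata._mutate(hap, rate, rng)
            flips.append(hap.sum())
        expected = 200 * 500 * rate
        sd = np.sqrt(expected)  # binomial, small rate
        assert abs(np.mean(flips) - expected) < 4 * sd / np.sqrt(len(flips))

    def test_single_sex_generation_aborts(self):
        genome = GenomeSpec(n_snps=29)
        with pytest.raises(ValueError, match="males|females"):
            simdata.simulate_historical(genome, [(0, 5), (2, 5)], prop_male=0.0)

    def test_adjacent_ld_exceeds_long_range_ld(self):
        genome = GenomeSpec(n_snps=580, n_chromosomes=29)
        hap = simdata.simulate_historical(genome, [(0, 60), (30, 40)], seed=5)
        loci = genome.loci()
        dosages = hap[0::2] + hap[1::2]
        panel = make_panel(
            dosages[:, loci.snp_index],
            chrom=loci.chrom[loci.snp_index],
            pos=loci.pos_cM[loci.snp_index],
        )
        curve = evalviz.ld_decay(panel, max_dist_cM=60.0, bin_width=10.0, seed=0)
        near = curve["mean_r2"].iloc[0]
        far = curve[curve["dist_lo_cM"] >= 40]["mean_r2"].mean()
        assert near > far  # monotone-decay signature of linkage disequilibrium


class TestMeiosis:
    def test_zero_length_chromosome_copies_one_haplotype(self):
        loci = simdata.Loci(
            chrom=np.ones(5, np.int16), pos_cM=np.zeros(5), is_qtn=np.zeros(5, bool)
        )
        pair = np.array([[0, 0, 0, 0, 0], [1, 1, 1, 1, 1]], dtype=np.uint8)
        for seed in range(8):
            g = simdata.meiosis(pair, loci, np.random.default_rng(seed))
            assert g.sum() in (0, 5)  # intact copy of either haplotype

    def test_homozygous_parent_gives_identical_gamete(self):
        loci = GenomeSpec(n_snps=58).loci()
        hap = np.ones((2, loci.n), dtype=np.uint8)
        g = simdata.meiosis(hap, loci, np.random.default_rng(0))
        np.testing.assert_array_equal(g, hap[0])

    def test_crossovers_average_one_per_morgan(self):
        genome = GenomeSpec(n_chromosomes=1, n_snps=1000)
        loci = genome.loci()
        pair = np.zeros((2, loci.n), dtype=np.uint8)
        pair[1] = 1  # gamete reads out the source-haplotype parity directly
        rng = np.random.default_rng(11)
        n = 3000
        gam = simdata._gametes(np.tile(pair, (1, 1)), np.zeros(n, dtype=np.intp), loci, rng)
        crossovers = (np.diff(gam.astype(int), axis=1) != 0).sum(axis=1)
        se = crossovers.std() / np.sqrt(n)
        assert abs(crossovers.mean() - 1.0) < 3 * se


class TestQtnEffects:
    def test_single_qtn_closed_form_scaling(self):
        # dosage variance 0.5 (HWE at p=0.5) -> |effect| = sqrt(V / 0.5)
        trait = TraitSpec(heritability=0.25)
        dosages = np.array([[0], [1], [1], [2]] * 50)  # var = 0.5 exactly
        eff = simdata.assign_qtn_effects(GenomeSpec(n_snps=29), trait, dosages, seed=0)
        v_target = trait.genetic_variance
        assert abs(eff[0]) == pytest.approx(np.sqrt(v_target / 0.5))

    def test_monomorphic_qtn_aborts(self):
        trait = TraitSpec(heritability=0.25)
        with pytest.raises(ValueError, match="monomorphic"):
            simdata.assign_qtn_effects(
                GenomeSpec(n_snps=29), trait, np.full((10, 29), 2.0), seed=0
            )

    def test_gamma_effect_magnitudes_right_skewed(self):
        trait = TraitSpec(heritability=0.25)
        rng = np.random.default_rng(0)
        dosages = rng.integers(0, 3, size=(100, 29)).astype(float)
        eff = np.abs(simdata.assign_qtn_effects(GenomeSpec(n_snps=29), trait, dosages, seed=1))
        from scipy.stats import skew

        assert skew(eff) > 0


class TestDesigns:
    def test_fish_counts_match_study_design(self, tiny_fish):
        ped = tiny_fish.pedigree
        assert int(ped.phenotyped.sum()) == 2040
        assert int(ped.genotyped.sum()) == 1040
        ped.validate()  # acyclic, topologically ordered, sexes consistent

    def test_fish_realized_heritability(self, tiny_fish):
        phen = tiny_fish.phenotypes
        resid = phen["value"] - phen["tbv"]
        slope = np.cov(phen["value"], phen["tbv"])[0, 1] / phen["tbv"].var()
        h2 = phen["tbv"].var() / phen["value"].var()
        assert slope == pytest.approx(1.0, abs=0.15)
        assert h2 == pytest.approx(0.25, abs=0.07)
        assert resid.var() == pytest.approx(1.0, abs=0.1)

    def test_dairy_flags_sex_limited(self):
        sim = simdata.simulate_scenario(
            "dairy", seed=2, genome=TINY_GENOME, trajectory=((0, 60), (5, 60)),
            n_sires=5, n_dams=25, n_gens=3, genotyped_gen=2,
        )
        ped = sim.pedigree
        assert not np.any(ped.genotyped & (ped.sex == "F"))
        assert not np.any(ped.phenotyped & (ped.sex == "M"))
        assert int(ped.genotyped.sum()) == 5

    def test_beef_lines_and_flags(self):
        sim = simdata.simulate_scenario(
            "beef", seed=2, genome=TINY_GENOME, trajectory=((0, 60), (5, 60)),
            n_sires=4, n_dams=40, n_lines=2, line_sires=1, line_dams=8,
            line_gens=1, pooled_gens=2,
        )
        ped = sim.pedigree
        assert not np.any(ped.phenotyped & (ped.sex == "M"))  # sex-limited
        last = ped.generation == ped.generation.max()
        assert np.all(ped.genotyped[last])  # last generation genotyped

    def test_same_seed_reproduces_everything(self):
        a = simdata.simulate_scenario(
            "fish", seed=42, genome=TINY_GENOME, trajectory=((0, 60), (5, 50))
        )
        b = simdata.simulate_scenario(
            "fish", seed=42, genome=TINY_GENOME, trajectory=((0, 60), (5, 50))
        )
        np.testing.assert_array_equal(a.pedigree.sire, b.pedigree.sire)
        np.testing.assert_array_equal(a.panel.dosages, b.panel.dosages)
        np.testing.assert_array_equal(
            a.phenotypes["value"].to_numpy(), b.phenotypes["value"].to_numpy()
        )


class TestIO:
    def test_roundtrip_and_plink(self, tiny_fish, tmp_path):
        simdata.write_scenario(tiny_fish, tmp_path)
        ped, panel, phen, qtn = simdata.read_scenario(tmp_path)
        np.testing.assert_array_equal(ped.sire, tiny_fish.pedigree.sire)
        np.testing.assert_array_equal(panel.dosages, tiny_fish.panel.dosages)
        np.testing.assert_allclose(
            phen["value"].to_numpy(), tiny_fish.phenotypes["value"].to_numpy()
        )
        np.testing.assert_allclose(
            qtn["effect"].to_numpy(), tiny_fish.qtn["effect"].to_numpy()
        )
        simdata.write_plink(tiny_fish, tmp_path / "panel")
        map_lines = (tmp_path / "panel.map").read_text().splitlines()
        ped_lines = (tmp_path / "panel.ped").read_text().splitlines()
        assert len(map_lines) == tiny_fish.panel.n_snps
        assert len(ped_lines) == tiny_fish.panel.n_animals

    def test_empty_pedigree_rejected(self, tiny_fish, tmp_path):
        import dataclasses

        empty_ped = simdata.Pedigree(
            sire=np.empty(0, int), dam=np.empty(0, int), sex=np.empty(0, str),
            generation=np.empty(0, int), genotyped=np.empty(0, bool),
            phenotyped=np.empty(0, bool),
        )
        broken = dataclasses.replace(tiny_fish, pedigree=empty_ped)
        with pytest.raises(ValueError, match="empty pedigree"):
            simdata.write_scenario(broken, tmp_path)


def test_unordered_pedigree_rejected():
    with pytest.raises(ValueError, match="topologically"):
        simdata.Pedigree(
            sire=np.array([1, -1]), dam=np.array([-1, -1]),
            sex=np.array(["F", "M"]), generation=np.array([0, 0]),
            genotyped=np.zeros(2, bool), phenotyped=np.zeros(2, bool),
        )
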