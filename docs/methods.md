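# Methods

This note records the models implemented in `gwasim`, the defaults and why
they were chosen, the numerical decisions, and what the simulations can and
cannot say about real data.

## Simulation model

**Genome.** 29 chromosomes of 100 cM. SNPs are evenly spaced — the i-th of
`n` SNPs on a chromosome sits at `(i + 0.25)·100/n` cM, a quarter-step offset
grid that can never coincide with the causal locus — and one QTN per
chromosome sits at the 50 cM midpoint. All loci are biallelic, start at
frequency 0.5 in the first historical generation, and mutate recurrently
(allele flips) at 2.5 × 10⁻⁵ per locus per generation; mutation applies to
SNPs and QTN alike.

**Meiosis.** Haldane model: crossover counts per chromosome are Poisson with
mean length/100 cM, positions uniform, no interference, plus independent
assortment across chromosomes. Implementation draws the crossover events
sparsely (Poisson per inter-locus interval; the source haplotype flips with
the parity of the count), so cost scales with map length rather than marker
count. This is exactly equivalent, for loci observed at fixed positions, to
per-interval Bernoulli recombination with the Haldane map function.

**Historical phase.** Random union of gametes with separate sexes and a
piecewise-linear population-size trajectory. Generation 0 is founded at
*exactly* frequency 0.5 per locus (fixed allele counts, random placement), so
a zero-generation, zero-mutation run reproduces the founder frequencies
identically — a useful contract for testing.

**Recent designs.** Each dam is mated to a single sire per generation, so
litters are full-sib families (this matters: the fish design's hallmark is
its 20 full-sib blocks of 100, and half-sib litters would dilute exactly the
structure the study is about).

- *Fish* (h² = 0.25, both sexes phenotyped): 20 sires × 20 dams, five
  generations of random mating/culling at 2 offspring per female, then one
  final generation of 20 × 20 with litter size 100. The final line plus its
  parents (2,040 animals) are phenotyped; the parents plus a random 1,000 of
  the line (1,040) are genotyped. Historical phase for the default scaled
  preset: 500 → 310 over 50 generations with 32% males.
- *Beef* (h² = 0.30, sex-limited): founders 20 sires × 1,000 dams, five
  random generations; then five lines founded from EBV strata (top sires and
  dams ranked and split), each bred two generations with within-line
  truncation selection on EBV; the lines' best animals (1 sire + 50 dams
  each) are pooled and randomly mated for five generations. Last generation
  plus its parents genotyped; all recent females phenotyped.
- *Dairy* (h² = 0.35, sex-limited): 100 sires × 1,000 dams per generation,
  ten generations of EBV selection of sires (all daughters become dams) with
  greedy inbreeding-minimizing mate allocation (each dam is assigned, in
  random order, to the quota-limited sire with the lowest pedigree kinship).
  Only the 100 sires used in generation 7 are genotyped; with 2 offspring
  per dam each has ~10 phenotyped daughters, the ratio that makes the
  deregression problem interesting. Cattle historical phase:
  100 → 5,000 → 2,300 over 200 generations.

**Trait.** QTN effect magnitudes are gamma(shape 0.40) with random sign,
rescaled once so the variance of the total QTN value among the recent
population's founders equals h²/(1 − h²) with residual variance fixed at 1;
the QTN therefore carry all genetic variance. Phenotype = 1.0 + Σ QTN
dosage·effect + N(0, 1), drawn once per animal at birth so in-simulation
selection and the final records see the same values. True breeding values
are retained for validation only.

**In-simulation EBV.** Selection uses pedigree BLUP with the true variance
ratio (sparse Henderson A⁻¹ with Meuwissen–Luo inbreeding, Jacobi-
preconditioned conjugate gradients). The alternative — phenotypic selection —
would understate the structure that EBV selection creates across lines.

## Scaling choices (and their rationale)

Full-size cattle scenarios (historical populations to 50,000 × 65,000 loci ×
2,000 generations) are not desk-scale. The shipped presets therefore scale:

- population sizes ÷ 10 for the cattle designs and the fish historical phase;
- historical generations ÷ 4 for fish (200 → 50) and ÷ 10 for cattle
  (2,000 → 200): matching the size divisor keeps the cumulative drift
  Σ 1/(2Nₜ) — and with it the terminal allele-frequency spectrum, hence the
  QC retention rate — at the full-size value;
- the cattle SNP panel ÷ 10 (6,500 SNPs): the quantities measured there
  (false-positive counts of kinship-aware methods, retention *fraction*) are
  density-insensitive, which we verified empirically;
- the fish panel is **not** thinned (35,000 SNPs): thinning 10× while
  keeping the cM map stretches the QTN-to-nearest-tag distance 10×, lowers
  tag r², and collapses detection power — it changes the measured quantity,
  not just its units. The fish recent design is small enough (2,240-animal
  pedigree) to carry the full panel.

The fish design at printed size *is* the ÷10 scaling of its large variant,
so one set of fish replicates serves both.

## Association methods

All four share the per-SNP output (effect, SE, two-sided p from the standard
normal reference) so comparisons are like-for-like; using the normal rather
than t reference for OLS is a deliberate harmonization, negligible at these
sample sizes.

- **SSA-NoCor**: closed-form OLS per SNP; monomorphic SNPs are flagged with
  p = 1 rather than dropped.
- **EMMAX**: the null-model variance components (exact spectral REML, below)
  are fixed for all SNPs — the defining EMMAX approximation. The kinship is
  the marker-sample-mean construction `G = (1/k) Σ (x_i − x̄_i)(x_i − x̄_i)'`.
  Per-SNP GLS is computed in the whitened eigenbasis of G, one matrix
  multiply for the whole panel.
- **GBLUP-GWAS**: VanRaden G (centering by twice the current allele
  frequencies of the genotyped sample) blended as `G = 0.95 G₀ + 0.05 I`;
  MME solved once with the full animal block of the inverse coefficient
  matrix; effects back-solved with the λ = 0.95 blending proportion in the
  scale factor; `Var(ĝᵢ)` from `G σ̂²ₐ − PEV` with PEV = C²²σ̂²ₑ (the only
  unit-consistent reading of the back-solving variance).
- **ssGWAS**: G additionally tuned so its mean diagonal and mean
  off-diagonal match A₂₂ (two-coefficient `a + bG` adjustment, solved
  exactly), which fixes the genetic-base mismatch; the residual base scalar
  δ = 1 − (0.5/n²)(ΣΣA₂₂ − ΣΣG) is then 1 by construction but is computed and
  carried through Eq-for-Eq so untuned configurations remain valid. H⁻¹ is
  assembled sparsely for large pedigrees; C²² for the genotyped block is
  extracted by unit-column solves from one LU factorization (minimum-degree
  ordering), so dairy-style systems (21,100 animals, 100 genotyped) stay
  cheap. Order of operations: construct G₀ → blend → tune → invert.

A sqrt(λ) variant of the back-solving scale is selectable
(`sqrt_lambda=True`); the default is the plain λ factor. Non-positive
back-solved variances (floating-point cancellation) are clamped to a tiny
positive value and flagged rather than aborting a full-panel scan.

## REML

`reml_estimate` is an exact maximizer of the restricted likelihood for the
single-genetic-random-effect model: project out the fixed effects, take the
eigendecomposition of the projected kinship once, profile the likelihood on
the variance ratio γ = σ²ₐ/σ²ₑ, and maximize by grid bracketing plus bounded
scalar refinement. Compared with iterative EM-REML this cannot fail to
converge and costs one O(n³) decomposition; the trade-off is that it is
limited to one random effect, which is all these models need. Degenerate
records (zero residual contrast) return boundary values instead of crashing.
A "true values" bypass supplies the simulation's variance components where
REML would be wasteful; the pipeline uses REML for the per-SNP methods and
the true values for the large sparse single-step systems.

## Quality control

Rules in order, strict inequalities, computed on the genotyped sample:
monomorphic; MAF < 0.05 (a locus at exactly 0.05 is kept); |observed
heterozygote frequency − 2pq| > 0.15. The third rule interprets the
"deviation between observed and expected frequencies" criterion as a
Hardy–Weinberg heterozygosity check, the convention of the software family
this pipeline mirrors; an allele-frequency-vs-0.5 alternative is available
behind `mode="freq"`. QTN are separate loci, never in the panel, so never
filtered.

## Deregressed proofs

For sex-limited scenarios the genotyped sires' EBV are deregressed:
DE_PA = rel_PA/(1 − rel_PA), DE_prog = rel_EBV/(1 − rel_EBV) − DE_PA,
DRP = PA + (EBV − PA)(DE_prog + DE_PA + 1)/DE_prog, with
rel_PA = (rel_sire + rel_dam)/4 and missing parents contributing zero.
Animals with DE_prog ≤ 0 have no progeny information beyond the parent
average and are excluded with a warning. DRP enter downstream GWAS
unweighted (the per-SNP models are unweighted); a daughter-equivalent weight
column is emitted for optional use.

## Evaluation layer

Significance at 0.05/n (Bonferroni over retained SNPs). A significant SNP
within ±2 cM (inclusive) of a same-chromosome QTN is a true positive,
otherwise a false positive; counts are per significant SNP, the only reading
under which count summaries can exceed the number of QTN. ROC curves sweep
the p-value threshold with the same window as truth label; the trapezoidal
area equals the Mann–Whitney statistic (tested as an identity). LD decay is
the squared dosage correlation of sampled same-chromosome pairs binned by cM
distance. PCA of G is a symmetric eigendecomposition with
eigenvalue-scaled scores. Effective population size is 1/(2·ΔF̄) with
ΔF = (Fₙ − Fₙ₋₁)/(1 − Fₙ₋₁) from the pedigree-realized mean inbreeding per
generation. The averaged rate ΔF̄ is the geometric mean of the survival
fractions (1 − ΔFₙ), which telescopes to the endpoint form
1 − ((1−F_T)/(1−F₁))^{1/(T−1)}: per-generation mean F fluctuates strongly at
census sizes of a few tens (single differences can even be negative), and
the endpoint form estimates the same rate with far lower variance, reducing
to the arithmetic mean exactly on constant-rate trajectories such as the
closed-form checks (ΔF = 0.0125 → Ne = 40). The founder-to-first-offspring
transition is excluded since unrelated founders cannot produce inbreeding in
one step. Note that a design fixing every dam at the same litter size with
no culling (the fish nucleus) has zero female family-size variance, so its
realized Ne sits somewhat above the census formula 4NₘN_f/(Nₘ+N_f).

## What the generator does and does not emulate

It reproduces: LD build-up by drift in a shrinking historical population,
mutation–drift balance, family blocking (full-sib litters), EBV-driven
selection structure across lines and generations, sex-limited recording, and
genotyping confined to selected strata. It does not model: genotyping or
pedigree errors, overlapping generations, multi-trait selection, dominance
or epistasis, non-Gaussian residuals, or marker ascertainment bias. Passing
tests therefore demonstrate correct method behaviour *under the stated
population models*, not robustness to the measurement pathologies of real
data.

A caveat on replicate dispersion: QTN effects are redrawn from the gamma
each replicate, so detection counts vary substantially across replicates
(the handful of large-effect QTN dominate power). Study summaries average
over five replicates; per-replicate counts should be read with that
dispersion in mind.

## Numerical choices

- Pedigree A: vectorized tabular method (dense) up to 3,000 animals; above
  that, inbreeding via a numba-compiled ancestor recursion, sparse Henderson
  A⁻¹, and any required block of A via two sparse triangular solves of the
  pedigree Cholesky structure A = (I−P)⁻¹D(I−P)⁻ᵀ.
- MME: dense LU at desk scale; sparse path uses Jacobi-preconditioned CG
  (rtol 1e-12) when only solutions are needed and a minimum-degree-ordered
  LU when inverse blocks are requested.
- Blending guarantees the smallest eigenvalue of G is ≥ β = 0.05, so G⁻¹ is
  always well-defined after blending; unblended singular G aborts with an
  instruction to blend.
- Seeds: one scenario seed expands into per-stage substreams
  (`numpy.random.SeedSequence.spawn`), so the historical phase, the recent
  design and each replicate are independently reproducible.
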