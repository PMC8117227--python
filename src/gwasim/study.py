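"""Study orchestration: simulate -> QC -> (DRP) -> associate -> evaluate.

One replicate of a scenario runs the full chain for the requested methods;
``run_study`` repeats it, aggregates true/false-positive counts across
replicates (mean and SD) and attaches paired-test significance groups, the
usual summary of a simulation comparison of association methods.

Method inputs per species follow the study designs:

* fish  -- both sexes phenotyped and half the final line genotyped; the
           single-kinship methods use the genotyped animals' own phenotypes.
* beef  -- sex-limited trait; the single-kinship methods use the genotyped
           females with own records.
* dairy -- sex-limited with genotyped sires only; sire EBV are deregressed
           into pseudo-phenotypes for SSA-NoCor/EMMAX/GBLUP-GWAS, while
           ssGWAS uses the raw daughter records directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import ttest_rel

from . import assoc as assoc_mod
from . import drp as drp_mod
from . import evalviz, kinship, qc, simdata
from .mixedmodel import VarianceComponents, pedigree_blup, reliability

__all__ = ["ScenarioConfig", "ReplicateResult", "run_replicate", "run_study"]

METHODS = ("ssa", "emmax", "gblup", "ssgwas")
_METHOD_TAG = {
    "ssa": "SSA-NoCor",
    "emmax": "EMMAX",
    "gblup": "GBLUP-GWAS",
    "ssgwas": "ssGWAS",
}


@dataclass(frozen=True, eq=False)
class ScenarioConfig:
    """Declarative description of one study scenario."""

    species: str = "fish"
    scaled: bool = True
    n_replicates: int = 5
    seed: int = 1
    vc_source: str = "reml"  # 'reml' for the per-SNP methods, 'true' bypass
    methods: tuple = METHODS
    out_dir: str | None = None
    alpha: float = 0.05
    window_cM: float = evalviz.WINDOW_CM
    maf_min: float = 0.05
    dev_max: float = 0.15
    save_assoc: bool = False
    save_diagnostics: bool = False  # ROC / LD-decay / PCA tables, replicate 0
    #: overrides forwarded to simulate_scenario (genome, trajectory, design
    #: keywords) for miniature runs; empty for the standard presets
    sim_overrides: dict = field(default_factory=dict)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ReplicateResult:
    species: str
    replicate: int
    sim: simdata.SimOutput
    qc_report: qc.QcReport
    assoc: dict = field(default_factory=dict)  # method key -> AssocResult frame
    evals: dict = field(default_factory=dict)  # method key -> EvalSummary
    threshold: float = np.nan
    drp_table: pd.DataFrame | None = None

    def detected_qtn(self, method: str) -> int:
        """Number of distinct QTN with >= 1 significant SNP in their window."""
        df = self.assoc[method]
        sig = df[df["pvalue"] < self.threshold]
        if sig.empty:
            return 0
        count = 0
        for _, row in self.sim.qtn.iterrows():
            on = (sig["chrom"] == row["chrom"]) & (
                np.abs(sig["pos_cM"] - row["pos_cM"]) <= evalviz.WINDOW_CM
            )
            count += bool(on.any())
        return count


def _true_vc(trait: simdata.TraitSpec) -> VarianceComponents:
    return VarianceComponents(trait.genetic_variance, 1.0, source="true-simulation")


def _panel_rows(panel, animal_idx: np.ndarray) -> np.ndarray:
    lookup = {int(i) - 1: r for r, i in enumerate(panel.ids)}
    return np.array([lookup[int(i)] for i in animal_idx])


def _dairy_drp(sim: simdata.SimOutput, vc: VarianceComponents):
    """Pedigree BLUP on daughter records, then deregressed sire proofs."""
    ped = sim.pedigree
    rec_idx = sim.phenotypes["id"].to_numpy() - 1
    y = sim.phenotypes["value"].to_numpy()
    gidx = np.flatnonzero(ped.genotyped)
    parents = np.concatenate([ped.sire[gidx], ped.dam[gidx]])
    need = np.unique(np.concatenate([gidx, parents[parents >= 0]]))
    sol = pedigree_blup(ped, y, rec_idx, vc, c22_index=need)
    F = kinship.inbreeding(ped)
    rel_sub = reliability(sol.pev, vc.sigma2_a, 1.0 + F[need])
    rel = np.full(ped.n, np.nan)
    rel[need] = np.clip(rel_sub, 0.0, 1.0 - 1e-9)
    table = drp_mod.compute_drp(sol.a, rel, ped, animals=gidx)
    return table, sol


def run_replicate(config: ScenarioConfig, replicate: int, seed) -> ReplicateResult:
    """One full pass: simulate, QC, DRP where needed, associate, evaluate."""
    sim = simdata.simulate_scenario(
        config.species, seed, scaled=config.scaled, **config.sim_overrides
    )
    ped = sim.pedigree
    panel, report = qc.qc_filter(sim.panel, config.maf_min, config.dev_max)
    threshold = evalviz.bonferroni_threshold(panel.n_snps, config.alpha)
    res = ReplicateResult(
        species=config.species, replicate=replicate, sim=sim,
        qc_report=report, threshold=threshold,
    )

    phen = sim.phenotypes.set_index("id")["value"]
    single_methods = [m for m in config.methods if m != "ssgwas"]
    if single_methods:
        if config.species == "dairy":
            table, _ = _dairy_drp(sim, _true_vc(sim.trait))
            res.drp_table = table
            sub_ids = table["id"].to_numpy()
            y_single = table["drp"].to_numpy()
        else:
            both = np.flatnonzero(ped.genotyped & ped.phenotyped)
            sub_ids = both + 1
            y_single = phen.loc[sub_ids].to_numpy()
        sub_panel = panel.subset_animals(_panel_rows(panel, sub_ids - 1))
        vc_single = None if config.vc_source == "reml" else _true_vc(sim.trait)
        for m in single_methods:
            if m == "ssa":
                res.assoc[m] = assoc_mod.ssa_nocor(y_single, sub_panel)
            elif m == "emmax":
                res.assoc[m] = assoc_mod.emmax(y_single, sub_panel, vc=vc_single)
            elif m == "gblup":
                res.assoc[m] = assoc_mod.gblup_gwas(y_single, sub_panel, vc=vc_single)
            else:
                raise ValueError(f"unknown method {m!r}")

    if "ssgwas" in config.methods:
        rec_idx = sim.phenotypes["id"].to_numpy() - 1
        y_all = sim.phenotypes["value"].to_numpy()
        res.assoc["ssgwas"] = assoc_mod.ssgwas(
            y_all, rec_idx, ped, panel, vc=_true_vc(sim.trait)
        )

    for m, df in res.assoc.items():
        res.evals[m] = evalviz.classify_tp_fp(
            df, sim.qtn, threshold, config.window_cM, replicate=replicate
        )
    return res


def _significance_groups(counts: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Letter groups from paired t-tests across replicates (same letter =
    no significant paired difference)."""
    methods = list(counts.columns)
    groups: list[list[str]] = []
    for m in sorted(methods, key=lambda m: counts[m].mean()):
        placed = False
        for grp in groups:
            ok = True
            for other in grp:
                d = counts[m] - counts[other]
                if np.allclose(d, d.iloc[0]):
                    p = 1.0 if np.allclose(d, 0) else (0.0 if abs(d.iloc[0]) > 0 else 1.0)
                else:
                    p = ttest_rel(counts[m], counts[other]).pvalue
                if p < alpha:
                    ok = False
                    break
            if ok:
                grp.append(m)
                placed = True
                break
        if not placed:
            groups.append([m])
    letters = {}
    for letter, grp in zip("abcdefgh", groups):
        for m in grp:
            letters[m] = letters.get(m, "") + letter
    return letters


def run_study(config: ScenarioConfig, force: bool = False):
    """Run all replicates of a scenario and aggregate TP/FP counts.

    Returns (aggregate DataFrame, list of ReplicateResult).  When ``out_dir``
    is set, per-replicate and aggregate tables are written there under a
    config-hash subdirectory; an existing aggregate short-circuits the run
    unless ``force``.
    """
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir) / f"{config.species}-{config.digest()}"
        agg_path = out / "aggregate.tsv"
        if agg_path.exists() and not force:
            return pd.read_csv(agg_path, sep="\t"), []
        out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    results = [run_replicate(config, r, seeds[r]) for r in range(config.n_replicates)]

    rows = []
    for res in results:
        for m, ev in res.evals.items():
            rows.append(
                dict(method=_METHOD_TAG[m], replicate=res.replicate,
                     tp=ev.tp, fp=ev.fp, threshold=ev.threshold,
                     n_snps=res.qc_report.n_retained)
            )
    evals = pd.DataFrame(rows)
    agg_rows = []
    for kind in ("tp", "fp"):
        counts = evals.pivot(index="replicate", columns="method", values=kind)
        letters = _significance_groups(counts) if len(counts) > 1 else {}
        for m in counts.columns:
            agg_rows.append(
                dict(metric=kind.upper(), method=m, mean=counts[m].mean(),
                     sd=counts[m].std(ddof=1) if len(counts) > 1 else 0.0,
                     group=letters.get(m, ""))
            )
    aggregate = pd.DataFrame(agg_rows)

    if out is not None:
        evals.to_csv(out / "eval_summary.tsv", sep="\t", index=False)
        aggregate.to_csv(out / "aggregate.tsv", sep="\t", index=False)
        if config.save_assoc:
            for res in results:
                for m, df in res.assoc.items():
                    df.to_csv(out / f"assoc_{m}_rep{res.replicate}.tsv",
                              sep="\t", index=False)
        if config.save_diagnostics:
            _write_diagnostics(results[0], out, config)
    return aggregate, results


def _write_diagnostics(res: ReplicateResult, out: Path, config: ScenarioConfig):
    """ROC per method, LD-decay curve and PCA of G for one replicate."""
    for m, df in res.assoc.items():
        points, area = evalviz.roc_curve(df, res.sim.qtn, config.window_cM)
        points.insert(0, "method", _METHOD_TAG[m])
        points.attrs["area"] = area
        points.to_csv(out / f"roc_{m}.tsv", sep="\t", index=False)
    panel, _ = qc.qc_filter(res.sim.panel, config.maf_min, config.dev_max)
    evalviz.ld_decay(panel, seed=0).to_csv(out / "ld_decay.tsv", sep="\t", index=False)
    G = kinship.blend_G(kinship.build_G_vanraden(panel.dosages))
    scores, _ = evalviz.pca_of_G(G)
    pd.DataFrame(
        {"id": panel.ids, "pc1": scores[:, 0], "pc2": scores[:, 1]}
    ).to_csv(out / "pca_scores.tsv", sep="\t", index=False)
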