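"""End-to-end experiment orchestration.

One *population replicate* runs the demographic simulation once, builds
the requested experimental datasets (two F2 crosses in a small- and a
large-founder variant, their pooled sets, and the purebred comparison
population), and reuses them for several *trait replicates*: each trait
draws fresh QTN and effects, simulates phenotypes, runs the mixed-model
GWAS per dataset and scenario, and computes the mapping metrics.  The
reference protocol is 10 population replicates x 5 traits = 50 trait
replicates.

Scale: the shipped default runs the demography rescaled by ``lam = 10``
(Ne and epoch lengths divided by 10, mutation rate multiplied by 10),
which preserves drift intensities and diversity; ``lam = 1`` reproduces
the full-scale history (long-running).  ``rescale_mutation=False``
additionally leaves the mutation rate at its base value, giving a
variant-density-reduced run whose per-variant statistics (F_ST, allele
frequency spectra) are unchanged — the configuration used for quick
studies.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross import (
    CrossDataset,
    CrossDesign,
    founder_pool,
    make_purebred,
    pool_crosses,
)
from .genome import DemographyPlan, GenomeSpec, pig_demography_plan, rescale_plan
from .gwas import mlma_loco
from .metrics import (
    FounderFrequencies,
    ScenarioConfig,
    aggregate,
    power_by_qtn_variance,
    replicate_metrics,
    scenario_sets,
)
from .popgen import allele_frequencies, breed_fst, union_segregating
from .simulate import run_demography
from .trait import add_residuals, breeding_values, sample_effects, select_qtn

_CROSS_DATASETS = {
    "EU1xEU2_small": ("EU1", "EU2", 2, 10),
    "EU1xEU2_large": ("EU1", "EU2", 10, 50),
    "ASxEU2_small": ("AS", "EU2", 2, 10),
    "ASxEU2_large": ("AS", "EU2", 10, 50),
}
_POOLED = {
    "pooled_small": ("EU1xEU2_small", "ASxEU2_small"),
    "pooled_large": ("EU1xEU2_large", "ASxEU2_large"),
}
_PUREBRED = {"EU2_500": 500, "EU2_1000": 1000}


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment."""

    genome: GenomeSpec = field(default_factory=GenomeSpec)
    plan: DemographyPlan = field(default_factory=pig_demography_plan)
    lam: float = 10.0
    rescale_mutation: bool = True
    datasets: tuple[str, ...] = (
        "EU1xEU2_small", "ASxEU2_small", "pooled_small",
        "EU1xEU2_large", "ASxEU2_large", "pooled_large",
        "EU2_500", "EU2_1000",
    )
    scenarios: tuple[str, ...] = ("ASG", "FSG")
    n_population_replicates: int = 10
    n_traits_per_population: int = 5
    qtn_per_chrom: int = 20
    qtn_min_distance: float = 0.02
    h2: float = 0.5
    alpha: float = 0.05
    maf_threshold: float = 0.05
    purebred_n: int = 1000
    fst_sample: int = 100
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_population_replicates < 1 or self.n_traits_per_population < 1:
            raise ValueError("replicate counts must be >= 1")
        unknown = (set(self.datasets) - set(_CROSS_DATASETS)
                   - set(_POOLED) - set(_PUREBRED))
        if unknown:
            raise ValueError(f"unknown datasets: {sorted(unknown)}")

    @property
    def run_plan(self) -> DemographyPlan:
        return rescale_plan(self.plan, self.lam)

    @property
    def run_genome(self) -> GenomeSpec:
        return self.genome.rescaled(self.lam) if self.rescale_mutation \
            else self.genome

    def scenario_config(self, scenario: str) -> ScenarioConfig:
        return ScenarioConfig(scenario=scenario, alpha=self.alpha,
                              maf_threshold=self.maf_threshold)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        """Load a configuration from YAML.

        Optional sections: ``genome`` (GenomeSpec fields) and
        ``demography`` with ``epochs`` (lineage -> [[start, end, ne], ...]),
        ``splits`` ([[generation, parent, [child, child]], ...]) and
        ``lam``; all other keys map directly onto the dataclass fields.
        """
        from .genome import Epoch, Split

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        if "genome" in raw:
            kwargs["genome"] = GenomeSpec(**raw.pop("genome"))
        if "demography" in raw:
            demo = raw.pop("demography")
            kwargs["plan"] = DemographyPlan(
                epochs={name: tuple(Epoch(*e) for e in eps)
                        for name, eps in demo["epochs"].items()},
                splits=tuple(Split(g, parent, tuple(children))
                             for g, parent, children in
                             demo.get("splits", [])),
            )
            if "lam" in demo:
                kwargs["lam"] = demo["lam"]
        for key in ("datasets", "scenarios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PopulationReplicate:
    """Cached simulation products shared by the traits of one replicate."""

    index: int
    breeds: dict
    datasets: dict[str, CrossDataset]
    founder_freqs: FounderFrequencies
    qtn_candidates: list[np.ndarray]
    fst: dict[str, float]
    manifest: dict


def _required_crosses(datasets) -> list[str]:
    need = [d for d in datasets if d in _CROSS_DATASETS]
    for name in datasets:
        if name in _POOLED:
            need.extend(_POOLED[name])
    return sorted(set(need), key=list(_CROSS_DATASETS).index)


def build_population_replicate(config: ExperimentConfig, index: int,
                               seed_seq: np.random.SeedSequence
                               ) -> PopulationReplicate:
    """Demography + experimental populations of one population replicate."""
    t0 = time.time()
    ss_demo, ss_cross, ss_fst = seed_seq.spawn(3)
    plan = config.run_plan
    spec = config.run_genome
    breeds = run_demography(plan, spec, ss_demo)
    rng = np.random.Generator(np.random.PCG64(ss_cross))
    key = f"rep{index}"

    crosses_needed = _required_crosses(config.datasets)
    datasets: dict[str, CrossDataset] = {}

    # founder pools: grown where the desk-scale breed is too small, with
    # the shared founder breed's animals kept disjoint between crosses
    demand: dict[str, int] = {}
    for name in crosses_needed:
        sire_b, dam_b, n_s, n_d = _CROSS_DATASETS[name]
        demand[sire_b] = demand.get(sire_b, 0) + n_s
        demand[dam_b] = demand.get(dam_b, 0) + n_d
    pools = {b: founder_pool(breeds[b], demand.get(b, 0), spec, rng)
             for b in breeds}
    available = {b: set(range(pools[b].n_individuals)) for b in pools}

    from .cross import make_f1, make_f2, sample_founders

    for name in crosses_needed:
        sire_b, dam_b, n_s, n_d = _CROSS_DATASETS[name]
        design = CrossDesign(sire_b, dam_b, n_s, n_d, name=name)
        f0 = sample_founders(
            pools[sire_b], pools[dam_b], design, rng, replicate_key=key,
            sire_candidates=sorted(available[sire_b]),
            dam_candidates=sorted(available[dam_b]))
        # founder animals of the shared breed are disjoint between crosses:
        # the pool is sized to the total demand, so exclusion is always safe
        available[sire_b] -= set(int(i) for i in f0.sire_indices)
        available[dam_b] -= set(int(i) for i in f0.dam_indices)
        datasets[name] = make_f2(make_f1(f0, spec, rng), spec, rng)

    for name in config.datasets:
        if name in _POOLED:
            a, b = _POOLED[name]
            datasets[name] = pool_crosses(datasets[a], datasets[b])
            datasets[name].name = name

    purebred_full = None
    if any(name in _PUREBRED for name in config.datasets):
        purebred_full = make_purebred(breeds["EU2"], config.purebred_n, spec,
                                      rng, replicate_key=key)
    for name in config.datasets:
        if name in _PUREBRED:
            n = _PUREBRED[name]
            if n == purebred_full.n_individuals:
                ds = purebred_full.subset(np.arange(n))
            else:
                idx = rng.choice(purebred_full.n_individuals, n, replace=False)
                ds = purebred_full.subset(np.sort(idx))
            ds.name = name
            datasets[name] = ds

    fst_rng = np.random.Generator(np.random.PCG64(ss_fst))
    fst = {
        "EU1-EU2": breed_fst(breeds["EU1"], breeds["EU2"],
                             n_sample=config.fst_sample, rng=fst_rng),
        "AS-EU2": breed_fst(breeds["AS"], breeds["EU2"],
                            n_sample=config.fst_sample, rng=fst_rng),
    }
    manifest = {
        "replicate": index,
        "seed_entropy": str(seed_seq.entropy),
        "version": __version__,
        "n_breed_variants": {b: breeds[b].n_variants for b in breeds},
        "wall_time_populations": time.time() - t0,
    }
    return PopulationReplicate(
        index=index,
        breeds=breeds,
        datasets=datasets,
        founder_freqs=FounderFrequencies(breeds["EU2"]),
        qtn_candidates=union_segregating(list(breeds.values())),
        fst=fst,
        manifest=manifest,
    )


def run_trait_replicate(config: ExperimentConfig, pop: PopulationReplicate,
                        trait_index: int, seed_seq: np.random.SeedSequence,
                        *, collect_figures: bool = False):
    """One trait replicate on the cached populations of ``pop``.

    Draws QTN and effects (shared across all datasets of the replicate),
    anchors the residual variance per founder-size family to its pooled
    dataset (per-dataset for the purebred population), runs the GWAS per
    dataset x scenario and returns the metric records.
    """
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    qtn_chrom, qtn_pos = select_qtn(pop.qtn_candidates, rng,
                                    qtn_per_chrom=config.qtn_per_chrom,
                                    min_distance=config.qtn_min_distance)
    effects = sample_effects(len(qtn_pos), rng)

    # phenotypes: one draw per individual, shared between a single-cross
    # analysis and the pooled analysis of the same family
    phenotypes: dict[str, np.ndarray] = {}
    var_y: dict[str, float] = {}
    for family in ("small", "large"):
        members = [n for n in (f"EU1xEU2_{family}", f"ASxEU2_{family}")
                   if n in pop.datasets]
        if not members:
            continue
        doses = [pop.datasets[n].doses_at(qtn_chrom, qtn_pos) for n in members]
        pooled_doses = np.concatenate(doses, axis=0)
        p_ref = allele_frequencies(pooled_doses)
        bv = breeding_values(pooled_doses, p_ref, effects)
        phen = add_residuals(bv, config.h2, rng)
        off = 0
        for n, d in zip(members, doses):
            phenotypes[n] = phen.y[off:off + d.shape[0]]
            var_y[n] = float(np.var(phen.y))
            off += d.shape[0]
        pooled_name = f"pooled_{family}"
        if pooled_name in pop.datasets:
            phenotypes[pooled_name] = phen.y
            var_y[pooled_name] = float(np.var(phen.y))
    purebred_names = [n for n in config.datasets if n in _PUREBRED]
    if purebred_names:
        base = pop.datasets[max(purebred_names, key=lambda n: _PUREBRED[n])]
        doses = base.doses_at(qtn_chrom, qtn_pos)
        p_ref = allele_frequencies(doses)
        bv = breeding_values(doses, p_ref, effects)
        phen = add_residuals(bv, config.h2, rng)
        id_to_y = dict(zip(base.ids, phen.y))
        for n in purebred_names:
            ds = pop.datasets[n]
            phenotypes[n] = np.array([id_to_y[i] for i in ds.ids])
            var_y[n] = float(np.var(phen.y))

    records = []
    figures = {}
    result_cache: dict = {}
    for name in config.datasets:
        if name not in pop.datasets or name not in phenotypes:
            continue
        ds = pop.datasets[name]
        y = phenotypes[name]
        for scenario in config.scenarios:
            sc = config.scenario_config(scenario)
            sets = scenario_sets(ds, qtn_chrom, qtn_pos, sc,
                                 founder_freqs=pop.founder_freqs)
            # scenarios with identical S (e.g. the founder breed's own
            # dataset under ASG and FSG) share one association pass
            cache_key = (name, sets.s_cols.tobytes())
            if cache_key in result_cache:
                result = result_cache[cache_key]
            else:
                result = mlma_loco(
                    ds.genotypes[:, sets.s_cols],
                    ds.chrom[sets.s_cols], ds.pos[sets.s_cols],
                    y, ds.cross_labels,
                    alpha=config.alpha, dataset=name, scenario=scenario)
                result_cache[cache_key] = result
            rec = replicate_metrics(result, sets, sc,
                                    replicate=(pop.index, trait_index))
            records.append(rec)
            if collect_figures:
                qd = ds.genotypes[:, sets.s_cols[sets.q_rows]]
                freqs = allele_frequencies(ds.genotypes[:, sets.s_cols])
                figures[(name, scenario)] = {
                    "manhattan": result.table.assign(
                        is_qtn=np.isin(np.arange(sets.n_s), sets.q_rows),
                        threshold=result.rule.threshold),
                    "power_by_variance": power_by_qtn_variance(
                        result, sets, qd,
                        effects[_match_qtn(qtn_chrom, qtn_pos, ds, sets)],
                        var_y[name]),
                    "maf": np.minimum(freqs, 1 - freqs),
                }
    return (records, figures) if collect_figures else (records, None)


def _match_qtn(qtn_chrom, qtn_pos, ds, sets) -> np.ndarray:
    """Indices into the full QTN list matching sets.q_rows (order aligned)."""
    s_chrom = ds.chrom[sets.s_cols]
    s_pos = ds.pos[sets.s_cols]
    out = []
    for r in sets.q_rows:
        match = np.flatnonzero((qtn_chrom == s_chrom[r]) & (qtn_pos == s_pos[r]))
        out.append(int(match[0]))
    return np.array(out, dtype=np.int64)


@dataclass
class ExperimentResult:
    """Aggregated outputs of a full experiment."""

    metrics: pd.DataFrame          # long format, one row per dataset x scenario x replicate
    summary: pd.DataFrame          # mean/sd across replicates
    snp_counts: pd.DataFrame       # #S mean/sd per dataset x scenario
    fst: pd.DataFrame              # per replicate breed-pair F_ST
    manifests: list[dict]
    figures: dict


def run_experiment(config: ExperimentConfig, *,
                   collect_figures: bool = True) -> ExperimentResult:
    """All population and trait replicates, aggregated."""
    root = np.random.SeedSequence(config.seed)
    pop_seeds = root.spawn(config.n_population_replicates)
    all_records: list[dict] = []
    fst_rows = []
    manifests = []
    figures: dict = {}
    for i, pop_ss in enumerate(pop_seeds):
        pop_ss_main, *trait_seeds = pop_ss.spawn(
            config.n_traits_per_population + 1)
        pop = build_population_replicate(config, i, pop_ss_main)
        manifests.append(pop.manifest)
        fst_rows.append({"replicate": i, **pop.fst})
        for t, t_ss in enumerate(trait_seeds):
            want_figs = collect_figures and i == 0 and t == 0
            records, figs = run_trait_replicate(config, pop, t, t_ss,
                                                collect_figures=want_figs)
            all_records.extend(records)
            if figs:
                figures = figs
    metrics = pd.DataFrame(all_records)
    summary = aggregate(metrics)
    snp_counts = summary[["dataset", "scenario", "n_s_mean", "n_s_sd",
                          "n_q_mean", "n_q_sd"]].copy()
    return ExperimentResult(
        metrics=metrics,
        summary=summary,
        snp_counts=snp_counts,
        fst=pd.DataFrame(fst_rows),
        manifests=manifests,
        figures=figures,
    )
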