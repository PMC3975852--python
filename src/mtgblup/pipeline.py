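"""End-to-end study driver.

A replicate simulates a population, estimates conventional EBVs with
single- and multiple-trait pedigree animal models on all cow phenotypes,
uses those EBVs (EBV_s / EBV_m) as response variables for single- and
multiple-trait GBLUP on the reference bulls, and scores the resulting GEBVs
against the true breeding values of the validation bulls.  Missing-data
scenarios mask a fraction (default 90%) of one trait's EBV responses; the
masked bulls' genotypes stay in G, so they act as unphenotyped connectors.

Within a replicate all scenarios share the same simulated population, the
same G and the same validation set, and every genomic model x response cell
of a scenario shares one masking draw, so model comparisons are paired.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluate, kinship
from .evaluate import EvaluationReport, aggregate_replicates
from .genome import ConfigurationError, build_genome_spec, sample_qtl_effects
from .model import AnimalModel, VarianceComponents
from .population import (
    ROLE_COW,
    ROLE_REFERENCE,
    ROLE_VALIDATION,
    compute_tbv,
    expand_and_breed,
    simulate_historical,
    simulate_phenotypes,
)

log = logging.getLogger("mtgblup")

SCENARIOS = ("no_missing", "missing_trait1", "missing_trait2")
_MASKED_TRAIT = {"no_missing": None, "missing_trait1": 0, "missing_trait2": 1}
_STREAMS = {
    "genome": 1,
    "effects": 2,
    "history": 3,
    "breeding": 4,
    "phenotypes": 5,
    "masking": 6,
}
TRAITS = ("trait1", "trait2")
RESPONSES = ("EBV_m", "EBV_s")
GMODELS = ("STGM", "MTGM")


def stream_rng(seed: int, replicate: int, stream: str, extra: int = 0):
    """Independent named random stream: master seed -> (replicate, stream)."""
    return np.random.default_rng(
        np.random.SeedSequence((int(seed), int(replicate), _STREAMS[stream], extra))
    )


@dataclass
class ScenarioConfig:
    """All knobs of a study run.

    The defaults are the reduced desk scale (100 sires x 2,000 dams per
    generation, 1,000 markers, 60 QTLs split 20/20/20); ``full_scale()``
    returns the full-scale configuration (long-running).
    """

    # genome / trait architecture
    chromosome_lengths: tuple = (100.0,) * 5
    marker_spacing: float = 0.5
    n_qtl: int = 60
    qtl_group_sizes: tuple | None = None
    gamma_shape: float = 0.84
    gamma_scale: float = 5.4
    heritabilities: tuple = (0.3, 0.05)
    # demography
    hist_sires: int = 50
    hist_dams: int = 50
    hist_generations: int = 50
    n_sires: int = 100
    n_dams: int = 2000
    n_eval_generations: int = 4
    # analysis
    scenario: str = "no_missing"
    masking_fraction: float = 0.9
    replicates: int = 10
    seed: int = 0
    reliability_variant: str = "pev"
    ridge: float = 1e-6
    pedigree_reml_method: str = "auto"
    genomic_reml_method: str = "auto"
    ai_obs_limit: int = 1000
    mme_exact_limit: int = 60_000

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"scenario must be one of {SCENARIOS}")
        if not 0.0 <= self.masking_fraction < 1.0:
            raise ConfigurationError("masking fraction must lie in [0, 1)")
        if self.replicates < 1:
            raise ConfigurationError("need at least one replicate")
        if self.reliability_variant not in ("pev", "empirical"):
            raise ConfigurationError("reliability_variant must be pev or empirical")

    @classmethod
    def full_scale(cls, **overrides) -> "ScenarioConfig":
        """Full-scale configuration; hours per replicate and multi-GB memory."""
        base = dict(
            marker_spacing=0.1,
            n_qtl=300,
            n_sires=1000,
            n_dams=200_000,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def reduced(cls, **overrides) -> "ScenarioConfig":
        return cls(**overrides)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("chromosome_lengths", "heritabilities", "qtl_group_sizes"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def simulated_tbv_correlation(
    seed: int,
    n_animals: int = 10_000,
    hist_sires: int = 50,
    hist_dams: int = 50,
    hist_generations: int = 50,
    genome_kwargs: dict | None = None,
    effect_kwargs: dict | None = None,
) -> float:
    """Cross-trait correlation of true breeding values in one expanded cohort.

    Builds the default genome and QTL architecture (unless overridden),
    runs the historical bottleneck, expands to a single cohort of
    ``n_animals`` and returns the Pearson correlation of the two variance-1
    TBV vectors.  Under equal pleiotropy-group sizes the expected value
    is 0.5.
    """
    ss = np.random.SeedSequence((int(seed), 101))
    g_rng, e_rng, h_rng, b_rng = [
        np.random.default_rng(s) for s in ss.spawn(4)
    ]
    genome = build_genome_spec(seed=g_rng, **(genome_kwargs or {}))
    arch = sample_qtl_effects(genome, seed=e_rng, **(effect_kwargs or {}))
    hist = simulate_historical(
        genome, hist_sires, hist_dams, hist_generations, seed=h_rng
    )
    n_s = max(n_animals // 20, 1)
    pop = expand_and_breed(
        hist, n_sires=n_s, n_dams=n_animals - n_s, n_eval_generations=0, seed=b_rng
    )
    cohort = pop.pedigree.index[
        pop.pedigree["generation"] == pop.pedigree["generation"].max()
    ].to_numpy()
    compute_tbv(pop, arch, scaling_cohort=cohort)
    t = pop.tbv[cohort]
    return float(np.corrcoef(t[:, 0], t[:, 1])[0, 1])


def mask_records(bull_ids, fraction: float, rng) -> np.ndarray:
    """Retain a uniform random subset of round((1 - fraction) * n) bulls."""
    bull_ids = np.asarray(bull_ids)
    if not 0.0 <= fraction < 1.0:
        raise ConfigurationError("masking fraction must lie in [0, 1)")
    n_keep = int(round((1.0 - fraction) * bull_ids.size))
    if n_keep == 0:
        raise ConfigurationError("masking would retain no records")
    return np.sort(rng.choice(bull_ids, size=n_keep, replace=False))


def simulate_replicate(config: ScenarioConfig, replicate: int):
    """Simulate one replicate's population (genome, effects, history,
    expansion, TBVs, cow phenotypes)."""
    genome = build_genome_spec(
        chromosome_lengths=config.chromosome_lengths,
        marker_spacing=config.marker_spacing,
        n_qtl=config.n_qtl,
        qtl_group_sizes=config.qtl_group_sizes,
        seed=stream_rng(config.seed, replicate, "genome"),
    )
    arch = sample_qtl_effects(
        genome,
        shape=config.gamma_shape,
        scale=config.gamma_scale,
        seed=stream_rng(config.seed, replicate, "effects"),
        heritabilities=config.heritabilities,
    )
    hist = simulate_historical(
        genome,
        n_sires=config.hist_sires,
        n_dams=config.hist_dams,
        n_generations=config.hist_generations,
        seed=stream_rng(config.seed, replicate, "history"),
    )
    pop = expand_and_breed(
        hist,
        n_sires=config.n_sires,
        n_dams=config.n_dams,
        n_eval_generations=config.n_eval_generations,
        seed=stream_rng(config.seed, replicate, "breeding"),
    )
    compute_tbv(pop, arch)
    simulate_phenotypes(pop, arch, seed=stream_rng(config.seed, replicate, "phenotypes"))
    log.info(
        "replicate %d: %d animals, %d cows, %d reference bulls, %d validation bulls",
        replicate,
        pop.n_animals,
        pop.animals_with_role(ROLE_COW).size,
        pop.animals_with_role(ROLE_REFERENCE).size,
        pop.animals_with_role(ROLE_VALIDATION).size,
    )
    return pop, genome, arch


@dataclass
class PedigreeStage:
    """Conventional evaluation: EBVs and their reliabilities."""

    ebv_s: pd.DataFrame  # animal x trait, single-trait models
    ebv_m: pd.DataFrame  # animal x trait, multiple-trait model
    rel_pev_s: pd.DataFrame  # PEV reliabilities of reference bulls (ST)
    rel_pev_m: pd.DataFrame
    varcomp_st: list
    varcomp_mt: VarianceComponents
    cells: list = field(default_factory=list)


def run_pedigree_stage(pop, config: ScenarioConfig) -> PedigreeStage:
    """Estimate EBV_s and EBV_m from all cow phenotypes with pedigree
    animal models (REML variance components, then BLUP)."""
    ped = pop.pedigree[["animal", "sire", "dam"]]
    ainv = kinship.build_a_inverse(ped)
    cows = pop.animals_with_role(ROLE_COW)
    data = pd.DataFrame(
        {
            "animal_id": cows,
            TRAITS[0]: pop.phenotypes[cows, 0],
            TRAITS[1]: pop.phenotypes[cows, 1],
        }
    )
    kwargs = dict(
        mme_exact_limit=config.mme_exact_limit, ai_obs_limit=config.ai_obs_limit
    )
    st_results, st_vc = [], []
    for a, trait in enumerate(TRAITS):
        m = AnimalModel(data[["animal_id", trait]], ainv, [trait], **kwargs)
        res = m.fit(method=config.pedigree_reml_method)
        log.info("pedigree ST %s: %s", trait, res.varcomp)
        st_results.append(res)
        st_vc.append(res.varcomp)
    mt_model = AnimalModel(data, ainv, list(TRAITS), **kwargs)
    h0 = np.diag([vc.H[0, 0] for vc in st_vc])
    r0 = np.diag([vc.R[0, 0] for vc in st_vc])
    mt_res = mt_model.fit(method=config.pedigree_reml_method, start=(h0, r0))
    log.info("pedigree MT: %s", mt_res.varcomp)

    ebv_s = pd.concat([r.solutions for r in st_results], axis=1)
    ebv_s.columns = list(TRAITS)
    ebv_m = mt_res.solutions

    ref = pop.animals_with_role(ROLE_REFERENCE)
    val = pop.animals_with_role(ROLE_VALIDATION)
    rel_pev_s = pd.concat(
        [r.reliability(ids=ref)[t] for r, t in zip(st_results, TRAITS)], axis=1
    )
    rel_pev_m = mt_res.reliability(ids=ref)

    cells = []
    # variance-component diagnostics: REML estimates next to the values
    # realized in the simulated cows
    cow_tbv = pop.tbv[cows]
    cow_phen = pop.phenotypes[cows]
    rg_real = float(np.corrcoef(cow_tbv[:, 0], cow_tbv[:, 1])[0, 1])
    cells.append(_cell("diagnostics", "-", "-", "-", "-", "rg_realized", rg_real))
    cells.append(
        _cell("diagnostics", "-", "-", "MT", "-", "rg_hat",
              mt_res.varcomp.genetic_correlation)
    )
    for a, trait in enumerate(TRAITS):
        h2_real = float(cow_tbv[:, a].var() / cow_phen[:, a].var())
        cells.append(_cell("diagnostics", trait, "-", "-", "-", "h2_realized", h2_real))
        cells.append(_cell("diagnostics", trait, "-", "ST", "-", "h2_hat",
                           st_vc[a].heritabilities[0]))
        cells.append(_cell("diagnostics", trait, "-", "MT", "-", "h2_hat",
                           mt_res.varcomp.heritabilities[a]))
    for a, trait in enumerate(TRAITS):
        for model, ebv in (("ST", ebv_s), ("MT", ebv_m)):
            for group, ids in (("ref", ref), ("val", val)):
                r2 = evaluate.reliability(
                    ebv.loc[ids, trait].to_numpy(), pop.tbv[ids, a]
                )
                cells.append(_cell("table1", trait, "-", model, "-",
                                   f"{group}_reliability", r2))
            icpt, slope = evaluate.regression_tbv_on_gebv(
                pop.tbv[val, a], ebv.loc[val, trait].to_numpy()
            )
            cells.append(_cell("table1", trait, "-", model, "-", "val_slope", slope))
            cells.append(_cell("table1", trait, "-", model, "-", "val_intercept", icpt))
    return PedigreeStage(
        ebv_s=ebv_s,
        ebv_m=ebv_m,
        rel_pev_s=rel_pev_s,
        rel_pev_m=rel_pev_m,
        varcomp_st=st_vc,
        varcomp_mt=mt_res.varcomp,
        cells=cells,
    )


def _cell(table, trait, scenario, model, response, statistic, value):
    return {
        "table": table,
        "trait": trait,
        "scenario": scenario,
        "model": model,
        "response": response,
        "statistic": statistic,
        "value": float(value),
    }


def build_genomic_kinship(pop, config: ScenarioConfig) -> kinship.RelationshipMatrix:
    """VanRaden G over all genotyped bulls (reference + validation), allele
    frequencies observed in that combined set, plus a small ridge."""
    bulls = np.concatenate(
        [pop.animals_with_role(ROLE_REFERENCE), pop.animals_with_role(ROLE_VALIDATION)]
    )
    bulls = np.sort(bulls)
    dos = pop.dosages(pop.genome.marker_index)[bulls]
    g = kinship.vanraden_g(dos, ids=bulls)
    return kinship.ensure_invertible(g, config.ridge)


def run_genomic_stage(
    pop, stage: PedigreeStage, G, config: ScenarioConfig, replicate: int
) -> list:
    """STGM and MTGM GBLUP for both response types under one scenario.

    Returns the table-2/3/4 cells for this (replicate, scenario).
    """
    scenario = config.scenario
    masked_trait = _MASKED_TRAIT[scenario]
    ref = np.sort(pop.animals_with_role(ROLE_REFERENCE))
    val = np.sort(pop.animals_with_role(ROLE_VALIDATION))
    retained = {a: ref for a in range(2)}
    if masked_trait is not None:
        rng = stream_rng(config.seed, replicate, "masking", SCENARIOS.index(scenario))
        retained[masked_trait] = mask_records(ref, config.masking_fraction, rng)

    kwargs = dict(
        mme_exact_limit=config.mme_exact_limit, ai_obs_limit=config.ai_obs_limit
    )
    cells = []
    for response, ebv in (("EBV_m", stage.ebv_m), ("EBV_s", stage.ebv_s)):
        # response table: reference-bull EBVs, masked entries absent
        resp = pd.DataFrame({"animal_id": ref}).set_index("animal_id", drop=False)
        for a, trait in enumerate(TRAITS):
            col = ebv.loc[ref, trait].copy()
            col[~col.index.isin(retained[a])] = np.nan
            resp[trait] = col
        # mean reference EBV reliability used for rescaling, over the bulls
        # whose responses actually enter the genomic model
        rel = stage.rel_pev_m if response == "EBV_m" else stage.rel_pev_s
        rbar2 = {}
        for a, trait in enumerate(TRAITS):
            if config.reliability_variant == "pev":
                rbar2[a] = float(rel.loc[retained[a], trait].mean())
            else:
                rbar2[a] = evaluate.reliability(
                    ebv.loc[retained[a], trait].to_numpy(),
                    pop.tbv[retained[a], a],
                )
            cells.append(_cell("table4", trait, scenario, "-", response,
                               "rbar2_ebv", rbar2[a]))

        gebv = {}
        for a, trait in enumerate(TRAITS):
            sub = resp[["animal_id", trait]].dropna()
            m = AnimalModel(sub, G, [trait], **kwargs)
            res = m.fit(method=config.genomic_reml_method)
            log.info("%s STGM %s %s: %s", scenario, response, trait, res.varcomp)
            gebv[("STGM", a)] = res.predict(val)[trait].to_numpy()
        mt = AnimalModel(resp, G, list(TRAITS), **kwargs)
        h0 = np.diag([mt_start for mt_start in (
            np.nanvar(resp[TRAITS[0]]), np.nanvar(resp[TRAITS[1]]))]) * 0.5
        mt_res = mt.fit(method=config.genomic_reml_method, start=(h0, h0))
        log.info("%s MTGM %s: %s", scenario, response, mt_res.varcomp)
        for a, trait in enumerate(TRAITS):
            gebv[("MTGM", a)] = mt_res.predict(val)[trait].to_numpy()

        for a, trait in enumerate(TRAITS):
            tbv = pop.tbv[val, a]
            for gmodel in GMODELS:
                pred = gebv[(gmodel, a)]
                cells.append(_cell("table2", trait, scenario, gmodel, response,
                                   "reliability", evaluate.reliability(pred, tbv)))
                icpt, slope = evaluate.regression_tbv_on_gebv(tbv, pred)
                cells.append(_cell("table4", trait, scenario, gmodel, response,
                                   "slope", slope))
                cells.append(_cell("table4", trait, scenario, gmodel, response,
                                   "intercept", icpt))
                _, slope_c = evaluate.regression_tbv_on_gebv(
                    tbv, evaluate.rescale_gebv(pred, rbar2[a])
                )
                cells.append(_cell("table4", trait, scenario, gmodel, response,
                                   "slope_rescaled", slope_c))
            r_mt = np.corrcoef(gebv[("MTGM", a)], tbv)[0, 1]
            r_st = np.corrcoef(gebv[("STGM", a)], tbv)[0, 1]
            r_12 = np.corrcoef(gebv[("MTGM", a)], gebv[("STGM", a)])[0, 1]
            t, df = evaluate.hotelling_williams_t(r_mt, r_st, r_12, val.size)
            p = evaluate.williams_p_value(t, df)
            cells.append(_cell("table3", trait, scenario, "-", response, "t", t))
            cells.append(_cell("table3", trait, scenario, "-", response, "df", df))
            cells.append(_cell("table3", trait, scenario, "-", response, "p", p))
    return cells


def run_replicate(config: ScenarioConfig, replicate: int) -> EvaluationReport:
    """One scenario, one replicate, end to end."""
    pop, genome, arch = simulate_replicate(config, replicate)
    stage = run_pedigree_stage(pop, config)
    G = build_genomic_kinship(pop, config)
    cells = stage.cells + run_genomic_stage(pop, stage, G, config, replicate)
    return EvaluationReport(cells=pd.DataFrame(cells))


def run_study(
    config: ScenarioConfig,
    scenarios=None,
    out_dir=None,
) -> EvaluationReport:
    """Loop scenarios x replicates, sharing each replicate's population and
    pedigree stage across scenarios, and aggregate the cells."""
    if scenarios is None:
        scenarios = SCENARIOS
    reports = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")
    for rep in range(config.replicates):
        pop, genome, arch = simulate_replicate(config, rep)
        stage = run_pedigree_stage(pop, config)
        G = build_genomic_kinship(pop, config)
        cells = list(stage.cells)
        for scen in scenarios:
            cfg = dataclasses.replace(config, scenario=scen)
            cells.extend(run_genomic_stage(pop, stage, G, cfg, rep))
        report = EvaluationReport(cells=pd.DataFrame(cells))
        reports.append(report)
        if out is not None:
            report.cells.to_csv(out / f"replicate_{rep}.tsv", sep="\t", index=False)
    agg = aggregate_replicates(reports)
    if out is not None:
        agg.cells.to_csv(out / "aggregated_cells.tsv", sep="\t", index=False)
        for name, tab in agg.to_tables().items():
            tab.to_csv(out / f"{name}.tsv", sep="\t")
    return agg
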