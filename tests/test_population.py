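import numpy as np
import pytest

from mtgblup.genome import (
    ConfigurationError,
    PLEIOTROPIC,
    TRAIT1_ONLY,
    TRAIT2_ONLY,
    TraitArchitecture,
    build_genome_spec,
    sample_qtl_effects,
)
from mtgblup.population import (
    DataError,
    compute_tbv,
    expand_and_breed,
    mendelian_error_count,
    meiosis,
    simulate_historical,
    simulate_phenotypes,
)


@pytest.fixture(scope="module")
def line_genome():
    # one 100 cM chromosome, markers every 1 cM
    return build_genome_spec(
        chromosome_lengths=(100.0,), marker_spacing=1.0, n_qtl=0, seed=0
    )


@pytest.fixture(scope="module")
def small_genome():
    return build_genome_spec(
        chromosome_lengths=(100.0,), marker_spacing=0.5, n_qtl=12, seed=1
    )


class TestMeiosis:
    def test_identical_parental_haplotypes(self, line_genome):
        rng = np.random.default_rng(0)
        h = rng.integers(0, 2, size=line_genome.n_loci, dtype=np.uint8)
        pair = np.stack([h, h])
        for _ in range(5):
            assert np.array_equal(meiosis(pair, line_genome, rng), h)

    def test_crossover_rate_one_per_morgan(self, line_genome):
        # parent 000.../111... makes the inherited strand directly visible
        rng = np.random.default_rng(1)
        pair = np.stack(
            [
                np.zeros(line_genome.n_loci, dtype=np.uint8),
                np.ones(line_genome.n_loci, dtype=np.uint8),
            ]
        )
        switches = [
            int(np.sum(np.diff(meiosis(pair, line_genome, rng)) != 0))
            for _ in range(4000)
        ]
        # Poisson(1) crossovers per 100 cM; observable strand switches lose
        # the rare even-count intervals, giving ~0.98 expected
        assert abs(np.mean(switches) - 1.0) < 0.07

    def test_haldane_fraction_at_10_cm(self, line_genome):
        rng = np.random.default_rng(2)
        pair = np.stack(
            [
                np.zeros(line_genome.n_loci, dtype=np.uint8),
                np.ones(line_genome.n_loci, dtype=np.uint8),
            ]
        )
        i = 10  # loci 10 cM apart
        j = np.flatnonzero(line_genome.pos_cm == line_genome.pos_cm[i] + 10.0)[0]
        gametes = [meiosis(pair, line_genome, rng) for _ in range(4000)]
        frac = np.mean([g[i] != g[j] for g in gametes])
        expected = 0.5 * (1 - np.exp(-0.2))
        assert abs(frac - expected) < 0.02

    def test_shape_mismatch_raises(self, line_genome):
        with pytest.raises(DataError):
            meiosis(np.zeros((2, 5), dtype=np.uint8), line_genome, 0)


class TestHistorical:
    def test_zero_generations_returns_founders(self, small_genome):
        pop = simulate_historical(small_genome, 10, 10, 0, seed=3)
        assert pop.n_animals == 20
        assert np.all(pop.pedigree["sire"] == -1)

    def test_drift_and_heterozygosity_decay(self, small_genome):
        n_gen = 30
        pop = simulate_historical(small_genome, 50, 50, n_gen, seed=4)
        last = pop.pedigree.index[pop.pedigree["generation"] == n_gen].to_numpy()
        freq = pop.haplotypes[last].mean(axis=(0, 1))
        assert (np.abs(freq - 0.5) > 0.1).mean() > 0.2  # drift moved many loci
        het = (2 * freq * (1 - freq)).mean()
        expected = 0.5 * (1 - 1 / 200) ** n_gen  # Wright-Fisher, N = 100
        assert het < 0.5
        assert abs(het - expected) < 0.08

    def test_ld_decay_with_distance(self, small_genome):
        pop = simulate_historical(small_genome, 25, 25, 30, seed=5)
        last = pop.pedigree.index[pop.pedigree["generation"] == 30].to_numpy()
        d = pop.dosages()[last].astype(float)
        poly = d.std(axis=0) > 0.3
        idx = np.flatnonzero(poly)
        pos = pop.genome.pos_cm
        r2_near, r2_far = [], []
        corr = np.corrcoef(d[:, idx].T)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                dist = abs(pos[idx[a]] - pos[idx[b]])
                if dist < 1.0:
                    r2_near.append(corr[a, b] ** 2)
                elif dist > 50.0:
                    r2_far.append(corr[a, b] ** 2)
        assert np.mean(r2_near) > np.mean(r2_far)


class TestExpansion:
    def test_role_counts_at_scaled_config(self, small_genome):
        hist = simulate_historical(small_genome, 10, 10, 2, seed=6)
        pop = expand_and_breed(hist, n_sires=100, n_dams=2000, n_eval_generations=4, seed=7)
        assert pop.animals_with_role("reference_bull").size == 300
        assert pop.animals_with_role("validation_bull").size == 100
        assert pop.animals_with_role("cow").size == 8000

    def test_zero_eval_generations(self, small_genome):
        hist = simulate_historical(small_genome, 10, 10, 2, seed=6)
        pop = expand_and_breed(hist, 20, 40, 0, seed=8)
        assert pop.animals_with_role("reference_bull").size == 0
        assert pop.animals_with_role("validation_bull").size == 0

    def test_parents_in_previous_generation(self, small_genome):
        hist = simulate_historical(small_genome, 10, 10, 3, seed=9)
        pop = expand_and_breed(hist, 15, 60, 3, seed=10)
        ped = pop.pedigree
        nonf = ped[ped["sire"] >= 0]
        gen = ped["generation"]
        assert np.all(
            gen.loc[nonf["sire"]].to_numpy() == nonf["generation"].to_numpy() - 1
        )
        assert np.all(
            gen.loc[nonf["dam"]].to_numpy() == nonf["generation"].to_numpy() - 1
        )

    def test_mendelian_consistency(self, small_genome):
        hist = simulate_historical(small_genome, 10, 10, 3, seed=11)
        pop = expand_and_breed(hist, 15, 60, 2, seed=12)
        assert mendelian_error_count(pop) == 0


@pytest.fixture(scope="module")
def bred_population():
    genome = build_genome_spec(
        chromosome_lengths=(100.0, 100.0), marker_spacing=1.0, n_qtl=30, seed=13
    )
    arch = sample_qtl_effects(genome, seed=14)
    hist = simulate_historical(genome, 20, 20, 10, seed=15)
    pop = expand_and_breed(hist, 25, 250, 4, seed=16)
    compute_tbv(pop, arch)
    simulate_phenotypes(pop, arch, seed=17)
    return pop, arch


class TestTrueBreedingValues:
    def test_unit_variance_in_scaling_cohort(self, bred_population):
        pop, arch = bred_population
        g1 = pop.eval_generation(1)
        assert np.allclose(pop.tbv[g1].var(axis=0), 1.0, atol=1e-10)

    def test_tbv_identity_everywhere(self, bred_population):
        pop, arch = bred_population
        d = pop.dosages(pop.genome.qtl_index).astype(float)
        assert np.allclose(pop.tbv, (d @ arch.effects) / arch.tbv_scale, atol=1e-10)

    def test_genetic_correlation_variance_decomposition(self, bred_population):
        # cor(TBV1, TBV2) decomposes exactly into the pleiotropic and
        # private (co)variance components realized in the cohort
        pop, arch = bred_population
        g = pop.genome
        cohort = pop.eval_generation(1)
        d = pop.dosages(g.qtl_index)[cohort].astype(float)
        parts = {}
        for grp in (TRAIT1_ONLY, TRAIT2_ONLY, PLEIOTROPIC):
            e = np.where((g.qtl_group == grp)[:, None], arch.effects, 0.0)
            parts[grp] = (d @ e) / arch.tbv_scale
        p = parts[PLEIOTROPIC]
        u1 = parts[TRAIT1_ONLY][:, 0]
        u2 = parts[TRAIT2_ONLY][:, 1]
        cov = (
            np.cov(p[:, 0], p[:, 1])[0, 1]
            + np.cov(p[:, 0], u2)[0, 1]
            + np.cov(p[:, 1], u1)[0, 1]
            + np.cov(u1, u2)[0, 1]
        )
        t1 = pop.tbv[cohort, 0]
        t2 = pop.tbv[cohort, 1]
        expected = cov / np.sqrt(t1.var(ddof=1) * t2.var(ddof=1))
        assert np.isclose(np.corrcoef(t1, t2)[0, 1], expected, atol=1e-10)

    def test_degenerate_architecture_raises(self, bred_population):
        pop, arch = bred_population
        zero = TraitArchitecture(effects=np.zeros((pop.genome.n_qtl, 2)))
        with pytest.raises(ConfigurationError):
            compute_tbv(pop, zero)


class TestPhenotypes:
    def test_residual_variance_matches_heritability(self, bred_population):
        pop, arch = bred_population
        cows = pop.animals_with_role("cow")
        resid = pop.phenotypes[cows] - pop.tbv[cows]
        for a, h2 in enumerate(arch.heritabilities):
            target = (1 - h2) / h2
            assert abs(resid[:, a].var() / target - 1.0) < 0.15
        # residuals independent across traits
        assert abs(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1]) < 0.1
        # realized narrow-sense heritability matches the configuration
        for a, h2 in enumerate(arch.heritabilities):
            realized = pop.tbv[cows, a].var() / pop.phenotypes[cows, a].var()
            assert abs(realized - h2) < 0.06

    def test_h2_one_gives_phenotype_equal_tbv(self, bred_population):
        pop, _ = bred_population
        arch1 = TraitArchitecture(
            effects=np.ones((pop.genome.n_qtl, 2)), heritabilities=(1.0, 1.0)
        )
        pop2 = compute_tbv(
            type(pop)(
                genome=pop.genome,
                pedigree=pop.pedigree,
                haplotypes=pop.haplotypes,
                first_eval_generation=pop.first_eval_generation,
            ),
            arch1,
        )
        simulate_phenotypes(pop2, arch1, seed=0)
        cows = pop2.animals_with_role("cow")
        assert np.array_equal(pop2.phenotypes[cows], pop2.tbv[cows])

    def test_only_cows_have_records(self, bred_population):
        pop, _ = bred_population
        bulls = pop.animals_with_role("reference_bull")
        assert np.all(np.isnan(pop.phenotypes[bulls]))


def test_full_reproducibility(small_genome):
    pops = []
    for _ in range(2):
        hist = simulate_historical(small_genome, 10, 10, 4, seed=99)
        pops.append(expand_and_breed(hist, 10, 30, 2, seed=100))
    assert np.array_equal(pops[0].haplotypes, pops[1].haplotypes)
    assert pops[0].pedigree.equals(pops[1].pedigree)
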