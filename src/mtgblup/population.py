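"""Forward-in-time gene-drop simulation of a dairy-cattle-like population.

The demographic history mirrors a progeny-testing scheme: a small closed
historical population (default 50 sires x 50 dams) is random-mated for many
discrete generations so that drift and linkage disequilibrium accumulate,
then expanded to the production scale (default 1,000 sires x 200,000 dams),
after which four evaluation generations G1-G4 are bred.  Males of G1-G3 are
genotyped reference bulls, males of G4 are validation bulls, and every
female of G1-G4 is a phenotyped cow.

Inheritance is simulated by gene dropping: each offspring receives one
recombined gamete per parent.  Crossovers follow Haldane's model (Poisson
counts, no interference), implemented in its equivalent Markov form as
independent strand switches between adjacent loci with probability
``0.5 * (1 - exp(-2d))`` for map distance ``d`` Morgans, and 0.5 across
chromosome boundaries.  There is no mutation and no selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import ConfigurationError, GenomeSpec, TraitArchitecture, _as_rng

ROLE_HISTORICAL = "historical"
ROLE_COW = "cow"
ROLE_REFERENCE = "reference_bull"
ROLE_VALIDATION = "validation_bull"

_GAMETE_CHUNK = 2000  # limits the size of the per-chunk random matrix


class DataError(ValueError):
    """Raised when haplotype/pedigree data are inconsistent."""


@dataclass
class Population:
    """Pedigree, phased haplotypes and per-animal trait values.

    Animals are numbered 0..n-1 in pedigree order (parents precede
    offspring).  ``haplotypes[i, 0]`` is the paternal and ``haplotypes[i, 1]``
    the maternal phased allele sequence over all loci of ``genome``.
    ``tbv`` and ``phenotypes`` are (n, 2) arrays (NaN where absent) filled by
    :func:`compute_tbv` / :func:`simulate_phenotypes`.
    """

    genome: GenomeSpec
    pedigree: pd.DataFrame
    haplotypes: np.ndarray
    tbv: np.ndarray | None = None
    phenotypes: np.ndarray | None = None
    first_eval_generation: int | None = None

    @property
    def n_animals(self) -> int:
        return len(self.pedigree)

    def dosages(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele counts in {0,1,2}, optionally restricted to given loci."""
        h = self.haplotypes if loci is None else self.haplotypes[:, :, loci]
        return h.sum(axis=1, dtype=np.int16)

    def animals_with_role(self, role: str) -> np.ndarray:
        return self.pedigree.index[self.pedigree["role"] == role].to_numpy()

    def eval_generation(self, k: int) -> np.ndarray:
        """Animal indices of evaluation generation Gk (k = 1..)."""
        if self.first_eval_generation is None:
            raise DataError("population has no evaluation generations")
        g = self.first_eval_generation + (k - 1)
        return self.pedigree.index[self.pedigree["generation"] == g].to_numpy()


def _gametes(parent_haps: np.ndarray, genome: GenomeSpec, rng) -> np.ndarray:
    """One recombined gamete per row of ``parent_haps`` (shape (n, 2, L))."""
    n, two, L = parent_haps.shape
    if two != 2 or L != genome.n_loci:
        raise DataError("haplotypes must have shape (n, 2, n_loci)")
    r = genome.adjacent_recombination
    out = np.empty((n, L), dtype=parent_haps.dtype)
    for lo in range(0, n, _GAMETE_CHUNK):
        hi = min(lo + _GAMETE_CHUNK, n)
        m = hi - lo
        switch = rng.random((m, L - 1)) < r
        strand = np.empty((m, L), dtype=np.int8)
        strand[:, 0] = rng.integers(0, 2, size=m)
        np.cumsum(switch, axis=1, out=strand[:, 1:], dtype=np.int8)
        strand[:, 1:] += strand[:, :1]
        strand[:, 1:] &= 1
        chunk = parent_haps[lo:hi]
        out[lo:hi] = np.where(strand == 0, chunk[:, 0, :], chunk[:, 1, :])
    return out


def meiosis(parent_haplopair: np.ndarray, genome: GenomeSpec, rng) -> np.ndarray:
    """Produce one gamete from a phased haplotype pair (shape (2, n_loci))."""
    parent_haplopair = np.asarray(parent_haplopair)
    if parent_haplopair.shape != (2, genome.n_loci):
        raise DataError(
            f"expected haplotype pair of shape (2, {genome.n_loci}), "
            f"got {parent_haplopair.shape}"
        )
    return _gametes(parent_haplopair[None], genome, _as_rng(rng))[0]


def _founders(genome: GenomeSpec, n: int, rng) -> np.ndarray:
    """Founder haplotypes: every allele i.i.d. Bernoulli(0.5)."""
    return rng.integers(0, 2, size=(n, 2, genome.n_loci), dtype=np.uint8)


def _breed_generation(
    haplotypes: np.ndarray,
    males: np.ndarray,
    females: np.ndarray,
    n_males_next: int,
    n_females_next: int,
    genome: GenomeSpec,
    rng,
    one_per_dam: bool = True,
):
    """Create the next generation's offspring.

    Females of the next generation are produced one per current dam (when
    counts allow); the males are produced from uniformly drawn dams.  Every
    offspring gets a uniformly drawn sire.  Returns (sire_idx, dam_idx, sex,
    haplotypes) for the n_females_next + n_males_next offspring, females
    first.
    """
    if males.size == 0 or females.size == 0:
        raise ConfigurationError("both parent sexes must be non-empty")
    nf, nm = int(n_females_next), int(n_males_next)
    if one_per_dam and nf == females.size:
        dams_f = females.copy()
    elif one_per_dam and nf < females.size:
        dams_f = rng.choice(females, size=nf, replace=False)
    else:
        dams_f = rng.choice(females, size=nf, replace=True)
    dams_m = rng.choice(females, size=nm, replace=True)
    dam_idx = np.concatenate([dams_f, dams_m])
    sire_idx = rng.choice(males, size=nf + nm, replace=True)
    sex = np.array(["F"] * nf + ["M"] * nm)
    pat = _gametes(haplotypes[sire_idx], genome, rng)
    mat = _gametes(haplotypes[dam_idx], genome, rng)
    haps = np.stack([pat, mat], axis=1)
    return sire_idx, dam_idx, sex, haps


def simulate_historical(
    genome: GenomeSpec,
    n_sires: int = 50,
    n_dams: int = 50,
    n_generations: int = 50,
    seed=None,
) -> Population:
    """Random-mate a constant-size closed population for ``n_generations``.

    Founders (generation 0) start at allele frequency 0.5 at every locus;
    the bottleneck then generates a realistic frequency spectrum, linkage
    disequilibrium and inbreeding.  The full pedigree is retained.
    """
    if n_sires < 1 or n_dams < 1 or n_generations < 0:
        raise ConfigurationError("counts must be >=1 (generations >=0)")
    rng = _as_rng(seed)
    n0 = n_sires + n_dams
    haps = [_founders(genome, n0, rng)]
    sex = np.array(["M"] * n_sires + ["F"] * n_dams)
    recs = {
        "animal": list(range(n0)),
        "sire": [-1] * n0,
        "dam": [-1] * n0,
        "sex": list(sex),
        "generation": [0] * n0,
        "role": [ROLE_HISTORICAL] * n0,
    }
    prev_ids = np.arange(n0)
    prev_sex = sex
    all_haps = haps[0]
    next_id = n0
    for g in range(1, n_generations + 1):
        males = prev_ids[prev_sex == "M"]
        females = prev_ids[prev_sex == "F"]
        s_idx, d_idx, off_sex, off_haps = _breed_generation(
            all_haps, males, females, n_sires, n_dams, genome, rng
        )
        n_off = off_sex.size
        ids = np.arange(next_id, next_id + n_off)
        recs["animal"].extend(ids)
        recs["sire"].extend(s_idx)
        recs["dam"].extend(d_idx)
        recs["sex"].extend(off_sex)
        recs["generation"].extend([g] * n_off)
        recs["role"].extend([ROLE_HISTORICAL] * n_off)
        all_haps = np.concatenate([all_haps, off_haps], axis=0)
        prev_ids, prev_sex = ids, off_sex
        next_id += n_off
    ped = pd.DataFrame(recs).set_index("animal", drop=False)
    ped.index.name = None
    return Population(genome=genome, pedigree=ped, haplotypes=all_haps)


def expand_and_breed(
    historical: Population,
    n_sires: int = 1000,
    n_dams: int = 200_000,
    n_eval_generations: int = 4,
    seed=None,
) -> Population:
    """Expand the historical population and breed the evaluation generations.

    A G0 parent cohort of ``n_sires`` males and ``n_dams`` females is created
    by one round of mating with parents drawn with replacement from the last
    historical generation.  Each of G1..Gk then consists of ``n_dams`` female
    offspring (one per dam) plus ``n_sires`` male offspring; males of the
    last generation are validation bulls, males of the earlier generations
    reference bulls, and all females are cows.
    """
    if historical.n_animals == 0:
        raise ConfigurationError("historical population is empty")
    if n_sires < 1 or n_dams < 1 or n_eval_generations < 0:
        raise ConfigurationError("invalid expansion counts")
    rng = _as_rng(seed)
    ped = historical.pedigree
    last_gen = int(ped["generation"].max())
    last = ped[ped["generation"] == last_gen]
    males = last.index[last["sex"] == "M"].to_numpy()
    females = last.index[last["sex"] == "F"].to_numpy()

    recs = {k: list(ped[k]) for k in ("animal", "sire", "dam", "sex", "generation", "role")}
    all_haps = historical.haplotypes
    next_id = historical.n_animals
    prev_ids, prev_sex = None, None

    # G0: expansion cohort (parents of G1), then G1..Gk at constant size.
    for step in range(n_eval_generations + 1):
        if step == 0:
            s_idx, d_idx, off_sex, off_haps = _breed_generation(
                all_haps, males, females, n_sires, n_dams,
                historical.genome, rng, one_per_dam=False,
            )
        else:
            m = prev_ids[prev_sex == "M"]
            f = prev_ids[prev_sex == "F"]
            s_idx, d_idx, off_sex, off_haps = _breed_generation(
                all_haps, m, f, n_sires, n_dams, historical.genome, rng
            )
        n_off = off_sex.size
        ids = np.arange(next_id, next_id + n_off)
        gen = last_gen + 1 + step
        if step == 0:
            roles = [ROLE_HISTORICAL] * n_off
        else:
            bull_role = (
                ROLE_VALIDATION if step == n_eval_generations else ROLE_REFERENCE
            )
            roles = [ROLE_COW if s == "F" else bull_role for s in off_sex]
        recs["animal"].extend(ids)
        recs["sire"].extend(s_idx)
        recs["dam"].extend(d_idx)
        recs["sex"].extend(off_sex)
        recs["generation"].extend([gen] * n_off)
        recs["role"].extend(roles)
        all_haps = np.concatenate([all_haps, off_haps], axis=0)
        prev_ids, prev_sex = ids, off_sex
        next_id += n_off

    new_ped = pd.DataFrame(recs).set_index("animal", drop=False)
    new_ped.index.name = None
    return Population(
        genome=historical.genome,
        pedigree=new_ped,
        haplotypes=all_haps,
        first_eval_generation=last_gen + 2 if n_eval_generations > 0 else None,
    )


def compute_tbv(
    pop: Population,
    arch: TraitArchitecture,
    scaling_cohort: np.ndarray | None = None,
) -> Population:
    """Fill true breeding values: scaled sums of QTL dosage x effect.

    The raw breeding value of animal i for trait t is
    ``sum_q dosage_iq * effect_qt``; each trait is then divided by the
    standard deviation realized in the scaling cohort, so the cohort's
    genetic variance is exactly 1.  The same divisor applies to every animal
    in every generation, and is stored in ``arch.tbv_scale``.

    By default the scaling cohort is all of G1 (the first evaluation
    generation), or the whole population when none exists.
    """
    if scaling_cohort is None:
        if pop.first_eval_generation is not None:
            scaling_cohort = pop.eval_generation(1)
        else:
            scaling_cohort = np.arange(pop.n_animals)
    scaling_cohort = np.asarray(scaling_cohort)
    if scaling_cohort.size == 0:
        raise ConfigurationError("scaling cohort must be non-empty")
    d = pop.dosages(pop.genome.qtl_index).astype(float)
    raw = d @ arch.effects
    var = raw[scaling_cohort].var(axis=0)
    if np.any(var <= 1e-12):
        raise ConfigurationError(
            "degenerate architecture: zero genetic variance in scaling cohort"
        )
    scale = np.sqrt(var)
    pop.tbv = raw / scale
    arch.tbv_scale = scale
    return pop


def simulate_phenotypes(
    pop: Population, arch: TraitArchitecture, seed=None
) -> Population:
    """Attach cow phenotypes: TBV plus N(0, (1 - h2) / h2) residuals.

    With genetic variance scaled to 1, this residual variance makes the
    narrow-sense heritability of the phenotype exactly h2.  Residuals are
    independent across traits (residual correlation 0) and only cows (G1+
    females) receive records.
    """
    if pop.tbv is None:
        raise DataError("compute_tbv must run before simulate_phenotypes")
    rng = _as_rng(seed)
    h2 = np.asarray(arch.heritabilities, dtype=float)
    resid_sd = np.sqrt((1.0 - h2) / h2)
    phen = np.full((pop.n_animals, 2), np.nan)
    cows = pop.animals_with_role(ROLE_COW)
    phen[cows] = pop.tbv[cows] + rng.standard_normal((cows.size, 2)) * resid_sd
    pop.phenotypes = phen
    return pop


def mendelian_error_count(pop: Population) -> int:
    """Number of (animal, locus) transmissions violating Mendelian inheritance.

    The paternal (maternal) allele of every non-founder must be present in
    its sire's (dam's) haplotype pair at that locus; under pure gene
    dropping the count is 0.
    """
    ped = pop.pedigree
    h = pop.haplotypes
    errors = 0
    for which, col in ((0, "sire"), (1, "dam")):
        parents = ped[col].to_numpy()
        child = ped["animal"].to_numpy()[parents >= 0]
        par = parents[parents >= 0]
        allele = h[child, which, :]
        ph = h[par]
        ok = (allele == ph[:, 0, :]) | (allele == ph[:, 1, :])
        errors += int((~ok).sum())
    return errors
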