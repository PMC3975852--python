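"""Genome and trait-architecture builders for the gene-drop simulator.

The simulated genome is a set of chromosomes measured in centimorgans,
carrying two classes of biallelic loci: evenly spaced SNP markers (the
genotyping panel) and randomly placed QTLs.  QTLs fall into three pleiotropy
groups: loci affecting only trait I, loci affecting only trait II, and
pleiotropic loci whose allele-substitution effect is identical on both
traits.  With equal group sizes and i.i.d. effect magnitudes this makes the
expected genetic correlation between the traits 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

QTL_GROUPS = ("trait1_only", "trait2_only", "pleiotropic")

#: integer codes for the ``qtl_group`` array
TRAIT1_ONLY, TRAIT2_ONLY, PLEIOTROPIC = 0, 1, 2


class ConfigurationError(ValueError):
    """Raised when a genome or scenario configuration is inconsistent."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class GenomeSpec:
    """Positions of all typed loci (markers and QTLs) on a genetic map.

    Loci are stored in a single sorted-by-(chromosome, position) table so
    that haplotypes are flat 0/1 vectors of length ``n_loci``.

    Attributes
    ----------
    chromosome_lengths : array of map lengths in cM.
    chrom : per-locus chromosome index (0-based).
    pos_cm : per-locus genetic position within its chromosome, in cM.
    is_qtl : per-locus flag; markers are ``~is_qtl``.
    qtl_group : per-QTL group code (in QTL order): 0 trait-I-only,
        1 trait-II-only, 2 pleiotropic.
    """

    chromosome_lengths: np.ndarray
    chrom: np.ndarray
    pos_cm: np.ndarray
    is_qtl: np.ndarray
    qtl_group: np.ndarray

    def __post_init__(self):
        self.chromosome_lengths = np.asarray(self.chromosome_lengths, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=np.int64)
        self.pos_cm = np.asarray(self.pos_cm, dtype=float)
        self.is_qtl = np.asarray(self.is_qtl, dtype=bool)
        self.qtl_group = np.asarray(self.qtl_group, dtype=np.int8)
        if self.qtl_group.size != int(self.is_qtl.sum()):
            raise ConfigurationError("one group label per QTL locus required")
        order_ok = True
        for c in range(len(self.chromosome_lengths)):
            p = self.pos_cm[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                order_ok = False
        if not order_ok:
            raise ConfigurationError("locus positions must be strictly increasing")

    @property
    def n_loci(self) -> int:
        return self.pos_cm.size

    @property
    def n_markers(self) -> int:
        return int((~self.is_qtl).sum())

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def marker_index(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    @property
    def qtl_index(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def adjacent_recombination(self) -> np.ndarray:
        """Recombination fraction between consecutive loci (length n_loci-1).

        Haldane's map function within a chromosome; 0.5 across chromosome
        boundaries (independent assortment).
        """
        d = np.diff(self.pos_cm) / 100.0  # Morgans
        r = 0.5 * (1.0 - np.exp(-2.0 * d))
        r[np.diff(self.chrom) != 0] = 0.5
        return r

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"chrom": self.chrom, "pos_cm": self.pos_cm, "is_qtl": self.is_qtl}
        )
        grp = np.full(self.n_loci, "", dtype=object)
        grp[self.is_qtl] = [QTL_GROUPS[g] for g in self.qtl_group]
        df["qtl_group"] = grp
        return df


def build_genome_spec(
    chromosome_lengths=(100.0,) * 5,
    marker_spacing: float = 0.1,
    n_qtl: int = 300,
    qtl_group_sizes=None,
    qtl_density: pd.DataFrame | None = None,
    seed=None,
) -> GenomeSpec:
    """Build the locus map: equally spaced markers plus random QTL positions.

    Markers are placed at interval midpoints ``(k - 1/2) * spacing`` so a
    chromosome of length L carries exactly ``L / spacing`` markers.  QTL
    positions are drawn uniformly over the genome by default; a positional
    density table with columns (chrom, start_cm, end_cm, weight) may be
    supplied to concentrate QTLs in gene-rich intervals.

    QTLs are split into the three pleiotropy groups uniformly at random
    (default: equal thirds).
    """
    lengths = np.asarray(chromosome_lengths, dtype=float)
    if lengths.size < 1 or np.any(lengths <= 0):
        raise ConfigurationError("need >=1 chromosome with positive length")
    if marker_spacing <= 0:
        raise ConfigurationError("marker spacing must be positive")
    if n_qtl < 0:
        raise ConfigurationError("n_qtl must be non-negative")
    if qtl_group_sizes is None:
        base = n_qtl // 3
        qtl_group_sizes = (base, base, n_qtl - 2 * base)
    qtl_group_sizes = tuple(int(s) for s in qtl_group_sizes)
    if sum(qtl_group_sizes) != n_qtl or any(s < 0 for s in qtl_group_sizes):
        raise ConfigurationError("qtl_group_sizes must be non-negative and sum to n_qtl")

    rng = _as_rng(seed)

    m_chrom, m_pos = [], []
    for c, length in enumerate(lengths):
        k = int(round(length / marker_spacing))
        pos = (np.arange(k) + 0.5) * marker_spacing
        m_chrom.append(np.full(k, c))
        m_pos.append(pos)
    m_chrom = np.concatenate(m_chrom)
    m_pos = np.concatenate(m_pos)

    # QTL positions: continuous uniform (or density-weighted), redrawn on the
    # measure-zero event of colliding with a marker or another QTL.
    q_chrom = np.empty(n_qtl, dtype=np.int64)
    q_pos = np.empty(n_qtl, dtype=float)
    if qtl_density is not None:
        dens = pd.DataFrame(qtl_density)
        w = dens["weight"].to_numpy(dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("density weights must be non-negative, not all zero")
        w = w / w.sum()
    taken: set[tuple[int, float]] = set()
    for i in range(n_qtl):
        while True:
            if qtl_density is None:
                c = int(rng.choice(lengths.size, p=lengths / lengths.sum()))
                p = float(rng.uniform(0.0, lengths[c]))
            else:
                row = dens.iloc[int(rng.choice(len(dens), p=w))]
                c = int(row["chrom"])
                p = float(rng.uniform(row["start_cm"], row["end_cm"]))
            key = (c, p)
            on_marker = np.any((m_chrom == c) & (m_pos == p))
            if key not in taken and not on_marker:
                taken.add(key)
                q_chrom[i] = c
                q_pos[i] = p
                break

    group_codes = np.repeat(
        np.arange(3, dtype=np.int8), np.asarray(qtl_group_sizes, dtype=int)
    )
    rng.shuffle(group_codes)

    chrom = np.concatenate([m_chrom, q_chrom])
    pos = np.concatenate([m_pos, q_pos])
    is_qtl = np.concatenate(
        [np.zeros(m_pos.size, dtype=bool), np.ones(n_qtl, dtype=bool)]
    )
    grp_per_locus = np.concatenate(
        [np.full(m_pos.size, -1, dtype=np.int8), group_codes]
    )
    order = np.lexsort((pos, chrom))
    chrom, pos, is_qtl = chrom[order], pos[order], is_qtl[order]
    grp_per_locus = grp_per_locus[order]
    return GenomeSpec(
        chromosome_lengths=lengths,
        chrom=chrom,
        pos_cm=pos,
        is_qtl=is_qtl,
        qtl_group=grp_per_locus[is_qtl],
    )


@dataclass
class TraitArchitecture:
    """Per-QTL allele-substitution effects for the two traits.

    ``effects`` has one row per QTL (in genome QTL order) and one column per
    trait.  Group-excluded entries are exactly zero; pleiotropic rows carry
    the identical signed value in both columns.  ``tbv_scale`` holds the
    per-trait divisor applied to raw breeding values so that the realized
    genetic variance in the scaling cohort is 1; it is ``None`` until
    :func:`mtgblup.population.compute_tbv` sets it.
    """

    effects: np.ndarray
    gamma_shape: float = 0.84
    gamma_scale: float = 5.4
    heritabilities: tuple = (0.3, 0.05)
    tbv_scale: np.ndarray | None = None

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim != 2 or self.effects.shape[1] != 2:
            raise ConfigurationError("effects must be (n_qtl, 2)")
        h2 = np.asarray(self.heritabilities, dtype=float)
        if np.any(h2 <= 0) or np.any(h2 > 1):
            raise ConfigurationError("heritabilities must lie in (0, 1]")
        self.heritabilities = tuple(h2)

    @property
    def n_traits(self) -> int:
        return 2


def sample_qtl_effects(
    genome: GenomeSpec,
    shape: float = 0.84,
    scale: float = 5.4,
    seed=None,
    heritabilities=(0.3, 0.05),
) -> TraitArchitecture:
    """Draw QTL effects: gamma magnitudes with random sign.

    One gamma(shape, scale) magnitude per QTL, sign + or - with equal
    probability.  Pleiotropic QTLs copy the identical signed value into both
    trait columns; single-trait QTLs have a zero in the other column.
    """
    if shape <= 0 or scale <= 0:
        raise ConfigurationError("gamma shape and scale must be positive")
    rng = _as_rng(seed)
    n = genome.n_qtl
    magnitude = rng.gamma(shape, scale, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    val = sign * magnitude
    effects = np.zeros((n, 2))
    g = genome.qtl_group
    effects[g == TRAIT1_ONLY, 0] = val[g == TRAIT1_ONLY]
    effects[g == TRAIT2_ONLY, 1] = val[g == TRAIT2_ONLY]
    effects[g == PLEIOTROPIC, 0] = val[g == PLEIOTROPIC]
    effects[g == PLEIOTROPIC, 1] = val[g == PLEIOTROPIC]
    return TraitArchitecture(
        effects=effects,
        gamma_shape=shape,
        gamma_scale=scale,
        heritabilities=tuple(heritabilities),
    )
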