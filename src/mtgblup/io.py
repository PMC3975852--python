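"""Readers and writers for the package's plain-text interchange formats.

Pedigrees travel as TSV with 1-based animal ids and 0 for unknown parents;
genotypes as PLINK .ped/.map (markers only) or a transposed locus x animal
dosage TSV; phenotypes as TSV with empty cells for missing records; genome
and trait architecture as a JSON bundle sufficient to replay a simulation;
relationship matrices as coordinate-format text with an id-map sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeSpec, QTL_GROUPS, TraitArchitecture
from .kinship import RelationshipMatrix
from .population import Population

PED_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "generation", "role"]


def write_pedigree(pop_or_frame, path) -> None:
    """Pedigree TSV (animal_id, sire_id, dam_id, sex, generation, role);
    ids are 1-based, 0 means unknown parent."""
    ped = pop_or_frame.pedigree if isinstance(pop_or_frame, Population) else pop_or_frame
    out = pd.DataFrame(
        {
            "animal_id": ped["animal"] + 1,
            "sire_id": ped["sire"] + 1,
            "dam_id": ped["dam"] + 1,
            "sex": ped["sex"],
            "generation": ped["generation"],
            "role": ped["role"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> pd.DataFrame:
    """Inverse of :func:`write_pedigree`: 0-based ids, -1 unknown."""
    df = pd.read_csv(path, sep="\t")
    missing = set(PED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pedigree file lacks columns: {sorted(missing)}")
    return pd.DataFrame(
        {
            "animal": df["animal_id"] - 1,
            "sire": df["sire_id"] - 1,
            "dam": df["dam_id"] - 1,
            "sex": df["sex"],
            "generation": df["generation"],
            "role": df["role"],
        }
    )


def write_phenotypes(pop: Population, path) -> None:
    """TSV animal_id, trait1, trait2 with empty cells for missing records."""
    if pop.phenotypes is None:
        raise ValueError("population has no phenotypes")
    has = ~np.all(np.isnan(pop.phenotypes), axis=1)
    df = pd.DataFrame(
        {
            "animal_id": np.flatnonzero(has) + 1,
            "trait1": pop.phenotypes[has, 0],
            "trait2": pop.phenotypes[has, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["animal_id"] = df["animal_id"] - 1
    return df


def write_plink(pop: Population, prefix, animals=None) -> None:
    """PLINK text .ped/.map for the marker panel (alleles coded 1/2).

    .map base-pair positions are synthetic (1 cM = 10,000 bp) since the
    simulation lives on a genetic map.
    """
    g = pop.genome
    markers = g.marker_index
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j, loc in enumerate(markers):
            fh.write(
                f"{g.chrom[loc] + 1}\tsnp{j + 1}\t{g.pos_cm[loc]:.6g}\t"
                f"{int(round(g.pos_cm[loc] * 1e4)) + 1}\n"
            )
    if animals is None:
        animals = np.arange(pop.n_animals)
    ped = pop.pedigree
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in animals:
            row = ped.loc[i]
            sex_code = 1 if row["sex"] == "M" else 2
            alleles = pop.haplotypes[i][:, markers] + 1  # 0/1 -> 1/2
            geno = " ".join(f"{a} {b}" for a, b in zip(alleles[0], alleles[1]))
            fh.write(
                f"FAM {i + 1} {row['sire'] + 1} {row['dam'] + 1} {sex_code} -9 {geno}\n"
            )


def write_dosages(pop: Population, path, animals=None, loci=None) -> None:
    """Transposed dosage TSV: one row per locus, one column per animal."""
    if animals is None:
        animals = np.arange(pop.n_animals)
    d = pop.dosages(loci)[animals].T
    cols = [f"animal_{i + 1}" for i in animals]
    pd.DataFrame(d, columns=cols).to_csv(path, sep="\t", index=False)


def write_genome_bundle(genome: GenomeSpec, arch: TraitArchitecture | None, path):
    """JSON bundle of the locus map and trait architecture, for replay."""
    obj = {
        "chromosome_lengths": genome.chromosome_lengths.tolist(),
        "chrom": genome.chrom.tolist(),
        "pos_cm": genome.pos_cm.tolist(),
        "is_qtl": genome.is_qtl.astype(int).tolist(),
        "qtl_group": [QTL_GROUPS[g] for g in genome.qtl_group],
    }
    if arch is not None:
        obj["architecture"] = {
            "effects": arch.effects.tolist(),
            "gamma_shape": arch.gamma_shape,
            "gamma_scale": arch.gamma_scale,
            "heritabilities": list(arch.heritabilities),
            "tbv_scale": None if arch.tbv_scale is None else arch.tbv_scale.tolist(),
        }
    Path(path).write_text(json.dumps(obj))


def read_genome_bundle(path):
    obj = json.loads(Path(path).read_text())
    genome = GenomeSpec(
        chromosome_lengths=np.array(obj["chromosome_lengths"]),
        chrom=np.array(obj["chrom"]),
        pos_cm=np.array(obj["pos_cm"]),
        is_qtl=np.array(obj["is_qtl"], dtype=bool),
        qtl_group=np.array([QTL_GROUPS.index(g) for g in obj["qtl_group"]]),
    )
    arch = None
    if "architecture" in obj:
        a = obj["architecture"]
        arch = TraitArchitecture(
            effects=np.array(a["effects"]),
            gamma_shape=a["gamma_shape"],
            gamma_scale=a["gamma_scale"],
            heritabilities=tuple(a["heritabilities"]),
            tbv_scale=None if a["tbv_scale"] is None else np.array(a["tbv_scale"]),
        )
    return genome, arch


def write_matrix(rm: RelationshipMatrix, prefix, dense: bool = False) -> None:
    """Coordinate-format text (i j value, 1-based, upper triangle included)
    with an id-map sidecar; ``dense=True`` writes a TSV instead."""
    prefix = Path(prefix)
    pd.DataFrame({"row": np.arange(rm.n) + 1, "animal_id": rm.ids + 1}).to_csv(
        prefix.with_suffix(".ids.tsv"), sep="\t", index=False
    )
    if dense:
        m = rm.matrix.toarray() if sp.issparse(rm.matrix) else np.asarray(rm.matrix)
        pd.DataFrame(m).to_csv(prefix.with_suffix(".tsv"), sep="\t", index=False)
        return
    coo = sp.coo_matrix(rm.matrix)
    with open(prefix.with_suffix(".coo.txt"), "w") as fh:
        fh.write(f"# kind={rm.kind} n={rm.n} ridge={rm.ridge}\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i + 1}\t{j + 1}\t{v!r}\n")


def write_solutions(results, path, reliability: bool = False) -> None:
    """Solutions TSV: animal_id, trait, value (optionally PEV reliability)."""
    sols = results.solutions
    rel = results.reliability() if reliability else None
    rows = []
    for trait in sols.columns:
        for animal, value in sols[trait].items():
            row = [animal + 1, trait, value]
            if rel is not None:
                row.append(rel.loc[animal, trait])
            rows.append(row)
    cols = ["animal_id", "trait", "value"] + (["reliability"] if reliability else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_varcomp(vc, path, model_tag: str = "", seed=None) -> None:
    obj = {
        "model_tag": model_tag,
        "H": np.asarray(vc.H).tolist(),
        "R": np.asarray(vc.R).tolist(),
        "converged": bool(vc.converged),
        "log_likelihood": float(vc.log_likelihood),
        "iterations": int(vc.iterations),
        "method": vc.method,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(obj, indent=1))
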