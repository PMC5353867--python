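"""Readers and writers for the plain-text interchange formats.

Genotypes travel as PLINK ``.raw``-style whitespace tables plus a
``.bim``-style map; phenotypes as TSV; regions as a BED-like TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genome_data import DRPTable, GenotypePanel, MarkerMap, RegionPartition

_PLINK_META_COLS = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


def read_marker_map(path) -> MarkerMap:
    """Read a map file: 6-column PLINK .bim or 3-column simple TSV.

    .bim columns: chromosome, marker_id, cM, position, allele1, allele2.
    Simple layout: chromosome, marker_id, position.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if df.shape[1] >= 6:
        chrom, mid, pos = df[0], df[1], df[3]
    elif df.shape[1] == 3:
        chrom, mid, pos = df[0], df[1], df[2]
    else:
        raise ValueError(f"unrecognized map layout with {df.shape[1]} columns")
    return MarkerMap(
        mid.to_numpy(dtype=object),
        chrom.astype(int).to_numpy(),
        pos.astype(int).to_numpy(),
    )


def read_genotypes_raw(path, marker_map: MarkerMap, population_id: str) -> GenotypePanel:
    """Read a PLINK .raw-style additive-dosage table.

    Accepts the standard PLINK header (FID IID PAT MAT SEX PHENOTYPE then
    one column per marker, optionally suffixed ``_A``) or a minimal layout
    with an ``animal_id`` column followed by marker columns.  Columns are
    matched to ``marker_map`` by marker id and reordered to map order.
    """
    df = pd.read_csv(path, sep=r"\s+")
    cols = list(df.columns)
    if cols[: len(_PLINK_META_COLS)] == list(_PLINK_META_COLS):
        ids = df["IID"].astype(str).to_numpy(dtype=object)
        geno_cols = cols[len(_PLINK_META_COLS):]
    elif cols[0] in ("animal_id", "ID", "id"):
        ids = df[cols[0]].astype(str).to_numpy(dtype=object)
        geno_cols = cols[1:]
    else:
        raise ValueError("unrecognized genotype table header")

    # strip PLINK's counted-allele suffix (SNP_A) if present
    name_of = {c: c.rsplit("_", 1)[0] if c.rsplit("_", 1)[-1] in "ACGT" else c
               for c in geno_cols}
    by_name = {name_of[c]: c for c in geno_cols}
    missing = [m for m in marker_map.marker_id if m not in by_name]
    if missing:
        raise ValueError(
            f"{len(missing)} map markers absent from genotype table "
            f"(first: {missing[0]!r})"
        )
    ordered = [by_name[m] for m in marker_map.marker_id]
    g = df[ordered].to_numpy()
    return GenotypePanel(population_id, g, marker_map, animal_id=ids)


def write_genotypes_raw(path, panel: GenotypePanel) -> None:
    df = pd.DataFrame(panel.genotypes, columns=list(panel.map.marker_id))
    df.insert(0, "animal_id", panel.animal_id)
    df.to_csv(path, sep=" ", index=False)


def write_marker_map(path, marker_map: MarkerMap) -> None:
    df = pd.DataFrame(
        {
            0: marker_map.chromosome,
            1: marker_map.marker_id,
            2: 0.0,
            3: marker_map.position,
            4: "A",
            5: "B",
        }
    )
    df.to_csv(path, sep="\t", index=False, header=False)


def read_phenotypes(path) -> dict:
    """Read DRP phenotypes from TSV with columns
    animal_id, population, trait, drp, reliability.

    Returns {(population, trait): DRPTable}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str, "population": str})
    required = {"animal_id", "population", "trait", "drp", "reliability"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file must have columns {sorted(required)}")
    out = {}
    for (pop, trait), grp in df.groupby(["population", "trait"], sort=False):
        out[(pop, trait)] = DRPTable(
            population_id=pop,
            animal_id=grp["animal_id"].to_numpy(dtype=object),
            drp=grp["drp"].to_numpy(dtype=np.float64),
            reliability=grp["reliability"].to_numpy(dtype=np.float64),
        )
    return out


def write_phenotypes(path, tables, trait: str = "trait1") -> None:
    frames = []
    for t in tables:
        df = t.to_dataframe()[["animal_id", "population", "drp", "reliability"]]
        df.insert(2, "trait", trait)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_regions_bed(path, partition: RegionPartition, marker_map: MarkerMap) -> None:
    partition.to_dataframe(marker_map).to_csv(path, sep="\t", index=False)


def read_vcf(path, population_id: str) -> GenotypePanel:
    """Optional VCF reader mapping GT to additive dosage (requires cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = np.array(vcf.samples, dtype=object)
    mids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        dosage = np.asarray(var.gt_types, dtype=np.int64)
        # cyvcf2 gt_types: 0=hom-ref 1=het 2=unknown 3=hom-alt
        if np.any(dosage == 2):
            raise ValueError("missing genotypes are not supported (impute upstream)")
        dosage[dosage == 3] = 2
        mids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chroms.append(int(var.CHROM))
        poss.append(var.POS)
        rows.append(dosage)
    marker_map = MarkerMap(np.array(mids, dtype=object), np.array(chroms), np.array(poss))
    g = np.column_stack(rows) if rows else np.empty((len(ids), 0), dtype=np.int8)
    return GenotypePanel(population_id, g, marker_map, animal_id=ids)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
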