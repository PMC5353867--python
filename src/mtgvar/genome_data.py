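"""Genotype/phenotype data containers and preparation.

Provides marker maps, genotype panels (0/1/2 additive coding), MAF
filtering, allele-frequency centering, contiguous region partitioning
and reliability-based residual weights for deregressed-proof (DRP)
phenotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMap",
    "GenotypePanel",
    "Region",
    "RegionPartition",
    "DRPTable",
    "filter_maf",
    "center_genotypes",
    "partition_regions",
    "drp_weights",
    "harmonize_panels",
    "align_phenotypes",
]


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerMap:
    """Ordered autosomal marker map.

    Markers must be strictly ordered by (chromosome, position) with unique
    identifiers; sex chromosomes are expected to be removed upstream.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        mid = np.asarray(self.marker_id, dtype=object)
        chrom = np.asarray(self.chromosome, dtype=np.int64)
        pos = np.asarray(self.position, dtype=np.int64)
        object.__setattr__(self, "marker_id", mid)
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position", pos)
        if not (len(mid) == len(chrom) == len(pos)):
            raise ValueError("marker map columns must have equal length")
        if len(np.unique(mid)) != len(mid):
            raise ValueError("duplicate marker_id in map")
        if np.any(pos < 0):
            raise ValueError("negative marker position")
        if np.any(chrom <= 0):
            raise ValueError("non-positive chromosome label (sex chromosomes and "
                             "unplaced markers must be removed upstream)")
        key = chrom.astype(np.float64) * (pos.max(initial=0) + 1.0) + pos
        if len(key) > 1 and np.any(np.diff(key) <= 0):
            raise ValueError("markers must be strictly ordered by (chromosome, position)")

    def __len__(self) -> int:
        return len(self.marker_id)

    @property
    def chromosomes(self) -> np.ndarray:
        """Distinct chromosome labels in map order."""
        return pd.unique(self.chromosome)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.marker_id[idx], self.chromosome[idx], self.position[idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            df["marker_id"].to_numpy(dtype=object),
            df["chromosome"].to_numpy(),
            df["position"].to_numpy(),
        )


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------


@dataclass
class GenotypePanel:
    """One population's genotype matrix with its marker map.

    ``genotypes`` counts copies of the coded allele (0/1/2), no missing
    entries (imputation is upstream).  ``allele_freq`` is the observed
    frequency of the coded allele in this panel (column mean / 2); after
    cross-population harmonization it may exceed 0.5.
    """

    population_id: str
    genotypes: np.ndarray
    map: MarkerMap
    animal_id: np.ndarray = None
    allele_freq: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        g = np.asarray(self.genotypes)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (animals x markers)")
        if g.shape[1] != len(self.map):
            raise ValueError(
                f"genotype columns ({g.shape[1]}) != map length ({len(self.map)})"
            )
        if not np.isin(g, (0, 1, 2)).all():
            raise ValueError("genotypes must be coded 0/1/2 with no missing entries")
        self.genotypes = g.astype(np.int8, copy=False)
        if self.animal_id is None:
            self.animal_id = np.array(
                [f"{self.population_id}_{i}" for i in range(g.shape[0])], dtype=object
            )
        else:
            self.animal_id = np.asarray(self.animal_id, dtype=object)
            if len(self.animal_id) != g.shape[0]:
                raise ValueError("animal_id length != number of genotype rows")
        if self.allele_freq is None:
            self.allele_freq = observed_allele_freq(self.genotypes)
        else:
            self.allele_freq = np.asarray(self.allele_freq, dtype=np.float64)
            if len(self.allele_freq) != g.shape[1]:
                raise ValueError("allele_freq length != number of markers")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor-allele frequency regardless of which allele is coded."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def subset_markers(self, idx: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            population_id=self.population_id,
            genotypes=self.genotypes[:, idx],
            map=self.map.subset(idx),
            animal_id=self.animal_id,
        )


def observed_allele_freq(genotypes: np.ndarray) -> np.ndarray:
    """Coded-allele frequency p_k = column mean dosage / 2."""
    return np.asarray(genotypes, dtype=np.float64).mean(axis=0) / 2.0


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """Contiguous marker-index block (inclusive bounds into the filtered map)."""

    index: int
    chromosome: int
    first: int
    last: int

    @property
    def n_markers(self) -> int:
        return self.last - self.first + 1

    def slice(self) -> slice:
        return slice(self.first, self.last + 1)


@dataclass(frozen=True)
class RegionPartition:
    """Ordered, contiguous, non-overlapping cover of the marker map."""

    regions: tuple
    mode: str
    n_markers: int

    def __post_init__(self) -> None:
        if self.mode not in ("all_snp", "per_chromosome", "fixed_size"):
            raise ValueError(f"unknown partition mode {self.mode!r}")
        if not self.regions:
            raise ValueError("partition must contain at least one region")
        prev_last = -1
        for reg in self.regions:
            if reg.first != prev_last + 1:
                raise ValueError("regions must be contiguous and non-overlapping")
            if reg.last < reg.first:
                raise ValueError("empty region")
            prev_last = reg.last
        if self.regions and prev_last != self.n_markers - 1:
            raise ValueError("regions must cover every marker exactly once")

    def __len__(self) -> int:
        return len(self.regions)

    def sizes(self) -> np.ndarray:
        return np.array([r.n_markers for r in self.regions], dtype=np.int64)

    def bounds(self) -> tuple:
        """(starts, ends) arrays of inclusive marker-index bounds."""
        starts = np.array([r.first for r in self.regions], dtype=np.int64)
        ends = np.array([r.last for r in self.regions], dtype=np.int64)
        return starts, ends

    def to_dataframe(self, marker_map: MarkerMap) -> pd.DataFrame:
        """BED-like table: chromosome, start_bp, end_bp, region_index, n_snp."""
        rows = []
        for reg in self.regions:
            rows.append(
                {
                    "chromosome": reg.chromosome,
                    "start_bp": int(marker_map.position[reg.first]),
                    "end_bp": int(marker_map.position[reg.last]),
                    "region_index": reg.index,
                    "n_snp": reg.n_markers,
                }
            )
        return pd.DataFrame(rows)


def partition_regions(
    marker_map: MarkerMap,
    mode: str = "fixed_size",
    window: int = 100,
    merge_threshold: int = 50,
) -> RegionPartition:
    """Partition the map into regions.

    ``all_snp`` returns one region covering the whole map; ``per_chromosome``
    one region per chromosome; ``fixed_size`` cuts each chromosome into
    consecutive windows of ``window`` markers, merging a trailing remainder
    of fewer than ``merge_threshold`` markers into the preceding window
    (a remainder of at least ``merge_threshold`` stands alone).  A chromosome
    with fewer than ``merge_threshold`` markers and no preceding window is
    emitted as its own small region with a warning.
    """
    m = len(marker_map)
    if m == 0:
        raise ValueError("empty marker map")
    regions: list[Region] = []

    if mode == "all_snp":
        chrom = int(marker_map.chromosome[0])
        regions.append(Region(0, chrom, 0, m - 1))
        return RegionPartition(tuple(regions), mode, m)

    chroms = marker_map.chromosomes
    offsets = {}
    for c in chroms:
        idx = np.flatnonzero(marker_map.chromosome == c)
        offsets[int(c)] = (int(idx[0]), int(idx[-1]))

    if mode == "per_chromosome":
        for j, c in enumerate(chroms):
            first, last = offsets[int(c)]
            regions.append(Region(j, int(c), first, last))
        return RegionPartition(tuple(regions), mode, m)

    if mode != "fixed_size":
        raise ValueError(f"unknown partition mode {mode!r}")
    if not (window > merge_threshold > 0):
        raise ValueError("fixed_size requires window > merge_threshold > 0")

    j = 0
    for c in chroms:
        first, last = offsets[int(c)]
        n = last - first + 1
        if n < merge_threshold:
            warnings.warn(
                f"chromosome {int(c)} has only {n} markers "
                f"(< merge threshold {merge_threshold}); kept as one small region"
            )
            regions.append(Region(j, int(c), first, last))
            j += 1
            continue
        starts = list(range(first, last + 1, window))
        # merge a short trailing remainder into the preceding window
        if len(starts) > 1 and (last - starts[-1] + 1) < merge_threshold:
            starts.pop()
        for i, s in enumerate(starts):
            e = starts[i + 1] - 1 if i + 1 < len(starts) else last
            regions.append(Region(j, int(c), s, e))
            j += 1
    return RegionPartition(tuple(regions), mode, m)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def drp_weights(
    reliability: np.ndarray,
    formula: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Residual-variance weights d from DRP reliabilities.

    Default d = (1 - r2) / r2, so a record's residual variance is modelled
    as d * sigma2_e.  ``formula`` may override the mapping (e.g. 1 / r2).
    """
    r2 = np.asarray(reliability, dtype=np.float64)
    if np.any(r2 <= 0.0) or np.any(r2 >= 1.0):
        raise ValueError("reliability must lie strictly in (0, 1)")
    if formula is None:
        d = (1.0 - r2) / r2
    else:
        d = np.asarray(formula(r2), dtype=np.float64)
    if np.any(d <= 0.0):
        raise ValueError("residual weights must be positive")
    return d


@dataclass
class DRPTable:
    """Per-animal deregressed proofs with reliabilities and residual weights."""

    population_id: str
    animal_id: np.ndarray
    drp: np.ndarray
    reliability: np.ndarray
    weight: np.ndarray = None

    def __post_init__(self) -> None:
        self.animal_id = np.asarray(self.animal_id, dtype=object)
        self.drp = np.asarray(self.drp, dtype=np.float64)
        self.reliability = np.asarray(self.reliability, dtype=np.float64)
        n = len(self.animal_id)
        if not (len(self.drp) == len(self.reliability) == n):
            raise ValueError("DRP table columns must have equal length")
        if len(np.unique(self.animal_id)) != n:
            raise ValueError("one record per animal: duplicate animal_id")
        if self.weight is None:
            self.weight = drp_weights(self.reliability)
        else:
            self.weight = np.asarray(self.weight, dtype=np.float64)
            if np.any(self.weight <= 0):
                raise ValueError("residual weights must be positive")

    def __len__(self) -> int:
        return len(self.animal_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal_id": self.animal_id,
                "population": self.population_id,
                "drp": self.drp,
                "reliability": self.reliability,
                "weight": self.weight,
            }
        )


def align_phenotypes(panel: GenotypePanel, table: DRPTable) -> tuple:
    """Return (y, d) ordered by the panel's genotype rows.

    Every animal with a DRP record must have a genotype row; animals
    genotyped but without a record are not allowed for the samplers here.
    """
    pos = {a: i for i, a in enumerate(table.animal_id)}
    missing = [a for a in panel.animal_id if a not in pos]
    if missing:
        raise ValueError(
            f"{len(missing)} genotyped animals lack DRP records "
            f"(first: {missing[0]!r})"
        )
    order = np.array([pos[a] for a in panel.animal_id], dtype=np.int64)
    return table.drp[order], table.weight[order]


# ---------------------------------------------------------------------------
# Filtering & harmonization
# ---------------------------------------------------------------------------


def filter_maf(panel: GenotypePanel, threshold: float = 0.01) -> GenotypePanel:
    """Drop markers with minor-allele frequency below ``threshold``."""
    if not (0.0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    keep = np.flatnonzero(panel.maf >= threshold)
    if keep.size == 0:
        raise ValueError(
            f"no markers survive MAF filtering at threshold {threshold}"
        )
    return panel.subset_markers(keep)


def center_genotypes(panel: GenotypePanel) -> np.ndarray:
    """Centered covariate matrix W with W[n,k] = genotype[n,k] - 2 p_k.

    With p_k the observed coded-allele frequency every column of W sums
    to zero (up to float round-off).
    """
    g = panel.genotypes.astype(np.float64)
    return g - 2.0 * panel.allele_freq[np.newaxis, :]


def harmonize_panels(
    panel1: GenotypePanel,
    panel2: GenotypePanel,
    maf_threshold: float = 0.01,
    flip: Sequence[bool] | None = None,
) -> tuple:
    """Restrict two panels to one shared marker set with one coded allele.

    Markers failing the MAF filter in EITHER population are dropped from
    both, so downstream models see a single common map.  ``flip`` marks
    markers whose coded allele in panel2 is the complement of panel1's
    (dosage is recoded as 2 - g there); after flipping the coded-allele
    frequency in panel2 may exceed 0.5.
    """
    ids1 = {m: i for i, m in enumerate(panel1.map.marker_id)}
    common = [m for m in panel2.map.marker_id if m in ids1]
    if not common:
        raise ValueError("panels share no markers")
    idx2 = np.array(
        [i for i, m in enumerate(panel2.map.marker_id) if m in ids1], dtype=np.int64
    )
    idx1 = np.array([ids1[m] for m in common], dtype=np.int64)

    g1 = panel1.genotypes[:, idx1]
    g2 = panel2.genotypes[:, idx2]
    if flip is not None:
        flip = np.asarray(flip, dtype=bool)
        if len(flip) != len(common):
            raise ValueError("flip mask length != number of shared markers")
        g2 = g2.copy()
        g2[:, flip] = 2 - g2[:, flip]

    sub_map = panel1.map.subset(idx1)
    p1 = GenotypePanel(panel1.population_id, g1, sub_map, panel1.animal_id)
    p2 = GenotypePanel(panel2.population_id, g2, sub_map, panel2.animal_id)

    keep = np.flatnonzero((p1.maf >= maf_threshold) & (p2.maf >= maf_threshold))
    if keep.size == 0:
        raise ValueError(
            f"no markers survive the joint MAF filter at threshold {maf_threshold}"
        )
    return p1.subset_markers(keep), p2.subset_markers(keep)
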