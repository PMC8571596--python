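"""Core data containers shared by all pipeline stages.

Coordinate convention: every interval held internally is 0-based,
half-open ``[start, end)``. Conversion from/to 1-based formats (VCF,
GFF3) happens only at the I/O boundary in :mod:`sweepscan.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

#: Sentinel dosage code for a missing (or half-missing) diploid genotype.
MISSING: int = -1

#: The two group labels every analysis is phrased in terms of: the case
#: group (``HG``) whose diversity loss is scanned for, and the control
#: group (``CG``).
GROUP_LABELS: Tuple[str, str] = ("HG", "CG")


class DataError(ValueError):
    """Fatal problem with user-supplied data (CLI exit code 2)."""


@dataclass(frozen=True)
class Site:
    """One biallelic SNP site (position is 1-based, as printed in VCF)."""

    chrom: str
    pos: int
    ref: str
    alt: str


@dataclass
class GenotypeMatrix:
    """Biallelic SNP sites x diploid individuals, alt-allele dosage coded.

    ``dosages`` is an ``int8`` array of shape ``(n_sites, n_individuals)``
    with entries in ``{0, 1, 2, MISSING}`` — the count of alternate
    alleles in each diploid genotype, phase ignored.
    """

    sites: List[Site]
    dosages: np.ndarray
    individual_ids: List[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.sites), len(self.individual_ids)):
            raise DataError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sites)} sites x {len(self.individual_ids)} individuals"
            )
        allowed = {0, 1, 2, MISSING}
        present = set(np.unique(self.dosages).tolist())
        if not present <= allowed:
            raise DataError(f"invalid dosage codes {sorted(present - allowed)}")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise DataError("duplicate individual ids")
        self._check_sorted()

    def _check_sorted(self) -> None:
        last: Dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise DataError(
                    f"positions not strictly increasing on {s.chrom} at {s.pos}"
                )
            last[s.chrom] = s.pos

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def positions(self, chrom: str) -> np.ndarray:
        """1-based positions of all sites on ``chrom`` (ascending)."""
        return np.array([s.pos for s in self.sites if s.chrom == chrom], dtype=np.int64)

    def chrom_slice(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(positions, dosage sub-matrix) for one chromosome."""
        idx = np.array([i for i, s in enumerate(self.sites) if s.chrom == chrom], dtype=np.intp)
        pos = np.array([self.sites[i].pos for i in idx], dtype=np.int64)
        return pos, self.dosages[idx]

    def chromosomes(self) -> List[str]:
        seen: Dict[str, None] = {}
        for s in self.sites:
            seen.setdefault(s.chrom)
        return list(seen)


@dataclass
class PopulationMap:
    """Individual id -> group label (``HG`` or ``CG``)."""

    assignments: Dict[str, str]

    def __post_init__(self) -> None:
        bad = {g for g in self.assignments.values() if g not in GROUP_LABELS}
        if bad:
            raise DataError(f"unknown group labels {sorted(bad)}; expected {GROUP_LABELS}")
        for g in GROUP_LABELS:
            if g not in self.assignments.values():
                raise DataError(f"group {g!r} has no individuals")

    def group(self, label: str) -> List[str]:
        return [i for i, g in self.assignments.items() if g == label]

    def indices(self, individual_ids: Sequence[str], label: str) -> np.ndarray:
        """Column indices of ``label`` members within ``individual_ids``."""
        missing = [i for i in individual_ids if i not in self.assignments]
        if missing:
            raise DataError(f"individuals missing from population map: {missing}")
        return np.array(
            [k for k, i in enumerate(individual_ids) if self.assignments[i] == label],
            dtype=np.intp,
        )

    def sizes(self) -> Tuple[int, int]:
        hg = sum(1 for g in self.assignments.values() if g == "HG")
        cg = sum(1 for g in self.assignments.values() if g == "CG")
        return hg, cg


@dataclass(frozen=True)
class Region:
    """A CNV region, 0-based half-open."""

    chrom: str
    start: int
    end: int
    region_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"region {self.region_id}: end {self.end} <= start {self.start}")


@dataclass
class CNMatrix:
    """CNV regions x individuals, diploid-total copy numbers (reference 2)."""

    regions: List[Region]
    values: np.ndarray
    individual_ids: List[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.regions), len(self.individual_ids)):
            raise DataError(
                f"CN matrix shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.individual_ids)} individuals"
            )
        if self.values.size and np.nanmin(self.values) < 0:
            raise DataError("negative copy-number value")
        ids = [r.region_id for r in self.regions]
        if len(set(ids)) != len(ids):
            raise DataError("duplicate region ids")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


@dataclass(frozen=True)
class GeneModel:
    """One gene span, 0-based half-open; strand in {'+', '-', '.'}."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise DataError(f"gene {self.gene_id}: end {self.end} <= start {self.start}")
        if self.strand not in ("+", "-", "."):
            raise DataError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class GeneSetCollection:
    """Term id -> (term name, member gene ids)."""

    sets: Dict[str, Tuple[str, List[str]]]

    def __post_init__(self) -> None:
        for term, (_, members) in self.sets.items():
            if not members:
                raise DataError(f"gene set {term!r} has no members")


@dataclass(frozen=True)
class Window:
    """One sliding-window tile, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class WindowStatRow:
    window: Window
    n_snps: int
    pi_hg: float
    pi_cg: float
    pi_ratio: float  # may be +inf or NaN (undefined)
    fst: float       # may be negative or NaN (undefined)


@dataclass
class CNVStatRow:
    region: Region
    maf: float
    silhouette: float
    vst: float
    fst: float       # NaN when undefined
    t_stat: float
    p_value: float
    mean_hg: float
    mean_cg: float
    var_hg: float
    var_cg: float
    var_total: float
    n_hg: int
    n_cg: int

    @property
    def n_total(self) -> int:
        return self.n_hg + self.n_cg


@dataclass
class CandidateSet:
    """Intervals surviving percentile intersection, with gene assignments.

    ``overlap`` maps an interval key to gene ids whose span intersects it;
    ``flank`` maps to (gene id, distance bp) pairs within the flank range
    but not overlapping. The two lists are disjoint per interval.
    """

    intervals: List  # Window or Region
    overlap: Dict[object, List[str]] = field(default_factory=dict)
    flank: Dict[object, List[Tuple[str, int]]] = field(default_factory=dict)

    def all_genes(self) -> List[str]:
        """Union of overlap and flank gene ids, sorted, deduplicated."""
        out = set()
        for genes in self.overlap.values():
            out.update(genes)
        for pairs in self.flank.values():
            out.update(g for g, _ in pairs)
        return sorted(out)
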