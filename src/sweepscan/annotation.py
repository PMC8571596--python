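"""Candidate-interval gene annotation: half-open overlap and +/- flank
assignment via a sorted sweep (no all-pairs scan). Strand is ignored."""

from __future__ import annotations

import logging
from typing import Dict, Iterable, List, Sequence, Tuple

from .model import CandidateSet, DataError, GeneModel

logger = logging.getLogger(__name__)


def _interval_key(iv) -> Tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def _by_chrom(genes: Sequence[GeneModel]) -> Dict[str, List[GeneModel]]:
    out: Dict[str, List[GeneModel]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    for lst in out.values():
        lst.sort(key=lambda g: (g.start, g.end))
    return out


def _sweep_overlaps(
    intervals: Sequence, genes_sorted: List[GeneModel]
) -> Dict[Tuple[str, int, int], List[str]]:
    """Sorted two-pointer sweep over one chromosome.

    Genes are consumed in start order; an active list holds genes whose
    span may still intersect upcoming intervals (pruned by end).
    """
    result: Dict[Tuple[str, int, int], List[str]] = {}
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    active: List[GeneModel] = []
    gi = 0
    for iv in ivs:
        while gi < len(genes_sorted) and genes_sorted[gi].start < iv.end:
            active.append(genes_sorted[gi])
            gi += 1
        active = [g for g in active if g.end > iv.start]
        hits = sorted({g.gene_id for g in active if g.start < iv.end})
        result[_interval_key(iv)] = hits
    return result


def overlap_genes(intervals: Sequence, genes: Sequence[GeneModel]) -> CandidateSet:
    """Assign each gene whose half-open span intersects an interval
    (>= 1 bp; abutting spans do not overlap)."""
    by_chrom = _by_chrom(genes)
    iv_by_chrom: Dict[str, List] = {}
    for iv in intervals:
        iv_by_chrom.setdefault(iv.chrom, []).append(iv)

    overlap: Dict[Tuple[str, int, int], List[str]] = {}
    for chrom, ivs in iv_by_chrom.items():
        if chrom not in by_chrom:
            logger.warning("overlap_genes: no genes on chromosome %s", chrom)
            for iv in ivs:
                overlap[_interval_key(iv)] = []
            continue
        overlap.update(_sweep_overlaps(ivs, by_chrom[chrom]))
    return CandidateSet(intervals=list(intervals), overlap=overlap)


def flank_genes(
    intervals: Sequence,
    genes: Sequence[GeneModel],
    flank_bp: int = 2_000_000,
) -> CandidateSet:
    """Assign genes within ``flank_bp`` of each interval edge that do NOT
    overlap it, with the nearest-edge gap distance in bp.

    The range is per side (+/- flank_bp from the interval's edges).
    Overlapping genes belong to :func:`overlap_genes` only, keeping the
    two categories disjoint.
    """
    if flank_bp < 0:
        raise DataError("flank_bp must be >= 0")
    by_chrom = _by_chrom(genes)
    flank: Dict[Tuple[str, int, int], List[Tuple[str, int]]] = {}
    for iv in intervals:
        hits: List[Tuple[str, int]] = []
        for g in by_chrom.get(iv.chrom, []):
            if g.start >= iv.end:
                dist = g.start - iv.end
            elif g.end <= iv.start:
                dist = iv.start - g.end
            else:
                continue  # overlapping -> not a flank gene
            if dist <= flank_bp:
                hits.append((g.gene_id, dist))
        seen = set()
        uniq = []
        for gid, dist in sorted(hits, key=lambda t: (t[1], t[0])):
            if gid not in seen:
                seen.add(gid)
                uniq.append((gid, dist))
        flank[_interval_key(iv)] = uniq
    return CandidateSet(intervals=list(intervals), flank=flank)


def annotate(
    intervals: Sequence,
    genes: Sequence[GeneModel],
    flank_bp: int = 2_000_000,
) -> CandidateSet:
    """Overlap and flank assignment in one CandidateSet."""
    ov = overlap_genes(intervals, genes)
    fl = flank_genes(intervals, genes, flank_bp=flank_bp)
    return CandidateSet(intervals=list(intervals), overlap=ov.overlap, flank=fl.flank)


def gene_universe(genes: Iterable[GeneModel]) -> List[str]:
    """Deduplicated, sorted gene ids (case-sensitive)."""
    return sorted({g.gene_id for g in genes})
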