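"""End-to-end orchestration of the scan stages.

Each run stage reads its inputs through io_formats, executes the
statistics modules, writes the deterministic result tables, and records
cutoffs plus input checksums in a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import pandas as pd
from cyvcf2 import VCF

from . import __version__
from .annotation import annotate, gene_universe
from .cnv_selection import compute_cnv_stats, filter_reliable, select_cnv_candidates
from .enrichment import EnrichmentRow, enrich
from .io_formats import (
    CANDIDATE_COLUMNS,
    ENRICH_COLUMNS,
    read_cn_matrix,
    read_genes,
    read_gmt,
    read_population_map,
    read_vcf,
    write_bed,
    write_results,
)
from .model import CandidateSet, DataError, Window
from .window_stats import (
    compute_window_stats,
    intersect_windows,
    make_windows,
    select_top,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; defaults mirror the published scan settings
    (40 kb windows, 20 kb step, top 1%, MAF 0.05, 2 Mb flank, p < .05,
    FDR <= .05)."""

    vcf: Optional[str] = None
    popmap: Optional[str] = None
    cn_matrix: Optional[str] = None
    genes: Optional[str] = None
    gene_format: str = "gff3"
    gene_sets: Optional[str] = None
    window_bp: int = 40_000
    step_bp: int = 20_000
    top_fraction_snp: float = 0.01
    top_fraction_cnv: float = 0.01
    maf_min: float = 0.05
    silhouette_min: float = 0.7
    flank_bp: int = 2_000_000
    p_max: float = 0.05
    q_max: float = 0.05
    out_dir: str = "sweepscan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_fraction_snp", "top_fraction_cnv"):
            v = getattr(self, name)
            if not (0.0 < v <= 0.5):
                raise DataError(f"{name} must lie in (0, 0.5], got {v}")
        if self.window_bp <= 0 or self.step_bp <= 0:
            raise DataError("window_bp and step_bp must be positive")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _contig_lengths(vcf_path: str, genotypes) -> Dict[str, int]:
    """Contig lengths from the VCF header, falling back to max(position)."""
    lengths: Dict[str, int] = {}
    try:
        v = VCF(vcf_path)
        for name, length in zip(v.seqnames, v.seqlens):
            if length > 0:
                lengths[name] = int(length)
    except Exception:
        pass
    for chrom in genotypes.chromosomes():
        if chrom not in lengths:
            lengths[chrom] = int(genotypes.positions(chrom).max())
    return {c: lengths[c] for c in genotypes.chromosomes()}


def _candidate_gene_frame(cs: CandidateSet) -> pd.DataFrame:
    rows = []
    for iv in cs.intervals:
        key = (iv.chrom, iv.start, iv.end)
        iid = getattr(iv, "region_id", f"{iv.chrom}:{iv.start}-{iv.end}")
        for gid in cs.overlap.get(key, []):
            rows.append((iv.chrom, iv.start, iv.end, iid, gid, "overlap", 0))
        for gid, dist in cs.flank.get(key, []):
            rows.append((iv.chrom, iv.start, iv.end, iid, gid, "flank", dist))
    return pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)


def run_snp_scan(config: RunConfig) -> CandidateSet:
    """Sliding-window scan: pi x2, pi-ratio, F_ST, top-percentile
    intersection, gene overlap. Writes window_stats.tsv,
    candidate_windows.bed and candidate_genes_snp.tsv."""
    os.makedirs(config.out_dir, exist_ok=True)
    genotypes = read_vcf(config.vcf)
    pops = read_population_map(config.popmap)
    genes = read_genes(config.genes, format=config.gene_format) if config.genes else []

    if genotypes.n_sites == 0:
        logger.warning("snp-scan: VCF holds no biallelic SNPs; writing empty outputs")
        write_results([], os.path.join(config.out_dir, "window_stats.tsv"), "window_stats")
        write_bed([], os.path.join(config.out_dir, "candidate_windows.bed"))
        write_results(
            pd.DataFrame(columns=CANDIDATE_COLUMNS),
            os.path.join(config.out_dir, "candidate_genes_snp.tsv"), "candidates",
        )
        _write_manifest(config, {"n_windows": 0, "n_candidates": 0}, "snp_scan")
        return CandidateSet(intervals=[])

    lengths = _contig_lengths(config.vcf, genotypes)
    windows = make_windows(lengths, config.window_bp, config.step_bp)
    logger.info("snp-scan: %d windows over %d chromosomes", len(windows), len(lengths))
    rows = compute_window_stats(genotypes, pops, windows)
    write_results(rows, os.path.join(config.out_dir, "window_stats.tsv"), "window_stats")

    frac = config.top_fraction_snp
    pi_cut, low_pi = select_top(rows, "pi_hg", tail="lower", fraction=frac)
    ratio_cut, high_ratio = select_top(rows, "pi_ratio", tail="upper", fraction=frac)
    fst_cut, high_fst = select_top(rows, "fst", tail="upper", fraction=frac)
    logger.info("snp-scan cutoffs: pi(HG) < %g | pi-ratio > %g | F_ST > %g",
                pi_cut, ratio_cut, fst_cut)
    candidates = intersect_windows(low_pi, high_ratio, high_fst)
    logger.info("snp-scan: %d candidate windows from the three-way intersection",
                len(candidates))
    write_bed(candidates, os.path.join(config.out_dir, "candidate_windows.bed"))

    cs = annotate(candidates, genes, flank_bp=config.flank_bp)
    write_results(
        _candidate_gene_frame(cs),
        os.path.join(config.out_dir, "candidate_genes_snp.tsv"), "candidates",
    )
    _write_manifest(
        config,
        {
            "n_windows": len(windows),
            "pi_hg_cutoff": pi_cut,
            "pi_ratio_cutoff": None if math.isinf(ratio_cut) else ratio_cut,
            "fst_cutoff": fst_cut,
            "n_candidates": len(candidates),
        },
        "snp_scan",
    )
    return cs


def run_cnv_scan(config: RunConfig) -> CandidateSet:
    """CNV scan: reliability filter, V_ST / F_ST / Welch t per region,
    top-percentile intersection, overlap + flank annotation."""
    os.makedirs(config.out_dir, exist_ok=True)
    matrix = read_cn_matrix(config.cn_matrix)
    pops = read_population_map(config.popmap)
    genes = read_genes(config.genes, format=config.gene_format) if config.genes else []

    reliable = filter_reliable(matrix, maf_min=config.maf_min,
                               silhouette_min=config.silhouette_min)
    stats = compute_cnv_stats(reliable, pops) if reliable.n_regions else []
    write_results(stats, os.path.join(config.out_dir, "cnv_stats.tsv"), "cnv_stats")

    if len(stats) < 2:
        logger.warning("cnv-scan: too few reliable regions; writing empty candidates")
        write_bed([], os.path.join(config.out_dir, "candidate_cnvs.bed"))
        write_results(
            pd.DataFrame(columns=CANDIDATE_COLUMNS),
            os.path.join(config.out_dir, "candidate_genes_cnv.tsv"), "candidates",
        )
        _write_manifest(config, {"n_reliable": len(stats), "n_candidates": 0}, "cnv_scan")
        return CandidateSet(intervals=[])

    fst_cut, vst_cut, candidates = select_cnv_candidates(
        stats, fraction=config.top_fraction_cnv
    )
    logger.info("cnv-scan cutoffs: F_ST > %g | V_ST > %g; %d candidates",
                fst_cut, vst_cut, len(candidates))
    regions = [r.region for r in candidates]
    write_bed(regions, os.path.join(config.out_dir, "candidate_cnvs.bed"))
    cs = annotate(regions, genes, flank_bp=config.flank_bp)
    write_results(
        _candidate_gene_frame(cs),
        os.path.join(config.out_dir, "candidate_genes_cnv.tsv"), "candidates",
    )
    _write_manifest(
        config,
        {
            "n_regions": matrix.n_regions,
            "n_reliable": reliable.n_regions,
            "fst_cutoff": fst_cut,
            "vst_cutoff": vst_cut,
            "n_candidates": len(candidates),
        },
        "cnv_scan",
    )
    return cs


def run_enrich(config: RunConfig, candidate_genes: Sequence[str]) -> List[EnrichmentRow]:
    """Over-representation of candidate genes against the annotation
    universe; skipped (empty result) when no gene sets are supplied."""
    os.makedirs(config.out_dir, exist_ok=True)
    if not config.gene_sets:
        logger.info("enrich: no gene-set file supplied; stage skipped")
        return []
    sets = read_gmt(config.gene_sets)
    genes = read_genes(config.genes, format=config.gene_format)
    universe = gene_universe(genes)
    rows = enrich(candidate_genes, universe, sets,
                  p_max=config.p_max, q_max=config.q_max)
    frame = pd.DataFrame(
        [
            (r.term_id, r.term_name, r.k, r.K, r.n, r.N, r.p_value, r.q_value,
             r.significant)
            for r in rows
        ],
        columns=ENRICH_COLUMNS,
    )
    write_results(frame, os.path.join(config.out_dir, "enrichment.tsv"), "enrichment")
    return rows


def run_all(config: RunConfig) -> None:
    snp_cs = run_snp_scan(config)
    cnv_cs = run_cnv_scan(config) if config.cn_matrix else CandidateSet(intervals=[])
    candidate_genes = sorted(set(snp_cs.all_genes()) | set(cnv_cs.all_genes()))
    run_enrich(config, candidate_genes)


def _write_manifest(config: RunConfig, stage_info: Dict, stage: str) -> None:
    manifest_path = os.path.join(config.out_dir, "run_manifest.json")
    manifest = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    checksums = {}
    for attr in ("vcf", "popmap", "cn_matrix", "genes", "gene_sets"):
        path = getattr(config, attr)
        if path and os.path.exists(path):
            checksums[attr] = _sha256(path)
    manifest["version"] = __version__
    manifest["config"] = dataclasses.asdict(config)
    manifest["input_sha256"] = checksums
    manifest[stage] = stage_info
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
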