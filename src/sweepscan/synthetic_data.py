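"""Two-population synthetic data with known ground truth.

SNP genotypes follow a Balding-Nichols allele-frequency model: per site
an ancestral frequency p ~ Uniform(0.05, 0.95) and group frequencies
drawn from Beta distributions with mean p and variance p(1-p)*F_bg.
Inside a sweep span the case-group (HG) frequency is pulled toward
fixation at the allele the control group carries at lower frequency,
which reduces pi(HG), raises the pi ratio and raises F_ST there. Copy
numbers come from shared neutral state distributions plus a few regions
with strongly shifted per-group distributions. Everything is a
deterministic function of (config, seed); linkage is not modelled
(sites are independent given their frequencies).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    CNMatrix,
    DataError,
    GenotypeMatrix,
    PopulationMap,
    Region,
    Site,
    Window,
)
from .io_formats import write_cn_matrix


@dataclass(frozen=True)
class SweepSpan:
    """A region where HG allele frequencies are pushed toward fixation.

    ``strength`` in [0, 1]: the swept HG frequency is drawn uniformly
    within ``0.5 * (1 - strength)`` of the target boundary, so 1 fixes
    the chosen allele (HG monomorphic) and higher strengths give lower
    case-group diversity.
    """

    start: int
    end: int
    strength: float = 1.0


@dataclass
class SimulationConfig:
    n_hg: int = 20
    n_cg: int = 52
    chrom: str = "1"
    chrom_length: int = 10_000_000
    snp_spacing_bp: int = 1_000          # one SNP per spacing bin (jittered)
    f_bg: float = 0.02                   # neutral background differentiation
    sweep_spans: Sequence[SweepSpan] = field(
        default_factory=lambda: tuple(
            SweepSpan(s, s + 40_000) for s in
            (1_000_000, 3_000_000, 5_000_000, 7_000_000, 9_000_000)
        )
    )
    n_cnv_regions: int = 200
    cnv_region_length: int = 10_000
    cnv_region_spacing: int = 50_000
    diff_cnv_indices: Sequence[int] = (20, 60, 100, 140, 180)
    cn_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hg < 2 or self.n_cg < 2:
            raise DataError("group sizes must be >= 2")
        if not (0.0 < self.f_bg < 1.0):
            raise DataError("f_bg must lie in (0, 1)")
        for span in self.sweep_spans:
            if not (0 <= span.start < span.end <= self.chrom_length):
                raise DataError(
                    f"sweep span ({span.start}, {span.end}) outside chromosome"
                )
            if not (0.0 <= span.strength <= 1.0):
                raise DataError("sweep strength must lie in [0, 1]")

    def individual_ids(self) -> Tuple[List[str], List[str]]:
        hg = [f"HG{i + 1:03d}" for i in range(self.n_hg)]
        cg = [f"CG{i + 1:03d}" for i in range(self.n_cg)]
        return hg, cg


def _population_map(config: SimulationConfig) -> PopulationMap:
    hg, cg = config.individual_ids()
    return PopulationMap({**{i: "HG" for i in hg}, **{i: "CG" for i in cg}})


def simulate_snp(
    config: SimulationConfig,
) -> Tuple[GenotypeMatrix, PopulationMap, List[Window]]:
    """Simulate the SNP dataset -> (genotypes, populations, swept windows).

    Sites are laid on a jittered grid (one per ``snp_spacing_bp``), so
    every window of the default tiling contains SNPs. The returned truth
    list holds the sweep spans as windows on the simulated chromosome.
    """
    rng = np.random.default_rng(config.seed)
    n_sites = config.chrom_length // config.snp_spacing_bp
    offsets = rng.integers(0, config.snp_spacing_bp, size=n_sites)
    pos = np.arange(n_sites, dtype=np.int64) * config.snp_spacing_bp + offsets + 1

    p_anc = rng.uniform(0.05, 0.95, size=n_sites)
    scale = (1.0 - config.f_bg) / config.f_bg
    p_hg = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)
    p_cg = rng.beta(p_anc * scale, (1.0 - p_anc) * scale)

    pos0 = pos - 1
    for span in config.sweep_spans:
        in_span = (pos0 >= span.start) & (pos0 < span.end)
        # sweep toward whichever allele the control group carries less of;
        # the swept frequency lands within 0.5*(1-strength) of the boundary,
        # so pi(HG) shrinks monotonically with strength (fixation at 1)
        target = np.where(p_cg[in_span] < 0.5, 1.0, 0.0)
        dist = rng.uniform(0.0, 0.5, size=int(in_span.sum())) * (1.0 - span.strength)
        p_hg[in_span] = np.abs(target - dist)

    dos_hg = rng.binomial(2, p_hg[:, None], size=(n_sites, config.n_hg))
    dos_cg = rng.binomial(2, p_cg[:, None], size=(n_sites, config.n_cg))
    dosages = np.hstack([dos_hg, dos_cg]).astype(np.int8)

    hg_ids, cg_ids = config.individual_ids()
    sites = [Site(config.chrom, int(p), "A", "G") for p in pos]
    gm = GenotypeMatrix(sites=sites, dosages=dosages, individual_ids=hg_ids + cg_ids)
    truth = [Window(config.chrom, s.start, s.end) for s in config.sweep_spans]
    return gm, _population_map(config), truth


# shared neutral CN state distribution and the shifted per-group ones
_NEUTRAL_STATES = (1, 2, 3)
_NEUTRAL_PROBS = (0.15, 0.70, 0.15)
_DIFF_HG_STATES = (0, 1)
_DIFF_HG_PROBS = (0.5, 0.5)
_DIFF_CG_STATES = (2, 3)
_DIFF_CG_PROBS = (0.85, 0.15)


def simulate_cn(config: SimulationConfig) -> Tuple[CNMatrix, List[str]]:
    """Simulate the CN matrix -> (matrix, differentiated region ids)."""
    rng = np.random.default_rng(config.seed + 1)  # independent of the SNP draw
    n_ind = config.n_hg + config.n_cg
    regions: List[Region] = []
    values = np.empty((config.n_cnv_regions, n_ind))
    diff = set(config.diff_cnv_indices)
    truth: List[str] = []
    for i in range(config.n_cnv_regions):
        start = i * config.cnv_region_spacing
        end = start + config.cnv_region_length
        rid = f"CNV{i + 1:04d}"
        regions.append(Region(config.chrom, start, end, rid))
        if i in diff:
            hg = rng.choice(_DIFF_HG_STATES, size=config.n_hg, p=_DIFF_HG_PROBS)
            cg = rng.choice(_DIFF_CG_STATES, size=config.n_cg, p=_DIFF_CG_PROBS)
            row = np.concatenate([hg, cg]).astype(float)
            truth.append(rid)
        else:
            row = rng.choice(_NEUTRAL_STATES, size=n_ind, p=_NEUTRAL_PROBS).astype(float)
        if config.cn_noise_sd > 0:
            row = row + rng.normal(0.0, config.cn_noise_sd, size=n_ind)
        values[i] = np.clip(row, 0.0, None)
    hg_ids, cg_ids = config.individual_ids()
    return CNMatrix(regions=regions, values=values, individual_ids=hg_ids + cg_ids), truth


@dataclass
class SimulatedBundle:
    config: SimulationConfig
    genotypes: GenotypeMatrix
    populations: PopulationMap
    swept_windows: List[Window]
    cn_matrix: CNMatrix
    diff_cnv_ids: List[str]
    genes: List[Tuple[str, int, int, str]]  # (chrom, start, end, gene id)


def _tile_genes(config: SimulationConfig) -> List[Tuple[str, int, int, str]]:
    """Toy genes every 100 kb (5 kb long); some fall inside sweep spans."""
    genes = []
    i = 0
    start = 20_000
    while start + 5_000 <= config.chrom_length:
        genes.append((config.chrom, start, start + 5_000, f"GENE{i + 1:04d}"))
        i += 1
        start += 100_000
    return genes


def simulate_bundle(config: SimulationConfig) -> SimulatedBundle:
    gm, pops, swept = simulate_snp(config)
    cn, diff_ids = simulate_cn(config)
    return SimulatedBundle(
        config=config,
        genotypes=gm,
        populations=pops,
        swept_windows=swept,
        cn_matrix=cn,
        diff_cnv_ids=diff_ids,
        genes=_tile_genes(config),
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_fixture(bundle: SimulatedBundle, directory: str, force: bool = False) -> Dict[str, str]:
    """Write the bundle as plain-text files consumable by io_formats.

    Emits snps.vcf, popmap.tsv, cn_matrix.tsv, genes.gff3,
    gene_sets.gmt and truth.json; returns the path of each. Re-running
    with the same config and seed reproduces the files byte for byte.
    """
    if os.path.isdir(directory) and os.listdir(directory) and not force:
        raise DataError(f"directory {directory} is not empty (use force to overwrite)")
    os.makedirs(directory, exist_ok=True)
    paths = {
        "vcf": os.path.join(directory, "snps.vcf"),
        "popmap": os.path.join(directory, "popmap.tsv"),
        "cn": os.path.join(directory, "cn_matrix.tsv"),
        "genes": os.path.join(directory, "genes.gff3"),
        "gmt": os.path.join(directory, "gene_sets.gmt"),
        "truth": os.path.join(directory, "truth.json"),
    }
    _write_vcf(bundle, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for ind, grp in bundle.populations.assignments.items():
            fh.write(f"{ind}\t{grp}\n")
    write_cn_matrix(bundle.cn_matrix, paths["cn"])
    _write_gff3(bundle, paths["genes"])
    _write_gmt(bundle, paths["gmt"])
    truth = {
        "swept_windows": [
            {"chrom": w.chrom, "start": w.start, "end": w.end}
            for w in bundle.swept_windows
        ],
        "diff_cnv_ids": bundle.diff_cnv_ids,
        "seed": bundle.config.seed,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def _write_vcf(bundle: SimulatedBundle, path: str) -> None:
    gm = bundle.genotypes
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            f"##contig=<ID={bundle.config.chrom},length={bundle.config.chrom_length}>\n"
        )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.individual_ids) + "\n"
        )
        for site, row in zip(gm.sites, gm.dosages):
            gts = "\t".join(_DOSAGE_GT[int(d)] for d in row)
            fh.write(
                f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


def _write_gff3(bundle: SimulatedBundle, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, start, end, gid in bundle.genes:
            # internal half-open -> GFF3 1-based inclusive
            fh.write(
                f"{chrom}\tsweepscan_sim\tgene\t{start + 1}\t{end}\t.\t+\t.\t"
                f"ID={gid};Name={gid}\n"
            )


def _swept_gene_ids(bundle: SimulatedBundle) -> List[str]:
    out = []
    for chrom, start, end, gid in bundle.genes:
        for w in bundle.swept_windows:
            if chrom == w.chrom and start < w.end and end > w.start:
                out.append(gid)
                break
    return out


def _write_gmt(bundle: SimulatedBundle, path: str) -> None:
    swept = _swept_gene_ids(bundle)
    all_ids = [g[3] for g in bundle.genes]
    background = [g for g in all_ids if g not in swept][:20]
    with open(path, "w") as fh:
        if swept:
            fh.write("SWEPT_SET\tgenes inside injected sweep spans\t" + "\t".join(swept) + "\n")
        fh.write("BACKGROUND_SET\tfirst 20 non-swept genes\t" + "\t".join(background) + "\n")
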