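"""Readers and writers for every external format the pipeline touches.

Reads: VCF 4.x (biallelic SNPs), two-column population maps, CN-matrix
TSV, GFF3/BED6 gene models, GMT gene sets. Writes: result TSVs and
candidate BED. All intervals become 0-based half-open on the way in;
GFF3's 1-based inclusive coordinates are shifted here and nowhere else.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .model import (
    MISSING,
    CNMatrix,
    CNVStatRow,
    DataError,
    GeneModel,
    GeneSetCollection,
    GenotypeMatrix,
    PopulationMap,
    Region,
    Site,
    WindowStatRow,
)

logger = logging.getLogger(__name__)

_SYMBOLIC = ("<", ">", "[", "]", "*")


def read_vcf(
    path: str,
    sample_subset: Optional[Sequence[str]] = None,
    pass_only: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF 4.x file.

    Multi-allelic, indel and symbolic records are skipped (counts are
    logged). Missing or half-missing genotypes are coded ``MISSING``;
    phase is ignored; ploidy other than 2 is rejected. The FILTER column
    is ignored unless ``pass_only`` is set.
    """
    if not os.path.exists(path):
        raise DataError(f"cannot read VCF: {path}")
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on bad files
        raise DataError(f"cannot read VCF {path}: {exc}") from exc

    header_samples = list(vcf.samples)
    if sample_subset is not None:
        absent = [s for s in sample_subset if s not in header_samples]
        if absent:
            raise DataError(f"samples absent from VCF header: {absent}")
        keep = [header_samples.index(s) for s in sample_subset]
        sample_ids = list(sample_subset)
    else:
        keep = list(range(len(header_samples)))
        sample_ids = header_samples

    sites: List[Site] = []
    rows: List[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or any(c in alt for c in _SYMBOLIC):
            n_skipped += 1
            continue
        if pass_only and var.FILTER is not None:
            n_skipped += 1
            continue
        gts = var.genotypes
        dos = np.empty(len(keep), dtype=np.int8)
        for out_i, col in enumerate(keep):
            gt = gts[col]
            alleles = gt[:-1]  # last element is the phase flag
            if len(alleles) != 2:
                raise DataError(
                    f"non-diploid genotype for sample {sample_ids[out_i]} "
                    f"at {var.CHROM}:{var.POS}"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[out_i] = MISSING
            else:
                dos[out_i] = alleles[0] + alleles[1]
        sites.append(Site(var.CHROM, var.POS, ref, alt))
        rows.append(dos)
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    dosages = (
        np.vstack(rows) if rows else np.empty((0, len(sample_ids)), dtype=np.int8)
    )
    return GenotypeMatrix(sites=sites, dosages=dosages, individual_ids=sample_ids)


def read_population_map(path: str) -> PopulationMap:
    """Read a two-column (id, group) delimited text file.

    Group labels are normalized case-insensitively to ``HG``/``CG``;
    a duplicate id or an unknown label is fatal.
    """
    assignments = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two columns, got {len(parts)}")
            ind, label = parts
            norm = label.upper()
            if norm not in ("HG", "CG"):
                raise DataError(f"{path}:{lineno}: unknown group label {label!r}")
            if ind in assignments:
                raise DataError(f"{path}:{lineno}: duplicate individual id {ind!r}")
            assignments[ind] = norm
    return PopulationMap(assignments)


def read_cn_matrix(path: str) -> CNMatrix:
    """Read a CN-matrix TSV: header of individual ids, then one row per
    region (chrom, start, end, id, values...)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise DataError(f"{path}: empty file")
        cols = header.split("\t")
        if len(cols) < 5 or cols[:4] != ["chrom", "start", "end", "region_id"]:
            raise DataError(
                f"{path}: header must start with chrom/start/end/region_id"
            )
        individual_ids = cols[4:]
        regions: List[Region] = []
        values: List[List[float]] = []
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(cols):
                raise DataError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}"
                )
            chrom, start, end, rid = parts[:4]
            try:
                row = [float(v) for v in parts[4:]]
                region = Region(chrom, int(start), int(end), rid)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            if min(row, default=0.0) < 0:
                raise DataError(f"{path}:{lineno}: negative copy-number value")
            regions.append(region)
            values.append(row)
    mat = (
        np.array(values, dtype=float)
        if values
        else np.empty((0, len(individual_ids)))
    )
    return CNMatrix(regions=regions, values=mat, individual_ids=individual_ids)


def read_genes(path: str, format: str = "gff3") -> List[GeneModel]:
    """Read gene models from GFF3 (``gene``-type features) or BED6.

    GFF3 1-based inclusive coordinates become 0-based half-open here;
    BED coordinates pass through. Output is sorted by (chrom, start).
    """
    if format == "gff3":
        genes = _read_gff3_genes(path)
    elif format == "bed":
        genes = _read_bed_genes(path)
    else:
        raise DataError(f"unknown gene format {format!r} (want gff3 or bed)")
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end, g.gene_id))


def _parse_gff3_attributes(field: str) -> dict:
    out = {}
    for item in field.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        k, v = item.split("=", 1)
        out[k] = v
    return out


def _read_gff3_genes(path: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise DataError(f"{path}:{lineno}: GFF3 line has {len(parts)} fields")
            chrom, _source, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype != "gene":
                continue
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            a = _parse_gff3_attributes(attrs)
            gid = a.get("ID", f"gene_{lineno}")
            name = a.get("Name", gid)
            if strand not in ("+", "-"):
                strand = "."
            genes.append(GeneModel(chrom, s - 1, e, strand, gid, name))
    return genes


def _read_bed_genes(path: str) -> List[GeneModel]:
    genes: List[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: BED line has {len(parts)} fields (need >= 4)")
            chrom, start, end = parts[0], parts[1], parts[2]
            name = parts[3]
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "."
            try:
                s, e = int(start), int(end)
            except ValueError as exc:
                raise DataError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(chrom, s, e, strand, name, name))
    return genes


def read_gmt(path: str) -> GeneSetCollection:
    """Read a GMT gene-set file: term, description, member genes per line."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            term, name = parts[0], parts[1]
            members = [g for g in parts[2:] if g]
            if not members:
                raise DataError(f"{path}:{lineno}: gene set {term!r} has no members")
            sets[term] = (name, members)
    return GeneSetCollection(sets)


# ---------------------------------------------------------------------------
# writers

WINDOW_COLUMNS = ["chrom", "start", "end", "n_snps", "pi_hg", "pi_cg", "pi_ratio", "fst"]
CNV_COLUMNS = [
    "chrom", "start", "end", "region_id", "maf", "silhouette", "vst", "fst",
    "t_stat", "p_value", "mean_hg", "mean_cg", "var_hg", "var_cg", "var_total",
    "n_hg", "n_cg",
]
CANDIDATE_COLUMNS = ["chrom", "start", "end", "interval_id", "gene_id", "relation", "distance_bp"]
ENRICH_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p_value", "q_value", "significant"]


def window_stats_frame(rows: Iterable[WindowStatRow]) -> pd.DataFrame:
    recs = [
        (r.window.chrom, r.window.start, r.window.end, r.n_snps,
         r.pi_hg, r.pi_cg, r.pi_ratio, r.fst)
        for r in rows
    ]
    return pd.DataFrame(recs, columns=WINDOW_COLUMNS)


def cnv_stats_frame(rows: Iterable[CNVStatRow]) -> pd.DataFrame:
    recs = [
        (r.region.chrom, r.region.start, r.region.end, r.region.region_id,
         r.maf, r.silhouette, r.vst, r.fst, r.t_stat, r.p_value,
         r.mean_hg, r.mean_cg, r.var_hg, r.var_cg, r.var_total, r.n_hg, r.n_cg)
        for r in rows
    ]
    return pd.DataFrame(recs, columns=CNV_COLUMNS)


def write_table(frame: pd.DataFrame, path: str) -> None:
    """Write a result table as TSV, floats at 6 significant digits."""
    try:
        frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


def write_bed(intervals: Iterable, path: str) -> None:
    """Write intervals (anything with chrom/start/end, plus optional id)
    as BED, 0-based half-open."""
    try:
        with open(path, "w") as fh:
            for iv in intervals:
                name = getattr(iv, "region_id", None)
                if name is not None:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
                else:
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    except OSError as exc:
        raise DataError(f"cannot write {path}: {exc}") from exc


def write_results(rows, path: str, kind: str) -> None:
    """Dispatching writer for the four result-table kinds.

    ``kind`` is one of window_stats / cnv_stats / candidates / enrichment;
    ``rows`` is the matching row list (or an already-built DataFrame for
    candidates / enrichment).
    """
    if kind == "window_stats":
        write_table(window_stats_frame(rows), path)
    elif kind == "cnv_stats":
        write_table(cnv_stats_frame(rows), path)
    elif kind in ("candidates", "enrichment"):
        frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(
            rows, columns=CANDIDATE_COLUMNS if kind == "candidates" else ENRICH_COLUMNS
        )
        write_table(frame, path)
    else:
        raise DataError(f"unknown result kind {kind!r}")


def write_cn_matrix(matrix: CNMatrix, path: str) -> None:
    """Write a CNMatrix in the TSV layout ``read_cn_matrix`` consumes."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tregion_id\t" + "\t".join(matrix.individual_ids) + "\n")
        for region, row in zip(matrix.regions, matrix.values):
            vals = "\t".join(_fmt(v) for v in row)
            fh.write(f"{region.chrom}\t{region.start}\t{region.end}\t{region.region_id}\t{vals}\n")


def _fmt(v: float) -> str:
    if math.isclose(v, round(v)) and abs(v) < 1e15:
        return str(int(round(v)))
    return format(v, ".6g")
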