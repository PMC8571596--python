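# sweepscan

Two-population selective-sweep and copy-number differentiation scan for
SNP genotypes and CNV copy-number matrices:

* **SNP scan** — sliding-window nucleotide diversity (π) per group,
  control/case π ratio, and Hudson's F_ST (ratio-of-averages), with
  empirical top-percentile selection of each statistic and a three-way
  window intersection that declares candidate sweep regions.
  Defaults: 40 kb windows, 20 kb step, top 1%.
* **CNV scan** — reliability filtering of CNV regions (variant-state MAF
  > 0.05 and silhouette-score separation of rounded copy-number
  clusters), then per-region V_ST (population-variance decomposition,
  bounded in [0, 1]), a dichotomized Hudson-form F_ST, and Welch's
  t-test; candidates are the intersection of the F_ST and V_ST top
  percentiles.
* **Annotation** — genes overlapping candidate intervals (half-open
  convention) and genes within a ±2 Mb flank, via a sorted interval
  sweep.
* **Enrichment** — gene-set over-representation (one-sided
  hypergeometric) against the annotation universe with Benjamini–
  Hochberg FDR control (significant at p < .05 and q ≤ .05).
* **Synthetic data** — a Balding–Nichols two-population simulator
  (default 20 vs 52 individuals, 10 Mb, 1 SNP/kb, F_bg = 0.02) with
  injected swept windows and differentiated CNV regions, for end-to-end
  testing with known ground truth.

Internally every interval is 0-based half-open; 1-based formats (VCF,
GFF3) are converted at the I/O boundary only.

## CLI

```sh
# generate a synthetic dataset with known ground truth
sweepscan simulate --out demo/ --seed 1

# full pipeline: SNP scan -> CNV scan -> enrichment
sweepscan all --vcf demo/snps.vcf --popmap demo/popmap.tsv \
    --cn demo/cn_matrix.tsv --genes demo/genes.gff3 \
    --gmt demo/gene_sets.gmt --out results_demo/

# individual stages
sweepscan snp-scan --vcf demo/snps.vcf --popmap demo/popmap.tsv \
    --genes demo/genes.gff3 --out results_demo/
sweepscan cnv-scan --cn demo/cn_matrix.tsv --popmap demo/popmap.tsv \
    --genes demo/genes.gff3 --out results_demo/
```

Options may also come from a YAML config file (`--config run.yaml`);
explicit CLI flags override file values, which override defaults. Exit
codes: 0 success, 1 usage error, 2 data error.

Inputs: VCF 4.x with GT (biallelic SNPs kept, everything else skipped),
a two-column individual/group map (`HG` = case, `CG` = control), a CN
matrix TSV (`chrom start end region_id` + one column per individual),
GFF3 or BED gene models, and an optional GMT gene-set file.

Outputs (TSV/BED/JSON, deterministic): `window_stats.tsv`,
`candidate_windows.bed`, `candidate_genes_snp.tsv`, `cnv_stats.tsv`,
`candidate_cnvs.bed`, `candidate_genes_cnv.tsv`, `enrichment.tsv` and a
`run_manifest.json` recording config, input checksums and the selection
cutoffs.

## Tests

```sh
python -m pytest -q tests/
```

The suite includes brute-force oracles (pairwise-difference π, per-site
Hudson F_ST, exhaustive hypergeometric enumeration), hypothesis property
tests (V_ST bounds, quantile-selection counts, BH equivariance) and
recovery tests that re-detect injected sweeps and CNVs from the
simulator across seeds. `tests/test_acceptance.py` holds the acceptance
criteria.

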