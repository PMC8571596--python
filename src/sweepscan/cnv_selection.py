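"""Per-region copy-number differentiation: reliability filtering
(variant-state MAF, silhouette), V_ST, a dichotomized Hudson-form F_ST,
Welch's t-test, and the top-percentile F_ST/V_ST intersection.

Copy-number states are assigned by rounding raw CN values to the nearest
integer (round-half-to-even); raw values are used for all variances and
t-tests. V_ST uses population (denominator-N) variances, which is what
bounds it in [0, 1].
"""

from __future__ import annotations

import logging
import math
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from sklearn.metrics import silhouette_samples

from .model import CNMatrix, CNVStatRow, DataError, PopulationMap, Region
from .window_stats import select_top

logger = logging.getLogger(__name__)

REFERENCE_CN = 2


def _round_states(values: np.ndarray) -> np.ndarray:
    # np.round is round-half-to-even, matching the documented state rule
    return np.round(np.asarray(values, dtype=float)).astype(int)


def cnv_maf(values_per_individual: Sequence[float], reference_cn: int = REFERENCE_CN) -> float:
    """Minor variant-state frequency: fraction of individuals whose
    rounded CN differs from the reference, folded at 0.5."""
    values = np.asarray(values_per_individual, dtype=float)
    if values.size < 2:
        raise DataError("cnv_maf needs >= 2 individuals")
    f = float(np.mean(_round_states(values) != reference_cn))
    return min(f, 1.0 - f)


def cnv_silhouette(values_per_individual: Sequence[float]) -> float:
    """Mean silhouette of rounded-CN clusters over raw values.

    Distance is absolute difference on the raw CN values; only
    individuals in clusters of size >= 2 enter the mean; a single
    effective cluster scores 0 by convention (uninformative).
    """
    values = np.asarray(values_per_individual, dtype=float)
    if values.size < 2:
        raise DataError("cnv_silhouette needs >= 2 individuals")
    labels = _round_states(values)
    uniq, counts = np.unique(labels, return_counts=True)
    keep_states = uniq[counts >= 2]
    mask = np.isin(labels, keep_states)
    kept_labels = labels[mask]
    if len(np.unique(kept_labels)) < 2:
        return 0.0
    scores = silhouette_samples(
        values[mask].reshape(-1, 1), kept_labels, metric="euclidean"
    )
    return float(scores.mean())


def filter_reliable(
    matrix: CNMatrix,
    maf_min: float = 0.05,
    silhouette_min: float = 0.7,
) -> CNMatrix:
    """Keep regions with MAF strictly above ``maf_min`` and silhouette at
    least ``silhouette_min``; logs per-criterion removal counts."""
    keep: List[int] = []
    n_maf = n_sil = 0
    for i in range(matrix.n_regions):
        row = matrix.values[i]
        maf_ok = cnv_maf(row) > maf_min
        sil_ok = cnv_silhouette(row) >= silhouette_min
        if not maf_ok:
            n_maf += 1
        if not sil_ok:
            n_sil += 1
        if maf_ok and sil_ok:
            keep.append(i)
    logger.info(
        "filter_reliable: %d/%d regions kept (%d failed MAF, %d failed silhouette)",
        len(keep), matrix.n_regions, n_maf, n_sil,
    )
    if not keep:
        logger.warning("filter_reliable: no region passed the reliability filters")
    return CNMatrix(
        regions=[matrix.regions[i] for i in keep],
        values=matrix.values[keep] if keep else np.empty((0, len(matrix.individual_ids))),
        individual_ids=matrix.individual_ids,
    )


def _split_groups(
    values: Sequence[float], pops: PopulationMap, individual_ids: Sequence[str]
) -> Tuple[np.ndarray, np.ndarray]:
    values = np.asarray(values, dtype=float)
    hg = pops.indices(individual_ids, "HG")
    cg = pops.indices(individual_ids, "CG")
    return values[hg], values[cg]


def cnv_vst(
    values: Sequence[float], pops: PopulationMap, individual_ids: Sequence[str]
) -> float:
    """V_ST = (V_total - (V_pop1*N_pop1 + V_pop2*N_pop2)/N_total) / V_total.

    All variances are population variances (denominator N), so the law of
    total variance bounds the result in [0, 1]. V_total = 0 returns 0.
    """
    a, b = _split_groups(values, pops, individual_ids)
    if a.size < 1 or b.size < 1:
        raise DataError("both groups need >= 1 individual")
    pooled = np.concatenate([a, b])
    v_total = float(np.var(pooled))
    if v_total == 0.0:
        return 0.0
    v_within = (np.var(a) * a.size + np.var(b) * b.size) / pooled.size
    return float((v_total - v_within) / v_total)


def cnv_fst(
    values: Sequence[float],
    pops: PopulationMap,
    individual_ids: Sequence[str],
    reference_cn: int = REFERENCE_CN,
) -> float:
    """Hudson-form estimate on the dichotomized variant-state frequency.

    q_g is the fraction of individuals in group g whose rounded CN
    differs from the reference; sample sizes are individual counts.
    Returns NaN when the denominator is 0 (monomorphic in both groups).
    """
    a, b = _split_groups(values, pops, individual_ids)
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need >= 2 individuals")
    q1 = float(np.mean(_round_states(a) != reference_cn))
    q2 = float(np.mean(_round_states(b) != reference_cn))
    den = q1 * (1 - q2) + q2 * (1 - q1)
    if den == 0.0:
        return math.nan
    num = (q1 - q2) ** 2 - q1 * (1 - q1) / (a.size - 1) - q2 * (1 - q2) / (b.size - 1)
    return num / den


def cnv_ttest(
    values: Sequence[float], pops: PopulationMap, individual_ids: Sequence[str]
) -> Tuple[float, float, float]:
    """Two-sided Welch t-test on raw CN values -> (t, df, p).

    Zero variance in both groups: p = 1 when the means agree, else the
    degenerate p = 0 convention (flagged in the log).
    """
    a, b = _split_groups(values, pops, individual_ids)
    if a.size < 2 or b.size < 2:
        raise DataError("both groups need >= 2 individuals")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        logger.warning("cnv_ttest: zero variance with unequal means; p = 0 by convention")
        return math.inf if np.mean(a) > np.mean(b) else -math.inf, \
            float(a.size + b.size - 2), 0.0
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def compute_cnv_stats(matrix: CNMatrix, pops: PopulationMap) -> List[CNVStatRow]:
    """All per-region statistics for a (filtered) CN matrix."""
    hg = pops.indices(matrix.individual_ids, "HG")
    cg = pops.indices(matrix.individual_ids, "CG")
    rows: List[CNVStatRow] = []
    for region, values in zip(matrix.regions, matrix.values):
        a, b = values[hg], values[cg]
        t, _df, p = cnv_ttest(values, pops, matrix.individual_ids)
        rows.append(
            CNVStatRow(
                region=region,
                maf=cnv_maf(values),
                silhouette=cnv_silhouette(values),
                vst=cnv_vst(values, pops, matrix.individual_ids),
                fst=cnv_fst(values, pops, matrix.individual_ids),
                t_stat=t,
                p_value=p,
                mean_hg=float(np.mean(a)),
                mean_cg=float(np.mean(b)),
                var_hg=float(np.var(a)),
                var_cg=float(np.var(b)),
                var_total=float(np.var(values)),
                n_hg=int(a.size),
                n_cg=int(b.size),
            )
        )
    return rows


def select_cnv_candidates(
    stats: Sequence[CNVStatRow], fraction: float = 0.01
) -> Tuple[float, float, List[CNVStatRow]]:
    """Intersect the upper-tail top percentile of F_ST and of V_ST.

    Returns ``(fst_cutoff, vst_cutoff, candidates)``; candidates carry
    their t-test p-values and are sorted by genomic position.
    """
    fst_cut, top_fst = select_top(stats, "fst", tail="upper", fraction=fraction)
    vst_cut, top_vst = select_top(stats, "vst", tail="upper", fraction=fraction)
    fst_ids = {r.region.region_id for r in top_fst}
    candidates = [r for r in top_vst if r.region.region_id in fst_ids]
    candidates.sort(key=lambda r: (r.region.chrom, r.region.start))
    return fst_cut, vst_cut, candidates
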