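"""Sliding-window diversity and differentiation statistics.

Per window and group: nucleotide diversity pi (per-bp, unbiased per-site
form ``2*c*(n-c) / (n*(n-1))`` summed over SNPs and divided by window
length); the control/case pi ratio; and Hudson's two-population F_ST in
its low-bias ratio-of-averages form. Top-percentile selection and the
three-way intersection that declares candidate sweep windows live here
too.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .model import DataError, GenotypeMatrix, PopulationMap, Window, WindowStatRow

logger = logging.getLogger(__name__)


def make_windows(
    chromosome_lengths: Mapping[str, int],
    window_bp: int = 40_000,
    step_bp: int = 20_000,
    keep_partial: bool = False,
) -> List[Window]:
    """Tile chromosomes with sliding windows starting at 0, step, 2*step...

    Only windows fully inside the chromosome are emitted; with
    ``keep_partial`` one truncated terminal window is added per
    chromosome when the tiling does not reach the chromosome end.
    """
    if window_bp <= 0 or step_bp <= 0:
        raise DataError("window_bp and step_bp must be positive")
    if step_bp > window_bp:
        logger.warning(
            "step (%d) exceeds window (%d): tiling leaves gaps", step_bp, window_bp
        )
    windows: List[Window] = []
    for chrom, length in chromosome_lengths.items():
        if length <= 0:
            raise DataError(f"chromosome {chrom}: non-positive length {length}")
        start = 0
        last_end = 0
        while start + window_bp <= length:
            windows.append(Window(chrom, start, start + window_bp))
            last_end = start + window_bp
            start += step_bp
        if keep_partial and last_end < length and start < length:
            windows.append(Window(chrom, start, length))
    return windows


# ---------------------------------------------------------------------------
# per-site arrays


@dataclass
class _SiteStats:
    """Per-site quantities for one chromosome, ready for window binning."""

    pos0: np.ndarray        # 0-based site positions, ascending
    pi_site: Dict[str, np.ndarray]
    fst_num: np.ndarray
    fst_den: np.ndarray
    usable: np.ndarray      # sites with >= 2 non-missing chromosomes in both groups


def _group_counts(dos: np.ndarray, cols: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """(alt-allele count, non-missing chromosome count) per site for a group."""
    sub = dos[:, cols].astype(np.int64)
    ok = sub >= 0
    c = np.where(ok, sub, 0).sum(axis=1)
    n = 2 * ok.sum(axis=1)
    return c, n


def _site_stats(
    pos: np.ndarray, dos: np.ndarray, hg_cols: np.ndarray, cg_cols: np.ndarray
) -> _SiteStats:
    pi_site = {}
    counts = {}
    for label, cols in (("HG", hg_cols), ("CG", cg_cols)):
        c, n = _group_counts(dos, cols)
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(n >= 2, 2.0 * c * (n - c) / (n * np.maximum(n - 1, 1)), 0.0)
        pi_site[label] = pi
        counts[label] = (c, n)
    c1, n1 = counts["HG"]
    c2, n2 = counts["CG"]
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(n1 > 0, c1 / n1, 0.0)
        p2 = np.where(n2 > 0, c2 / n2, 0.0)
        num = (p1 - p2) ** 2 \
            - p1 * (1 - p1) / np.maximum(n1 - 1, 1) \
            - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(valid & (den > 0), num, 0.0)
    den = np.where(valid & (den > 0), den, 0.0)
    return _SiteStats(
        pos0=pos - 1,
        pi_site=pi_site,
        fst_num=num,
        fst_den=den,
        usable=valid.astype(np.int64),
    )


def _window_slice(stats: _SiteStats, window: Window) -> slice:
    lo = int(np.searchsorted(stats.pos0, window.start, side="left"))
    hi = int(np.searchsorted(stats.pos0, window.end, side="left"))
    return slice(lo, hi)


def window_pi(
    genotypes: GenotypeMatrix,
    pops: PopulationMap,
    window: Window,
    group: str,
    per_site_norm: bool = False,
) -> float:
    """Per-bp nucleotide diversity of one group within one window.

    With ``per_site_norm`` the sum of per-site pi is divided by the number
    of usable SNPs instead of the window length.
    """
    cols = pops.indices(genotypes.individual_ids, group)
    if cols.size == 0:
        raise DataError(f"group {group!r} has no individuals in the matrix")
    other = "CG" if group == "HG" else "HG"
    pos, dos = genotypes.chrom_slice(window.chrom)
    hg = cols if group == "HG" else pops.indices(genotypes.individual_ids, other)
    cg = cols if group == "CG" else pops.indices(genotypes.individual_ids, other)
    stats = _site_stats(pos, dos, hg, cg)
    sl = _window_slice(stats, window)
    total = float(stats.pi_site[group][sl].sum())
    if per_site_norm:
        n = int(stats.usable[sl].sum())
        return total / n if n else 0.0
    return total / window.length


def window_fst(
    genotypes: GenotypeMatrix,
    pops: PopulationMap,
    window: Window,
    mode: str = "ratio",
) -> float:
    """Hudson F_ST for one window; NaN when no site is informative.

    ``mode='ratio'`` (default) is the ratio-of-averages estimator
    (sum of per-site numerators over sum of denominators); ``'mean'``
    averages per-site ratios instead.
    """
    hg = pops.indices(genotypes.individual_ids, "HG")
    cg = pops.indices(genotypes.individual_ids, "CG")
    if hg.size == 0 or cg.size == 0:
        raise DataError("both groups must be non-empty")
    pos, dos = genotypes.chrom_slice(window.chrom)
    stats = _site_stats(pos, dos, hg, cg)
    sl = _window_slice(stats, window)
    return _fst_from_sums(stats.fst_num[sl], stats.fst_den[sl], mode)


def _fst_from_sums(num: np.ndarray, den: np.ndarray, mode: str) -> float:
    informative = den > 0
    if not informative.any():
        return math.nan
    if mode == "ratio":
        return float(num[informative].sum() / den[informative].sum())
    if mode == "mean":
        return float(np.mean(num[informative] / den[informative]))
    raise DataError(f"unknown F_ST mode {mode!r}")


def pi_ratio(pi_cg: float, pi_hg: float) -> float:
    """Control-over-case diversity ratio; +inf when only the case group
    is monomorphic, NaN when both are."""
    if pi_cg < 0 or pi_hg < 0:
        raise DataError("pi values must be non-negative")
    if pi_hg == 0:
        return math.inf if pi_cg > 0 else math.nan
    return pi_cg / pi_hg


def compute_window_stats(
    genotypes: GenotypeMatrix,
    pops: PopulationMap,
    windows: Sequence[Window],
    per_site_norm: bool = False,
    fst_mode: str = "ratio",
) -> List[WindowStatRow]:
    """All window statistics in one pass (cumulative-sum binning).

    Equivalent to calling :func:`window_pi` / :func:`window_fst` /
    :func:`pi_ratio` per window but linear in sites + windows.
    """
    hg = pops.indices(genotypes.individual_ids, "HG")
    cg = pops.indices(genotypes.individual_ids, "CG")
    if hg.size == 0 or cg.size == 0:
        raise DataError("both groups must be non-empty")

    by_chrom: Dict[str, List[Window]] = {}
    for w in windows:
        by_chrom.setdefault(w.chrom, []).append(w)

    rows: List[WindowStatRow] = []
    order = {id(w): i for i, w in enumerate(windows)}
    for chrom, wins in by_chrom.items():
        pos, dos = genotypes.chrom_slice(chrom)
        stats = _site_stats(pos, dos, hg, cg)

        def cum(a: np.ndarray) -> np.ndarray:
            return np.concatenate(([0.0], np.cumsum(a)))

        cum_pi_hg = cum(stats.pi_site["HG"])
        cum_pi_cg = cum(stats.pi_site["CG"])
        cum_num = cum(stats.fst_num)
        cum_den = cum(stats.fst_den)
        cum_use = cum(stats.usable)
        starts = np.array([w.start for w in wins])
        ends = np.array([w.end for w in wins])
        lo = np.searchsorted(stats.pos0, starts, side="left")
        hi = np.searchsorted(stats.pos0, ends, side="left")
        for w, a, b in zip(wins, lo, hi):
            sum_hg = cum_pi_hg[b] - cum_pi_hg[a]
            sum_cg = cum_pi_cg[b] - cum_pi_cg[a]
            n_use = int(cum_use[b] - cum_use[a])
            if per_site_norm:
                denom = n_use if n_use else math.nan
            else:
                denom = w.length
            p_hg = sum_hg / denom if denom == denom else 0.0
            p_cg = sum_cg / denom if denom == denom else 0.0
            den = cum_den[b] - cum_den[a]
            if fst_mode == "ratio":
                fst = (cum_num[b] - cum_num[a]) / den if den > 0 else math.nan
            else:
                sl = slice(a, b)
                fst = _fst_from_sums(stats.fst_num[sl], stats.fst_den[sl], fst_mode)
            rows.append(
                WindowStatRow(
                    window=w,
                    n_snps=n_use,
                    pi_hg=p_hg,
                    pi_cg=p_cg,
                    pi_ratio=pi_ratio(p_cg, p_hg),
                    fst=float(fst),
                )
            )
    rows.sort(key=lambda r: order[id(r.window)] if id(r.window) in order else 0)
    return rows


# ---------------------------------------------------------------------------
# percentile selection

StatKey = Union[str, Callable[[object], float], None]


def select_top(
    rows: Sequence,
    statistic: StatKey = None,
    tail: str = "upper",
    fraction: float = 0.01,
) -> Tuple[float, List]:
    """Empirical top-percentile selection with a reproducible cutoff.

    The cutoff is the linear-interpolation ``1 - fraction`` quantile
    (upper tail) or ``fraction`` quantile (lower tail) of the *defined*
    (non-NaN) statistic values; selection is strict inequality past the
    cutoff. ``+inf`` values are always selected for the upper tail.
    Returns ``(cutoff, selected_rows)``.
    """
    if tail not in ("upper", "lower"):
        raise DataError(f"tail must be upper or lower, got {tail!r}")
    if statistic is None:
        key = lambda r: float(r)  # noqa: E731
    elif callable(statistic):
        key = statistic
    else:
        key = lambda r: float(getattr(r, statistic))  # noqa: E731

    values = np.array([key(r) for r in rows], dtype=float)
    defined = ~np.isnan(values)
    if defined.sum() < 2:
        raise DataError("need at least 2 defined statistic values to select a cutoff")
    vals = values[defined]
    if tail == "upper":
        cutoff = float(np.quantile(vals, 1.0 - fraction))
        if not np.isfinite(cutoff):
            # +inf values pushed the quantile off the finite scale; fall
            # back to the largest finite value so strict > still works.
            finite = vals[np.isfinite(vals)]
            cutoff = float(finite.max()) if finite.size else math.inf
        selected = [
            r for r, v, d in zip(rows, values, defined)
            if d and (v > cutoff or np.isposinf(v))
        ]
    else:
        cutoff = float(np.quantile(vals, fraction))
        selected = [r for r, v, d in zip(rows, values, defined) if d and v < cutoff]
    return cutoff, selected


def intersect_windows(
    selected_pi_hg: Sequence[WindowStatRow],
    selected_ratio: Sequence[WindowStatRow],
    selected_fst: Sequence[WindowStatRow],
) -> List[Window]:
    """Windows present in all three top-percentile lists, sorted."""
    def keys(rows):
        return {(r.window.chrom, r.window.start, r.window.end) for r in rows}

    common = keys(selected_pi_hg) & keys(selected_ratio) & keys(selected_fst)
    return [Window(*k) for k in sorted(common)]
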