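"""Gene-set over-representation analysis with BH FDR control.

One-sided hypergeometric upper-tail test per term against a user-supplied
universe; Benjamini-Hochberg step-up q-values across tested terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import hypergeom

from .model import DataError, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    k: int  # candidate hits in the term
    K: int  # term size within the universe
    n: int  # candidate genes in the universe
    N: int  # universe size
    p_value: float
    q_value: float
    significant: bool = False


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= K <= N and k <= n <= N):
        raise DataError(f"inconsistent hypergeometric counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise DataError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def enrich(
    candidates: Sequence[str],
    universe: Sequence[str],
    sets: GeneSetCollection,
    p_max: float = 0.05,
    q_max: float = 0.05,
) -> List[EnrichmentRow]:
    """One row per term with >= 1 candidate hit, sorted by p-value.

    Candidates outside the universe are dropped with a warning. A row is
    flagged significant when p < p_max and q <= q_max.
    """
    uni = set(universe)
    if not uni:
        raise DataError("empty gene universe")
    cand = set(candidates)
    dropped = cand - uni
    if dropped:
        logger.warning(
            "enrich: %d candidate genes absent from the universe dropped: %s",
            len(dropped), sorted(dropped)[:10],
        )
        cand &= uni

    N, n = len(uni), len(cand)
    rows: List[EnrichmentRow] = []
    for term_id, (name, members) in sets.sets.items():
        term_genes = set(members) & uni
        K = len(term_genes)
        k = len(term_genes & cand)
        if k == 0:
            continue
        p = hypergeom_test(k, K, n, N)
        rows.append(EnrichmentRow(term_id, name, k, K, n, N, p, q_value=1.0))

    qs = bh_fdr([r.p_value for r in rows])
    for r, q in zip(rows, qs):
        r.q_value = q
        r.significant = (r.p_value < p_max) and (q <= q_max)
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows
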