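"""Shared statistical primitives.

One definition each of the Benjamini-Hochberg adjustment, the two-sided
conditional Fisher exact test used by the per-sample caller, the one-sided
(excess in row 2) Fisher test used for cohort reversal screening, and the
cumulative-binomial concordance tail.  Every module in the package goes
through these.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

# relative tolerance when comparing point probabilities against the observed
# table's probability (ties in the two-sided enumeration)
_TIE_RTOL = 1e-7

__all__ = [
    "bh_adjust",
    "binomial_tail_p",
    "fisher_exact_two_sided",
    "fisher_exact_two_sided_many",
    "hypergeom_sf_one_sided",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Raises if any input lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def binomial_tail_p(k: int, s: int, pe: float = 0.5) -> float:
    """Upper-tail probability P(X >= s) for X ~ Binomial(k, pe).

    This is the chance of observing at least ``s`` direction agreements
    among ``k`` shared items when each agrees independently with
    probability ``pe``.  ``s = 0`` gives 1 exactly (empty lower sum).
    Stable for k up to ~1e9 via the regularised incomplete beta function.
    """
    if not 0 <= s <= k:
        raise ValueError(f"require 0 <= s <= k, got s={s}, k={k}")
    if not 0 < pe < 1:
        raise ValueError("pe must lie in (0, 1)")
    if s == 0:
        return 1.0
    return float(stats.binom.sf(s - 1, k, pe))


def fisher_exact_two_sided(table) -> float:
    """Two-sided conditional Fisher exact p for a 2x2 table.

    Sums, over all tables with the observed margins, the hypergeometric
    point probabilities no larger than the observed table's (with a 1e-7
    relative tolerance for ties).  An all-zero table is degenerate and
    returns 1.
    """
    (a, b), (c, d) = np.asarray(table, dtype=np.int64)
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    return float(fisher_exact_two_sided_many([a], [b], [c], [d])[0])


def fisher_exact_two_sided_many(n11, n12, n21, n22) -> np.ndarray:
    """Vectorised two-sided Fisher exact test over many 2x2 tables.

    Cell arrays are aligned: table i is [[n11[i], n12[i]], [n21[i], n22[i]]].
    """
    n11 = np.asarray(n11, dtype=np.int64)
    n12 = np.asarray(n12, dtype=np.int64)
    n21 = np.asarray(n21, dtype=np.int64)
    n22 = np.asarray(n22, dtype=np.int64)
    out = np.ones(n11.shape, dtype=float)
    r1 = n11 + n12
    c1 = n11 + n21
    n = r1 + n21 + n22
    for i in range(out.size):
        if n.flat[i] == 0:
            continue  # degenerate, p = 1
        lo = max(0, c1.flat[i] - (n.flat[i] - r1.flat[i]))
        hi = min(r1.flat[i], c1.flat[i])
        support = np.arange(lo, hi + 1)
        pmf = stats.hypergeom.pmf(support, n.flat[i], r1.flat[i], c1.flat[i])
        p_obs = pmf[n11.flat[i] - lo]
        out.flat[i] = min(1.0, pmf[pmf <= p_obs * (1 + _TIE_RTOL)].sum())
    return out


def hypergeom_sf_one_sided(n11, n12, n21, n22) -> np.ndarray:
    """One-sided Fisher exact p (vectorised): excess of n21 given the margins.

    For tables [[row1_consistent, row1_reversed], [row2_consistent,
    row2_reversed]] laid out as (n11, n12, n21, n22) = (consistent_1,
    reversed_1, consistent_2, reversed_2), tests whether row 2 carries more
    "reversed" events than the margins predict: P(X >= reversed_2) with X
    hypergeometric.  Identical to scipy's ``fisher_exact`` with
    ``alternative='greater'`` on the reversed-first arrangement.
    """
    c1 = np.asarray(n11, dtype=np.int64)
    r1 = np.asarray(n12, dtype=np.int64)
    c2 = np.asarray(n21, dtype=np.int64)
    r2 = np.asarray(n22, dtype=np.int64)
    total = c1 + r1 + c2 + r2
    reversed_total = r1 + r2
    row2_total = c2 + r2
    return stats.hypergeom.sf(r2 - 1, total, reversed_total, row2_total)
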