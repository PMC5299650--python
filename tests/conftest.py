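"""Shared fixtures and independent oracles.

The oracle functions here deliberately use naive loops and exact integer
arithmetic so they share no code path with the package implementations
they check.
"""

from math import comb

import numpy as np
import pandas as pd
import pytest

from rmocomp import MethylationMatrix


# -- independent oracles ------------------------------------------------

def brute_force_pair_counts(values: np.ndarray) -> dict:
    """Triple-loop ordering counts: {(i, j): (n_gt, n_lt, n_tie, n_valid)}
    over row pairs i < j (rows already in the analysis order)."""
    p, n = values.shape
    out = {}
    for i in range(p):
        for j in range(i + 1, p):
            gt = lt = tie = valid = 0
            for k in range(n):
                a, b = values[i, k], values[j, k]
                if np.isnan(a) or np.isnan(b):
                    continue
                valid += 1
                if a > b:
                    gt += 1
                elif a < b:
                    lt += 1
                else:
                    tie += 1
            out[(i, j)] = (gt, lt, tie, valid)
    return out


def fisher_two_sided_enumeration(a, b, c, d) -> float:
    """Exact two-sided Fisher p by integer enumeration over all tables with
    the observed margins: sum the hypergeometric weights no larger than the
    observed table's weight (ties are exact in integer arithmetic)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        w = comb(r1, x) * comb(r2, c1 - x)
        if w <= w_obs:
            total += w
    return total / comb(n, c1)


def binomial_tail_naive(k: int, s: int, pe: float) -> float:
    """P(X >= s) for X ~ Binomial(k, pe) by direct summation."""
    return sum(comb(k, i) * pe**i * (1 - pe) ** (k - i) for i in range(s, k + 1))


def bh_naive(p):
    """Step-up BH computed by hand (sort, cummin from the right, unsort)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


# -- fixtures -----------------------------------------------------------

@pytest.fixture
def toy_matrix():
    """4 sites x 3 samples with one missing cell."""
    values = np.array([
        [0.10, 0.12, 0.11],
        [0.40, 0.38, 0.41],
        [0.70, np.nan, 0.72],
        [0.90, 0.88, 0.91],
    ])
    return MethylationMatrix(
        ["cgA", "cgB", "cgC", "cgD"],
        ["s1", "s2", "s3"],
        values,
        ["normal", "normal", "normal"],
    )


@pytest.fixture
def toy_annotation():
    return pd.DataFrame({
        "site_id": ["cgA", "cgB", "cgC", "cgD"],
        "gene_symbol": ["G1", "G1", "G2", "G3"],
        "promoter_flag": [True, True, True, False],
        "platforms": ["27K,450K", "27K,450K", "27K", "27K,450K"],
    })
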