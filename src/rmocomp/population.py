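"""Population-level differential methylation and cohort reversal screening.

Two complementary cohort-scale analyses: (1) the conventional two-group
Welch t-test per CpG site with Benjamini-Hochberg control, yielding
hyper-/hypomethylated sites at the population level; (2) a per-pair Fisher
exact screen for stable pairs whose ordering reverses significantly more
often in cancer samples than in normal samples.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .background import StablePairSet
from .concordance import ConcordanceResult, concordance_score
from .matrix import MethylationMatrix
from .stats import bh_adjust, fisher_exact_two_sided_many, hypergeom_sf_one_sided

__all__ = ["ttest_dm", "reversal_pair_test", "consistent_overlap"]


def ttest_dm(cancer: MethylationMatrix, normal: MethylationMatrix,
             fdr_threshold: float = 0.05, equal_var: bool = False) -> pd.DataFrame:
    """Per-site two-group t-test (Welch by default) with BH adjustment.

    Both matrices must share a site universe (sites are aligned by id; the
    intersection is tested).  Sites with fewer than two observations in
    either group are skipped and reported with NaN statistics.

    Returns a frame indexed by site with columns ``mean_diff`` (cancer -
    normal), ``direction`` (hyper/hypo by the sign of ``mean_diff``),
    ``p``, ``fdr`` and ``significant`` (fdr < threshold).
    """
    sites = sorted(set(cancer.site_ids) & set(normal.site_ids))
    if not sites:
        raise ValueError("cohorts share no CpG sites")
    c = cancer.select_sites(sites).values
    n = normal.select_sites(sites).values
    n_c = np.isfinite(c).sum(axis=1)
    n_n = np.isfinite(n).sum(axis=1)
    testable = (n_c >= 2) & (n_n >= 2)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # near-constant sites trigger scipy's precision-loss warning; their
        # p-values are ~1 and harmless
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(c, n, axis=1, equal_var=equal_var,
                              nan_policy="omit")
        mean_diff = np.nanmean(c, axis=1) - np.nanmean(n, axis=1)
    p = np.where(testable, res.pvalue, np.nan)
    fdr = np.full(len(sites), np.nan)
    if testable.any():
        fdr[testable] = bh_adjust(p[testable])
    df = pd.DataFrame({
        "site_id": sites,
        "mean_diff": mean_diff,
        "direction": np.where(mean_diff > 0, "hyper", "hypo"),
        "p": p,
        "fdr": fdr,
        "skipped": ~testable,
    })
    df.loc[~testable, "direction"] = None
    df["significant"] = df["fdr"] < fdr_threshold
    return df


def reversal_pair_test(pairs: StablePairSet, cancer: MethylationMatrix,
                       normal: MethylationMatrix,
                       fdr_threshold: float = 0.05,
                       alternative: str = "greater") -> pd.DataFrame:
    """Fisher exact screen for pairs reversing more often in cancer.

    For each stable pair, samples in each cohort are classified as
    consistent (ordering matches the stable direction) or reversed
    (strictly contradicts it); ties and pairs with a missing member are
    excluded.  The 2x2 table [(normal consistent, normal reversed),
    (cancer consistent, cancer reversed)] is tested one-sided toward an
    excess of cancer reversals (``alternative='two-sided'`` for the
    agnostic version), with BH across all stable pairs.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")

    def classify(matrix: MethylationMatrix):
        m = matrix.select_sites(list(pairs.site_ids))
        i, j = pairs.pair_members()
        d = m.values[i] - m.values[j]            # (n_pairs, n_samples)
        sign = np.sign(d)
        consistent = (sign == pairs.direction[:, None]).sum(axis=1)
        reversed_ = (sign == -pairs.direction[:, None]).sum(axis=1)
        return consistent.astype(np.int64), reversed_.astype(np.int64)

    nc, nr = classify(normal)
    cc, cr = classify(cancer)
    if (cc + cr).max(initial=0) == 0:
        raise ValueError("cancer cohort has no pairwise-valid samples")
    if alternative == "greater":
        p = hypergeom_sf_one_sided(nc, nr, cc, cr)
    else:
        p = fisher_exact_two_sided_many(nc, nr, cc, cr)
    df = pairs.to_frame()
    df["normal_consistent"] = nc
    df["normal_reversed"] = nr
    df["cancer_consistent"] = cc
    df["cancer_reversed"] = cr
    df["p"] = p
    df["fdr"] = bh_adjust(p)
    df["significant"] = df["fdr"] < fdr_threshold
    return df


def consistent_overlap(records_a: pd.DataFrame, records_b: pd.DataFrame,
                       ) -> tuple[list, ConcordanceResult]:
    """Sites detected in both population-level DM lists with one direction.

    Input frames need ``site_id`` and ``direction`` columns (typically the
    significant rows of :func:`ttest_dm` from two independent cohorts).
    Returns the consistently detected sites (sorted) plus the concordance
    over all shared sites.
    """
    a = dict(zip(records_a["site_id"], records_a["direction"]))
    b = dict(zip(records_b["site_id"], records_b["direction"]))
    result = concordance_score(a, b)
    sites = sorted(s for s in a.keys() & b.keys() if a[s] == b[s])
    return sites, result
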