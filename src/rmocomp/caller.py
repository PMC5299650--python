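"""Individualized differential-methylation calling (the RankComp scheme).

Given the stable-pair background from normal tissue, a single tumor sample
is scored on its own: every stable pair whose ordering the sample strictly
contradicts is a *reversal pair*.  For a site Ci with ``a`` stable partners
above it and ``b`` below it, a reversal of a pair in which Ci is the lower
site supports hypermethylation of Ci (Ci climbed past that partner), and a
reversal in which Ci is the higher site supports hypomethylation.  If Ci
itself is unchanged, rank shifts induced by other sites' aberrations are
taken to be random, so under the null the reversal proportions on the two
sides are equal; Fisher's exact test on the 2x2 table

    [[a1, a - a1], [b1, b - b1]]

(a1/b1 = reversed pairs on each side, after discounting pairs that are not
evaluable in this sample) decides whether Ci is differentially methylated,
with Benjamini-Hochberg control within the sample and the direction set by
the larger reversal proportion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .background import StablePairSet
from .matrix import MethylationMatrix
from .stats import bh_adjust, fisher_exact_two_sided_many

NOT_EVALUABLE = -1
CONSISTENT = 0
REVERSED = 1

__all__ = [
    "sample_reversal_flags",
    "site_contingencies",
    "SiteContingency",
    "call_sample_dm",
    "call_cohort",
]


@dataclass
class SiteContingency:
    """Per-site 2x2 reversal table for one sample.

    ``a`` / ``b``: evaluable stable pairs where the site is the lower /
    higher member; ``a1`` / ``b1``: how many of those are reversed.
    """

    site_id: str
    a: int
    a1: int
    b: int
    b1: int

    @property
    def table(self):
        return [[self.a1, self.a - self.a1], [self.b1, self.b - self.b1]]


def sample_reversal_flags(pairs: StablePairSet, beta) -> np.ndarray:
    """Per-pair reversal status of one sample against the background.

    ``beta`` is a site-indexed Series (or array aligned to
    ``pairs.site_ids``).  Returns int8 flags: 1 = reversed (the sample's
    strict ordering contradicts the stable direction), 0 = consistent,
    -1 = not evaluable (a missing member or an exact tie).
    """
    if isinstance(beta, pd.Series):
        beta = beta.reindex(pairs.site_ids).to_numpy(float)
    else:
        beta = np.asarray(beta, dtype=float)
        if beta.shape != (pairs.n_sites,):
            raise ValueError("beta vector does not match the background's "
                             "site universe")
    i, j = pairs.pair_members()
    sign = np.sign(beta[i] - beta[j])  # NaN -> nan, tie -> 0
    flags = np.full(pairs.n_pairs, NOT_EVALUABLE, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        flags[sign == pairs.direction] = CONSISTENT
        flags[sign == -pairs.direction] = REVERSED
    return flags


def site_contingencies(pairs: StablePairSet, flags: np.ndarray):
    """Per-site reversal tables from one sample's pair flags.

    Degrees shrink to the evaluable pairs before cells are filled, so the
    margins always reconcile with the flag totals.  Returns four int64
    arrays (a, a1, b, b1) aligned to ``pairs.site_ids``.
    """
    p = pairs.n_sites
    lower, higher = pairs.lower_higher()
    ev = flags != NOT_EVALUABLE
    rev = flags == REVERSED
    a = np.bincount(lower[ev], minlength=p)
    a1 = np.bincount(lower[ev & rev], minlength=p)
    b = np.bincount(higher[ev], minlength=p)
    b1 = np.bincount(higher[ev & rev], minlength=p)
    return a, a1, b, b1


def site_contingency(site_id: str, pairs: StablePairSet,
                     flags: np.ndarray) -> SiteContingency:
    """Single-site convenience wrapper around :func:`site_contingencies`."""
    a, a1, b, b1 = site_contingencies(pairs, flags)
    k = int(np.flatnonzero(pairs.site_ids == site_id)[0])
    return SiteContingency(site_id, int(a[k]), int(a1[k]), int(b[k]), int(b1[k]))


def call_sample_dm(beta, pairs: StablePairSet, sample_id: str = "sample",
                   fdr_threshold: float = 0.01, restrict_to=None,
                   include_one_sided: bool = False) -> pd.DataFrame:
    """Call hyper-/hypomethylated CpG sites in one sample.

    Parameters
    ----------
    beta : Series or array
        The sample's beta profile over the background's site universe.
    pairs : StablePairSet
        Stable-ordering background from normal tissue.
    fdr_threshold : float
        Within-sample BH threshold on the per-site Fisher p-values.
    restrict_to : iterable of site ids, optional
        Test (and adjust over) only these sites, e.g. the population-level
        DM sites, mirroring the precision-evaluation protocol.
    include_one_sided : bool
        Rank-extreme sites with all stable partners on one side (a = 0 or
        b = 0) have no two-proportion comparison; when enabled they are
        tested with an exact binomial of their reversals against the
        sample's global reversal rate.  Off by default.

    Returns a frame with columns ``sample_id``, ``site_id``, ``direction``,
    ``p``, ``fdr``, sorted by p.
    """
    if pairs.n_pairs == 0:
        raise ValueError("empty stable-pair background")
    flags = sample_reversal_flags(pairs, beta)
    a, a1, b, b1 = site_contingencies(pairs, flags)
    testable = (a > 0) & (b > 0)
    if restrict_to is not None:
        allowed = np.isin(pairs.site_ids.astype(str),
                          np.asarray(list(restrict_to), dtype=str))
        testable &= allowed
    idx = np.flatnonzero(testable)
    p_vals = fisher_exact_two_sided_many(a1[idx], a[idx] - a1[idx],
                                         b1[idx], b[idx] - b1[idx])
    sites = list(pairs.site_ids[idx])
    prop_a = a1[idx] / a[idx]
    prop_b = b1[idx] / b[idx]

    if include_one_sided:
        one_sided = ((a == 0) ^ (b == 0)) & ((a1 + b1) >= 1)
        if restrict_to is not None:
            one_sided &= allowed
        ev_total = int((flags != NOT_EVALUABLE).sum())
        rate = (flags == REVERSED).sum() / ev_total if ev_total else 0.0
        os_idx = np.flatnonzero(one_sided)
        n_side = a[os_idx] + b[os_idx]
        k_side = a1[os_idx] + b1[os_idx]
        p_os = sps.binom.sf(k_side - 1, n_side, rate)
        sites += list(pairs.site_ids[os_idx])
        p_vals = np.concatenate([p_vals, p_os])
        # reversals on the a side support hyper, on the b side hypo
        prop_a = np.concatenate([prop_a, np.where(a[os_idx] > 0, 1.0, 0.0)])
        prop_b = np.concatenate([prop_b, np.where(b[os_idx] > 0, 1.0, 0.0)])

    if len(sites) == 0:
        return pd.DataFrame(columns=["sample_id", "site_id", "direction",
                                     "p", "fdr"])
    fdr = bh_adjust(p_vals)
    df = pd.DataFrame({
        "sample_id": sample_id,
        "site_id": sites,
        "hyper_prop": prop_a,
        "hypo_prop": prop_b,
        "p": p_vals,
        "fdr": fdr,
    })
    df = df[df["fdr"] < fdr_threshold]
    # equal reversal proportions give no directional evidence: no call
    df = df[df["hyper_prop"] != df["hypo_prop"]]
    df["direction"] = np.where(df["hyper_prop"] > df["hypo_prop"],
                               "hyper", "hypo")
    return (df[["sample_id", "site_id", "direction", "p", "fdr"]]
            .sort_values(["p", "site_id"], kind="stable")
            .reset_index(drop=True))


def call_cohort(matrix: MethylationMatrix, pairs: StablePairSet,
                fdr_threshold: float = 0.01, restrict_to=None,
                include_one_sided: bool = False) -> pd.DataFrame:
    """Run :func:`call_sample_dm` for every sample in a matrix and
    concatenate the per-sample call tables."""
    out = []
    for sid in matrix.sample_ids:
        out.append(call_sample_dm(matrix.sample_vector(sid), pairs,
                                  sample_id=sid, fdr_threshold=fdr_threshold,
                                  restrict_to=restrict_to,
                                  include_one_sided=include_one_sided))
    return pd.concat(out, ignore_index=True) if out else pd.DataFrame(
        columns=["sample_id", "site_id", "direction", "p", "fdr"])
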