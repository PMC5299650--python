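"""Stable relative-ordering background from a normal cohort.

The relative methylation-level ordering (RMO) of two CpG sites A and B
within one sample is A > B or A < B by beta value.  Across a cohort of
normal tissues these orderings are remarkably conserved; a pair whose
ordering direction recurs in at least a fraction ``theta`` (default 99%,
allowing a 1% detection error rate) of the pairwise-complete normal samples
is a *stable pair*.  The set of stable pairs, together with each site's
counts of stable partners above and below it, is the fixed background
against which individual tumor samples are scored.

Pairs are indexed over the lexicographically sorted site universe using the
condensed (upper-triangle) convention, pair (i, j) with i < j at position
``i * (2p - i - 1) / 2 + (j - i - 1)``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

_MAGIC = b"RMOBG001"

__all__ = [
    "PairOrderingCounts",
    "StablePairSet",
    "SiteDegrees",
    "count_pair_orderings",
    "build_stable_pairs",
    "site_degrees",
    "save_background",
    "load_background",
    "export_pairs_tsv",
    "pair_index",
    "pair_from_index",
]


def pair_index(i, j, p: int):
    """Condensed index of pair (i, j), i < j, among p sites."""
    i = np.asarray(i, dtype=np.int64)
    j = np.asarray(j, dtype=np.int64)
    return i * (2 * p - i - 1) // 2 + (j - i - 1)


def pair_from_index(idx, p: int):
    """Inverse of :func:`pair_index`: condensed index -> (i, j) arrays."""
    idx = np.asarray(idx, dtype=np.int64)
    # row i is the largest i with i*(2p-i-1)/2 <= idx
    i = (2 * p - 1 - np.sqrt((2 * p - 1) ** 2 - 8.0 * idx)) // 2
    i = i.astype(np.int64)
    # guard against float round-off at block boundaries
    base = i * (2 * p - i - 1) // 2
    too_far = base > idx
    i[too_far] -= 1
    base = i * (2 * p - i - 1) // 2
    j = idx - base + i + 1
    return i, j


@dataclass
class PairOrderingCounts:
    """Exhaustive pairwise ordering counts over a cohort.

    Arrays are condensed over all C(p, 2) pairs of the sorted site universe:
    ``n_gt[k]`` counts samples with beta_i > beta_j for pair k = (i, j),
    ``n_lt`` the converse, ``n_tie`` exact equality, and
    ``n_valid = n_gt + n_lt + n_tie`` the pairwise-complete sample count.
    """

    site_ids: np.ndarray
    n_gt: np.ndarray
    n_lt: np.ndarray
    n_tie: np.ndarray
    n_samples: int

    @property
    def n_valid(self) -> np.ndarray:
        return self.n_gt + self.n_lt + self.n_tie


def count_pair_orderings(matrix: MethylationMatrix,
                         chunk_size: int = 256) -> PairOrderingCounts:
    """Count all pairwise orderings across the cohort, in bounded memory.

    Sites are first sorted lexicographically; results are identical for any
    ``chunk_size``.
    """
    if matrix.n_samples < 2:
        raise ValueError("pair counting needs a cohort of >= 2 samples")
    order = np.argsort(matrix.site_ids.astype(str), kind="stable")
    site_ids = matrix.site_ids[order]
    x = matrix.values[order]
    p, n = x.shape
    n_pairs = p * (p - 1) // 2
    n_gt = np.zeros(n_pairs, dtype=np.int32)
    n_lt = np.zeros(n_pairs, dtype=np.int32)
    n_tie = np.zeros(n_pairs, dtype=np.int32)
    for s1 in range(0, p, chunk_size):
        e1 = min(s1 + chunk_size, p)
        a = x[s1:e1]
        for s2 in range(s1, p, chunk_size):
            e2 = min(s2 + chunk_size, p)
            b = x[s2:e2]
            d = a[:, None, :] - b[None, :, :]
            gt = (d > 0).sum(axis=2)
            lt = (d < 0).sum(axis=2)
            valid = np.isfinite(d).sum(axis=2)
            ii, jj = np.meshgrid(np.arange(s1, e1), np.arange(s2, e2),
                                 indexing="ij")
            keep = ii < jj
            idx = pair_index(ii[keep], jj[keep], p)
            n_gt[idx] = gt[keep]
            n_lt[idx] = lt[keep]
            n_tie[idx] = valid[keep] - gt[keep] - lt[keep]
    return PairOrderingCounts(site_ids, n_gt, n_lt, n_tie, n)


@dataclass
class StablePairSet:
    """Directed stable pairs over a sorted site universe.

    ``direction`` is +1 where beta_i > beta_j is the stable ordering of
    pair (i, j) (i lexicographically before j), -1 where beta_i < beta_j.
    ``support`` is the fraction of pairwise-complete normal samples showing
    that direction.  Provenance (cohort size, theta) travels with the set.
    """

    site_ids: np.ndarray
    pair_idx: np.ndarray      # condensed indices, strictly increasing
    direction: np.ndarray     # int8, +1 / -1
    support: np.ndarray       # float64 in [theta, 1]
    theta: float
    n_samples: int

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.pair_idx = np.asarray(self.pair_idx, dtype=np.int64)
        self.direction = np.asarray(self.direction, dtype=np.int8)
        self.support = np.asarray(self.support, dtype=float)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_pairs(self) -> int:
        return len(self.pair_idx)

    def pair_members(self):
        """(i, j) index arrays of the stored pairs, i < j."""
        return pair_from_index(self.pair_idx, self.n_sites)

    def lower_higher(self):
        """Per pair, the (lower-site, higher-site) index arrays under the
        stable direction."""
        i, j = self.pair_members()
        lower = np.where(self.direction == 1, j, i)
        higher = np.where(self.direction == 1, i, j)
        return lower, higher

    def to_frame(self) -> pd.DataFrame:
        i, j = self.pair_members()
        return pd.DataFrame({
            "site_i": self.site_ids[i],
            "site_j": self.site_ids[j],
            "direction": np.where(self.direction == 1, "i_greater", "i_less"),
            "support": self.support,
        })


def build_stable_pairs(counts: PairOrderingCounts,
                       theta: float = 0.99) -> StablePairSet:
    """Retain pairs whose dominant ordering direction recurs in at least a
    fraction ``theta`` of pairwise-complete samples.

    Ties never count as support for either direction; the denominator is
    the pairwise-complete sample count, so missingness does not penalise a
    pair beyond shrinking its evidence base.
    """
    if not 0.5 < theta <= 1.0:
        raise ValueError(f"theta must lie in (0.5, 1], got {theta}")
    n_valid = counts.n_valid
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_gt = np.where(n_valid > 0, counts.n_gt / n_valid, 0.0)
        frac_lt = np.where(n_valid > 0, counts.n_lt / n_valid, 0.0)
    keep_gt = frac_gt >= theta
    keep_lt = frac_lt >= theta
    keep = keep_gt | keep_lt
    idx = np.flatnonzero(keep)
    direction = np.where(keep_gt[idx], 1, -1).astype(np.int8)
    support = np.where(keep_gt[idx], frac_gt[idx], frac_lt[idx])
    return StablePairSet(counts.site_ids, idx.astype(np.int64), direction,
                         support, theta, counts.n_samples)


@dataclass
class SiteDegrees:
    """Per-site stable-pair degrees.

    ``a[i]`` counts stable pairs in which site i is the lower site (its
    reversal would support hypermethylation of site i); ``b[i]`` counts
    those in which it is the higher site.  Conservation:
    sum(a) + sum(b) == 2 * n_pairs.
    """

    site_ids: np.ndarray
    a: np.ndarray
    b: np.ndarray


def site_degrees(pairs: StablePairSet) -> SiteDegrees:
    p = pairs.n_sites
    lower, higher = pairs.lower_higher()
    a = np.bincount(lower, minlength=p).astype(np.int64)
    b = np.bincount(higher, minlength=p).astype(np.int64)
    return SiteDegrees(pairs.site_ids, a, b)


# -- persistence --------------------------------------------------------

def save_background(pairs: StablePairSet, path) -> None:
    """Serialise a stable-pair background to a compact versioned binary file."""
    header = {
        "theta": pairs.theta,
        "n_samples": int(pairs.n_samples),
        "n_sites": int(pairs.n_sites),
        "n_pairs": int(pairs.n_pairs),
    }
    blob = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(blob).to_bytes(4, "little"))
        fh.write(blob)
        np.save(fh, pairs.site_ids.astype(str))
        np.save(fh, pairs.pair_idx)
        np.save(fh, pairs.direction)
        np.save(fh, pairs.support)


def load_background(path) -> StablePairSet:
    """Load a background written by :func:`save_background`.

    Raises ``ValueError`` on a wrong magic/version prefix or a truncated
    file.
    """
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise ValueError(f"{path}: not an RMO background file "
                             f"(bad magic {magic!r})")
        try:
            n = int.from_bytes(fh.read(4), "little")
            header = json.loads(fh.read(n).decode())
            site_ids = np.load(fh, allow_pickle=False).astype(object)
            pair_idx = np.load(fh, allow_pickle=False)
            direction = np.load(fh, allow_pickle=False)
            support = np.load(fh, allow_pickle=False)
        except Exception as exc:
            raise ValueError(f"{path}: truncated or corrupt background file"
                             ) from exc
    if len(pair_idx) != header["n_pairs"] or len(site_ids) != header["n_sites"]:
        raise ValueError(f"{path}: header/payload size mismatch")
    return StablePairSet(site_ids, pair_idx, direction, support,
                         header["theta"], header["n_samples"])


def export_pairs_tsv(pairs: StablePairSet, path) -> None:
    """Human-readable TSV export (site_i, site_j, direction, support)."""
    pairs.to_frame().to_csv(path, sep="\t", index=False,
                            float_format="%.6f")
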