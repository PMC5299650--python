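"""Cross-dataset reproducibility scoring of direction-labelled lists.

Two independently derived lists of directed items (stable CpG-site pairs,
reversal pairs, or differentially methylated sites, each labelled with one
of two directions) are compared on their shared items: the concordance
score is s/k, with k shared items and s of them agreeing in direction.
Significance comes from the upper binomial tail P(X >= s), X ~
Binomial(k, Pe), with Pe = 0.5 the chance of agreeing by coin flip.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .background import StablePairSet
from .stats import binomial_tail_p

__all__ = ["ConcordanceResult", "concordance_score", "compare_stable_pair_sets"]


@dataclass
class ConcordanceResult:
    """Outcome of a two-list direction concordance comparison.

    ``score`` and ``p`` are None when the lists share no items (k = 0) —
    an explicit no-overlap result rather than a 0/0.
    """

    k: int
    s: int
    score: Optional[float]
    pe: float
    p: Optional[float]


def _as_mapping(items) -> Mapping:
    if isinstance(items, Mapping):
        return items
    return dict(items)


def concordance_score(list_a, list_b, pe: float = 0.5) -> ConcordanceResult:
    """Concordance of two direction-labelled lists.

    Each list is a mapping ``item -> direction`` (or an iterable of
    (item, direction) pairs) with directions from any two-valued label set.
    Symmetric in its arguments.
    """
    a = _as_mapping(list_a)
    b = _as_mapping(list_b)
    shared = a.keys() & b.keys()
    k = len(shared)
    if k == 0:
        return ConcordanceResult(0, 0, None, pe, None)
    s = sum(1 for item in shared if a[item] == b[item])
    return ConcordanceResult(k, s, s / k, pe, binomial_tail_p(k, s, pe))


def compare_stable_pair_sets(set_a: StablePairSet, set_b: StablePairSet,
                             pe: float = 0.5) -> dict:
    """Reproducibility of two stable-pair backgrounds (e.g. two platforms).

    Reports the containment of the shorter list in the longer one and the
    direction concordance over the shared pairs, the two headline
    reproducibility statistics for cross-cohort stable-pair lists.
    """
    def as_dict(s: StablePairSet) -> dict:
        i, j = s.pair_members()
        return {
            (s.site_ids[ii], s.site_ids[jj]): int(d)
            for ii, jj, d in zip(i, j, s.direction)
        }

    a = as_dict(set_a)
    b = as_dict(set_b)
    shorter, longer = (a, b) if len(a) <= len(b) else (b, a)
    shared = shorter.keys() & longer.keys()
    containment = len(shared) / len(shorter) if shorter else None
    result = concordance_score(a, b, pe=pe)
    return {
        "n_pairs_a": len(a),
        "n_pairs_b": len(b),
        "containment_shorter_in_longer": containment,
        "concordance": result,
    }
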