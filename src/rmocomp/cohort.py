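"""Cohort-level summaries of individualized calls.

Precision against paired adjacent-normal tissue, recurrence frequencies
across a cohort, paired direction validation, the promoter-gene
hypermethylation rule, expression down-regulation frequencies, and
per-sample pathway over-representation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "PrecisionReport",
    "precision_against_paired",
    "aberration_frequency",
    "PairedDirectionResult",
    "paired_direction_frequency",
    "gene_methylation_status",
    "downregulation_frequency",
    "read_gmt",
    "pathway_enrichment",
]


@dataclass
class PrecisionReport:
    """Positive-predictive-value report for one sample's calls.

    A call is a true positive when its direction matches the sign of
    (tumor beta - paired normal beta) at that site; a zero difference
    contradicts the call and counts as a false positive.  Sites missing in
    either profile are excluded (and counted).  ``precision`` is None when
    no call could be scored.
    """

    sample_id: str
    tp: int
    fp: int
    excluded: int

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else None


def precision_against_paired(calls: pd.DataFrame, tumor_beta: pd.Series,
                             normal_beta: pd.Series,
                             restrict_to=None) -> PrecisionReport:
    """Score one sample's calls against its paired adjacent normal.

    ``calls`` holds that sample's rows (columns ``site_id``,
    ``direction``); ``restrict_to`` optionally limits scoring to a site
    set (e.g. population-level DM sites) before counting.
    """
    sample_id = calls["sample_id"].iloc[0] if len(calls) else "sample"
    if restrict_to is not None:
        calls = calls[calls["site_id"].isin(set(restrict_to))]
    tp = fp = excluded = 0
    for site, direction in zip(calls["site_id"], calls["direction"]):
        t = tumor_beta.get(site, np.nan)
        n = normal_beta.get(site, np.nan)
        if not (np.isfinite(t) and np.isfinite(n)):
            excluded += 1
            continue
        diff = t - n
        if (direction == "hyper" and diff > 0) or (direction == "hypo" and diff < 0):
            tp += 1
        else:
            fp += 1
    return PrecisionReport(sample_id, tp, fp, excluded)


def aberration_frequency(calls: pd.DataFrame, n_samples: int,
                         min_frequency: float = 0.9
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site hyper/hypo recurrence frequencies across a cohort.

    ``calls`` concatenates per-sample call tables from one
    background/threshold configuration; ``n_samples`` is the cohort size
    (samples with zero calls still count in the denominator).  Returns the
    full frequency table plus the high-recurrence subset where
    max(hyper, hypo) frequency strictly exceeds ``min_frequency``.
    """
    counts = (calls.groupby(["site_id", "direction"])["sample_id"]
              .nunique().unstack(fill_value=0))
    for col in ("hyper", "hypo"):
        if col not in counts:
            counts[col] = 0
    df = pd.DataFrame({
        "site_id": counts.index,
        "n_samples": n_samples,
        "hyper_frequency": counts["hyper"].to_numpy() / n_samples,
        "hypo_frequency": counts["hypo"].to_numpy() / n_samples,
    }).reset_index(drop=True)
    top = df[np.maximum(df["hyper_frequency"], df["hypo_frequency"])
             > min_frequency]
    return df, top.reset_index(drop=True)


@dataclass
class PairedDirectionResult:
    site_id: str
    n_pairs: int
    higher_fraction: float   # tumor beta strictly above paired normal
    lower_fraction: float


def paired_direction_frequency(site_id: str, tumor_beta: pd.DataFrame,
                               normal_beta: pd.DataFrame
                               ) -> Optional[PairedDirectionResult]:
    """Fraction of paired tumor/normal profiles with tumor beta above (and
    below) the paired normal at one site.

    The two frames are sites x samples with matching column order (column
    k of each is one patient's pair).  Pairs with a missing value on
    either side are dropped; None is returned when no valid pair remains.
    """
    if tumor_beta.shape[1] != normal_beta.shape[1]:
        raise ValueError("tumor and normal profiles are not paired")
    t = tumor_beta.loc[site_id].to_numpy(float)
    n = normal_beta.loc[site_id].to_numpy(float)
    valid = np.isfinite(t) & np.isfinite(n)
    if not valid.any():
        return None
    t, n = t[valid], n[valid]
    return PairedDirectionResult(site_id, int(valid.sum()),
                                 float((t > n).mean()), float((t < n).mean()))


def gene_methylation_status(calls: pd.DataFrame, annotation: pd.DataFrame,
                            direction: str = "hyper") -> pd.DataFrame:
    """Promoter-gene methylation status for one sample.

    A gene is hypermethylated in a sample iff at least one CpG site in its
    promoter is called hyper and none is called hypo (the symmetric rule
    applies for ``direction='hypo'``).  Genes without any annotated
    promoter CpG are absent from the output.
    """
    if direction not in ("hyper", "hypo"):
        raise ValueError("direction must be 'hyper' or 'hypo'")
    other = "hypo" if direction == "hyper" else "hyper"
    promoter = annotation[annotation["promoter_flag"]]
    merged = promoter.merge(calls[["site_id", "direction"]], on="site_id",
                            how="left")
    by_gene = merged.groupby("gene_symbol")["direction"].agg(
        n_same=lambda d: (d == direction).sum(),
        n_other=lambda d: (d == other).sum(),
    )
    status = np.where((by_gene["n_same"] >= 1) & (by_gene["n_other"] == 0),
                      f"{direction}methylated", "not")
    sample_id = calls["sample_id"].iloc[0] if len(calls) else "sample"
    return pd.DataFrame({
        "sample_id": sample_id,
        "gene_symbol": by_gene.index,
        "n_" + direction: by_gene["n_same"].to_numpy(),
        "n_" + other: by_gene["n_other"].to_numpy(),
        "status": status,
    }).reset_index(drop=True)


def downregulation_frequency(gene: str, tumor_expr: pd.DataFrame,
                             normal_expr: pd.DataFrame) -> Optional[float]:
    """Fraction of patient pairs whose tumor expression of ``gene`` is
    strictly below the paired normal expression (ties count against
    down-regulation)."""
    if tumor_expr.shape[1] != normal_expr.shape[1]:
        raise ValueError("tumor and normal expression are not paired")
    t = tumor_expr.loc[gene].to_numpy(float)
    n = normal_expr.loc[gene].to_numpy(float)
    valid = np.isfinite(t) & np.isfinite(n)
    if not valid.any():
        return None
    return float((t[valid] < n[valid]).mean())


def read_gmt(path) -> dict[str, set]:
    """Parse a GMT gene-set file into {pathway_id: set of gene symbols}.

    GMT lines are tab-separated: name, description, genes...
    """
    pathways: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                continue
            pathways[fields[0]] = {g for g in fields[2:] if g}
    return pathways


def pathway_enrichment(genes, pathways: dict, universe,
                       fdr_threshold: float = 0.05,
                       sample_id: str = "sample") -> pd.DataFrame:
    """One-sided hypergeometric over-representation of a gene list.

    ``genes`` is one sample's hyper- (or hypo-) methylated gene list;
    ``universe`` the annotated genes on the platform.  P(overlap >= k) per
    pathway, BH across pathways within the sample.
    """
    universe = set(universe)
    genes = set(genes) & universe
    rows = []
    for pid, members in sorted(pathways.items()):
        members = members & universe
        k = len(genes & members)
        p = float(sps.hypergeom.sf(k - 1, len(universe), len(members),
                                   len(genes))) if members else 1.0
        rows.append((pid, len(members), k, p))
    df = pd.DataFrame(rows, columns=["pathway_id", "pathway_size",
                                     "overlap", "p"])
    if len(genes) == 0 or df.empty:
        df["fdr"] = np.nan
        df["significant"] = False
        df.insert(0, "sample_id", sample_id)
        return df.iloc[0:0] if len(genes) == 0 else df
    df["fdr"] = bh_adjust(df["p"])
    df["significant"] = df["fdr"] < fdr_threshold
    df.insert(0, "sample_id", sample_id)
    return df
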