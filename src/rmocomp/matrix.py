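"""Containers and I/O for CpG beta-value matrices.

The central container is :class:`MethylationMatrix`: beta values (the
fraction of methylated signal at a CpG site, bounded in [0, 1)) laid out as
sites x samples, with missing measurements represented as NaN.  All
downstream statistics in this package are rank-based within a sample, so no
between-sample normalisation is ever applied here; preprocessing is limited
to beta computation from raw signal intensities, detection-p filtering,
platform intersection and cohort quality control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LABELS = ("normal", "tumor", "unknown")

__all__ = [
    "MethylationMatrix",
    "compute_beta",
    "intersect_common_sites",
    "filter_detection",
    "qc_normal_correlation",
    "read_matrix",
    "write_matrix",
    "read_annotation",
]


@dataclass
class MethylationMatrix:
    """Beta values for CpG sites x samples.

    Parameters
    ----------
    site_ids : sequence of str
        Unique CpG identifiers (rows).
    sample_ids : sequence of str
        Unique sample identifiers (columns).
    values : ndarray, shape (n_sites, n_samples)
        Beta fractions in [0, 1]; NaN marks a missing measurement.
    groups : sequence of str, optional
        Per-sample label, one of ``normal``/``tumor``/``unknown``.
    """

    site_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray
    groups: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.site_ids = np.asarray(self.site_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.site_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.sample_ids)} samples"
            )
        for name, ids in (("site", self.site_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
                raise ValueError(f"duplicate {name} ids: {dupes}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("beta values must lie in [0, 1]")
        if self.groups is None:
            self.groups = np.array(["unknown"] * self.n_samples, dtype=object)
        else:
            self.groups = np.asarray(self.groups, dtype=object)
            if len(self.groups) != self.n_samples:
                raise ValueError("groups length does not match sample count")
            bad = set(self.groups) - set(GROUP_LABELS)
            if bad:
                raise ValueError(f"unknown group labels: {sorted(bad)}")

    # -- basic geometry -------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (n_sites, n_samples) array; True where the value is missing."""
        return np.isnan(self.values)

    # -- selection ------------------------------------------------------
    def select_sites(self, site_ids) -> "MethylationMatrix":
        """Restrict to ``site_ids`` (kept in the order given)."""
        idx = pd.Index(self.site_ids).get_indexer(list(site_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(site_ids, idx) if i < 0]
            raise KeyError(f"sites not present in matrix: {missing[:5]}")
        return MethylationMatrix(
            np.asarray(list(site_ids), dtype=object),
            self.sample_ids.copy(),
            self.values[idx],
            self.groups.copy(),
        )

    def select_samples(self, sample_ids) -> "MethylationMatrix":
        idx = pd.Index(self.sample_ids).get_indexer(list(sample_ids))
        if (idx < 0).any():
            missing = [s for s, i in zip(sample_ids, idx) if i < 0]
            raise KeyError(f"samples not present in matrix: {missing[:5]}")
        return MethylationMatrix(
            self.site_ids.copy(),
            np.asarray(list(sample_ids), dtype=object),
            self.values[:, idx],
            self.groups[idx],
        )

    def select_group(self, group: str) -> "MethylationMatrix":
        """Restrict to samples carrying a given group label."""
        keep = self.groups == group
        return MethylationMatrix(
            self.site_ids.copy(),
            self.sample_ids[keep],
            self.values[:, keep],
            self.groups[keep],
        )

    def sample_vector(self, sample_id: str) -> pd.Series:
        """One sample's beta profile as a site-indexed Series."""
        j = int(np.flatnonzero(self.sample_ids == sample_id)[0])
        return pd.Series(self.values[:, j], index=self.site_ids, name=sample_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.site_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, groups=None) -> "MethylationMatrix":
        return cls(df.index.to_numpy(object), df.columns.to_numpy(object),
                   df.to_numpy(float), groups)


def compute_beta(signals: pd.DataFrame, offset: float = 100.0) -> MethylationMatrix:
    """Beta values from methylated/unmethylated signal intensities.

    ``signals`` is a long-format frame with columns ``site_id``,
    ``sample_id``, ``M`` (methylated intensity) and ``U`` (unmethylated
    intensity).  Each beta value is M / (U + M + offset); the additive
    offset regularises low-intensity probes, so beta is strictly below 1.

    Raises
    ------
    ValueError
        If any intensity is negative (the offending site/sample is named).
    """
    required = {"site_id", "sample_id", "M", "U"}
    if not required <= set(signals.columns):
        raise ValueError(f"signal table must have columns {sorted(required)}")
    neg = signals[(signals["M"] < 0) | (signals["U"] < 0)]
    if len(neg):
        row = neg.iloc[0]
        raise ValueError(
            f"negative signal intensity at site {row['site_id']!r}, "
            f"sample {row['sample_id']!r} (M={row['M']}, U={row['U']})"
        )
    beta = signals["M"] / (signals["U"] + signals["M"] + offset)
    wide = signals.assign(beta=beta).pivot_table(
        index="site_id", columns="sample_id", values="beta", aggfunc="first"
    )
    return MethylationMatrix.from_dataframe(wide)


def intersect_common_sites(annotation: pd.DataFrame, *matrices: MethylationMatrix,
                           platforms=("27K", "450K")) -> list[str]:
    """Sites annotated to every platform in ``platforms`` and present in all matrices.

    Returns the intersection in lexicographic order.  An empty result is an
    error: it almost always means mismatched identifier conventions.
    """
    member = annotation["platforms"].map(
        lambda p: set(platforms) <= set(str(p).replace(";", ",").split(","))
    )
    common = set(annotation.loc[member, "site_id"])
    for m in matrices:
        common &= set(m.site_ids)
    if not common:
        raise ValueError("no CpG sites shared across platforms and matrices")
    return sorted(common)


def filter_detection(matrix: MethylationMatrix, detection_p: np.ndarray,
                     threshold: float = 0.05) -> MethylationMatrix:
    """Mask cells whose detection p-value exceeds ``threshold``.

    Retained values are left bit-for-bit untouched.
    """
    detection_p = np.asarray(detection_p, dtype=float)
    if detection_p.shape != matrix.values.shape:
        raise ValueError(
            f"detection p shape {detection_p.shape} does not match "
            f"matrix shape {matrix.values.shape}"
        )
    values = matrix.values.copy()
    values[detection_p > threshold] = np.nan
    return MethylationMatrix(matrix.site_ids.copy(), matrix.sample_ids.copy(),
                             values, matrix.groups.copy())


def qc_normal_correlation(matrix: MethylationMatrix,
                          flag_threshold: float = 0.72) -> pd.DataFrame:
    """Per-sample minimum pairwise Spearman correlation across a normal cohort.

    A sample whose methylation profile correlates poorly with every other
    normal sample (as in the one outlier adjacent-normal tissue whose best
    correlation was below 0.72) is flagged, never silently dropped.

    Returns a frame with columns ``sample_id``, ``min_spearman``, ``flagged``.
    """
    if matrix.n_samples < 3:
        raise ValueError("QC requires at least 3 samples")
    rho, _ = stats.spearmanr(matrix.values, nan_policy="omit")
    rho = np.asarray(rho, dtype=float)
    np.fill_diagonal(rho, np.nan)
    min_rho = np.nanmin(rho, axis=1)
    return pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "min_spearman": min_rho,
        "flagged": min_rho < flag_threshold,
    })


# -- delimited-text I/O -------------------------------------------------

def read_matrix(path, groups=None) -> MethylationMatrix:
    """Read a sites x samples beta matrix from tab-delimited text.

    First column: site ids; header row: sample ids; "NA" (or empty) marks a
    missing cell.  Duplicate ids, ragged rows and non-numeric cells raise a
    parse error naming the offending line.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise ValueError(f"{path}: malformed matrix file: {exc}") from exc
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate site id(s): {dup}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate sample id(s): {dup}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col].replace({"NA": None, "": None}),
                                  errors="coerce")
        bad = converted.isna() & ~df[col].isin(["NA", ""])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"{path}: non-numeric cell {df[col].iloc[i]!r} at line {i + 2}, "
                f"column {col!r}"
            )
        values[:, j] = converted.to_numpy(float)
    return MethylationMatrix(df.index.to_numpy(object),
                             df.columns.to_numpy(object), values, groups)


def write_matrix(matrix: MethylationMatrix, path, decimals: int = 6) -> None:
    """Write a matrix as tab-delimited text ("NA" for missing), rounded to
    ``decimals`` places."""
    df = matrix.to_dataframe()
    df.to_csv(path, sep="\t", na_rep="NA", float_format=f"%.{decimals}f",
              index_label="site_id")


def read_annotation(path) -> pd.DataFrame:
    """Read a CpG annotation table.

    Tab-delimited with columns ``site_id``, ``gene_symbol``,
    ``promoter_flag`` (0/1 or true/false) and ``platforms``
    (comma- or semicolon-separated subset of 27K/450K).  A site may map to
    several genes via repeated rows.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"site_id", "gene_symbol", "promoter_flag", "platforms"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    df["promoter_flag"] = df["promoter_flag"].str.lower().isin(
        ["1", "true", "yes"])
    return df
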