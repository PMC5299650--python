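"""Synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure the ordering-based caller
relies on: per-site baseline means drawn from a bimodal law (the familiar
low/high two-hump shape of promoter CpG beta distributions), per-cell
beta-distributed measurement noise around those means in normal samples
(so within-sample orderings of well-separated sites are conserved in
essentially all normals), and tumor samples that carry sparse directional
aberrations — each aberrant site fires in a given tumor with a recurrence
probability and, when it fires, has its mean shifted by a fixed effect
size before noise.  Every injected aberration is recorded exactly, so
calls can be scored for precision and recall against the truth.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawns; identical configs give byte-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import MethylationMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "baseline_means",
    "simulate_normal_cohort",
    "simulate_tumor_cohort",
    "recovery_metrics",
]

_MEAN_CLIP = 1e-6


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Parameters
    ----------
    n_sites, n_normals, n_tumors : int
        Universe and cohort sizes.
    dm_fraction : float
        Fraction of sites in the aberrant-site registry.
    delta : float
        Mean beta shift of an aberration (clipped so means stay in (0, 1)).
    recurrence : float
        Probability an aberrant site fires in a given tumor.
    hyper_fraction : float
        Fraction of aberrant sites whose shift is upward.
    kappa : float
        Beta-noise concentration; per-cell values are Beta(m*kappa,
        (1-m)*kappa), i.e. within-site sd ~ sqrt(m(1-m)/(kappa+1))
        (~0.03 at m = 0.5 for the default 300).
    low_mode_ab, high_mode_ab, high_mode_weight :
        The bimodal baseline law: site means are drawn from
        Beta(*low_mode_ab*) with probability 1 - weight, else
        Beta(*high_mode_ab*).
    seed : int
        Mandatory; the sole entropy source.
    replicate : int
        Cohort replicate index.  The baseline means and the aberrant-site
        registry depend only on ``seed``; sample noise and per-tumor
        firing also depend on ``replicate``, so configs differing only in
        ``replicate`` are independent cohorts drawn from one underlying
        disease model — the multi-dataset situation the population-level
        and concordance analyses assume.
    """

    n_sites: int = 500
    n_normals: int = 80
    n_tumors: int = 30
    dm_fraction: float = 0.1
    delta: float = 0.3
    recurrence: float = 0.9
    hyper_fraction: float = 0.5
    kappa: float = 300.0
    low_mode_ab: tuple = (2.0, 12.0)
    high_mode_ab: tuple = (12.0, 4.0)
    high_mode_weight: float = 0.4
    seed: int = None
    replicate: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("dm_fraction", "recurrence", "hyper_fraction",
                     "high_mode_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.delta < 1.0:
            raise ValueError("delta must lie in [0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if min(self.n_sites, self.n_normals, self.n_tumors) < 0:
            raise ValueError("sizes must be non-negative")


@dataclass
class SimulationTruth:
    """Injected aberrations: the registry of aberrant sites with their
    directions, and the exact (sample, site, direction) firings."""

    registry: pd.DataFrame          # site_id, direction
    events: pd.DataFrame            # sample_id, site_id, direction

    def per_sample(self, sample_id: str) -> set:
        ev = self.events[self.events["sample_id"] == sample_id]
        return set(zip(ev["site_id"], ev["direction"]))


def _model_streams(config: SimulationConfig):
    """RNGs for the disease model (baseline, registry): seed-only."""
    children = np.random.SeedSequence(config.seed).spawn(2)
    return [np.random.default_rng(c) for c in children]


def _cohort_streams(config: SimulationConfig):
    """RNGs for cohort sampling (normal noise, firing, tumor noise):
    seed + replicate."""
    children = np.random.SeedSequence(
        [config.seed, config.replicate]).spawn(3)
    return [np.random.default_rng(c) for c in children]


def _site_ids(n: int) -> np.ndarray:
    width = len(str(max(n - 1, 1)))
    return np.array([f"cg{k:0{width}d}" for k in range(n)], dtype=object)


def baseline_means(config: SimulationConfig) -> pd.Series:
    """Per-site baseline means m_i under the bimodal law (deterministic in
    the config seed)."""
    rng, _ = _model_streams(config)
    hi = rng.random(config.n_sites) < config.high_mode_weight
    m = np.where(hi,
                 rng.beta(*config.high_mode_ab, size=config.n_sites),
                 rng.beta(*config.low_mode_ab, size=config.n_sites))
    m = np.clip(m, _MEAN_CLIP, 1 - _MEAN_CLIP)
    return pd.Series(m, index=_site_ids(config.n_sites), name="baseline_mean")


def _beta_noise(rng, means: np.ndarray, kappa: float) -> np.ndarray:
    m = np.clip(means, _MEAN_CLIP, 1 - _MEAN_CLIP)
    return rng.beta(m * kappa, (1 - m) * kappa)


def simulate_normal_cohort(config: SimulationConfig,
                           means=None) -> MethylationMatrix:
    """Normal cohort: per-cell beta noise around each site's baseline mean.

    ``means`` overrides the drawn baseline (for constructing edge cases);
    by default it is :func:`baseline_means` of the same config.
    """
    rng, _, _ = _cohort_streams(config)
    m = baseline_means(config) if means is None else pd.Series(
        np.asarray(means, float), index=_site_ids(config.n_sites))
    grid = np.repeat(m.to_numpy()[:, None], config.n_normals, axis=1)
    values = _beta_noise(rng, grid, config.kappa)
    return MethylationMatrix(
        m.index.to_numpy(object),
        np.array([f"N{k:03d}" for k in range(config.n_normals)], dtype=object),
        values,
        ["normal"] * config.n_normals,
    )


def simulate_tumor_cohort(config: SimulationConfig, means=None
                          ) -> tuple[MethylationMatrix, SimulationTruth]:
    """Tumor cohort with injected aberrations plus the exact truth.

    An aberrant-site registry of round(dm_fraction * n_sites) sites is
    drawn once; each registry site is hyper with probability
    ``hyper_fraction``.  In each tumor, each registry site fires with
    probability ``recurrence``; firing shifts the site's mean by +/- delta
    (clipped into (0, 1)) before beta noise is applied.
    """
    _, rng_registry = _model_streams(config)
    _, rng_fire, rng_noise = _cohort_streams(config)
    m = baseline_means(config) if means is None else pd.Series(
        np.asarray(means, float), index=_site_ids(config.n_sites))
    site_ids = m.index.to_numpy(object)
    sample_ids = np.array([f"T{k:03d}" for k in range(config.n_tumors)],
                          dtype=object)

    n_ab = int(round(config.dm_fraction * config.n_sites))
    ab_sites = np.sort(rng_registry.choice(config.n_sites, size=n_ab,
                                           replace=False))
    hyper = rng_registry.random(n_ab) < config.hyper_fraction
    shift = np.where(hyper, config.delta, -config.delta)
    fires = rng_fire.random((n_ab, config.n_tumors)) < config.recurrence

    grid = np.repeat(m.to_numpy()[:, None], config.n_tumors, axis=1)
    shifted = np.clip(grid[ab_sites] + shift[:, None], _MEAN_CLIP,
                      1 - _MEAN_CLIP)
    grid[ab_sites] = np.where(fires, shifted, grid[ab_sites])
    values = _beta_noise(rng_noise, grid, config.kappa)

    directions = np.where(hyper, "hyper", "hypo")
    registry = pd.DataFrame({"site_id": site_ids[ab_sites],
                             "direction": directions})
    rows = [(sample_ids[t], site_ids[ab_sites[k]], directions[k])
            for k in range(n_ab) for t in range(config.n_tumors)
            if fires[k, t]]
    events = pd.DataFrame(rows, columns=["sample_id", "site_id", "direction"])
    matrix = MethylationMatrix(site_ids, sample_ids, values,
                               ["tumor"] * config.n_tumors)
    return matrix, SimulationTruth(registry, events)


def recovery_metrics(calls: pd.DataFrame, truth: SimulationTruth) -> dict:
    """Direction-matched precision/recall of calls against injected truth.

    Pooled over samples: precision = |calls matching a truth event| /
    |calls| (None when nothing was called), recall = matched truth events /
    all truth events.  A per-sample breakdown accompanies the pooled
    numbers.
    """
    truth_set = set(zip(truth.events["sample_id"], truth.events["site_id"],
                        truth.events["direction"]))
    call_set = set(zip(calls["sample_id"], calls["site_id"],
                       calls["direction"]))
    matched = call_set & truth_set
    pooled_precision = len(matched) / len(call_set) if call_set else None
    pooled_recall = len(matched) / len(truth_set) if truth_set else None
    per_sample = []
    for sid in sorted({s for s, _, _ in truth_set} |
                      {s for s, _, _ in call_set}):
        t = {x for x in truth_set if x[0] == sid}
        c = {x for x in call_set if x[0] == sid}
        m = t & c
        per_sample.append({
            "sample_id": sid,
            "n_calls": len(c),
            "n_truth": len(t),
            "precision": len(m) / len(c) if c else None,
            "recall": len(m) / len(t) if t else None,
        })
    return {
        "precision": pooled_precision,
        "recall": pooled_recall,
        "per_sample": pd.DataFrame(per_sample),
    }
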