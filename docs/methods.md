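# Methods

## Model and assumptions

The unit of information is the *relative methylation-level ordering* (RMO):
within one sample, site A is above or below site B by beta value.  The
method rests on two empirical premises: (1) RMOs of well-separated CpG
sites are nearly invariant across normal samples of a tissue, so a
background of stable pairs can be predetermined once from accumulated
normals and reused for any new sample measured on a compatible platform;
(2) tumors disrupt these orderings broadly.  Because orderings are
invariant under any monotone within-sample transformation, no
between-sample normalisation is applied anywhere — this is also why
pooling normal cohorts from different platforms/laboratories into one
background is defensible, and pooling (after restriction to the shared
site universe) is the default when multiple normal sources are given.

**Stable pairs.**  Pair (i, j) is stable with direction d if the fraction
of pairwise-complete normal samples showing d is at least θ.  The
denominator is the pairwise-complete count (both sites non-missing), so
detection-filtered cells shrink the evidence base rather than veto the
pair.  Exact beta ties support neither direction.  θ defaults to 0.99
("at least 99%", read literally as support/n_valid ≥ θ with no rounding);
note that in a cohort of n < 100 samples this effectively demands
unanimity, since (n−1)/n < 0.99.

**Per-sample test.**  For site C_i, the evaluable stable pairs split into
the a pairs where C_i is the lower site and the b pairs where it is the
higher site; a1 and b1 of them are reversed in the sample.  Reversals of
lower-side pairs support hypermethylation, higher-side reversals support
hypomethylation; treating other sites' aberrations as random rank noise,
the null is equal reversal proportions on both sides, tested by the
two-sided conditional Fisher exact test on [[a1, a−a1], [b1, b−b1]].
P-values are BH-adjusted within the sample over the tested sites only;
direction is hyper iff a1/a > b1/b, and an exact proportion tie yields no
call.  Pairs with a missing member or a tied beta in the sample are
excluded from both margins before the table is filled.

**Population screens.**  The population-level DM screen is a per-site
Welch t-test (unequal variances; a pooled-variance flag exists) with BH at
0.05; sites detected with consistent directions in two independent
datasets form the population-level DM set.  The reversal-pair screen
tests, per stable pair, the 2×2 table of (consistent, reversed) sample
counts in normal vs cancer cohorts, one-sided toward excess cancer
reversals (computed as a vectorised hypergeometric survival function,
identical to Fisher's one-sided exact test), BH across pairs.

**Concordance model.**  Two direction-labelled lists sharing k items, s of
them with equal direction, get score s/k and significance
P(X ≥ s), X ~ Binomial(k, P_e), with P_e = 0.5 by default.  The tail is
computed through the regularised incomplete beta function, stable to
k ~ 1e9; s = 0 returns exactly 1.

## Evaluation protocol

Precision of individualized calls is positive predictive value against
the sign of (tumor β − paired-normal β); a zero observed difference
contradicts the call and counts as a false positive, and sites missing in
either profile are excluded but reported.  Calling for precision
evaluation is *restricted to population-level DM sites* and BH runs over
that restricted set — this mirrors the original evaluation design and is
load-bearing: the one-pass rank test inherits bias at quiescent sites
whose stable partners are themselves aberrant ("dirty" partners pile
reversals onto one side of the table), and the population-level
restriction removes essentially all such sites.  Unrestricted calling is
fully supported (both modes are exposed) but carries lower precision on
cohorts with many recurrent aberrations; the iterative partner-cleaning
refinement of the original expression-domain algorithm is deliberately out
of scope.

Rank-extreme sites with all stable partners on one side (a = 0 or b = 0)
have no two-proportion comparison.  By default they are not callable; an
opt-in flag tests the non-empty side's reversal count as an exact binomial
against the sample's global reversal rate.

## Synthetic cohorts

The generator emulates exactly the structure the method assumes.  Site
baseline means come from a bimodal mixture (60% Beta(2, 12), mean ≈ 0.14;
40% Beta(12, 4), mean ≈ 0.75) mimicking the low/high two-hump shape of
promoter CpG beta distributions.  Each measurement is
Beta(mκ, (1−m)κ) around its site mean; the default concentration κ = 300
gives a within-site sd of ≈ 0.03 at m = 0.5, so pairs separated by ≳ 0.1
in mean are stable in essentially every normal sample while close pairs
are not — reproducing the observed mix of huge stable-pair counts with
imperfect cross-cohort containment.  A registry of round(dm_fraction ·
n_sites) aberrant sites is drawn once per disease model (direction hyper
with probability hyper_fraction, default 0.5); in each tumor a registry
site fires with probability `recurrence`, shifting its mean by ±δ
(clipped into (0, 1)) before noise.  Defaults — 500 sites, 80 normals,
30 tumors, dm_fraction 0.1, δ = 0.3, recurrence 0.9 — are the package's
standard desk-scale study conditions, sized so the full pipeline runs in
seconds while keeping per-site pair degrees in the hundreds.

All randomness flows from one mandatory seed via `SeedSequence` spawns.
The `replicate` field re-draws cohort noise and per-tumor firings while
keeping the baseline means and aberration registry fixed, giving
independent datasets of one disease model — the multi-dataset situation
the population-level and concordance analyses require.

What the simulator does **not** model: probe-level chemistry and detection
failure mechanisms, batch and purity effects, spatially correlated
aberrations (CpG-island co-methylation), and subtype structure.  Passing
recovery tests therefore demonstrates correctness of the ordering
machinery and its statistics under the stated assumptions, not performance
on any real cohort.  Aberrations injected at sites whose shifted mean
clips at the beta boundary (e.g. a hypomethylation at baseline 0.03) have
little or no ordering consequence and are invisible to any rank-based
caller; they bound achievable recall below 1 by construction.

## Numerical choices

- Fisher two-sided p sums hypergeometric point masses ≤ the observed
  mass with relative tie tolerance 1e-7; the all-zero table returns 1.
  Agreement with exact integer enumeration is exhaustive for N ≤ 40.
- Pair counting is chunked (default 256×256 site blocks) and
  chunk-size-invariant; pairs are indexed in condensed upper-triangle
  order over the lexicographically sorted site universe, so results are
  deterministic across runs and platforms.
- BH is a single shared step-up implementation (delegating to
  statsmodels) used by every module; inputs outside [0, 1] are rejected.
- Stability thresholding divides support by n_valid and compares ≥ θ
  directly; counts are never rounded.
- The serialized background is a small versioned binary container (magic
  prefix, JSON provenance header, raw arrays); wrong magic or truncation
  raises immediately.

## Known limitations

- Site universes of ~26k (the dual-platform promoter set) imply ~3×10⁸
  pairs; counting is memory-bounded but the condensed count arrays grow
  quadratically, so genome-wide 450k universes are out of scope.
- The caller is one-pass: no iterative re-estimation of dirty partners.
- The pathway enrichment test is a design choice (one-sided
  hypergeometric over-representation + BH within sample); "enrichment"
  admits other models.
- QC flags low-correlation normals (default Spearman 0.72 floor) but
  never drops them automatically; curation is the caller's decision.
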