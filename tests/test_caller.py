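"""The individualized caller: reversal flags, contingencies, Fisher test,
and per-sample DM calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rmocomp import (SimulationConfig, build_stable_pairs, call_cohort,
                     call_sample_dm, count_pair_orderings,
                     fisher_exact_two_sided, recovery_metrics,
                     sample_reversal_flags, simulate_normal_cohort,
                     simulate_tumor_cohort, site_contingencies,
                     site_contingency)
from rmocomp.background import StablePairSet
from rmocomp.caller import NOT_EVALUABLE, REVERSED
from rmocomp.stats import fisher_exact_two_sided_many

from conftest import fisher_two_sided_enumeration


def two_site_background(direction):
    return StablePairSet(np.array(["A", "B"], dtype=object),
                         np.array([0]), np.array([direction]),
                         np.array([1.0]), 0.99, 50)


class TestSampleReversalFlags:
    def test_strict_contradiction_is_reversed(self):
        pairs = two_site_background(-1)  # stable A < B
        flags = sample_reversal_flags(pairs, np.array([0.8, 0.2]))
        assert flags[0] == REVERSED

    def test_tie_not_evaluable(self):
        pairs = two_site_background(-1)
        flags = sample_reversal_flags(pairs, np.array([0.5, 0.5]))
        assert flags[0] == NOT_EVALUABLE

    def test_missing_member_not_evaluable(self):
        pairs = two_site_background(-1)
        flags = sample_reversal_flags(pairs, np.array([np.nan, 0.5]))
        assert flags[0] == NOT_EVALUABLE

    def test_series_input_aligns_by_site_id(self):
        pairs = two_site_background(-1)
        beta = pd.Series({"B": 0.2, "A": 0.8})  # shuffled order
        assert sample_reversal_flags(pairs, beta)[0] == REVERSED

    def test_matches_per_pair_recomputation(self):
        cfg = SimulationConfig(n_sites=40, n_normals=30, n_tumors=1, seed=2)
        pairs = build_stable_pairs(
            count_pair_orderings(simulate_normal_cohort(cfg)))
        tumors, _ = simulate_tumor_cohort(cfg)
        beta = tumors.sample_vector(tumors.sample_ids[0])
        flags = sample_reversal_flags(pairs, beta)
        i, j = pairs.pair_members()
        for k in range(pairs.n_pairs):
            bi = beta[pairs.site_ids[i[k]]]
            bj = beta[pairs.site_ids[j[k]]]
            if np.isnan(bi) or np.isnan(bj) or bi == bj:
                assert flags[k] == NOT_EVALUABLE
            else:
                observed = 1 if bi > bj else -1
                assert flags[k] == (1 if observed == -pairs.direction[k]
                                    else 0)


class TestSiteContingency:
    def _star_background(self):
        # universe A,B,C,D,E; pairs: A<B, A<C (a-side of A), D<A, E<A
        # (b-side of A)
        ids = np.array(["A", "B", "C", "D", "E"], dtype=object)
        # condensed over p=5: (A,B)=0 (A,C)=1 (A,D)=2 (A,E)=3
        return StablePairSet(ids, np.array([0, 1, 2, 3]),
                             np.array([-1, -1, 1, 1]),
                             np.ones(4), 0.99, 50)

    def test_hand_worked_cells(self):
        pairs = self._star_background()
        # A=0.9 exceeds B,C (reversals on a-side); D,E below stay below
        beta = np.array([0.9, 0.3, 0.4, 0.1, 0.2])
        ct = site_contingency("A", pairs, sample_reversal_flags(pairs, beta))
        assert (ct.a, ct.a1, ct.b, ct.b1) == (2, 2, 2, 0)
        assert ct.table == [[2, 0], [0, 2]]

    def test_not_evaluable_pairs_shrink_margins(self):
        pairs = self._star_background()
        beta = np.array([0.9, np.nan, 0.4, 0.1, 0.9])  # B missing, E tie
        ct = site_contingency("A", pairs, sample_reversal_flags(pairs, beta))
        assert (ct.a, ct.a1, ct.b, ct.b1) == (1, 1, 1, 0)

    def test_all_pairs_not_evaluable_gives_empty_table(self):
        pairs = self._star_background()
        beta = np.full(5, np.nan)
        ct = site_contingency("A", pairs, sample_reversal_flags(pairs, beta))
        assert (ct.a, ct.b) == (0, 0)

    def test_reversal_conservation_across_sites(self):
        """Every reversed pair contributes exactly one a-side count (at its
        lower site) and one b-side count (at its higher site)."""
        cfg = SimulationConfig(n_sites=60, n_normals=30, n_tumors=1,
                               dm_fraction=0.2, seed=12)
        pairs = build_stable_pairs(
            count_pair_orderings(simulate_normal_cohort(cfg)))
        tumors, _ = simulate_tumor_cohort(cfg)
        flags = sample_reversal_flags(
            pairs, tumors.sample_vector(tumors.sample_ids[0]))
        a, a1, b, b1 = site_contingencies(pairs, flags)
        n_rev = int((flags == REVERSED).sum())
        assert a1.sum() == n_rev
        assert b1.sum() == n_rev
        assert a.sum() == b.sum() == int((flags != NOT_EVALUABLE).sum())


class TestFisherExactTwoSided:
    @pytest.mark.parametrize("table,expected", [
        ([[5, 0], [0, 5]], 2 / 252),
        ([[1, 1], [1, 1]], 1.0),
        ([[2, 0], [0, 2]], 2 / 6),
    ])
    def test_enumeration_derived_values(self, table, expected):
        assert fisher_exact_two_sided(table) == pytest.approx(expected,
                                                              rel=1e-9)

    def test_all_zero_table_degenerate(self):
        assert fisher_exact_two_sided([[0, 0], [0, 0]]) == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 2]])

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            t = rng.integers(0, 25, size=(2, 2))
            ours = fisher_exact_two_sided(t)
            _, scipy_p = sps.fisher_exact(t)
            assert ours == pytest.approx(scipy_p, rel=1e-7, abs=1e-12)

    def test_matches_integer_enumeration_on_small_tables(self):
        for a in range(6):
            for b in range(6):
                for c in range(6):
                    for d in range(6):
                        ours = fisher_exact_two_sided([[a, b], [c, d]])
                        oracle = fisher_two_sided_enumeration(a, b, c, d)
                        assert ours == pytest.approx(oracle, rel=1e-9,
                                                     abs=1e-14)

    def test_batch_equals_scalar(self):
        rng = np.random.default_rng(8)
        t = rng.integers(0, 30, size=(50, 4))
        batch = fisher_exact_two_sided_many(t[:, 0], t[:, 1], t[:, 2],
                                            t[:, 3])
        for k in range(50):
            assert batch[k] == fisher_exact_two_sided(
                [[t[k, 0], t[k, 1]], [t[k, 2], t[k, 3]]])


class TestCallSampleDm:
    def _setup(self, **kw):
        cfg = SimulationConfig(n_sites=kw.pop("n_sites", 120),
                               n_normals=kw.pop("n_normals", 40),
                               n_tumors=kw.pop("n_tumors", 1), **kw)
        normals = simulate_normal_cohort(cfg)
        pairs = build_stable_pairs(count_pair_orderings(normals))
        return cfg, normals, pairs

    def test_consensus_ordering_yields_zero_calls(self):
        from rmocomp import baseline_means
        cfg, normals, pairs = self._setup(dm_fraction=0.0, seed=30)
        calls = call_sample_dm(
            baseline_means(cfg).rename(None), pairs)
        assert len(calls) == 0

    def test_single_extreme_site_called_with_direction(self):
        from rmocomp import baseline_means
        cfg, normals, pairs = self._setup(dm_fraction=0.0, seed=31)
        beta = baseline_means(cfg).copy()
        victim = beta.index[60]
        beta[victim] = min(0.999, beta[victim] + 0.5)
        calls = call_sample_dm(beta, pairs, fdr_threshold=0.01)
        assert victim in set(calls["site_id"])
        assert calls.set_index("site_id").loc[victim, "direction"] == "hyper"

    def test_injected_sites_dominate_and_precision_high(self):
        cfg = SimulationConfig(n_sites=500, n_normals=60, n_tumors=1,
                               dm_fraction=0.1, delta=0.3, recurrence=1.0,
                               seed=33)
        normals = simulate_normal_cohort(cfg)
        pairs = build_stable_pairs(count_pair_orderings(normals))
        tumors, truth = simulate_tumor_cohort(cfg)
        calls = call_sample_dm(tumors.sample_vector("T000"), pairs,
                               sample_id="T000",
                               restrict_to=truth.registry["site_id"])
        m = recovery_metrics(calls, truth)
        assert m["precision"] >= 0.9

    def test_direction_flip_symmetry(self):
        """Mirroring every beta value (1 - beta) swaps the a- and b-sides:
        all calls flip direction, all p-values are unchanged."""
        cfg = SimulationConfig(n_sites=100, n_normals=40, n_tumors=1,
                               dm_fraction=0.2, recurrence=1.0, seed=34)
        normals = simulate_normal_cohort(cfg)
        pairs = build_stable_pairs(count_pair_orderings(normals))
        tumors, _ = simulate_tumor_cohort(cfg)
        beta = tumors.sample_vector("T000")

        mirrored = StablePairSet(pairs.site_ids, pairs.pair_idx,
                                 -pairs.direction, pairs.support,
                                 pairs.theta, pairs.n_samples)
        calls = call_sample_dm(beta, pairs).set_index("site_id")
        flipped = call_sample_dm(1 - beta, mirrored).set_index("site_id")
        assert set(calls.index) == set(flipped.index)
        for site in calls.index:
            assert calls.loc[site, "p"] == pytest.approx(
                flipped.loc[site, "p"], rel=1e-12)
            assert calls.loc[site, "direction"] != flipped.loc[site,
                                                               "direction"]

    def test_deterministic_byte_identical(self):
        cfg = SimulationConfig(n_sites=80, n_normals=30, n_tumors=3,
                               seed=35)
        normals = simulate_normal_cohort(cfg)
        pairs = build_stable_pairs(count_pair_orderings(normals))
        tumors, _ = simulate_tumor_cohort(cfg)
        a = call_cohort(tumors, pairs)
        b = call_cohort(tumors, pairs)
        pd.testing.assert_frame_equal(a, b)

    def test_restrict_to_limits_tested_sites_and_bh_scope(self):
        cfg = SimulationConfig(n_sites=100, n_normals=40, n_tumors=1,
                               dm_fraction=0.2, recurrence=1.0, seed=36)
        normals = simulate_normal_cohort(cfg)
        pairs = build_stable_pairs(count_pair_orderings(normals))
        tumors, truth = simulate_tumor_cohort(cfg)
        subset = list(truth.registry["site_id"][:5])
        calls = call_sample_dm(tumors.sample_vector("T000"), pairs,
                               restrict_to=subset)
        assert set(calls["site_id"]) <= set(subset)

    def test_empty_background_error(self):
        empty = StablePairSet(np.array(["A", "B"], dtype=object),
                              np.array([], dtype=int),
                              np.array([], dtype=np.int8),
                              np.array([]), 0.99, 10)
        with pytest.raises(ValueError, match="empty"):
            call_sample_dm(np.array([0.1, 0.2]), empty)

    def test_heldout_normals_much_quieter_than_tumors(self):
        """Specificity: held-out normal samples scored against the
        background yield far fewer calls than matched tumors."""
        cfg = SimulationConfig(n_sites=200, n_normals=60, n_tumors=10,
                               dm_fraction=0.1, seed=37)
        normals = simulate_normal_cohort(cfg)
        train = normals.select_samples(normals.sample_ids[:45])
        heldout = normals.select_samples(normals.sample_ids[45:])
        pairs = build_stable_pairs(count_pair_orderings(train))
        tumors, _ = simulate_tumor_cohort(cfg)
        n_calls_normal = len(call_cohort(heldout, pairs))
        n_calls_tumor = len(call_cohort(tumors, pairs))
        assert n_calls_normal / heldout.n_samples < \
            0.2 * n_calls_tumor / tumors.n_samples
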