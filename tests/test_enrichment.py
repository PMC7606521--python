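"""Sweep-window merging, overlap permutation tests, DMR-SNP LD tests
and hypergeometric candidate enrichment."""
import itertools

import numpy as np
import pytest

from epimsfs import (IntervalSet, candidate_enrichment, dmr_snp_ld_test,
                     merge_outlier_windows, overlap_permutation_test)


def windows_from_scores(scores, width=50_000, step=5_000, chrom="chr1"):
    tuples = [(chrom, i * step, i * step + width) for i in range(len(scores))]
    return IntervalSet.from_tuples("xpclr", tuples, scores=scores)


class TestMergeOutlierWindows:
    def test_isolated_top_window_returned_unmerged(self, rng):
        scores = rng.normal(0, 1, 1000)
        scores[500] = 100.0
        out = merge_outlier_windows(windows_from_scores(scores))
        # the planted window is the unique 0.5% outlier; neighbours below
        # the 10% tail do not merge into it
        assert len(out) >= 1
        top = np.argmax(out.scores)
        assert out.scores[top] == 100.0

    def test_adjacent_tail_windows_merge(self, rng):
        # two adjacent planted windows against a noise background: both
        # exceed the 0.5% outlier cut and come back as one merged region
        scores = np.concatenate([rng.normal(0, 1, 98), [10.0, 10.0]])
        out = merge_outlier_windows(windows_from_scores(scores, width=5000))
        assert len(out) == 1
        assert (out.starts[0], out.ends[0]) == (98 * 5000, 100 * 5000)
        assert out.scores[0] == 10.0

    def test_all_equal_scores_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            out = merge_outlier_windows(windows_from_scores(np.ones(50)))
        assert len(out) == 0

    def test_matches_brute_force_quantile_merge_oracle(self, rng):
        scores = rng.normal(0, 1, 1000)
        planted = [100, 101, 102, 400, 401, 700, 701]  # adjacent clusters
        scores[planted] = rng.normal(20, 1, len(planted))
        win = windows_from_scores(scores, width=5000, step=5000)
        out = merge_outlier_windows(win, tail_frac=0.10, outlier_frac=0.005)

        # oracle: independent quantile + scan-line merge
        tail_cut = np.quantile(scores, 0.90)
        out_cut = np.quantile(scores, 0.995)
        regions = []
        for i in np.nonzero(scores >= tail_cut)[0]:
            s, e, sc = i * 5000, i * 5000 + 5000, scores[i]
            if regions and s <= regions[-1][1]:
                regions[-1][1] = max(regions[-1][1], e)
                regions[-1][2] = max(regions[-1][2], sc)
            else:
                regions.append([s, e, sc])
        want = [(s, e) for s, e, sc in regions if sc >= out_cut]
        got = list(zip(out.starts, out.ends))
        assert got == want


class TestOverlapPermutation:
    def universe(self, length=1_000_000):
        return IntervalSet.from_tuples("uni", [("chr1", 0, length)])

    def test_self_overlap_attains_minimum_p(self, rng):
        tuples = [("chr1", int(s), int(s) + 500)
                  for s in rng.choice(900_000, 20, replace=False) * 1]
        q = IntervalSet.from_tuples("q", tuples)
        res = overlap_permutation_test(q, q, self.universe(), n_perm=999,
                                       seed=1)
        assert res.observed == 20
        assert res.p_value == pytest.approx(1 / 1000)

    def test_query_longer_than_universe_errors(self):
        q = IntervalSet.from_tuples("q", [("chr1", 0, 5000)])
        t = IntervalSet.from_tuples("t", [("chr1", 0, 10)])
        uni = IntervalSet.from_tuples("u", [("chr1", 0, 1000)])
        with pytest.raises(ValueError):
            overlap_permutation_test(q, t, uni, n_perm=9)

    def test_statistic_invariant_to_query_order(self, rng):
        starts = rng.choice(90_000, 10, replace=False)
        tuples = [("chr1", int(s), int(s) + 100) for s in starts]
        t = IntervalSet.from_tuples("t", [("chr1", 40_000, 60_000)])
        a = overlap_permutation_test(IntervalSet.from_tuples("q", tuples),
                                     t, self.universe(100_000), 49, seed=3)
        b = overlap_permutation_test(
            IntervalSet.from_tuples("q", tuples[::-1]), t,
            self.universe(100_000), 49, seed=3)
        assert a.observed == b.observed

    def test_null_calibration_and_enrichment_ratio(self, rng):
        # queries placed uniformly at random: p should be uniform and
        # the enrichment ratio ~1 on average
        uni = self.universe(500_000)
        t_tuples = [("chr1", int(s), int(s) + 2000)
                    for s in np.arange(0, 480_000, 25_000)]
        target = IntervalSet.from_tuples("t", t_tuples)
        pvals, ratios = [], []
        for i in range(120):
            starts = rng.choice(499_000, 8, replace=False)
            q = IntervalSet.from_tuples(
                "q", [("chr1", int(s), int(s) + 800) for s in starts])
            res = overlap_permutation_test(q, target, uni, n_perm=99,
                                           seed=1000 + i)
            pvals.append(res.p_value)
            ratios.append(res.enrichment_ratio)
        rej = np.mean(np.array(pvals) <= 0.05)
        assert 0.0 <= rej < 0.12  # near nominal with 120 replicates
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)


class TestDmrSnpLd:
    def test_perfect_ld_snp_hits_minimum_p(self, rng):
        states = rng.integers(0, 3, 30).astype(float)
        geno = np.vstack([states, states, states])
        pvals, in_ld = dmr_snp_ld_test(states, geno, n_perm=999, seed=1)
        assert np.all(pvals == pytest.approx(1 / 1000))
        assert in_ld

    def test_two_significant_snps_are_not_enough(self, rng):
        states = rng.integers(0, 3, 30).astype(float)
        geno = np.vstack([states, states])
        pvals, in_ld = dmr_snp_ld_test(states, geno, n_perm=999, seed=2)
        assert np.sum(pvals < 0.01) == 2
        assert not in_ld  # needs at least three significant SNPs

    def test_monomorphic_snp_gets_p_one(self, rng):
        states = rng.integers(0, 3, 30).astype(float)
        geno = np.vstack([np.zeros(30), states])
        pvals, _ = dmr_snp_ld_test(states, geno, n_perm=99, seed=3)
        assert pvals[0] == 1.0

    def test_null_calibration(self, rng):
        # independent SNPs: fraction with p < 0.01 should be ~1%
        n_sims, snps_per = 300, 4
        hits, total = 0, 0
        for i in range(n_sims):
            states = rng.integers(0, 3, 24).astype(float)
            geno = rng.integers(0, 3, size=(snps_per, 24)).astype(float)
            pvals, _ = dmr_snp_ld_test(states, geno, n_perm=199,
                                       seed=5000 + i)
            hits += np.sum(pvals < 0.01)
            total += snps_per
        rate = hits / total
        se = np.sqrt(0.01 * 0.99 / total)
        assert abs(rate - 0.01) < 3 * se + 0.003

    def test_shared_permutations_reproducible_by_seed_replay(self, rng):
        states = rng.integers(0, 3, 20).astype(float)
        geno = rng.integers(0, 3, size=(5, 20)).astype(float)
        a, _ = dmr_snp_ld_test(states, geno, n_perm=199, seed=7)
        b, _ = dmr_snp_ld_test(states, geno, n_perm=199, seed=7)
        np.testing.assert_array_equal(a, b)


class TestCandidateEnrichment:
    def test_zero_overlap_with_small_candidate_set(self):
        universe = set(range(100))
        p = candidate_enrichment(set(range(10)), {98, 99}, universe)
        assert p == pytest.approx(1.0, abs=0.25)

    def test_forced_full_overlap_gives_p_one(self):
        u = set(range(20))
        assert candidate_enrichment(u, u, u) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # universe 20, candidates 5, hits 4, overlap 3
        universe = list(range(20))
        candidates = set(range(5))
        hits = {0, 1, 2, 10}
        p = candidate_enrichment(hits, candidates, set(universe))
        count = sum(1 for draw in itertools.combinations(universe, 4)
                    if len(set(draw) & candidates) >= 3)
        from math import comb
        assert p == pytest.approx(count / comb(20, 4))

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            candidate_enrichment(set(), set(), set())
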