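"""Psychometric metric, paired comparisons, cluster permutation testing."""

import numpy as np
import pytest
from scipy import stats as sps

from qeeg.stats import (
    PsychometricRecord,
    cluster_permutation,
    paired_compare,
    psychometric_impairment,
    spatiospectral_adjacency,
)


def _psy(rts, correct):
    return PsychometricRecord(
        participant_id="p00", exposure="air_baseline",
        reaction_times=np.asarray(rts, dtype=float),
        correct=np.asarray(correct, dtype=bool),
    )


class TestPsychometricImpairment:
    def test_ceiling_reaction_times(self):
        rec = _psy([5.0] * 20, [True] * 20)
        assert psychometric_impairment(rec) == pytest.approx(0.5)

    def test_fast_and_correct_approaches_zero(self):
        rec = _psy([0.01] * 20, [True] * 20)
        assert psychometric_impairment(rec) == pytest.approx(0.001)

    def test_half_errors_at_half_ceiling(self):
        rec = _psy([2.5] * 20, [True] * 10 + [False] * 10)
        assert psychometric_impairment(rec) == pytest.approx(0.5)

    def test_all_timed_out_is_one(self):
        rec = _psy([np.nan] * 20, [False] * 20)
        assert psychometric_impairment(rec) == 1.0

    def test_timeouts_count_as_errors(self):
        rts = [1.0] * 15 + [np.nan] * 5
        rec = _psy(rts, [True] * 15 + [False] * 5)
        expected = (1.0 / 5.0 + 5 / 20) / 2
        assert psychometric_impairment(rec) == pytest.approx(expected)

    def test_observed_max_normalizer(self):
        rec = _psy([2.0] * 19 + [4.0], [True] * 20)
        m = psychometric_impairment(rec, normalizer="observed_max")
        assert m == pytest.approx(((2.1 / 4.0) + 0.0) / 2)

    @pytest.mark.parametrize("seed", range(5))
    def test_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        rts = rng.uniform(0.1, 5.0, 20)
        rts[rng.random(20) < 0.3] = np.nan
        rec = _psy(rts, rng.random(20) < 0.7)
        assert 0.0 <= psychometric_impairment(rec) <= 1.0

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ValueError, match="20 items"):
            PsychometricRecord("p", "air_baseline",
                               np.ones(19), np.ones(19, dtype=bool))


class TestPairedCompare:
    def test_constant_shift_degenerate(self):
        a = np.arange(12.0)
        c = paired_compare(a, a + 1.0)
        assert c.test == "degenerate"
        assert c.p == 0.0
        assert c.mean_difference == pytest.approx(-1.0)
        assert c.significant

    def test_identical_samples_p_one(self):
        a = np.arange(12.0)
        c = paired_compare(a, a.copy())
        assert c.p == 1.0 and not c.significant

    def test_normal_branch_reports_ci_containing_mean(self):
        rng = np.random.default_rng(0)
        a = rng.normal(1.0, 1.0, 12)
        b = rng.normal(0.0, 1.0, 12)
        c = paired_compare(a, b)
        assert c.test == "paired_t"
        lo, hi = c.ci95
        assert lo <= c.mean_difference <= hi

    def test_skewed_differences_take_wilcoxon_branch(self):
        rng = np.random.default_rng(1)
        a = np.exp(rng.normal(0, 1.2, 40))  # heavily skewed
        b = rng.normal(0, 0.1, 40)
        c = paired_compare(a, b)
        assert c.test == "wilcoxon"
        assert c.median_difference is not None
        assert c.diff_range is not None

    def test_bonferroni_never_more_liberal(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = rng.normal(0.3, 1.0, 12)
            b = rng.normal(0.0, 1.0, 12)
            corrected = paired_compare(a, b, family_size=3)
            uncorrected = paired_compare(a, b, family_size=1)
            assert (not corrected.significant) or uncorrected.significant

    def test_null_rejection_rate_matches_bonferroni_level(self):
        """Corrected rejections under the null run at ~ alpha/family."""
        rng = np.random.default_rng(3)
        n_sims, family = 800, 3
        hits = sum(
            paired_compare(rng.normal(0, 1, 12), rng.normal(0, 1, 12),
                           family_size=family).significant
            for _ in range(n_sims)
        )
        rate = hits / n_sims
        nominal = 0.05 / family
        assert rate == pytest.approx(nominal, abs=0.013)

    def test_power_matches_monte_carlo_oracle(self):
        """Detection rate at n=12, shift 0.18, sd 0.16 tracks a direct
        t-test simulation at the same settings."""
        rng = np.random.default_rng(4)
        n_sims = 400
        ours = oracle = 0
        for _ in range(n_sims):
            d = rng.normal(0.18, 0.16, 12)
            a = rng.normal(1.0, 0.5, 12)
            ours += paired_compare(a + d, a).p < 0.05
            oracle += sps.ttest_rel(a + d, a).pvalue < 0.05
        assert ours / n_sims == pytest.approx(oracle / n_sims, abs=0.07)
        assert ours / n_sims > 0.85  # a d~1.1 effect is near-certain at n=12

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            paired_compare(np.ones(3), np.zeros(3))


def _chain_adjacency(n_ch):
    adj = np.zeros((n_ch, n_ch), dtype=bool)
    for i in range(n_ch - 1):
        adj[i, i + 1] = adj[i + 1, i] = True
    return adj


class TestClusterPermutation:
    def test_identical_conditions_empty(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, (12, 8, 4))
        res = cluster_permutation(a, a.copy(), _chain_adjacency(8),
                                  n_permutations=200, seed=1)
        assert res.clusters == []

    def test_planted_patch_recovered(self):
        """A d=1.5 effect on 4 contiguous channels in one band is found."""
        rng = np.random.default_rng(5)
        adj = _chain_adjacency(10)
        found = 0
        n_sims = 25
        for _ in range(n_sims):
            a = rng.normal(0, 1, (12, 10, 4))
            b = a + rng.normal(0, 0.3, a.shape)
            b[:, 3:7, 2] += 1.5  # planted patch, alpha-like band
            res = cluster_permutation(b, a, adj, n_permutations=200,
                                      seed=int(rng.integers(2**31)))
            sig = res.significant
            if sig:
                channels = {ch for c in sig for (ch, band) in c.nodes if band == 2}
                if len(channels & {3, 4, 5, 6}) >= 3:
                    found += 1
        assert found / n_sims >= 0.9

    def test_effect_size_sign_and_scale(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.2, (12, 6, 2))
        b = a.copy()
        b[:, :3, 0] -= 1.0  # strong decrease
        res = cluster_permutation(a, b, _chain_adjacency(6),
                                  n_permutations=200, seed=7)
        sig = res.significant
        assert sig
        assert sig[0].cohens_d > 2.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, (10, 6, 3))
        b = rng.normal(0.4, 1, (10, 6, 3))
        r1 = cluster_permutation(a, b, _chain_adjacency(6), n_permutations=300, seed=9)
        r2 = cluster_permutation(a, b, _chain_adjacency(6), n_permutations=300, seed=9)
        assert [c.p for c in r1.clusters] == [c.p for c in r2.clusters]

    def test_participant_order_invariance_within_mc_error(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.0, 1, (12, 6, 3))
        b = a + rng.normal(0.35, 0.6, a.shape)
        r1 = cluster_permutation(a, b, _chain_adjacency(6), n_permutations=500, seed=11)
        perm = rng.permutation(12)
        r2 = cluster_permutation(a[perm], b[perm], _chain_adjacency(6),
                                 n_permutations=500, seed=11)
        # observed clusters identical; permutation p-values agree to MC error
        assert [c.mass for c in r1.clusters] == pytest.approx(
            [c.mass for c in r2.clusters]
        )
        for c1, c2 in zip(r1.clusters, r2.clusters):
            assert c1.p == pytest.approx(c2.p, abs=0.06)

    def test_spatiospectral_adjacency_structure(self):
        adj = spatiospectral_adjacency(_chain_adjacency(3), n_bands=2).toarray()
        # node order: (ch0,b0),(ch0,b1),(ch1,b0),...
        assert adj[0, 1]          # same channel, adjacent bands
        assert adj[0, 2]          # neighbour channel, same band
        assert not adj[0, 3]      # diagonal moves are not adjacent
        assert not adj[0, 4]      # non-neighbour channel
        assert np.array_equal(adj, adj.T)

    def test_input_validation(self):
        a = np.zeros((3, 4, 2))
        with pytest.raises(ValueError, match="5 participants"):
            cluster_permutation(a, a, _chain_adjacency(4))
        b = np.zeros((6, 4, 2))
        with pytest.raises(ValueError, match="100 permutations"):
            cluster_permutation(b, b, _chain_adjacency(4), n_permutations=10)
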