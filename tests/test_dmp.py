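"""Unit and oracle tests for the moderated differential-methylation statistic.

The independent oracles: a closed-form pooled two-sample t, brute-force
Benjamini-Hochberg step-up over all permutations of small p-vectors, and
statsmodels' multipletests as a second implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import methylscape as ms
from methylscape.dmp import fit_variance_prior


def _matrix(rng, n_probes, samples):
    return pd.DataFrame(
        rng.random((n_probes, len(samples))),
        index=[f"cg{i:05d}" for i in range(n_probes)],
        columns=samples,
    )


def _pooled_t_oracle(a, b):
    """Ordinary pooled two-sample t, closed form, per row."""
    n_a, n_b = a.shape[1], b.shape[1]
    d = n_a + n_b - 2
    sp2 = (
        ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
        + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
    ) / d
    t = (b.mean(1) - a.mean(1)) / np.sqrt(sp2 * (1 / n_a + 1 / n_b))
    p = 2 * sps.t.sf(np.abs(t), d)
    return t, p


class TestModeratedT:
    def test_identical_group_means_give_t0_p1(self):
        df = pd.DataFrame(
            [[0.4, 0.5, 0.6, 0.4, 0.5, 0.6]],
            index=["cg1"], columns=[f"s{i}" for i in range(6)],
        )
        st_ = ms.moderated_t(df, ["s0", "s1", "s2"], ["s3", "s4", "s5"], shrink=False)
        assert st_.table["t"].iloc[0] == pytest.approx(0.0)
        assert st_.table["p"].iloc[0] == pytest.approx(1.0)

    def test_no_shrinkage_equals_pooled_t_oracle(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(12)]
        df = _matrix(rng, 200, samples)
        st_ = ms.moderated_t(df, samples[:6], samples[6:], shrink=False)
        t, p = _pooled_t_oracle(df[samples[:6]].to_numpy(), df[samples[6:]].to_numpy())
        np.testing.assert_allclose(st_.table["t"].to_numpy(), t, atol=1e-10)
        np.testing.assert_allclose(st_.table["p"].to_numpy(), p, atol=1e-10)

    def test_few_probes_fall_back_to_ordinary_t(self):
        """Below the prior-fit floor the moderated t is exactly the pooled t."""
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(8)]
        df = _matrix(rng, 1, samples)
        st_ = ms.moderated_t(df, samples[:4], samples[4:], shrink=True)
        t, p = _pooled_t_oracle(df[samples[:4]].to_numpy(), df[samples[4:]].to_numpy())
        assert st_.d0 == 0.0
        np.testing.assert_allclose(st_.table["t"].to_numpy(), t, atol=1e-10)

    def test_shrinkage_pulls_variances_toward_prior(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(10)]
        df = _matrix(rng, 500, samples)
        st_ = ms.moderated_t(df, samples[:5], samples[5:], shrink=True)
        assert st_.d0 > 0
        a, b = df[samples[:5]].to_numpy(), df[samples[5:]].to_numpy()
        d = 8
        raw = (
            ((a - a.mean(1, keepdims=True)) ** 2).sum(1)
            + ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        ) / d
        shrunk = st_.table["var_shrunk"].to_numpy()
        # shrunk variance lies between the raw variance and the prior
        between = ((shrunk - raw) * (shrunk - st_.s0_sq) <= 1e-15).mean()
        assert between > 0.99

    def test_swapping_groups_flips_delta_keeps_p_and_calls(self):
        rng = np.random.default_rng(3)
        samples = [f"s{i}" for i in range(10)]
        df = _matrix(rng, 300, samples)
        ab = ms.moderated_t(df, samples[:5], samples[5:])
        ba = ms.moderated_t(df, samples[5:], samples[:5])
        np.testing.assert_allclose(ab.table["delta"], -ba.table["delta"], atol=1e-12)
        np.testing.assert_allclose(np.abs(ab.table["t"]), np.abs(ba.table["t"]), atol=1e-12)
        np.testing.assert_allclose(ab.table["p"], ba.table["p"], atol=1e-12)
        assert ms.call_dmps(ab, 0.5, 0.05).probe_ids == ms.call_dmps(ba, 0.5, 0.05).probe_ids

    def test_small_group_rejected(self):
        df = _matrix(np.random.default_rng(0), 10, ["a", "b", "c"])
        with pytest.raises(ValueError, match="need >= 2"):
            ms.moderated_t(df, ["a"], ["b", "c"])

    def test_variance_prior_moment_fit_recovers_known_prior(self):
        """Variances simulated from the scaled inverse-chi-square model are
        recovered by the method-of-moments fit."""
        rng = np.random.default_rng(4)
        d0_true, s0_true, d = 4.0, 0.05, 10
        n = 200_000
        true_var = d0_true * s0_true / rng.chisquare(d0_true, n)
        s2 = true_var * rng.chisquare(d, n) / d
        d0, s0 = fit_variance_prior(s2, d)
        assert d0 == pytest.approx(d0_true, rel=0.05)
        assert s0 == pytest.approx(s0_true, rel=0.05)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert ms.bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            ms.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_all_ones_stay_ones(self):
        assert (ms.bh_adjust([1.0] * 5) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ms.bh_adjust([0.5, 1.5])

    def test_brute_force_step_up_all_permutations(self):
        """BH equals the definitional step-up on every permutation of <= 6
        p-values (brute-force oracle)."""
        base = [0.001, 0.01, 0.04, 0.2, 0.5, 0.9]
        for perm in itertools.permutations(base):
            p = np.array(perm)
            m = len(p)
            order = np.argsort(p)
            expected = np.empty(m)
            running = 1.0
            for rank in range(m - 1, -1, -1):
                running = min(running, p[order[rank]] * m / (rank + 1))
                expected[order[rank]] = running
            np.testing.assert_allclose(ms.bh_adjust(p), expected, atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_statsmodels_and_dominates_raw(self, pvals):
        from statsmodels.stats.multitest import multipletests

        adj = ms.bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(adj, ref, atol=1e-12)
        assert (adj >= np.asarray(pvals) - 1e-15).all()


class TestCallDmps:
    def _stats(self, deltas, p_adjs):
        table = pd.DataFrame({
            "delta": deltas, "var_shrunk": 0.01, "t": 1.0, "df": 10,
            "p": p_adjs, "p_adj": p_adjs,
        }, index=[f"cg{i}" for i in range(len(deltas))])
        return ms.DMPStats(table=table, group_a="A", group_b="B", d0=0, s0_sq=0)

    def test_threshold_boundaries(self):
        st_ = self._stats([0.35, 0.29, 0.35], [0.005, 0.005, 0.02])
        called = ms.call_dmps(st_, p_adj_max=0.01, abs_lfc_min=0.3)
        assert called.probe_ids == frozenset({"cg0"})

    def test_tightening_thresholds_gives_subset(self):
        rng = np.random.default_rng(5)
        st_ = self._stats(rng.uniform(-0.6, 0.6, 200), rng.uniform(0, 0.05, 200))
        base = ms.call_dmps(st_, 0.01, 0.3).probe_ids
        assert ms.call_dmps(st_, 0.005, 0.3).probe_ids <= base
        assert ms.call_dmps(st_, 0.01, 0.4).probe_ids <= base


class TestPairwiseCounts:
    def test_two_groups_one_pair(self, small_cohort):
        beta, _, sheet, _, _ = small_cohort
        two = ms.SampleSheet(sheet.data[sheet.data["group_label"].isin(["A", "C"])]
                             .reset_index(drop=True))
        counts = ms.pairwise_dmp_counts(beta, two)
        assert counts.n_pairs == 1

    def test_identically_generated_groups_have_zero_count(self, small_cohort):
        """The planted sibling pair (shared signature) yields zero DMPs."""
        beta, _, sheet, _, _ = small_cohort
        counts = ms.pairwise_dmp_counts(beta, sheet)
        assert counts.count("A", "B") == 0
        assert counts.count("A", "C") > 0

    def test_counts_symmetric_zero_diagonal(self, small_cohort):
        beta, _, sheet, _, _ = small_cohort
        counts = ms.pairwise_dmp_counts(beta, sheet)
        c = counts.counts.to_numpy()
        assert (c == c.T).all()
        assert (np.diag(c) == 0).all()

    def test_invariant_to_sample_order_and_constant_probes(self, small_cohort):
        beta, _, sheet, _, _ = small_cohort
        counts = ms.pairwise_dmp_counts(beta, sheet)
        shuffled = beta.data.sample(frac=1, axis=1, random_state=0)
        const = pd.DataFrame(
            0.5, index=[f"const{i}" for i in range(20)], columns=shuffled.columns
        )
        augmented = pd.concat([shuffled, const])
        counts2 = ms.pairwise_dmp_counts(ms.BetaMatrix(augmented), sheet)
        pd.testing.assert_frame_equal(counts.counts, counts2.counts)

    def test_single_group_rejected(self, small_cohort):
        beta, _, sheet, _, _ = small_cohort
        one = ms.SampleSheet(sheet.data[sheet.data["group_label"] == "A"]
                             .reset_index(drop=True))
        with pytest.raises(ValueError, match="at least 2 groups"):
            ms.pairwise_dmp_counts(beta, one)
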