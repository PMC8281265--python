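"""Modulation depth: closed forms, permutation normalization, screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikemod as sm
from spikemod.errors import DegenerateDataError, ValidationError


def md_unit_oracle(sample, ddof=1):
    """Independent exhaustive enumeration of all (i, j) pairs."""
    fingers = sorted(sample)
    mu = {f: np.mean(sample[f]) for f in fingers}
    var = {f: np.var(sample[f], ddof=ddof) for f in fingers}
    md_i = {}
    for i in fingers:
        best = np.inf
        for j in fingers:
            if j == i:
                continue
            best = min(best, abs(mu[i] - mu[j]) / np.sqrt(var[i] + var[j]))
        md_i[i] = best
    return md_i, float(np.mean(list(md_i.values())))


def _exact_sd1_sample(means):
    """Per-finger triples with exact mean mu and exact sample SD 1."""
    return {f + 1: np.array([m - 1.0, m, m + 1.0]) for f, m in enumerate(means)}


class TestMdPair:
    def test_closed_form(self):
        assert sm.md_pair(5.0, np.sqrt(2), 3.0, np.sqrt(2)) == pytest.approx(1.0)

    def test_equal_means_zero(self):
        assert sm.md_pair(4.0, 1.0, 4.0, 2.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.floats(0, 50), st.floats(0.1, 10), st.floats(0, 50), st.floats(0.1, 10)
    )
    def test_symmetry(self, mi, si, mj, sj):
        assert sm.md_pair(mi, si, mj, sj) == sm.md_pair(mj, sj, mi, si)

    def test_zero_variance_equal_means_zero(self):
        assert sm.md_pair(3.0, 0.0, 3.0, 0.0) == 0.0

    def test_zero_variance_distinct_means_capped(self):
        with pytest.warns(UserWarning, match="capped"):
            value = sm.md_pair(3.0, 0.0, 5.0, 0.0)
        assert value == 1e6


class TestMdUnit:
    def test_staircase_means_closed_form(self):
        # means (10, 8, 6, 4), all sample SD = 1: nearest-neighbour gap is 2,
        # so every MD_i = 2 / sqrt(2) and MD = sqrt(2)
        md_i, md = sm.md_unit(_exact_sd1_sample([10.0, 8.0, 6.0, 4.0]))
        for v in md_i.values():
            assert v == pytest.approx(np.sqrt(2.0))
        assert md == pytest.approx(np.sqrt(2.0))

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            sample = {f: rng.uniform(0, 20, rng.integers(3, 9)) for f in range(1, 5)}
            md_i, md = sm.md_unit(sample)
            oracle_i, oracle = md_unit_oracle(sample)
            assert md == pytest.approx(oracle, rel=1e-12)
            for f in sample:
                assert md_i[f] == pytest.approx(oracle_i[f], rel=1e-12)

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.uniform(0, 10, 6) for _ in range(4)]
        _, md_a = sm.md_unit({f + 1: g for f, g in enumerate(groups)})
        _, md_b = sm.md_unit({f + 1: g for f, g in enumerate(groups[::-1])})
        assert md_a == pytest.approx(md_b)

    def test_no_signal_limit_near_zero(self):
        rng = np.random.default_rng(3)
        sample = {f: 5.0 + 0.01 * rng.standard_normal(50) for f in range(1, 5)}
        _, md = sm.md_unit(sample)
        assert md < 0.3

    def test_single_trial_finger_rejected(self):
        with pytest.raises(DegenerateDataError):
            sm.md_unit({1: np.array([1.0]), 2: np.array([2.0, 3.0])})


class TestMdNormalized:
    def test_identity_permutation_self_normalizes(self):
        rng = np.random.default_rng(4)
        rates = rng.uniform(2, 10, 24)
        fingers = np.repeat([1, 2, 3, 4], 6)
        res = sm.md_normalized(rates, fingers, n_perm=1, seed=0, force_identity=True)
        assert res.md_n == pytest.approx(1.0)

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        rates = rng.uniform(2, 10, 40)
        fingers = np.tile([1, 2, 3, 4], 10)
        a = sm.md_normalized(rates, fingers, n_perm=200, seed=9)
        b = sm.md_normalized(rates, fingers, n_perm=200, seed=9)
        assert a.md_n == b.md_n and a.md_rand == b.md_rand

    def test_untuned_null_centred_near_one(self):
        # small-scale version of the null-calibration invariant
        from spikemod.calibration import mdn_null_calibration
        _, mdn = mdn_null_calibration(n_units=100, trials_per_finger=20,
                                      n_perm=100, seed=6)
        assert 0.85 < mdn < 1.15

    def test_tuned_unit_exceeds_two(self):
        rng = np.random.default_rng(7)
        lam = np.full(80, 7.0 * 3)
        fingers = np.tile([1, 2, 3, 4], 20)
        lam[fingers == 2] *= 3.0  # gain 3 on the preferred finger
        rates = rng.poisson(lam) / 3.0
        res = sm.md_normalized(rates, fingers, n_perm=500, seed=8)
        assert res.md_n > 2.0

    def test_expected_mdn_monotone_in_gain(self):
        # same base noise (common random numbers) across gains; the
        # *expected* MD_N is non-decreasing in the tuning gain
        rng = np.random.default_rng(9)
        fingers = np.tile([1, 2, 3, 4], 15)
        gains = (0.0, 1.0, 2.0, 4.0)
        mdns = np.empty((40, len(gains)))
        for rep in range(40):
            base = rng.standard_normal(60)
            for g, gain in enumerate(gains):
                rates = 10.0 + base + gain * (fingers == 3)
                mdns[rep, g] = sm.md_normalized(rates, fingers, n_perm=100,
                                                seed=rep).md_n
        assert np.all(np.diff(mdns.mean(axis=0)) >= 0)

    def test_too_few_trials_rejected(self):
        with pytest.raises(DegenerateDataError):
            sm.md_normalized(np.arange(5.0), np.array([1, 1, 2, 2, 3]), n_perm=10)


class TestCountModulated:
    def test_strict_threshold(self):
        assert sm.count_modulated(np.array([2.0, 2.0, 2.0])) == 0
        assert sm.count_modulated(np.array([2.0001, 1.0, 5.0])) == 2

    def test_empty_list(self):
        assert sm.count_modulated([]) == 0

    def test_agrees_with_bruteforce(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(0, 4, 200)
        assert sm.count_modulated(vals) == sum(1 for v in vals if v > 2.0)


class TestTuningCurve:
    def test_means_match_bruteforce(self):
        rng = np.random.default_rng(12)
        sample = {f: rng.uniform(0, 20, 8) for f in range(1, 5)}
        tc = sm.tuning_curve(sample).set_index("finger")
        for f, r in sample.items():
            assert tc.loc[f, "mean_hz"] == pytest.approx(r.mean())
            assert tc.loc[f, "sem_hz"] == pytest.approx(r.std(ddof=1) / np.sqrt(8))

    def test_single_trial_warns_sem_zero(self):
        with pytest.warns(UserWarning, match="single trial"):
            tc = sm.tuning_curve({1: np.array([5.0]), 2: np.array([1.0, 2.0])})
        assert tc.set_index("finger").loc[1, "sem_hz"] == 0.0

    def test_constant_rates_zero_sem(self):
        tc = sm.tuning_curve({1: np.full(5, 3.0)})
        assert tc["sem_hz"].iloc[0] == 0.0


class TestAnovaScreen:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(13)
        a, b = rng.uniform(0, 10, 12), rng.uniform(2, 12, 12)
        f_stat, p, _ = sm.anova_screen({1: a, 2: b})
        from scipy import stats
        t, p_t = stats.ttest_ind(a, b)
        assert f_stat == pytest.approx(t**2)
        assert p == pytest.approx(p_t)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(14)
        flags = []
        for _ in range(800):
            sample = {f: rng.standard_normal(8) + 5 for f in range(1, 5)}
            _, _, flag = sm.anova_screen(sample, alpha=0.05)
            flags.append(flag)
        rate = np.mean(flags)
        assert 0.03 < rate < 0.07  # ~alpha by construction

    def test_tuned_unit_flagged(self):
        rng = np.random.default_rng(15)
        sample = {f: rng.poisson(21, 20) / 3.0 for f in range(1, 5)}
        sample[2] = rng.poisson(63, 20) / 3.0  # gain 3
        _, p, flag = sm.anova_screen(sample)
        assert flag and p < 1e-6

    def test_degenerate_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            sm.anova_screen({1: np.full(4, 2.0), 2: np.full(4, 5.0)})


class TestCorrelation:
    def test_exact_linear_r2_one(self):
        pre = np.linspace(2, 10, 20)
        drug = pre * np.linspace(1.0, 2.0, 20)
        x = (drug - pre) / pre
        md_n = 0.5 + 2.0 * x
        r2, p = sm.md_rate_correlation(md_n, pre, drug)
        assert r2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_inputs_small_r2(self):
        rng = np.random.default_rng(16)
        r2s, ps = [], []
        for _ in range(50):
            pre = rng.uniform(2, 10, 100)
            drug = pre * rng.uniform(0.8, 1.8, 100)
            md_n = rng.uniform(0.5, 3.0, 100)
            r2, p = sm.md_rate_correlation(md_n, pre, drug)
            r2s.append(r2)
            ps.append(p)
        assert np.mean(r2s) < 0.05
        # null p-values roughly uniform: about half below 0.5
        assert 0.3 < np.mean(np.asarray(ps) < 0.5) < 0.7

    def test_constant_predictor_rejected(self):
        pre = np.full(10, 4.0)
        with pytest.raises(DegenerateDataError):
            sm.md_rate_correlation(np.arange(10.0), pre, pre * 1.5)

    def test_zero_pre_rate_excluded_with_warning(self):
        pre = np.array([0.0, 2.0, 4.0, 6.0, 8.0])
        drug = pre * 1.5 + 1.0
        with pytest.warns(UserWarning, match="zero pre-drug"):
            sm.md_rate_correlation(np.array([1.0, 1.2, 1.4, 1.1, 0.9]), pre, drug)


class TestFisher:
    def test_identical_proportions_p_one(self):
        assert sm.fisher_modulated_counts(5, 10, 5, 10) == pytest.approx(1.0)

    def test_swap_symmetry(self):
        assert sm.fisher_modulated_counts(3, 12, 9, 14) == pytest.approx(
            sm.fisher_modulated_counts(9, 14, 3, 12)
        )

    def test_extreme_table_matches_enumeration_oracle(self):
        # exhaustive hypergeometric enumeration of tables with the same margins
        from math import comb
        k1, n1, k2, n2 = 10, 10, 0, 10
        total_k = k1 + k2
        denom = comb(n1 + n2, total_k)
        probs = {a: comb(n1, a) * comb(n2, total_k - a) / denom
                 for a in range(max(0, total_k - n2), min(n1, total_k) + 1)}
        p_obs = probs[k1]
        oracle = sum(p for p in probs.values() if p <= p_obs + 1e-12)
        assert sm.fisher_modulated_counts(k1, n1, k2, n2) == pytest.approx(oracle)
        assert oracle < 0.001

    def test_invalid_table_rejected(self):
        with pytest.raises(ValidationError):
            sm.fisher_modulated_counts(5, 3, 1, 10)
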