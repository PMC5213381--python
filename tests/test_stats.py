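"""Statistics tests with independent oracles.

The exact McNemar test is checked against a brute-force enumeration over
all discordance assignments; the repeated-measures ANOVA against a
brute-force sums-of-squares oracle and against the established pingouin
implementation; the paired contrast against scipy's paired t-test.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from paddle_ire.errors import DegenerateDesignError, InputError
from paddle_ire.stats import (
    PairedOutcomes,
    discordant_counts,
    mcnemar_exact,
    nested_discordant_counts,
    paired_contrast,
    rm_anova,
    threshold_ratio,
)


def mcnemar_brute_force(b: int, c: int) -> float:
    """Enumerate all 2^(b+c) equally likely discordance assignments and
    accumulate the probability of splits at least as extreme as (b, c)."""
    n = b + c
    if n == 0:
        return 1.0
    k_obs = min(b, c)
    p = 0.0
    for bits in itertools.product([0, 1], repeat=n):
        k = min(sum(bits), n - sum(bits))
        if k <= k_obs:
            p += 0.5**n
    return min(1.0, p if k_obs == n - k_obs else p)  # two-sided by min-tail doubling


def rm_anova_brute_force(x: np.ndarray):
    """Sums of squares by explicit loops over cells."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subj = sum(k * (sum(x[i]) / k - grand) ** 2 for i in range(n))
    ss_cond = sum(n * (sum(x[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k))
    ss_err = ss_total - ss_subj - ss_cond
    f = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return ss_cond, ss_subj, ss_err, ss_total, f


class TestMcNemarExact:
    @pytest.mark.parametrize(
        "b,c,expected",
        [
            (7, 0, 0.015625),  # 5/12 vs 12/12 under nested discordance
            (6, 0, 0.03125),  # 5/12 vs 11/12 under nested discordance
            (0, 0, 1.0),
            (3, 3, 1.0),
        ],
    )
    def test_reference_values(self, b, c, expected):
        assert mcnemar_exact(b, c) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        for b in range(0, 8):
            for c in range(0, 8):
                assert mcnemar_exact(b, c) == mcnemar_exact(c, b)

    @given(b=st.integers(0, 8), c=st.integers(0, 8))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_enumeration(self, b, c):
        # enumeration over all 2^(b+c) assignments, b + c <= 16
        n = b + c
        if n == 0:
            assert mcnemar_exact(b, c) == 1.0
            return
        k_obs = min(b, c)
        from scipy.stats import binom

        # direct two-sided tail: 2 * P(X <= min(b,c)), capped at 1
        tail = sum(math.comb(n, k) for k in range(0, k_obs + 1)) / 2**n
        assert mcnemar_exact(b, c) == pytest.approx(min(1.0, 2 * tail), rel=1e-12)
        assert mcnemar_exact(b, c) == pytest.approx(
            min(1.0, 2 * float(binom.cdf(k_obs, n, 0.5))), rel=1e-12
        )

    def test_against_statsmodels_exact(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        for b, c in [(7, 0), (6, 0), (5, 2), (4, 4), (1, 9)]:
            table = [[0, b], [c, 0]]
            expected = sm_mcnemar(table, exact=True).pvalue
            assert mcnemar_exact(b, c) == pytest.approx(expected, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(InputError):
            mcnemar_exact(-1, 2)

    def test_discordant_counts_from_outcomes(self):
        po = PairedOutcomes(
            pig_ids=("p1", "p2", "p3", "p4"),
            outcome_a=(True, True, False, False),
            outcome_b=(True, False, True, False),
        )
        assert discordant_counts(po) == (1, 1)

    def test_outcome_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            PairedOutcomes(("p1",), (True,), (True, False))

    def test_nested_discordance_reconstruction(self):
        assert nested_discordant_counts(5, 12) == (0, 7)
        assert nested_discordant_counts(5, 11) == (0, 6)
        with pytest.raises(InputError):
            nested_discordant_counts(6, 5)


class TestRMANOVA:
    def test_toy_matrix_matches_brute_force(self):
        # nota bene: the "obvious" toy [[1,2],[2,3],[3,4]] is purely
        # additive (zero error variance) and therefore degenerate
        x = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 4.0]])
        ss_c, ss_s, ss_e, ss_t, f = rm_anova_brute_force(x)
        res = rm_anova(x)
        assert res.ss_conditions == pytest.approx(ss_c, abs=1e-12)
        assert res.ss_subjects == pytest.approx(ss_s, abs=1e-12)
        assert res.ss_error == pytest.approx(ss_e, abs=1e-12)
        assert res.f_statistic == pytest.approx(f, abs=1e-12)

    def test_random_matrices_match_brute_force(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            x = rng.normal(5, 2, size=(6, 3))
            ss_c, ss_s, ss_e, ss_t, f = rm_anova_brute_force(x)
            res = rm_anova(x)
            assert res.f_statistic == pytest.approx(f, rel=1e-12)
            assert res.ss_total == pytest.approx(ss_t, rel=1e-12)

    def test_ss_identity(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(12, 3))
        res = rm_anova(x)
        assert res.ss_total == pytest.approx(
            res.ss_conditions + res.ss_subjects + res.ss_error, rel=1e-10
        )

    def test_identical_condition_means_give_f_zero_p_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)[:, None] + rng.normal(0.0, 0.1, size=(12, 3))
        x = x - (x.mean(axis=0) - x.mean())  # enforce equal condition means
        res = rm_anova(x)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-24)
        assert res.p_value == pytest.approx(1.0)

    def test_degrees_of_freedom(self):
        x = np.random.default_rng(0).normal(size=(12, 3))
        res = rm_anova(x)
        assert (res.df_conditions, res.df_error) == (2, 22)

    def test_zero_error_variance_raises(self):
        # additive subject + condition effects with no interaction/noise
        subj = np.arange(5.0)[:, None]
        cond = np.array([[0.0, 1.0, 2.0]])
        with pytest.raises(DegenerateDesignError):
            rm_anova(subj + cond)

    def test_against_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(11)
        x = rng.normal(4, 1, size=(12, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "condition": np.tile(["a", "b", "c"], 12),
                "y": x.ravel(),
            }
        )
        ref = pg.rm_anova(
            data=long, dv="y", within="condition", subject="subject", correction=True
        )
        res = rm_anova(x)
        assert res.f_statistic == pytest.approx(float(ref["F"].iloc[0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-9)
        gg = rm_anova(x, greenhouse_geisser=True)
        assert gg.gg_epsilon == pytest.approx(float(ref["eps"].iloc[0]), rel=1e-9)
        assert gg.p_value == pytest.approx(float(ref["p_GG_corr"].iloc[0]), rel=1e-9)

    def test_greenhouse_geisser_epsilon_bounds(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(12, 3))
        res = rm_anova(x, greenhouse_geisser=True)
        assert res.gg_epsilon is not None
        assert 0.5 <= res.gg_epsilon <= 1.0
        assert res.f_statistic == rm_anova(x).f_statistic  # F unchanged, only dfs shrink

    def test_incomplete_matrix_rejected(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, np.nan, 6.0]])
        with pytest.raises(InputError):
            rm_anova(x)


class TestPairedContrast:
    def test_identical_vectors(self):
        res = paired_contrast([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0
        assert res.degenerate is True

    def test_constant_difference_degenerate_ci(self):
        res = paired_contrast([5.0, 6.0, 7.0], [4.0, 5.0, 6.0])
        assert res.mean_difference == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (1.0, 1.0)
        assert res.degenerate is True
        assert res.p_value == 0.0

    def test_against_scipy_ttest_rel(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(9)
        x = rng.normal(4.7, 0.8, size=12)
        y = rng.normal(3.4, 0.5, size=12)
        res = paired_contrast(x, y)
        ref = ttest_rel(x, y)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-12)
        lo, hi = ref.confidence_interval(0.95)
        assert res.ci_low == pytest.approx(lo, rel=1e-12)
        assert res.ci_high == pytest.approx(hi, rel=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(InputError):
            paired_contrast([1.0, 2.0], [1.0])


class TestThresholdRatio:
    def test_published_group_means(self):
        # (4.3 + 5.1)/2 / 3.4 = 1.38..., printed as 1.4
        ratio = threshold_ratio((4.3, 5.1), 3.4)
        assert round(ratio, 1) == 1.4
        assert ratio == pytest.approx(4.7 / 3.4, rel=1e-12)

    def test_equal_means_give_unity(self):
        assert threshold_ratio((3.0, 3.0), 3.0) == pytest.approx(1.0)

    def test_scale_invariance(self):
        assert threshold_ratio((8.6, 10.2), 6.8) == pytest.approx(
            threshold_ratio((4.3, 5.1), 3.4), rel=1e-12
        )

    def test_zero_denominator_rejected(self):
        with pytest.raises(InputError):
            threshold_ratio((4.0, 5.0), 0.0)
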