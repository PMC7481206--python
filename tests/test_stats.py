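"""Association-layer statistics against hand-computed oracles and
null-calibration simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adchist import (
    CohortSpec,
    ValidationError,
    group_ttest,
    km_logrank,
    make_cohort,
    median_split,
    pearson,
    run_association_suite,
    zscore_within,
)


def hand_pearson(x, y):
    """Direct covariance-formula oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    cx, cy = x - x.mean(), y - y.mean()
    return float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))


def hand_pooled_t(a, b):
    """Pooled-variance Student's t oracle."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    return float((a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb)))


def hand_logrank(times_a, times_b):
    """Hand-tabulated observed-minus-expected log-rank (no censoring)."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    o_a = e_a = v = 0.0
    for t in np.unique(np.concatenate([times_a, times_b])):
        na, nb = (times_a >= t).sum(), (times_b >= t).sum()
        d = (times_a == t).sum() + (times_b == t).sum()
        n = na + nb
        o_a += (times_a == t).sum()
        e_a += d * na / n
        if n > 1:
            v += d * (n - d) * na * nb / (n**2 * (n - 1))
    return (o_a - e_a) ** 2 / v


class TestPearson:
    def test_exact_linearity(self):
        x = np.arange(10.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0) and res.r_squared == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        x, y = [1, 2, 3, 4], [2, 1, 4, 3]
        assert pearson(x, y).r == pytest.approx(hand_pearson(x, y), abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_null_p_values_calibrated(self):
        rng = np.random.default_rng(0)
        n_rep = 500
        hits = sum(
            pearson(rng.normal(size=200), rng.normal(size=200)).p_two_sided < 0.05
            for _ in range(n_rep)
        )
        assert 0.03 <= hits / n_rep <= 0.07


class TestTTest:
    def test_unpaired_matches_pooled_formula(self):
        a, b = [1, 2, 3], [4, 5, 6]
        t, _ = group_ttest(a, b)
        assert t == pytest.approx(hand_pooled_t(a, b), abs=1e-12)

    def test_identical_paired_samples_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            group_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], paired=True)

    def test_paired_detects_constant_shift(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=20)
        t, p = group_ttest(a + 1.0 + rng.normal(0, 0.1, 20), a, paired=True)
        assert t > 0 and p < 1e-6

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(2)
        n_rep = 500
        hits = sum(
            group_ttest(rng.normal(size=30), rng.normal(size=30))[1] < 0.05
            for _ in range(n_rep)
        )
        assert 0.03 <= hits / n_rep <= 0.07


class TestZscore:
    def test_two_member_group_convention(self):
        out = zscore_within([1.0, 3.0], ["a", "a"])
        np.testing.assert_allclose(out, [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_group_means_are_zero(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        out = zscore_within(vals, groups)
        for g in "abc":
            assert abs(out[groups == g].mean()) < 1e-12
            assert out[groups == g].std(ddof=1) == pytest.approx(1.0)

    def test_order_invariance(self):
        vals = np.array([1.0, 5.0, 2.0, 7.0, 3.0, 6.0])
        groups = np.array(["a", "b", "a", "b", "a", "b"])
        perm = np.array([3, 0, 4, 1, 5, 2])
        out = zscore_within(vals, groups)
        out_perm = zscore_within(vals[perm], groups[perm])
        np.testing.assert_allclose(out[perm], out_perm)

    def test_error_names_offending_group(self):
        with pytest.raises(ValidationError, match="solo"):
            zscore_within([1.0, 2.0, 3.0], ["a", "a", "solo"])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=20, unique=True))
    def test_idempotent(self, vals):
        groups = ["g"] * len(vals)
        once = zscore_within(vals, groups)
        twice = zscore_within(once, groups)
        np.testing.assert_allclose(once, twice, atol=1e-9)


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 2, 3, 4], ["low", "low", "high", "high"]),
            ([1, 2, 3], ["low", "low", "high"]),
            ([5, 5, 5, 5], ["low", "low", "low", "low"]),
        ],
    )
    def test_conventions(self, values, expected):
        assert median_split(values) == expected


class TestKmLogrank:
    @staticmethod
    def _table(times_a, times_b, events_a=None, events_b=None):
        na, nb = len(times_a), len(times_b)
        return pd.DataFrame(
            {
                "group": ["high"] * na + ["low"] * nb,
                "surv_months": list(times_a) + list(times_b),
                "event": (events_a or [1] * na) + (events_b or [1] * nb),
            }
        )

    def test_identical_groups_give_chi2_zero(self):
        res = km_logrank(self._table([1, 2, 3], [1, 2, 3]), "group")
        assert res.logrank_chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_tabulated_oracle(self):
        a, b = [1, 2, 3], [4, 5, 6]
        res = km_logrank(self._table(a, b), "group")
        assert res.logrank_chi2 == pytest.approx(hand_logrank(a, b), rel=1e-9)

    def test_median_is_first_time_survival_at_half(self):
        res = km_logrank(self._table([1, 2, 3, 4], [10, 20, 30, 40]), "group")
        assert res.median_high == 2  # S(2) = 0.5 with four events
        assert res.median_low == 20

    def test_undefined_median_serialized_as_none(self):
        res = km_logrank(
            self._table([1, 2, 3], [5, 6, 7], events_b=[1, 0, 0]), "group"
        )
        assert res.median_low is None

    def test_time_unit_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        t = self._table(rng.exponential(10, 30), rng.exponential(5, 30))
        months = km_logrank(t, "group")
        t_days = t.assign(surv_months=t.surv_months * 30.44)
        days = km_logrank(t_days, "group")
        assert months.logrank_chi2 == pytest.approx(days.logrank_chi2)

    def test_single_group_rejected(self):
        t = self._table([1, 2], [3, 4]).assign(group="high")
        with pytest.raises(ValidationError):
            km_logrank(t, "group")

    def test_power_against_planted_hazard_ratio(self):
        """Hazard ratio 2 at n=400 should be detected in the typical run."""
        ps = []
        for seed in range(200):
            table, _ = make_cohort(
                CohortSpec(
                    n_subjects=400,
                    median_surv_high=12.0,
                    median_surv_low=6.0,
                    censor_prob=0.0,
                    seed=seed,
                )
            )
            ps.append(km_logrank(table, "phenotype").p)
        assert np.median(ps) < 0.05


class TestAssociationSuite:
    def test_noiseless_cohort_recovers_planted_signal(self):
        table, _ = make_cohort(CohortSpec(n_subjects=60, expr_noise_sd=0.0, seed=6))
        report = run_association_suite(table)
        assert report["expression_vs_adcl"]["r_squared"] == pytest.approx(1.0, abs=1e-9)
        assert report["expression_by_phenotype"]["p"] < 1e-6

    def test_intratumoral_branch_runs_on_site_tables(self):
        rng = np.random.default_rng(7)
        rows = []
        for tumor in range(6):
            base = rng.uniform(0.6, 1.8)
            for site in range(4):
                adcl = base + rng.normal(0, 0.2)
                rows.append(
                    dict(
                        subject_id=f"T{tumor}S{site}",
                        tumor_id=f"T{tumor}",
                        adcl_true=max(adcl, 0.1),
                        expression=2 * adcl + rng.normal(0, 0.1),
                    )
                )
        report = run_association_suite(pd.DataFrame(rows))
        intra = report["intratumoral"]
        assert intra["zscore_correlation"]["r"] > 0.5
        assert intra["paired_high_vs_low_sites"]["t"] > 0
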