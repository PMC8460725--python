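"""Binding statistics: exclusion rule, t tests, effect sizes, estimates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from clockbind import (
    binding_estimates,
    build_summaries,
    cohen_ds,
    cohen_dz,
    cohort_binding_report,
    mad_median_outliers,
    mad_median_screen,
    paired_t,
    simulate_cohort,
    unpaired_t,
)
from clockbind.binding_stats import ZeroVarianceError

from conftest import noise_free_config


class TestMadMedianRule:
    def test_hand_example_flags_only_extreme(self):
        # P = [0, 10, 20, 30, 1000]: median 20, MAD 10;
        # |1000-20|*0.6745 = 661.01 > 30, |0-20|*0.6745 = 13.49 <= 30
        flags = mad_median_outliers([0, 10, 20, 30, 1000])
        assert list(flags) == [False, False, False, False, True]

    def test_identical_values_unflagged(self):
        assert not mad_median_outliers([5.0] * 6).any()

    def test_degenerate_mad_flags_off_median_with_warning(self):
        with pytest.warns(RuntimeWarning, match="MAD-median is zero"):
            flags = mad_median_outliers([5.0, 5.0, 5.0, 9.0])
        assert list(flags) == [False, False, False, True]

    @given(
        shift=st.integers(-100_000, 100_000),
        values=st.lists(st.integers(-1000, 1000), min_size=3, max_size=20),
    )
    def test_translation_invariance(self, shift, values):
        # integer-valued floats keep the shift exact in binary
        v = np.asarray(values, float)
        if np.median(np.abs(v - np.median(v))) == 0:
            return  # degenerate branch warns; covered above
        np.testing.assert_array_equal(
            mad_median_outliers(v), mad_median_outliers(v + float(shift))
        )

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            mad_median_outliers([1.0, 2.0])


class TestEffectSizes:
    def test_dz_zero_stat(self):
        assert cohen_dz(0.0, 17) == 0.0

    def test_ds_closed_form_and_symmetry(self):
        assert cohen_ds(1.0, 8, 8) == pytest.approx(np.sqrt(2 / 8))
        assert cohen_ds(2.2, 10, 30) == pytest.approx(cohen_ds(2.2, 30, 10))

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ValueError):
            cohen_dz(1.0, 0)
        with pytest.raises(ValueError):
            cohen_ds(1.0, 0, 5)


class TestTTests:
    def test_paired_hand_computation(self):
        # differences [1, 2, 3]: mean 2, sd 1 -> t = 2/(1/sqrt(3)) = 3.4641
        res = paired_t([1, 2, 3], [0, 0, 0])
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2

    def test_paired_zero_variance_is_error(self):
        with pytest.raises(ZeroVarianceError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_paired_sign_flip_antisymmetry(self):
        x, y = [1.0, 2.5, 3.0], [0.5, 1.0, 4.0]
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t)

    def test_unpaired_hand_computation(self):
        # pooled sd 1 -> t = (2-5)/sqrt(1*(2/3)) = -3.6742, df 4
        res = unpaired_t([1, 2, 3], [4, 5, 6])
        assert res.t == pytest.approx(-3.6742, abs=1e-4)
        assert res.df == 4

    def test_unpaired_identical_samples_t_zero(self):
        res = unpaired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_unpaired_translation_invariance(self):
        x = np.array([1.0, 4.0, 2.0])
        y = np.array([3.0, 3.5, 5.0, 6.0])
        a = unpaired_t(x, y)
        b = unpaired_t(x + 100.0, y + 100.0)
        assert a.t == pytest.approx(b.t)
        assert a.p == pytest.approx(b.p)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_agreement_with_scipy_oracle(self, alternative):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 14), rng.normal(0.4, 1.3, 11)
        mine = unpaired_t(x, y, alternative)
        ref = stats.ttest_ind(x, y, alternative=alternative)
        assert mine.t == pytest.approx(float(ref.statistic))
        assert mine.p == pytest.approx(float(ref.pvalue))
        mine = paired_t(x[:11], y, alternative)
        ref = stats.ttest_rel(x[:11], y, alternative=alternative)
        assert mine.t == pytest.approx(float(ref.statistic))
        assert mine.p == pytest.approx(float(ref.pvalue))

    def test_dz_from_paired_t_round_trip(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 1, 20), rng.normal(0, 1, 20)
        res = paired_t(x, y)
        d = x - y
        assert cohen_dz(res.t, 20) == pytest.approx(
            np.mean(d) / np.std(d, ddof=1)
        )


class TestBindingEstimates:
    def test_hand_medians(self):
        from clockbind.trial_prep import ParticipantSummary

        s = ParticipantSummary(
            "P1",
            "AO-AS",
            {"AO": np.array([0.0, 0, 0, 0]), "AS": np.array([10.0, 10, 20, 20])},
            {"AO": 0.0, "AS": 15.0},
            {},
            {},
        )
        est = binding_estimates([s], n_drop=0)
        assert est.loc[0, "binding_ms"] == 15.0

    def test_noise_free_binding_is_exact_for_any_drop(self):
        cfg = noise_free_config(n_per_group=3, binding_mean=23.0)
        trials, _, _ = simulate_cohort(cfg)
        summaries = build_summaries(trials)
        for n_drop in (0, 5, 17):
            est = binding_estimates(summaries, n_drop=n_drop)
            np.testing.assert_allclose(est["binding_ms"], 23.0, atol=1e-9)
            # zero trial variance: the per-participant t is undefined
            assert est["binding_t"].isna().all()

    def test_drop_exhausting_series_is_error(self, default_cohort):
        *_, summaries = default_cohort
        with pytest.raises(ValueError):
            binding_estimates(summaries, n_drop=40)

    def test_binding_t_and_ms_agree_in_sign(self, default_cohort):
        *_, summaries = default_cohort
        est = binding_estimates(summaries, n_drop=10)
        strong = est[est["binding_ms"].abs() > 5]
        assert (np.sign(strong["binding_t"]) == np.sign(strong["binding_ms"])).mean() > 0.9


class TestCohortPipeline:
    def test_screen_flags_planted_extreme_participant(self, default_cohort):
        *_, summaries = default_cohort
        screen = mad_median_screen(summaries)
        assert not screen["flagged"].iloc[0]
        base_flagged = int(screen["flagged"].sum())
        import copy

        bent = copy.deepcopy(summaries)
        bent[0].medians["AO"] += 500.0
        bent[0].medians["AS"] += 500.0
        screen = mad_median_screen(bent)
        assert screen["flagged"].iloc[0]
        assert screen["flagged"].sum() <= base_flagged + 1

    def test_report_structure_and_binding_direction(self, default_cohort):
        *_, summaries = default_cohort
        est = binding_estimates(summaries, n_drop=0)
        rep = cohort_binding_report(est, summaries)
        ws = rep["whole_sample"]
        assert ws["AS"]["mean"] > ws["AO"]["mean"]  # binding shifts AS later
        assert ws["as_vs_ao"]["p"] < 0.01
        assert ws["AS"]["ci_low"] < ws["AS"]["mean"] < ws["AS"]["ci_high"]
        assert rep["order_contrast"]["df"] == len(est) - 2

    def test_small_group_is_error(self):
        from clockbind import SimulationConfig

        cfg = SimulationConfig(n_per_group=1, seed=3)
        trials, _, _ = simulate_cohort(cfg)
        summaries = build_summaries(trials)
        est = binding_estimates(summaries, n_drop=0)
        with pytest.raises(ValueError, match="fewer than 2"):
            cohort_binding_report(est, summaries)
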