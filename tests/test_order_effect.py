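"""Trial-by-trial drift and the leave-first-n-out order-effect scan."""

import math

import numpy as np
import pytest

from clockbind import (
    SimulationConfig,
    binding_estimates,
    build_summaries,
    cohort_binding_report,
    cutoff_from_scan,
    leave_first_n_scan,
    simulate_cohort,
    slope_group_tests,
    trial_slope,
)
from clockbind.order_effect import OrderScanResult, condition_slopes
from clockbind.trial_prep import ParticipantSummary

from conftest import noise_free_config

import pandas as pd


def make_summary(pid, group, ao, as_):
    ao = np.asarray(ao, float)
    as_ = np.asarray(as_, float)
    return ParticipantSummary(
        pid,
        group,
        {"AO": ao, "AS": as_},
        {"AO": float(np.median(ao)), "AS": float(np.median(as_))},
        {},
        {},
    )


class TestTrialSlope:
    def test_hand_computation(self):
        res = trial_slope([2.0, 4.0, 6.0])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(0.0)

    def test_constant_series_zero_slope(self):
        assert trial_slope([5.0] * 8).slope == pytest.approx(0.0)

    def test_index_reversal_negates_slope(self):
        y = [1.0, 3.0, 2.0, 7.0, 4.0]
        assert trial_slope(y[::-1]).slope == pytest.approx(-trial_slope(y).slope)

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(0, 5, 25)
        res = trial_slope(y)
        coef = np.polyfit(np.arange(1, 26), y, 1)
        assert res.slope == pytest.approx(coef[0])

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            trial_slope([1.0])


class TestSlopeGroupTests:
    def test_carryover_signs_over_seeds(self):
        """AS->AO carryover alone makes the AO condition trend down when
        tested second and not when tested first; adding the default common
        drift, the AO slope contrast (first minus second) stays positive."""
        pure_first, pure_second, contrast = [], [], []
        for seed in range(40):
            cfg = SimulationConfig(seed=seed, drift_slope=0.0)
            trials, _, _ = simulate_cohort(cfg)
            slopes = condition_slopes(build_summaries(trials))
            ao = slopes[slopes["condition"] == "AO"]
            pure_first.append(ao.loc[ao["order_group"] == "AO-AS", "slope"].mean())
            pure_second.append(ao.loc[ao["order_group"] == "AS-AO", "slope"].mean())
            cfg = SimulationConfig(seed=seed)  # drift back on
            trials, _, _ = simulate_cohort(cfg)
            slopes = condition_slopes(build_summaries(trials))
            ao = slopes[slopes["condition"] == "AO"]
            contrast.append(
                ao.loc[ao["order_group"] == "AO-AS", "slope"].mean()
                - ao.loc[ao["order_group"] == "AS-AO", "slope"].mean()
            )
        assert np.mean(pure_second) < 0
        assert abs(np.mean(pure_first)) < abs(np.mean(pure_second))
        assert np.mean(contrast) > 0

    def test_report_structure(self, default_cohort):
        *_, summaries = default_cohort
        rep = slope_group_tests(condition_slopes(summaries))
        assert set(rep["group_contrast"]) == {"AO", "AS"}
        assert rep["one_sample"]["AO/AO-AS"]["df"] == 25
        # the AO slope contrast carries the order effect
        assert rep["group_contrast"]["AO"]["t"] > 0


class TestLeaveFirstNScan:
    def test_row_zero_matches_base_order_contrast(self, default_cohort):
        *_, summaries = default_cohort
        est = binding_estimates(summaries, n_drop=0)
        rep = cohort_binding_report(est, summaries)
        scan = leave_first_n_scan(summaries, n_max=5)
        row0 = scan.table.iloc[0]
        assert row0["t"] == pytest.approx(rep["order_contrast"]["t"])
        assert row0["p"] == pytest.approx(rep["order_contrast"]["p"])
        assert row0["mean_ao_first"] == pytest.approx(
            rep["order_contrast"]["mean_binding_ao_first"]
        )

    def test_noise_free_gap_decays_geometrically(self):
        """Noise-free carryover tau=3: the trial-level group gap contracts by
        exactly exp(-1/3) per 'at-12' trial, and the scan's mean-binding gap
        by exactly exp(-1/3) per TWO dropped trials (the median's window
        midpoint advances half an index per dropped trial)."""
        cfg = noise_free_config(
            binding_mean=23.0,
            baseline_shift_sd=0.0,
            carryover_into_ao=1.0,
            carryover_tau=3.0,
            seed=5,
        )
        trials, _, _ = simulate_cohort(cfg)
        summaries = build_summaries(trials)
        # trial-level gap: AO perceived time, AS-first minus AO-first group
        ao_first = np.mean(
            [s.series["AO"] for s in summaries if s.order_group == "AO-AS"], axis=0
        )
        as_first = np.mean(
            [s.series["AO"] for s in summaries if s.order_group == "AS-AO"], axis=0
        )
        gap_k = as_first - ao_first  # = 23 * exp(-k/3)
        ratios = gap_k[1:] / gap_k[:-1]
        np.testing.assert_allclose(ratios, math.exp(-1.0 / 3.0), rtol=1e-6)
        assert gap_k[0] == pytest.approx(23.0)

        scan = leave_first_n_scan(summaries, n_max=24)
        gap_n = (scan.table["mean_ao_first"] - scan.table["mean_as_first"]).to_numpy()
        two_step = gap_n[2:] / gap_n[:-2]
        np.testing.assert_allclose(two_step, math.exp(-1.0 / 3.0), rtol=1e-6)
        assert np.all(np.diff(gap_n) < 0)  # monotone shrinkage

    def test_mirrored_groups_give_exact_zero_t(self):
        summaries = [
            make_summary("A1", "AO-AS", [0, 0, 0], [10, 10, 10]),
            make_summary("A2", "AO-AS", [5, 5, 5], [25, 25, 25]),
            make_summary("B1", "AS-AO", [1, 1, 1], [11, 11, 11]),
            make_summary("B2", "AS-AO", [7, 7, 7], [27, 27, 27]),
        ]
        scan = leave_first_n_scan(summaries, n_max=2)
        np.testing.assert_allclose(scan.table["t"], 0.0, atol=1e-12)

    def test_n_max_beyond_series_is_error(self, default_cohort):
        *_, summaries = default_cohort
        with pytest.raises(ValueError):
            leave_first_n_scan(summaries, n_max=40)

    def test_single_trial_row_is_allowed(self, default_cohort):
        *_, summaries = default_cohort
        scan = leave_first_n_scan(summaries, n_max=39)
        assert len(scan.table) == 40
        assert np.isfinite(scan.table["t"]).all()


class TestCutoff:
    def _scan(self, pvals):
        tab = pd.DataFrame(
            {
                "n": range(len(pvals)),
                "mean_ao_first": 0.0,
                "se_ao_first": 1.0,
                "mean_as_first": 0.0,
                "se_as_first": 1.0,
                "t": 0.0,
                "df": 10,
                "p": pvals,
            }
        )
        return OrderScanResult(tab, n_max=len(pvals) - 1)

    def test_first_stable_exceedance(self):
        pvals = [0.01, 0.03] + [0.2, 0.3, 0.4] + [0.5] * 10
        assert cutoff_from_scan(self._scan(pvals), horizon=14) == 2

    def test_all_above_alpha_gives_zero(self):
        assert cutoff_from_scan(self._scan([0.3] * 8), horizon=7) == 0

    def test_late_dip_pushes_cutoff_past_it(self):
        pvals = [0.2] * 5 + [0.04] + [0.6] * 6
        assert cutoff_from_scan(self._scan(pvals), horizon=11) == 6

    def test_never_stable_gives_none(self):
        pvals = [0.2, 0.01] * 5
        assert cutoff_from_scan(self._scan(pvals), horizon=9) is None

    def test_horizon_beyond_scan_is_error(self):
        with pytest.raises(ValueError):
            cutoff_from_scan(self._scan([0.5] * 3), horizon=10)

    def test_empty_scan_is_error(self):
        with pytest.raises(ValueError):
            cutoff_from_scan(OrderScanResult(pd.DataFrame(), n_max=0), horizon=0)
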