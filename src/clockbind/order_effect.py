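"""Testing-order diagnostics: trial-by-trial drift and the leave-first-n scan.

Two complementary views of carryover between conditions:

* per participant x condition, the least-squares slope of perceived press
  time over 'at-12' trial index — a condition tested second inherits the
  previous condition's subjective shift for its first few trials, which the
  slope picks up as a transient trend;
* the leave-first-n-out scan — the between-order-group binding contrast is
  recomputed after dropping the first n 'at-12' trials of each condition,
  n = 0, 1, 2, ...; the cut-off n* is the smallest n from which the contrast
  stays non-significant through a stability horizon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .binding_stats import ZeroVarianceError, cohen_ds, cohen_dz, unpaired_t
from .trial_prep import ParticipantSummary


@dataclass(frozen=True)
class SlopeResult:
    participant_id: str | None
    condition: str | None
    slope: float      # ms per 'at-12' trial
    intercept: float  # ms, at index 0
    n_trials: int


@dataclass
class OrderScanResult:
    """One row per n: per-group mean binding/SE and the between-group test."""

    table: pd.DataFrame  # columns n, mean_ao_first, se_ao_first, mean_as_first,
    #                      se_as_first, t, df, p
    n_max: int
    stop_reason: str | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def trial_slope(
    series,
    indices=None,
    participant_id: str | None = None,
    condition: str | None = None,
) -> SlopeResult:
    """OLS slope of a perceived-time series over its 'at-12' index (1-based)."""
    y = np.asarray(series, float)
    if y.ndim != 1 or len(y) < 2:
        raise ValueError("need at least 2 trials for a slope")
    x = np.arange(1, len(y) + 1, dtype=float) if indices is None else np.asarray(indices, float)
    if len(x) != len(y):
        raise ValueError("indices and series lengths differ")
    if np.all(x == x[0]):
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    return SlopeResult(participant_id, condition, float(fit.slope), float(fit.intercept), len(y))


def condition_slopes(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    """Per participant x condition slopes, tidy."""
    rows = []
    for s in summaries:
        for cond, series in s.series.items():
            res = trial_slope(series, participant_id=s.participant_id, condition=cond)
            rows.append(
                {
                    "participant_id": s.participant_id,
                    "order_group": s.order_group,
                    "condition": cond,
                    "slope": res.slope,
                    "intercept": res.intercept,
                    "n_trials": res.n_trials,
                }
            )
    return pd.DataFrame(rows)


def slope_group_tests(slopes: pd.DataFrame) -> dict:
    """Slopes against zero per condition x group (two-tailed, with dz) and the
    between-group slope contrast per condition (two-tailed, with ds)."""
    report: dict = {"one_sample": {}, "group_contrast": {}}
    for cond in ("AO", "AS"):
        for grp in ("AO-AS", "AS-AO"):
            vals = slopes.loc[
                (slopes["condition"] == cond) & (slopes["order_group"] == grp), "slope"
            ].to_numpy()
            if len(vals) < 2:
                raise ValueError(f"fewer than 2 slopes for {cond}/{grp}")
            res = stats.ttest_1samp(vals, 0.0, alternative="two-sided")
            report["one_sample"][f"{cond}/{grp}"] = {
                "mean_slope": float(np.mean(vals)),
                "t": float(res.statistic),
                "df": len(vals) - 1,
                "p": float(res.pvalue),
                "dz": cohen_dz(float(res.statistic), len(vals)),
            }
        x = slopes.loc[
            (slopes["condition"] == cond) & (slopes["order_group"] == "AO-AS"), "slope"
        ].to_numpy()
        y = slopes.loc[
            (slopes["condition"] == cond) & (slopes["order_group"] == "AS-AO"), "slope"
        ].to_numpy()
        res = unpaired_t(x, y, "two-sided")
        report["group_contrast"][cond] = {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "ds": cohen_ds(res.t, len(x), len(y)),
        }
    return report


def leave_first_n_scan(
    summaries: Sequence[ParticipantSummary], n_max: int | None = None
) -> OrderScanResult:
    """Recompute the order contrast for n dropped leading trials, n = 0..n_max.

    Binding per participant is the difference of truncated-series medians
    (down to single-trial series at the largest n).  The scan stops early,
    recording why, if some participant runs out of trials or a group
    degenerates, rather than silently unbalancing the groups.
    """
    if not summaries:
        raise ValueError("no summaries to scan")
    min_len = min(len(s.series[c]) for s in summaries for c in ("AO", "AS"))
    if n_max is None:
        n_max = min_len - 1
    if n_max > min_len - 1:
        raise ValueError(
            f"n_max={n_max} leaves no trials for some participant (min series {min_len})"
        )
    groups = np.array([s.order_group for s in summaries])
    rows = []
    stop_reason = None
    for n in range(n_max + 1):
        binding = np.array(
            [
                np.median(s.series["AS"][n:]) - np.median(s.series["AO"][n:])
                for s in summaries
            ]
        )
        x = binding[groups == "AO-AS"]
        y = binding[groups == "AS-AO"]
        if len(x) < 2 or len(y) < 2:
            stop_reason = f"group smaller than 2 at n={n}"
            break
        try:
            res = unpaired_t(x, y, "two-sided")
            t, df, p = res.t, res.df, res.p
        except ZeroVarianceError:
            t, df, p = 0.0, len(x) + len(y) - 2, 1.0
        rows.append(
            {
                "n": n,
                "mean_ao_first": float(np.mean(x)),
                "se_ao_first": float(np.std(x, ddof=1) / math.sqrt(len(x))),
                "mean_as_first": float(np.mean(y)),
                "se_as_first": float(np.std(y, ddof=1) / math.sqrt(len(y))),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return OrderScanResult(pd.DataFrame(rows), n_max=n_max, stop_reason=stop_reason)


def cutoff_from_scan(
    scan: OrderScanResult, alpha: float = 0.05, horizon: int = 30
) -> int | None:
    """Smallest n such that the scan's p exceeds ``alpha`` for every m in
    [n, horizon]; ``None`` when no such n exists.  The horizon operationalises
    "non-significant consistently thereafter" while staying clear of the very
    deep rows where binding rests on a handful of trials.
    """
    tab = scan.table
    if tab.empty:
        raise ValueError("empty scan")
    horizon = int(horizon)
    if horizon > int(tab["n"].max()):
        raise ValueError(f"horizon {horizon} beyond scanned n_max {int(tab['n'].max())}")
    window = tab[tab["n"] <= horizon].sort_values("n")
    ok = (window["p"] > alpha).to_numpy()
    # suffix scan: smallest n with every later row (up to horizon) also ok
    good_from = None
    for i in range(len(ok) - 1, -1, -1):
        if not ok[i]:
            break
        good_from = int(window["n"].iloc[i])
    return good_from
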