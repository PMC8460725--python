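"""Trial-table ingestion, derived timing quantities, and per-participant summaries.

The analysis works on two derived times per trial:

* perceived keypress time ``t2 - t1`` — how much later than the physical
  press awareness places it (``t2`` is the 12 o'clock crossing the press was
  aimed at, ``t1`` the registered press);
* actual keypress time ``t1 - t2`` — the physical press relative to the
  crossing (negative = pressed early).

Binding inference uses only trials the participant judged to be exactly *at*
12 o'clock, ordered by their acquisition index among 'at-12' responses;
*before*/*after* trials feed the validity report only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import CONDITIONS, ORDER_GROUPS, RESPONSES

MAX_PRESS_OFFSET_MS = 900.0  # press must fall within half a rotation of the crossing

REQUIRED_COLUMNS = (
    "participant_id",
    "order_group",
    "condition",
    "trial_index",
    "at12_index",
    "t_press_ms",
    "t_twelve_ms",
    "response",
)


class TrialDataError(ValueError):
    """The trial table violates the input contract (strict-fail, no row dropping)."""


def perceived_keypress_time(trial: Mapping[str, float]) -> float:
    """Perceived press time ``t2 - t1`` for one trial record.

    Positive values mean awareness placed the press later than it physically
    occurred.  Defined for every response category, but binding uses 'at-12'
    trials only.
    """
    t1, t2 = _timestamps(trial)
    return t2 - t1


def actual_keypress_time(trial: Mapping[str, float]) -> float:
    """Physical press time relative to the crossing, ``t1 - t2`` (negative = early)."""
    t1, t2 = _timestamps(trial)
    return t1 - t2


def _timestamps(trial: Mapping[str, float]) -> tuple[float, float]:
    try:
        t1, t2 = trial["t_press_ms"], trial["t_twelve_ms"]
    except KeyError as exc:
        raise TrialDataError(f"trial record lacks timestamp field {exc}") from exc
    if t1 is None or t2 is None or math.isnan(float(t1)) or math.isnan(float(t2)):
        raise TrialDataError("trial record has a missing timestamp")
    return float(t1), float(t2)


@dataclass
class ParticipantSummary:
    """Per-participant condition series and response-category descriptives."""

    participant_id: str
    order_group: str
    series: dict[str, np.ndarray]        # condition -> ordered 'at-12' perceived times
    medians: dict[str, float]            # condition -> median of the series
    actual_mean_by_response: dict[str, float]  # NaN when the category is empty
    counts_by_response: dict[str, int]

    def truncated_median(self, condition: str, n_drop: int) -> float:
        s = self.series[condition]
        if n_drop >= len(s):
            raise TrialDataError(
                f"{self.participant_id}/{condition}: cannot drop {n_drop} of {len(s)} trials"
            )
        return float(np.median(s[n_drop:]))


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial CSV (header required, times in ms)."""
    df = pd.read_csv(
        path,
        dtype={"participant_id": str, "order_group": str, "condition": str, "response": str},
    )
    df["at12_index"] = df["at12_index"].astype("Int64")
    validate_trials(df)
    return df


def validate_trials(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"missing columns: {missing}")
    if df.empty:
        raise TrialDataError("empty trial table")
    for col, allowed in (
        ("order_group", ORDER_GROUPS),
        ("condition", CONDITIONS),
        ("response", RESPONSES),
    ):
        bad = set(df[col].unique()) - set(allowed)
        if bad:
            raise TrialDataError(f"invalid {col} values: {sorted(bad)}")
    if df[["t_press_ms", "t_twelve_ms"]].isna().any().any():
        raise TrialDataError("missing timestamps")
    offset = (df["t_press_ms"] - df["t_twelve_ms"]).abs()
    if (offset >= MAX_PRESS_OFFSET_MS).any():
        n_bad = int((offset >= MAX_PRESS_OFFSET_MS).sum())
        raise TrialDataError(
            f"{n_bad} trial(s) with |t1 - t2| >= {MAX_PRESS_OFFSET_MS:g} ms"
        )
    is_at = df["response"] == "at"
    if (df["at12_index"].notna() != is_at).any():
        raise TrialDataError("at12_index must be present exactly for 'at' responses")
    if (df.groupby("participant_id")["order_group"].nunique() > 1).any():
        raise TrialDataError("participant with more than one order_group")
    at = df[is_at]
    for (pid, cond), grp in at.sort_values("trial_index").groupby(
        ["participant_id", "condition"], sort=False
    ):
        idx = grp["at12_index"].to_numpy(dtype=float)
        if len(np.unique(idx)) != len(idx):
            raise TrialDataError(f"duplicate at12_index for {pid}/{cond}")
        if np.any(np.diff(idx) <= 0):
            raise TrialDataError(f"at12_index not strictly increasing for {pid}/{cond}")


def build_summaries(trials: pd.DataFrame) -> list[ParticipantSummary]:
    """Collapse a validated trial table into per-participant summaries.

    The 'at-12' perceived-time series is ordered by ``at12_index``
    (acquisition order among 'at' responses); response-category actual-time
    means and counts pool both conditions, mirroring how validity is assessed.
    Row order of the input is irrelevant.
    """
    validate_trials(trials)
    df = trials.assign(
        perceived_ms=trials["t_twelve_ms"] - trials["t_press_ms"],
        actual_ms=trials["t_press_ms"] - trials["t_twelve_ms"],
    )
    order_of = df.groupby("participant_id", sort=True)["order_group"].first()

    at = df[df["response"] == "at"].sort_values(
        ["participant_id", "condition", "at12_index"]
    )
    series_map: dict[tuple[str, str], np.ndarray] = {
        key: grp["perceived_ms"].to_numpy(dtype=float)
        for key, grp in at.groupby(["participant_id", "condition"], sort=False)
    }
    actual_stats = df.groupby(["participant_id", "response"], sort=False)[
        "actual_ms"
    ].agg(["mean", "count"])

    summaries: list[ParticipantSummary] = []
    for pid in order_of.index:
        series: dict[str, np.ndarray] = {}
        medians: dict[str, float] = {}
        for cond in CONDITIONS:
            s = series_map.get((pid, cond))
            if s is None or len(s) == 0:
                raise TrialDataError(f"{pid}: no 'at-12' trials in condition {cond}")
            series[cond] = s
            medians[cond] = float(np.median(s))
        actual_mean = {}
        counts = {}
        for resp in RESPONSES:
            if (pid, resp) in actual_stats.index:
                row = actual_stats.loc[(pid, resp)]
                actual_mean[resp] = float(row["mean"])
                counts[resp] = int(row["count"])
            else:
                actual_mean[resp] = math.nan
                counts[resp] = 0
        summaries.append(
            ParticipantSummary(pid, order_of[pid], series, medians, actual_mean, counts)
        )
    return summaries


def response_validity_report(summaries: Sequence[ParticipantSummary]) -> dict:
    """Check that the before/at/after judgements track the actual press time.

    Group-level means of per-participant mean actual press times per
    category, the two paired contrasts (before vs at, at vs after) and the
    paired contrast of before vs after counts, each with Cohen's dz.
    Categories empty for every participant are flagged rather than failing.
    """
    from .binding_stats import cohen_dz, paired_t  # local import avoids a cycle

    rows = pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            **{
                f"mean_{r}": [s.actual_mean_by_response[r] for s in summaries]
                for r in RESPONSES
            },
            **{
                f"count_{r}": [s.counts_by_response[r] for s in summaries]
                for r in RESPONSES
            },
        }
    )
    report: dict = {"n_participants": len(summaries), "categories": {}, "contrasts": {}}
    empty = []
    for r in RESPONSES:
        vals = rows[f"mean_{r}"].dropna()
        report["categories"][r] = {
            "mean_actual_ms": float(vals.mean()) if len(vals) else None,
            "sd_actual_ms": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "mean_count": float(rows[f"count_{r}"].mean()),
            "n_participants": int(len(vals)),
        }
        if not len(vals):
            empty.append(r)
    report["empty_categories"] = empty

    def _paired(a: str, b: str) -> dict | None:
        both = rows[[f"mean_{a}", f"mean_{b}"]].dropna()
        if len(both) < 2:
            return None
        res = paired_t(
            both[f"mean_{a}"].to_numpy(), both[f"mean_{b}"].to_numpy(), "two-sided"
        )
        return {
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "dz": cohen_dz(res.t, len(both)),
            "n": int(len(both)),
        }

    report["contrasts"]["before_vs_at"] = _paired("before", "at")
    report["contrasts"]["at_vs_after"] = _paired("at", "after")
    counts = rows[["count_before", "count_after"]].astype(float)
    if len(counts) >= 2 and counts.sub(counts.mean()).abs().to_numpy().sum() > 0:
        from .binding_stats import ZeroVarianceError

        try:
            res = paired_t(
                counts["count_before"].to_numpy(), counts["count_after"].to_numpy(),
                "two-sided",
            )
            report["contrasts"]["count_before_vs_after"] = {
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "dz": cohen_dz(res.t, len(counts)),
                "n": int(len(counts)),
            }
        except ZeroVarianceError:
            report["contrasts"]["count_before_vs_after"] = None
    else:
        report["contrasts"]["count_before_vs_after"] = None
    return report
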