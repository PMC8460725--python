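"""Action-binding estimation: robust exclusion, condition contrasts, effect sizes.

Central quantities
------------------
Per participant, binding is measured two ways from the ordered 'at-12'
perceived-time series of the two conditions (optionally after dropping the
first ``n_drop`` trials of each condition to shed testing-order carryover):

* ``binding_ms`` — median(AS) - median(AO), the classic difference of
  condition medians, in ms;
* ``binding_t`` — the trial-level unpaired t statistic of AS vs AO perceived
  times, a variance-aware per-participant binding *strength* used as the
  correlate of delusional ideation.

Participant exclusion uses the MAD-median rule on the average of the two
condition medians, applied to the whole cohort vector at once:
``|p - median(P)| * 0.6745 > 3 * MAD-median`` flags ``p`` as an outlier.

Effect sizes follow the paired/unpaired conventions ``dz = t/sqrt(n)`` and
``ds = t*sqrt(1/n1 + 1/n2)``.  All t tests are Student (pooled variance);
a Welch switch exists for sensitivity analyses but the pooled form matches
the balanced design and the ``ds`` formula.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .trial_prep import ParticipantSummary

MAD_SCALE = 0.6745  # normal-consistency constant as used in the printed rule
MAD_CUTOFF = 3.0


class ZeroVarianceError(ValueError):
    """A t statistic is undefined because the relevant variance is zero."""


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float


def cohen_dz(t: float, n: int) -> float:
    """Paired-design effect size ``dz = t / sqrt(n)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return t / math.sqrt(n)


def cohen_ds(t: float, n1: int, n2: int) -> float:
    """Unpaired-design effect size ``ds = t * sqrt(1/n1 + 1/n2)`` (symmetric in n1, n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be >= 1")
    return t * math.sqrt(1.0 / n1 + 1.0 / n2)


def _t_pvalue(t: float, df: float, alternative: str) -> float:
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise ValueError(f"unknown alternative {alternative!r}")


def paired_t(x, y, alternative: str = "two-sided") -> TTestResult:
    """Paired t test on ``x - y``: ``t = mean(d) / (sd(d)/sqrt(n))``, df = n - 1.

    Raises :class:`ZeroVarianceError` when the differences have zero
    variance (including the x == y case), where t is undefined.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired_t needs two equal-length vectors of length >= 2")
    d = x - y
    n = len(d)
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ZeroVarianceError("zero-variance differences: paired t undefined")
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    return TTestResult(t, n - 1, _t_pvalue(t, n - 1, alternative))


def unpaired_t(
    x, y, alternative: str = "two-sided", equal_var: bool = True
) -> TTestResult:
    """Two-sample t test, Student (pooled variance) by default; df = n1 + n2 - 2.

    The pooled form matches the balanced design and the ``ds`` effect-size
    convention; ``equal_var=False`` switches to Welch for sensitivity checks.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.ndim != 1 or y.ndim != 1 or len(x) < 2 or len(y) < 2:
        raise ValueError("unpaired_t needs two vectors of length >= 2")
    n1, n2 = len(x), len(y)
    v1, v2 = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    if (n1 - 1) * v1 + (n2 - 1) * v2 == 0:
        raise ZeroVarianceError("zero pooled variance: unpaired t undefined")
    diff = float(np.mean(x) - np.mean(y))
    if equal_var:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df: float = n1 + n2 - 2
    else:
        se = math.sqrt(v1 / n1 + v2 / n2)
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1)
        )
    t = diff / se
    return TTestResult(t, df, _t_pvalue(t, df, alternative))


def mad_median_outliers(values) -> np.ndarray:
    """Flag outliers by the MAD-median rule, exactly as printed:
    ``|p - median(P)| * 0.6745 > 3 * median(|p_i - median(P)|)``.

    The rule is evaluated on the full vector, candidates included.  When the
    MAD is zero but values differ (more than half the cohort tied at the
    median), every value off the median is flagged and a warning emitted —
    the rule's own prescription degenerates there.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 3:
        raise ValueError("MAD-median rule needs at least 3 values")
    med = np.median(v)
    dev = np.abs(v - med)
    mad = np.median(dev)
    if mad == 0:
        if np.all(dev == 0):
            return np.zeros(len(v), bool)
        warnings.warn(
            "MAD-median is zero with non-identical values; flagging everything "
            "off the median",
            RuntimeWarning,
            stacklevel=2,
        )
        return dev > 0
    return dev * MAD_SCALE > MAD_CUTOFF * mad


def mad_median_screen(summaries: Sequence[ParticipantSummary]) -> pd.DataFrame:
    """Cohort-level exclusion screen on the per-participant average of the
    AO and AS perceived-time medians.  Returns one row per participant with
    the statistic and the flag; callers filter downstream stages on it.
    """
    stat = np.array(
        [(s.medians["AO"] + s.medians["AS"]) / 2.0 for s in summaries], float
    )
    flags = mad_median_outliers(stat)
    return pd.DataFrame(
        {
            "participant_id": [s.participant_id for s in summaries],
            "avg_median_ms": stat,
            "flagged": flags,
            "rule": "mad_median",
        }
    )


def binding_estimates(
    summaries: Sequence[ParticipantSummary], n_drop: int = 10
) -> pd.DataFrame:
    """Per-participant binding after dropping the first ``n_drop`` 'at-12'
    trials of each condition.

    ``binding_ms`` uses medians of the truncated series; ``binding_t`` the
    trial-level unpaired t (AS vs AO) on the same trials, NaN when a series
    is shorter than 2 or the pooled variance vanishes (noise-free data).
    """
    if n_drop < 0:
        raise ValueError("n_drop must be >= 0")
    rows = []
    for s in summaries:
        ao = s.series["AO"][n_drop:]
        as_ = s.series["AS"][n_drop:]
        if len(ao) == 0 or len(as_) == 0:
            raise ValueError(
                f"{s.participant_id}: no trials left after dropping {n_drop}"
            )
        binding_ms = float(np.median(as_) - np.median(ao))
        # trial variance indistinguishable from timestamp round-off means the
        # per-participant t is undefined, not astronomically large
        scale = max(1.0, float(np.max(np.abs(np.concatenate([ao, as_])))))
        degenerate = (
            len(ao) < 2
            or len(as_) < 2
            or math.sqrt(np.var(ao, ddof=1) + np.var(as_, ddof=1)) <= 1e-9 * scale
        )
        if degenerate:
            binding_t = math.nan
        else:
            try:
                binding_t = unpaired_t(as_, ao, "two-sided").t
            except ZeroVarianceError:
                binding_t = math.nan
        rows.append(
            {
                "participant_id": s.participant_id,
                "order_group": s.order_group,
                "binding_ms": binding_ms,
                "binding_t": binding_t,
                "n_drop": n_drop,
                "n_trials_ao": len(ao),
                "n_trials_as": len(as_),
            }
        )
    return pd.DataFrame(rows)


def _mean_ci(values: np.ndarray, level: float = 0.95) -> dict:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return {"mean": mean, "ci_low": None, "ci_high": None, "n": n}
    sem = float(np.std(values, ddof=1) / math.sqrt(n))
    tcrit = float(stats.t.ppf(0.5 + level / 2.0, n - 1))
    return {"mean": mean, "ci_low": mean - tcrit * sem, "ci_high": mean + tcrit * sem, "n": n}


def cohort_binding_report(
    estimates: pd.DataFrame, summaries: Sequence[ParticipantSummary]
) -> dict:
    """Group-level binding report at the estimates' ``n_drop``.

    Whole-sample and per-order-group condition means with t-based 95% CIs,
    the paired AS-vs-AO contrast (one-tailed, AS later) with dz, the
    between-order-group contrast on ``binding_ms`` (two-tailed) with ds, and
    the per-condition between-group contrasts behind the "absolute change
    due to testing order" numbers.
    """
    n_drop = int(estimates["n_drop"].iloc[0])
    by_id = {s.participant_id: s for s in summaries}
    kept = [by_id[p] for p in estimates["participant_id"]]
    meds = {
        cond: np.array([s.truncated_median(cond, n_drop) for s in kept])
        for cond in ("AO", "AS")
    }
    groups = estimates["order_group"].to_numpy()

    def _condition_block(mask: np.ndarray) -> dict:
        block = {c: _mean_ci(meds[c][mask]) for c in ("AO", "AS")}
        if mask.sum() >= 2:
            res = paired_t(meds["AS"][mask], meds["AO"][mask], "greater")
            block["as_vs_ao"] = {
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "dz": cohen_dz(res.t, int(mask.sum())),
                "tail": "greater",
            }
        else:
            block["as_vs_ao"] = None
        return block

    all_mask = np.ones(len(kept), bool)
    report = {
        "n_drop": n_drop,
        "n_participants": len(kept),
        "whole_sample": _condition_block(all_mask),
        "groups": {},
    }
    for g in ("AO-AS", "AS-AO"):
        mask = groups == g
        if mask.sum() < 2:
            raise ValueError(f"order group {g} has fewer than 2 participants")
        report["groups"][g] = _condition_block(mask)

    b_aofirst = estimates.loc[groups == "AO-AS", "binding_ms"].to_numpy()
    b_asfirst = estimates.loc[groups == "AS-AO", "binding_ms"].to_numpy()
    res = unpaired_t(b_aofirst, b_asfirst, "two-sided")
    report["order_contrast"] = {
        "mean_binding_ao_first": float(np.mean(b_aofirst)),
        "mean_binding_as_first": float(np.mean(b_asfirst)),
        "t": res.t,
        "df": res.df,
        "p": res.p,
        "ds": cohen_ds(res.t, len(b_aofirst), len(b_asfirst)),
        "tail": "two-sided",
    }
    report["condition_order_contrasts"] = {}
    for cond in ("AO", "AS"):
        x = meds[cond][groups == "AO-AS"]
        y = meds[cond][groups == "AS-AO"]
        res = unpaired_t(x, y, "two-sided")
        report["condition_order_contrasts"][cond] = {
            "abs_change_ms": abs(float(np.mean(x) - np.mean(y))),
            "t": res.t,
            "df": res.df,
            "p": res.p,
            "ds": cohen_ds(res.t, len(x), len(y)),
        }
    return report
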