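"""PDI-21 scoring and the delusional-ideation / binding-strength correlation.

The 21-item Peters et al. Delusions Inventory gives one point per endorsed
item plus three 1-5 ratings (distress, preoccupation, conviction), so the
overall score spans 0-336.  The analysis correlates it, Pearson, one-tailed
(a positive association is the hypothesis), with the per-participant
binding-strength t value, after dropping incomplete questionnaires and
boxplot-rule outliers; the confidence interval comes from a seeded
percentile bootstrap over participant pairs.

Interpretive choice, documented in the methods note: the boxplot rule is
applied to each variable independently and the excluded set is the union.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import PDI_N_ITEMS

IQR_WHISKER = 1.5


class IncompletePDIError(ValueError):
    """A questionnaire with unanswered items cannot be scored."""


@dataclass
class CorrelationResult:
    r: float
    n: int
    p: float
    alternative: str
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int
    exclusions: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "n": self.n,
            "p": self.p,
            "alternative": self.alternative,
            "ci95": [self.ci_low, self.ci_high],
            "n_boot": self.n_boot,
            "seed": self.seed,
            "exclusions": self.exclusions,
        }


def _rating_fields(i: int) -> tuple[str, str, str]:
    return f"distress_{i}", f"preoccupation_{i}", f"conviction_{i}"


def pdi_overall_score(record: Mapping[str, object]) -> int:
    """Overall PDI-21 score: sum over endorsed items of
    ``1 + distress + preoccupation + conviction``.

    Raises :class:`IncompletePDIError` on missing endorsements or missing /
    out-of-range ratings for an endorsed item — incomplete questionnaires are
    excluded downstream, never imputed.
    """
    total = 0
    for i in range(1, PDI_N_ITEMS + 1):
        endorsed = record.get(f"endorsed_{i}")
        if endorsed is None or (isinstance(endorsed, float) and math.isnan(endorsed)) or endorsed is pd.NA:
            raise IncompletePDIError(f"item {i}: endorsement missing")
        endorsed = int(endorsed)
        if endorsed not in (0, 1):
            raise IncompletePDIError(f"item {i}: endorsement must be 0 or 1")
        if endorsed:
            pts = 1
            for fname in _rating_fields(i):
                val = record.get(fname)
                if val is None or val is pd.NA or (isinstance(val, float) and math.isnan(val)):
                    raise IncompletePDIError(f"item {i}: rating {fname} missing")
                val = int(val)
                if not 1 <= val <= 5:
                    raise IncompletePDIError(f"item {i}: rating {fname}={val} outside 1-5")
                pts += val
            total += pts
    return total


def read_pdi(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"participant_id": str})
    expected = {"participant_id"}
    for i in range(1, PDI_N_ITEMS + 1):
        expected.add(f"endorsed_{i}")
        expected.update(_rating_fields(i))
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"PDI table missing columns: {sorted(missing)[:5]}...")
    for col in df.columns:
        if col != "participant_id":
            df[col] = df[col].astype("Int64")
    return df


def score_pdi_table(pdi: pd.DataFrame) -> pd.DataFrame:
    """Score every questionnaire; incomplete ones get a null score and
    ``complete = False`` instead of an exception."""
    rows = []
    for _, rec in pdi.iterrows():
        try:
            score: int | None = pdi_overall_score(rec)
            complete = True
        except IncompletePDIError:
            score, complete = None, False
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "overall_score": score,
                "complete": complete,
            }
        )
    out = pd.DataFrame(rows)
    out["overall_score"] = out["overall_score"].astype("Int64")
    return out


def boxplot_outliers(values) -> np.ndarray:
    """Flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation between order statistics (numpy's
    default), the convention the flag set can depend on.
    """
    v = np.asarray(values, float)
    if v.ndim != 1 or len(v) < 4:
        raise ValueError("boxplot rule needs at least 4 values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    iqr = q3 - q1
    return (v < q1 - IQR_WHISKER * iqr) | (v > q3 + IQR_WHISKER * iqr)


def pearson_bootstrap(
    x,
    y,
    n_boot: int = 2000,
    seed: int = 0,
    alternative: str = "greater",
) -> CorrelationResult:
    """Pearson r with a one-tailed t-transform p (df = n - 2) and a seeded
    percentile-bootstrap 95% CI over resampled pairs."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need paired vectors of length >= 4")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    t = r * math.sqrt((n - 2) / max(1e-300, 1.0 - r * r))
    if alternative == "greater":
        p = float(stats.t.sf(t, n - 2))
    elif alternative == "less":
        p = float(stats.t.cdf(t, n - 2))
    elif alternative == "two-sided":
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    bx, by = x[idx], y[idx]
    bx = bx - bx.mean(axis=1, keepdims=True)
    by = by - by.mean(axis=1, keepdims=True)
    denom = np.sqrt((bx**2).sum(axis=1) * (by**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        boot_r = (bx * by).sum(axis=1) / denom
    boot_r = boot_r[np.isfinite(boot_r)]  # degenerate resamples dropped
    ci_low, ci_high = np.percentile(boot_r, [2.5, 97.5])
    return CorrelationResult(
        r=r,
        n=n,
        p=p,
        alternative=alternative,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        seed=seed,
    )


def delusion_binding_analysis(
    estimates: pd.DataFrame,
    pdi: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    alternative: str = "greater",
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Join binding strength with PDI scores and correlate.

    Pipeline: join on participant, drop incomplete questionnaires, flag
    boxplot outliers on each variable (union), correlate the survivors.
    Returns the result (with a full exclusion ledger) and the scatter table
    (participant_id, pdi_score, binding_t, excluded_reason).
    """
    scored = score_pdi_table(pdi)
    merged = estimates.merge(scored, on="participant_id", how="inner")
    if merged["binding_t"].isna().any():
        raise ValueError("binding_t undefined for some participants")
    n_start = len(merged)
    merged["excluded_reason"] = ""
    merged.loc[~merged["complete"], "excluded_reason"] = "incomplete_pdi"
    usable = merged[merged["complete"]].copy()
    if len(usable) >= 4:
        score_flags = boxplot_outliers(usable["overall_score"].astype(float).to_numpy())
        t_flags = boxplot_outliers(usable["binding_t"].to_numpy())
        reasons = np.select(
            [score_flags & t_flags, score_flags, t_flags],
            ["boxplot_pdi+boxplot_binding", "boxplot_pdi", "boxplot_binding"],
            default="",
        )
        usable["excluded_reason"] = reasons
        merged.loc[usable.index, "excluded_reason"] = reasons
    final = usable[usable["excluded_reason"] == ""]
    if len(final) < 4:
        raise ValueError(f"only {len(final)} usable pairs after exclusions")
    result = pearson_bootstrap(
        final["overall_score"].astype(float).to_numpy(),
        final["binding_t"].to_numpy(),
        n_boot=n_boot,
        seed=seed,
        alternative=alternative,
    )
    result.exclusions = {
        "n_start": n_start,
        "n_incomplete_pdi": int((~merged["complete"]).sum()),
        "n_boxplot": int((usable["excluded_reason"] != "").sum()),
        "n_final": int(len(final)),
        "excluded": merged.loc[
            merged["excluded_reason"] != "", ["participant_id", "excluded_reason"]
        ].to_dict(orient="records"),
    }
    scatter = merged[
        ["participant_id", "overall_score", "binding_t", "excluded_reason"]
    ].rename(columns={"overall_score": "pdi_score"})
    return result, scatter
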