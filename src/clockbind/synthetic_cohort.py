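"""Synthetic Libet-clock cohorts with the statistical structure of the binding task.

The generator emulates a two-condition timing experiment.  On every trial a
participant tries to press a key exactly when a rotating clock hand (1800 ms
period) crosses the 12 o'clock position and afterwards categorises the press
as *before*, *at*, or *after* 12.  In the action-only condition (``AO``) the
press is silent; in the action-sound condition (``AS``) it triggers a tone
250 ms later, which shifts the perceived press time later (action binding).
A condition runs until a target number of 'at-12' trials has been acquired.

The latent model, per participant ``i`` and trial with 'at-12' count ``k``::

    shift s = b_i + d_i * [AS] + w * (s_prev_end - s_own_base) * exp(-k/tau)
              + drift_slope * k
    aiming error   eta ~ Normal(aim_bias, aim_sd**2)
    actual press   a = -s + eta         (ms relative to the crossing)
    subjective pos q = a + s = eta      (categorised against +/- threshold)

so the perceived press time recovered downstream, t2 - t1 = -a = s - eta, is
the subjective shift corrupted by (truncated) aiming noise.  Carryover decays
in the count of acquired 'at-12' trials, mirroring how the analysis indexes
trials; it is asymmetric by default (a preceding AS condition pulls early AO
trials later, the reverse influence is absent).

Delusional ideation enters through a latent trait z_i correlated with the
binding increment; the questionnaire table maps z_i through a right-skewed
(lognormal) transform onto the 0-336 overall-score scale and then spreads the
score over 21 items.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

CONDITIONS = ("AO", "AS")
ORDER_GROUPS = ("AO-AS", "AS-AO")
RESPONSES = ("before", "at", "after")

HAND_PERIOD_MS = 1800.0
POST_PRESS_ROTATION_MS = 900.0
ITI_RANGE_MS = (2000.0, 2500.0)

PDI_N_ITEMS = 21
PDI_MAX_SCORE = 336  # 21 * (1 + 5 + 5 + 5)
_PDI_MIN_ITEM = 4    # endorsement + three ratings of 1
_PDI_MAX_ITEM = 16   # endorsement + three ratings of 5


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class SimulationError(RuntimeError):
    """The acquisition loop could not complete (e.g. max attempts exhausted)."""


@dataclass(frozen=True)
class PDIShape:
    """Lognormal map from the latent trait to the PDI-21 overall score.

    ``score = clip(round(median * exp(sigma * z)), 0, 336)`` — right-skewed,
    monotone in ``z``.  The defaults (median 50, sigma 0.55) give a cohort
    mean near 58 and SD near 34, in the range published for healthy adults.
    """

    median: float = 50.0
    sigma: float = 0.55


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator.  Times in ms.

    Defaults are calibrated to the task this package analyses: a mean binding
    increment of 23 ms, per-condition 'at-12' SDs near 41 ms, 40 'at-12'
    trials per condition, 26 participants per testing-order group, and an
    observable trait-binding correlation of 0.27.
    """

    n_per_group: int = 26
    baseline_shift_mean: float = 15.0   # mean of per-participant AO shift b_i
    baseline_shift_sd: float = 25.0
    binding_mean: float = 23.0          # mean of AS increment d_i
    binding_sd: float = 15.0
    carryover_tau: float = 3.0          # e-folding, in acquired 'at-12' trials
    carryover_into_ao: float = 1.0      # weight of AS -> AO carryover
    carryover_into_as: float = 0.0      # weight of AO -> AS carryover
    drift_slope: float = 0.3            # ms per acquired 'at-12' trial
    aim_sd: float = 60.0                # sigma of aiming/judgement noise eta
    aim_bias: float = -10.0             # mean of eta (negative: presses early)
    response_threshold: float = 80.0    # half-width of the 'at-12' window
    trials_at12_target: int = 40
    max_attempts_per_condition: int = 400
    pdi_binding_rho: float = 0.27       # target OBSERVED trait-binding corr
    pdi_shape: PDIShape = field(default_factory=PDIShape)
    analysis_n_drop: int = 10           # trial-exclusion depth of the intended analysis
    outlier_fraction: float = 0.0       # contaminant participants w/ extreme shifts
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be >= 1")
        for name in ("baseline_shift_sd", "binding_sd", "aim_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("carryover_into_ao", "carryover_into_as"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.carryover_tau <= 0:
            raise ConfigError("carryover_tau must be > 0")
        if abs(self.pdi_binding_rho) > 1:
            raise ConfigError("|pdi_binding_rho| must be <= 1")
        if self.trials_at12_target < 1:
            raise ConfigError("trials_at12_target must be >= 1")
        if self.response_threshold <= 0:
            raise ConfigError("response_threshold must be > 0")
        if self.max_attempts_per_condition < self.trials_at12_target:
            raise ConfigError("max_attempts_per_condition < trials_at12_target")
        if not 0.0 <= self.outlier_fraction <= 1.0:
            raise ConfigError("outlier_fraction must be in [0, 1]")
        if self.pdi_shape.median <= 0 or self.pdi_shape.sigma <= 0:
            raise ConfigError("pdi_shape parameters must be positive")
        if not 0 <= self.analysis_n_drop < self.trials_at12_target:
            raise ConfigError("analysis_n_drop must be in [0, trials_at12_target)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class GroundTruth:
    """Latent per-participant values behind a simulated cohort."""

    per_participant: pd.DataFrame  # participant_id, order_group, baseline_shift_ms,
    #                                binding_increment_ms, latent_trait, outlier
    config: SimulationConfig
    latent_rho: float  # z-zeta correlation actually used (after attenuation correction)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config.to_dict(),
            "latent_rho": self.latent_rho,
            "participants": self.per_participant.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def truncated_aim_moments(config: SimulationConfig) -> tuple[float, float]:
    """Mean and SD of the aiming error conditional on an 'at-12' response.

    The 'at-12' window truncates eta to [-theta, theta]; these are the
    truncated-normal moments, the closed-form expectation of the observable
    trial noise.
    """
    theta, mu, sd = config.response_threshold, config.aim_bias, config.aim_sd
    if sd == 0:
        return (mu if abs(mu) <= theta else math.nan), 0.0
    a, b = (-theta - mu) / sd, (theta - mu) / sd
    dist = stats.truncnorm(a, b, loc=mu, scale=sd)
    return float(dist.mean()), float(dist.std())


def latent_trait_rho(config: SimulationConfig) -> float:
    """Latent z-zeta correlation needed so the OBSERVED trait-binding
    correlation targets ``pdi_binding_rho``.

    Two attenuation factors, both closed-form in the config, separate the
    latent correlation from the one an analyst can measure:

    * ``a_score`` — the Pearson correlation between the lognormal score
      transform and the underlying normal trait, sigma/sqrt(exp(sigma^2)-1);
    * ``a_bind`` — the reliability of the per-participant binding estimate,
      binding_sd / sqrt(binding_sd^2 + 2*sd_trunc^2/m), with m the number of
      'at-12' trials per condition retained by the intended analysis.

    The generator divides the target by both so that parameter-recovery of
    the observable correlation is unbiased.  The result is clipped to
    +/-0.995 (a target too large to survive the noise cannot be represented).
    """
    rho = config.pdi_binding_rho
    if rho == 0 or config.binding_sd == 0:
        return rho
    sigma = config.pdi_shape.sigma
    a_score = sigma / math.sqrt(math.expm1(sigma**2))
    _, sd_trunc = truncated_aim_moments(config)
    m = config.trials_at12_target - config.analysis_n_drop
    noise_var = 2.0 * sd_trunc**2 / m
    a_bind = config.binding_sd / math.sqrt(config.binding_sd**2 + noise_var)
    return float(np.clip(rho / (a_score * a_bind), -0.995, 0.995))


def _simulate_condition(rng, config, b, d, condition, prev_condition, t_start):
    """Vectorised acquisition run for one participant x condition.

    Returns a dict of per-attempt arrays plus the clock time after the run.
    """
    theta = config.response_threshold
    n_max = config.max_attempts_per_condition
    eta = rng.normal(config.aim_bias, config.aim_sd, n_max)
    at = np.abs(eta) <= theta
    cum = np.cumsum(at)
    if cum[-1] < config.trials_at12_target:
        raise SimulationError(
            f"condition {condition}: only {int(cum[-1])} 'at-12' trials in "
            f"{n_max} attempts (response_threshold too small for aim_sd?)"
        )
    n_att = int(np.searchsorted(cum, config.trials_at12_target)) + 1
    eta, at, cum = eta[:n_att], at[:n_att], cum[:n_att]

    # 'at-12' count before each attempt drives carryover decay and drift
    k = np.concatenate(([0.0], cum[:-1].astype(float)))
    is_as = condition == "AS"
    own_base = b + (d if is_as else 0.0)
    if prev_condition is None:
        carry = 0.0
    else:
        prev_end = b + (d if prev_condition == "AS" else 0.0)
        w = config.carryover_into_as if is_as else config.carryover_into_ao
        carry = w * (prev_end - own_base) * np.exp(-k / config.carryover_tau)
    s = own_base + carry + config.drift_slope * k
    a = -s + eta

    iti = rng.uniform(*ITI_RANGE_MS, n_att)
    # clock: ITI, hand starts at 12, press aimed at the next full crossing
    step = iti + HAND_PERIOD_MS + a + POST_PRESS_ROTATION_MS
    block_start = t_start + np.concatenate(([0.0], np.cumsum(step[:-1])))
    t2 = block_start + iti + HAND_PERIOD_MS
    t1 = t2 + a

    response = np.where(eta < -theta, "before", np.where(eta > theta, "after", "at"))
    at12_index = np.where(at, cum, 0)
    return {
        "n_attempts": n_att,
        "t1": t1,
        "t2": t2,
        "response": response,
        "at12_index": at12_index,  # 0 encodes "not an at-12 trial"
        "t_end": float(block_start[-1] + step[-1]),
    }


def _pdi_items_from_score(score: int) -> list[tuple[int, int, int, int]]:
    """Deterministically spread an overall score over 21 items.

    Returns per item (endorsed, distress, preoccupation, conviction); ratings
    are 0 when not endorsed (written as empty cells).  Any allocation whose
    endorsed items sum to the score is valid; this one endorses the fewest
    items possible and balances ratings.
    """
    if not 0 <= score <= PDI_MAX_SCORE:
        raise ValueError(f"PDI score {score} outside [0, {PDI_MAX_SCORE}]")
    if 0 < score < _PDI_MIN_ITEM:
        raise ValueError(f"PDI score {score} unreachable (single item scores >= 4)")
    items: list[tuple[int, int, int, int]] = []
    if score > 0:
        n_endorsed = max(1, math.ceil(score / _PDI_MAX_ITEM))
        base, rem = divmod(score, n_endorsed)
        for j in range(n_endorsed):
            pts = base + (1 if j < rem else 0) - 1  # ratings total, in [3, 15]
            rb, rr = divmod(pts, 3)
            ratings = [rb + (1 if i < rr else 0) for i in range(3)]
            items.append((1, ratings[0], ratings[1], ratings[2]))
    items.extend((0, 0, 0, 0) for _ in range(PDI_N_ITEMS - len(items)))
    return items


def pdi_score_from_trait(z: np.ndarray, shape: PDIShape) -> np.ndarray:
    """Monotone right-skewed map from a standard-normal trait to 0-336."""
    raw = np.rint(shape.median * np.exp(shape.sigma * np.asarray(z, float)))
    score = np.clip(raw, 0, PDI_MAX_SCORE).astype(int)
    score[(score > 0) & (score < _PDI_MIN_ITEM)] = _PDI_MIN_ITEM
    return score


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one cohort: trial table, PDI table, and ground truth.

    A single seed drives everything: one cohort-level stream draws the
    per-participant latent values, and per-participant substreams (spawned
    deterministically from the same seed) drive trial noise and timing, so a
    given participant's trials do not depend on how many others exist.
    """
    config.validate()
    n_total = 2 * config.n_per_group
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(n_total + 1)
    crng = np.random.default_rng(children[0])

    # one row of standard normals per participant (row-major fill), so a
    # participant's latent draws do not move when the cohort grows or shrinks
    latent = crng.standard_normal((n_total, 5))
    b = config.baseline_shift_mean + config.baseline_shift_sd * latent[:, 0]
    rho_l = latent_trait_rho(config)
    z = latent[:, 1]
    zeta = rho_l * z + math.sqrt(1.0 - rho_l**2) * latent[:, 2]
    d = config.binding_mean + config.binding_sd * zeta
    is_outlier = stats.norm.cdf(latent[:, 3]) < config.outlier_fraction
    out_sign = np.where(latent[:, 4] > 0, 1.0, -1.0)
    b = np.where(is_outlier, b + 300.0 * out_sign, b)

    width = len(str(n_total))
    pids = [f"P{i + 1:0{width}d}" for i in range(n_total)]
    groups = ["AO-AS"] * config.n_per_group + ["AS-AO"] * config.n_per_group

    cols: dict[str, list] = {
        "participant_id": [],
        "order_group": [],
        "condition": [],
        "trial_index": [],
        "at12_index": [],
        "t_press_ms": [],
        "t_twelve_ms": [],
        "response": [],
    }
    for i, (pid, group) in enumerate(zip(pids, groups)):
        prng = np.random.default_rng(children[i + 1])
        t_clock = 0.0
        prev = None
        for cond in group.split("-"):
            run = _simulate_condition(prng, config, b[i], d[i], cond, prev, t_clock)
            n_att = run["n_attempts"]
            cols["participant_id"].append(np.repeat(pid, n_att))
            cols["order_group"].append(np.repeat(group, n_att))
            cols["condition"].append(np.repeat(cond, n_att))
            cols["trial_index"].append(np.arange(1, n_att + 1))
            cols["at12_index"].append(run["at12_index"])
            cols["t_press_ms"].append(run["t1"])
            cols["t_twelve_ms"].append(run["t2"])
            cols["response"].append(run["response"])
            t_clock = run["t_end"]
            prev = cond
    flat = {k: np.concatenate(v) for k, v in cols.items()}
    at12 = flat.pop("at12_index")
    trials = pd.DataFrame(flat)
    trials.insert(
        4,
        "at12_index",
        pd.array(np.where(at12 > 0, at12, -1), dtype="Int64"),
    )
    trials.loc[trials["at12_index"] == -1, "at12_index"] = pd.NA

    scores = pdi_score_from_trait(z, config.pdi_shape)
    pdi_rows = []
    for pid, score in zip(pids, scores):
        row: dict[str, object] = {"participant_id": pid}
        for item_no, (e, di, pr, co) in enumerate(_pdi_items_from_score(int(score)), 1):
            row[f"endorsed_{item_no}"] = e
            row[f"distress_{item_no}"] = di if e else pd.NA
            row[f"preoccupation_{item_no}"] = pr if e else pd.NA
            row[f"conviction_{item_no}"] = co if e else pd.NA
        pdi_rows.append(row)
    pdi = pd.DataFrame(pdi_rows)
    for col in pdi.columns[1:]:
        pdi[col] = pdi[col].astype("Int64")

    truth = GroundTruth(
        per_participant=pd.DataFrame(
            {
                "participant_id": pids,
                "order_group": groups,
                "baseline_shift_ms": b,
                "binding_increment_ms": d,
                "latent_trait": z,
                "pdi_overall_score": scores,
                "outlier": is_outlier,
            }
        ),
        config=config,
        latent_rho=rho_l,
    )
    return trials, pdi, truth


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False, float_format="%.3f")


def write_pdi(pdi: pd.DataFrame, path: str | Path) -> None:
    pdi.to_csv(path, index=False)
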