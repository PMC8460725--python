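import dataclasses

import pandas as pd
import pytest
from hypothesis import settings

from clockbind import SimulationConfig, build_summaries, simulate_cohort

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def noise_free_config(**overrides) -> SimulationConfig:
    """Deterministic generator: no aiming noise, no carryover, no drift."""
    base = dict(
        aim_sd=0.0,
        aim_bias=0.0,
        carryover_into_ao=0.0,
        carryover_into_as=0.0,
        drift_slope=0.0,
        binding_sd=0.0,
        seed=7,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition cohort shared across read-only tests."""
    cfg = SimulationConfig(seed=11)
    trials, pdi, truth = simulate_cohort(cfg)
    summaries = build_summaries(trials)
    return cfg, trials, pdi, truth, summaries


@pytest.fixture()
def tiny_trials() -> pd.DataFrame:
    """One participant, hand-written series: AO perceived [10, 20, 30],
    AS perceived [10, 20, 30, 800]."""
    rows = []
    t = 10_000.0
    for cond, perceived in (("AO", [10, 20, 30]), ("AS", [10, 20, 30, 800])):
        for i, p in enumerate(perceived, 1):
            t += 5000.0
            rows.append(
                {
                    "participant_id": "P1",
                    "order_group": "AO-AS",
                    "condition": cond,
                    "trial_index": i,
                    "at12_index": i,
                    "t_press_ms": t - p,
                    "t_twelve_ms": t,
                    "response": "at",
                }
            )
    df = pd.DataFrame(rows)
    df["at12_index"] = df["at12_index"].astype("Int64")
    return df


def replace(cfg: SimulationConfig, **kw) -> SimulationConfig:
    return dataclasses.replace(cfg, **kw)


def rng_seeds(n: int, start: int = 0) -> range:
    return range(start, start + n)
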