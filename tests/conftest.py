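import numpy as np
import pandas as pd
import pytest

from gidiet.config import SimulationConfig
from gidiet.pipeline import build_analytic_cohort
from gidiet.simulate import simulate_dataset


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    # higher event rate than the default so small-cohort model fits converge
    return SimulationConfig(n_participants=2500, seed=11, baseline_scale=90.0)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def built_small(small_cfg, small_dataset):
    return build_analytic_cohort(small_dataset, cfg=small_cfg)


@pytest.fixture(scope="session")
def small_cohort(built_small) -> pd.DataFrame:
    return built_small["cohort"]


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240521)


def make_mean_intake(rng: np.random.Generator, n: int = 60) -> pd.DataFrame:
    """Random per-participant mean intake table covering every component."""
    from gidiet.simulate import INTAKE_DISTRIBUTIONS

    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    df["sex"] = rng.choice(["female", "male"], size=n)
    for comp in INTAKE_DISTRIBUTIONS:
        vals = rng.gamma(1.5, 30.0, size=n)
        vals[rng.random(n) < 0.3] = 0.0
        df[comp] = vals
    df["total_energy_kcal"] = rng.normal(2000, 300, size=n)
    df["fat_energy_fraction"] = rng.uniform(0.15, 0.55, size=n)
    df["n_recalls"] = rng.integers(1, 5, size=n)
    return df
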