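import dataclasses

import numpy as np
import pandas as pd
import pytest

from droughtsoc.model import ModelParams
from droughtsoc.pipeline import RunConfig, run_experiment
from droughtsoc.profile import (
    CLOCAENOG_LAYER_FC_MM,
    clocaenog_horizons,
    discretize_profile,
    layer_capacities,
)


@pytest.fixture(scope="session")
def horizons():
    return clocaenog_horizons()


@pytest.fixture(scope="session")
def site_layers(horizons):
    """The six site layers with the prescribed water capacities."""
    layers = discretize_profile(horizons, 5.0)
    return layer_capacities(layers, "prescribed", CLOCAENOG_LAYER_FC_MM)


@pytest.fixture()
def params():
    return ModelParams()


def constant_forcing(n_months: int, p: float, temp: float, pet: float) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "year": np.repeat(np.arange((n_months + 11) // 12), 12)[:n_months],
            "month": np.tile(np.arange(1, 13), (n_months + 11) // 12)[:n_months],
            "P_mm": p,
            "T_C": temp,
            "PET_mm": pet,
        }
    )


@pytest.fixture(scope="session")
def experiment():
    """Full seeded 192-year experiment over all four drought scenarios."""
    cfg = RunConfig(seed=42)
    cfg.synth = dataclasses.replace(cfg.synth, seed=42)
    return cfg, run_experiment(cfg)
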