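import numpy as np
import pandas as pd
import pytest

from coordflux import ScenarioConfig, simulate_condition_series
from coordflux.model import Metabolite, Reaction, StoichiometricModel
from coordflux.synth import build_toy_network


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_network()


@pytest.fixture(scope="session")
def zero_noise_dataset():
    cfg = ScenarioConfig(seed=11)
    cfg.noise = cfg.noise.zeroed()
    return simulate_condition_series(cfg)


@pytest.fixture(scope="session")
def noisy_dataset():
    return simulate_condition_series(ScenarioConfig(seed=11))


@pytest.fixture()
def branch_model():
    """The worked two-branch LP fixture: uptake split 80/20 between an
    ATP-producing branch and a secretion branch."""
    mets = {
        "a": Metabolite("a"),
        "b": Metabolite("b"),
        "atp": Metabolite("atp"),
    }
    rxns = {
        "EX_in": Reaction("EX_in", {"a": -1.0}, -10.5, -9.5, is_exchange=True),
        "BR_A": Reaction("BR_A", {"a": -1.0, "atp": 1.0}, 0.0, 1000.0),
        "BR_B": Reaction("BR_B", {"a": -1.0, "b": 1.0}, 0.0, 1000.0),
        "EX_b": Reaction("EX_b", {"b": -1.0}, 1.8, 2.2, is_exchange=True),
        "ATPM": Reaction("ATPM", {"atp": -1.0}, 0.0, 1000.0),
    }
    return StoichiometricModel(mets, rxns, atp_maintenance_id="ATPM",
                               biomass_id="BR_B")


def model_bounds(model):
    return {rid: (r.lower_bound, r.upper_bound) for rid, r in model.reactions.items()}
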