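"""Shared fixtures: a simulated multi-census stand with known truth."""

import numpy as np
import pandas as pd
import pytest

import neighgrowth as ng
from neighgrowth.model import HierarchicalGrowthModel, ModelData


@pytest.fixture(scope="session")
def stand_cfg():
    return ng.StandConfig(seed=42)


@pytest.fixture(scope="session")
def sim(stand_cfg):
    """Full forward simulation at the default study conditions."""
    stand = ng.generate_stand(stand_cfg)
    traits = ng.generate_traits(stand_cfg.n_species, seed=43)
    climate = ng.generate_climate(ng.ClimateGenConfig(seed=44))
    truth = ng.SimulationTruth()
    records, truth_log = ng.simulate_growth(
        stand, traits, climate, truth, n_intervals=5,
        plot_side=stand_cfg.plot_side, seed=45)
    return {"config": stand_cfg, "stand": stand, "traits": traits,
            "climate": climate, "truth": truth, "records": records,
            "truth_log": truth_log}


@pytest.fixture(scope="session")
def bundle(sim):
    """End-to-end prepared inputs from the simulated censuses."""
    return ng.prepare_inputs(sim["records"], sim["traits"], sim["climate"],
                             baseline=(1991, 2021),
                             plot_side=sim["config"].plot_side)


@pytest.fixture(scope="session")
def fitted(sim):
    """A small but real posterior fit on the simulator's stored design."""
    data = ModelData.from_frame(sim["truth_log"]["design"])
    model = HierarchicalGrowthModel(chains=2, iterations=400, warmup=200,
                                    seed=7).fit(data)
    return {"model": model, "fit": model.posterior_, "data": data}


@pytest.fixture()
def tiny_census():
    """Four-census record of three trees for arithmetic-level tests."""
    rows = []
    spec = {
        "a": [(1991, 10.0, "alive"), (1993, 12.0, "alive"), (1995, 12.0, "alive")],
        "b": [(1991, 20.0, "alive"), (1993, 21.0, "alive"), (1995, 21.5, "dead")],
        "c": [(1991, 30.0, "alive"), (1994, 31.0, "alive")],
    }
    for tree, entries in spec.items():
        for year, dbh, status in entries:
            rows.append({"tree_id": tree, "plot_id": "p01", "species_id": "s1",
                         "x_m": 1.0, "y_m": 1.0, "census_year": year,
                         "dbh_cm": dbh, "status": status})
    return pd.DataFrame(rows)
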