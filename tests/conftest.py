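import dataclasses

import pandas as pd
import pytest

from active_travel_hia import MileageAnchors, RunConfig, generate_inputs, run_analysis


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def default_inputs(default_config):
    return generate_inputs(default_config)


@pytest.fixture(scope="session")
def default_result(default_config, default_inputs):
    """Central-bound run of the default synthetic scenario, shared across tests."""
    return run_analysis(default_inputs, default_config)


@pytest.fixture(scope="session")
def zero_mileage_config(default_config):
    anchors = MileageAnchors(walk=((2021, 0.0),), cycle=((2021, 0.0),),
                             ebike_share=((2021, 0.0),))
    return dataclasses.replace(
        default_config,
        synth=dataclasses.replace(default_config.synth, anchors=anchors))


def toy_demography(years, populations, qs, les=None):
    """Long demography frame from per-age vectors repeated over years."""
    rows = []
    for year in years:
        for age, (pop, q) in enumerate(zip(populations, qs)):
            rows.append({
                "year": year, "age": age, "population": float(pop),
                "mortality_q": float(q),
                "residual_le": float(les[age]) if les is not None else 1.0,
            })
    return pd.DataFrame(rows)
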