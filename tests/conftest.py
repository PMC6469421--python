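import logging
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from hyperblup.simulate import SimConfig, simulate_dataset

logging.getLogger("hyperblup").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Two cycles x two treatments, small everything: fast end-to-end runs."""
    return replace(
        SimConfig(),
        n_cycles=2,
        treatments=("Optimal Bed", "Heat"),
        n_founders=12,
        n_families=12,
        n_trials=2,
        n_markers=80,
        n_bands=10,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    return simulate_dataset(tiny_config, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_phenotypes(n_lines=4, site_years=(("2013-14", "Heat"),)):
    """Minimal valid phenotype frame for parser tests."""
    rows = []
    for cyc, treat in site_years:
        for i in range(n_lines):
            rows.append(
                {
                    "plot_id": f"{cyc}|{treat}|p{i}",
                    "line_id": f"L{i}",
                    "cycle": cyc,
                    "treatment": treat,
                    "trial": 1,
                    "replicate": 1,
                    "block": 1 + i % 2,
                    "gy": 4.0 + 0.1 * i,
                    "lodging": 0.0,
                    "dthd": 80.0,
                    "dtmt": 115.0,
                }
            )
    return pd.DataFrame(rows)
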