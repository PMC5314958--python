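import numpy as np
import pandas as pd
import pytest

import protgrad as pg


@pytest.fixture(scope="session")
def fraction_world():
    """Standard 5,000-cell world under the fraction-representative regime."""
    return pg.filter_cells(pg.generate_world(pg.WorldConfig(seed=11, regime="fraction")))


@pytest.fixture(scope="session")
def opportunistic_world():
    """Small world with isolation planted as the dominant protection driver."""
    cfg = pg.WorldConfig(
        seed=3,
        regime="opportunistic",
        effect_sizes={"isolation": 2.0, "population": 1.0, "tourism": 0.5},
        lat_range=(-10.0, 2.5),
        lon_range=(0.0, 12.5),
    )
    return pg.filter_cells(pg.generate_world(cfg))


@pytest.fixture
def hand_cells():
    """Four cells along one gradient with known per-class aggregates."""
    return pd.DataFrame(
        {
            "cell_id": ["a", "b", "c", "d"],
            "lat": [0.25, 0.75, 1.25, 1.75],
            "lon": [0.25, 0.25, 0.25, 0.25],
            "cell_area_km2": [100.0, 100.0, 200.0, 100.0],
            "terrestrial_fraction": [1.0, 1.0, 1.0, 1.0],
            "protected_fraction": [0.1, 0.3, 0.1, 0.0],
            "region": ["r1", "r1", "r2", "r2"],
            "v": [1.0, 1.4, 2.2, 3.0],
        }
    )


def make_cells(n, rng, **overrides):
    """Random but valid cell table for property-style checks."""
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(n)],
            "lat": rng.uniform(-60, 60, n),
            "lon": rng.uniform(-180, 180, n),
            "cell_area_km2": rng.uniform(500, 3000, n),
            "terrestrial_fraction": rng.uniform(0.05, 1.0, n),
            "protected_fraction": rng.uniform(0.0, 1.0, n),
            "region": rng.choice(["r1", "r2", "r3"], n),
            "v": rng.lognormal(1.0, 0.8, n),
        }
    )
    for key, value in overrides.items():
        df[key] = value
    return df
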