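import numpy as np
import pandas as pd
import pytest

from altishift.simulate import SimulationConfig, simulate_bundle


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """One synthetic study shared across read-only tests."""
    return simulate_bundle(default_config)


@pytest.fixture()
def tiny_counts():
    """Hand-written count table: 1 grid, 2 points, 2 species, both periods."""
    rows = []
    for point, alt in (("p1", 420.0), ("p2", 610.0)):
        for year in (1999, 2001, 2015, 2016):
            for sp, c in (("sp_a", 2), ("sp_b", 0)):
                rows.append(dict(country="SWE", grid_id="g1", point_id=point,
                                 longitude=15.0, latitude=64.0, altitude=alt,
                                 year=year, species=sp, count=c))
    return pd.DataFrame(rows)
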