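import numpy as np
import pytest

from manglift import CommunityTable, SampleFrame, SimConfig, simulate


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """Scaled-down study design used across tests (fast, same structure)."""
    kwargs = dict(
        n_sites=3,
        site_names=("LD", "ZZ", "FG"),
        latitudes=(18.44, 21.62, 24.39),
        longitudes=(108.95, 108.24, 117.92),
        n_plots_per_site=3,
        universe_size=400,
        pool_sizes={"NS": 120, "RS": 90, "RE": 60, "LE": 40},
        depth=2000,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(small_sim_config(seed=7))


@pytest.fixture()
def toy_table() -> CommunityTable:
    counts = np.array(
        [
            [6, 2, 0, 1],
            [2, 2, 4, 0],
            [0, 5, 5, 3],
        ]
    )
    return CommunityTable(["s1", "s2", "s3"], ["a1", "a2", "a3", "a4"], counts)


@pytest.fixture()
def toy_samples() -> SampleFrame:
    import pandas as pd

    rows = []
    for comp in ("NS", "RS", "RE", "LE"):
        for plot in ("P1", "P2"):
            rows.append(
                {
                    "sample_id": f"X_{plot}_{comp}",
                    "site": "X",
                    "compartment": comp,
                    "latitude": 20.0,
                    "longitude": 110.0,
                    "plot": plot,
                }
            )
    return SampleFrame(pd.DataFrame(rows))
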