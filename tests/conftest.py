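import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_lineage():
    """One 64-tip recorded lineage at the default study conditions."""
    from tapelineage import SimConfig, simulate_lineage_recording

    cfg = SimConfig(seed=0, n_generations=6)
    return simulate_lineage_recording(cfg), cfg


@pytest.fixture(scope="session")
def small_capture(small_lineage):
    from tapelineage import simulate_capture

    lin, cfg = small_lineage
    return simulate_capture(lin, cfg)


def obs_to_true_matrix(obs: pd.DataFrame) -> pd.DataFrame:
    """Cell x locus matrix from observations using the true locus labels."""
    from tapelineage.tape_io import pattern_of_row

    obs = obs[obs["true_locus"] >= 0]
    data = {}
    for li, grp in obs.groupby("true_locus"):
        data[f"L{li}"] = {
            r.cell_id: pattern_of_row(r) for _, r in grp.iterrows()
        }
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def true_matrix(small_capture):
    return obs_to_true_matrix(small_capture)
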