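import numpy as np
import pandas as pd
import pytest

from twinmet import SimulationConfig, simulate_dataset
from twinmet.containers import FeatureMatrix


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced-scale study: fast, but preserves every structural element."""
    return SimulationConfig(
        n_concordant_low_pairs=60, n_concordant_high_pairs=40,
        n_discordant_pairs=40, n_control_pairs=25, n_clinical=40,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def default_dataset():
    """Full design-scale dataset, shared across the heavier tests."""
    return simulate_dataset(SimulationConfig(seed=2024))


def make_matrix(values: np.ndarray, panel: str = "amines",
                lods=None, below=None, stage: str = "raw",
                feature_names=None) -> FeatureMatrix:
    """Hand-build a FeatureMatrix from a dense array (test helper)."""
    n, k = values.shape
    cols = feature_names or [f"f{j}" for j in range(k)]
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    vals = pd.DataFrame(values, index=idx, columns=cols)
    meta = pd.DataFrame({"panel": [panel] * k,
                         "lod": lods if lods is not None else [np.nan] * k},
                        index=pd.Index(cols, name="feature_id"))
    below_df = (pd.DataFrame(below, index=idx, columns=cols)
                if below is not None else None)
    return FeatureMatrix(values=vals, feature_meta=meta, below_lod=below_df,
                         stage=stage)
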