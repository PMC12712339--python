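import numpy as np
import pandas as pd
import pytest

from ecmet import io
from ecmet.synthetic import SimulationConfig, gen_omics_matrix


@pytest.fixture(scope="session")
def two_day_dataset():
    """4 cell types x days {2,5} x 3 reps with planted state and bed markers."""
    cfg = SimulationConfig(
        n_features=500, days=(2, 5), frac_state_markers=0.1,
        frac_bed_markers=0.1, effect_size_log2=1.5, seed=42,
    )
    return (cfg,) + gen_omics_matrix(cfg)


@pytest.fixture
def toy_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0], [3.0, np.nan]],
        index=["f1", "f2"],
        columns=["s1", "s2"],
    )
    return io.OmicsMatrix(df)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
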