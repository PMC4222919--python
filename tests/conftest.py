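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


@pytest.fixture
def tiny_matrix():
    """Three individuals, two plots, two loci, one missing call."""
    from divlink import BinaryMarkerMatrix

    meta = pd.DataFrame(
        {
            "individual_id": ["a", "b", "c"],
            "species": ["Picea"] * 3,
            "plot": ["P1", "P1", "P2"],
        }
    )
    calls = pd.DataFrame(
        {"L1": [1.0, 0.0, 1.0], "L2": [0.0, np.nan, 1.0]}
    )
    return BinaryMarkerMatrix(meta, calls)


def random_marker_matrix(rng, n_ind=12, n_loci=5, n_plots=3, missing_rate=0.1):
    from divlink import BinaryMarkerMatrix

    meta = pd.DataFrame(
        {
            "individual_id": [f"i{k}" for k in range(n_ind)],
            "species": ["Sp"] * n_ind,
            "plot": [f"P{k % n_plots + 1}" for k in range(n_ind)],
        }
    )
    calls = rng.integers(0, 2, size=(n_ind, n_loci)).astype(float)
    mask = rng.random((n_ind, n_loci)) < missing_rate
    calls[mask] = np.nan
    return BinaryMarkerMatrix(
        meta, pd.DataFrame(calls, columns=[f"L{j + 1}" for j in range(n_loci)])
    )
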