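import numpy as np
import pytest

from slipfret.synthetic import KineticScheme, build_preset, simulate_traces


@pytest.fixture(scope="session")
def two_state_scheme():
    """Symmetric 2-state chain, k12 = k21 = 1/s, no bleaching, no offsets."""
    q = np.array([[-1.0, 1.0], [1.0, -1.0]])
    return KineticScheme(name="sym2", rate_matrix=q,
                         emission_mean=np.array([0.2, 0.8]),
                         emission_sd=np.array([0.05, 0.05]),
                         bleach_rate=0.0, level_offset_sd=0.0)


@pytest.fixture(scope="session")
def hairpin_traces():
    """Small hairpin2 sample reused by several tests."""
    scheme = build_preset("hairpin2")
    return simulate_traces(scheme, n_traces=20, seed=42)


@pytest.fixture(scope="session")
def cag10_scheme():
    return build_preset("cag10")
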