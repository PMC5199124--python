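import numpy as np
import pytest

from castates.model import StimulusProtocol
from castates.pipeline import preprocess_cell
from castates.fitting import ScoreConfig
from castates.synthetic import (NoiseSpec, default_regimes, render_traces,
                                sample_population)

N = 17


@pytest.fixture(scope="session")
def short_protocol():
    return StimulusProtocol(atp=10.0, t_on=30.0, duration=270.0, dt_out=2.0)


@pytest.fixture(scope="session")
def regimes():
    return default_regimes()


@pytest.fixture(scope="session")
def synthetic_cell(short_protocol, regimes):
    """One strong-positive synthetic cell: (raw trace, true theta)."""
    rng = np.random.default_rng(123)
    thetas, labels = sample_population([regimes[0]], 1, rng)
    noise = NoiseSpec(sigma_meas=0.02, hf_amp=0.02, seed=5)
    traces, used = render_traces(thetas, short_protocol, noise)
    return traces[0], used[0]


@pytest.fixture(scope="session")
def processed_cell(synthetic_cell):
    """(processed trace, epsilon_final) for the synthetic cell."""
    trace, _ = synthetic_cell
    return preprocess_cell(trace, cutoff=0.1, score_cfg=ScoreConfig())
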