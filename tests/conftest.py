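import numpy as np
import pytest

from alleledyn import mixture_quantify as mq
from alleledyn.model_fit import estimate_delays
from alleledyn.synthetic_data import MovieSpec, generate_movie


@pytest.fixture(scope="session")
def default_movie():
    """One study-condition synthetic movie, shared across tests."""
    spec = MovieSpec(rng_seed=42)
    tracks, truth = generate_movie(spec)
    return spec, tracks, truth


@pytest.fixture(scope="session")
def quantified_movie(default_movie):
    """Mixture-quantified fraction series for the shared movie."""
    spec, tracks, truth = default_movie
    anchor = mq.fit_negative_anchor(tracks[tracks.time_h < 10])
    series = mq.fractions_over_time(tracks, 5.0, anchor)
    return spec, tracks, truth, anchor, series


@pytest.fixture(scope="session")
def movie_delays(quantified_movie):
    _, _, _, _, series = quantified_movie
    return estimate_delays(series)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
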