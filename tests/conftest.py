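import numpy as np
import pytest

from fatrack import AnalysisConfig, FrameImage, run_pipeline, score_against_truth
from fatrack.simulate import simulate_stationary


@pytest.fixture(scope="session")
def default_config():
    return AnalysisConfig(seed=0)


@pytest.fixture(scope="session")
def small_stationary():
    """A compact stationary movie (bright, well-detectable grid) with its
    pipeline result and truth scores; shared across tracking/simulation
    tests."""
    cfg = AnalysisConfig(seed=0)
    movie = simulate_stationary(
        radii=(1.5, 3.0, 5.0),
        intensities=(0.21, 0.35, 0.47),
        lifespan_frames=10,
        seed=0,
        config=cfg,
    )
    result = run_pipeline(movie.frames, config=cfg)
    scores = score_against_truth(movie, result.lineages, result.decompositions)
    return movie, result, scores


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_frame(pixels, **kwargs) -> FrameImage:
    return FrameImage(np.asarray(pixels, dtype=float), **kwargs)
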