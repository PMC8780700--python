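import numpy as np
import pytest

from headgest import hmm, segmentation, synth


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def clean_session():
    """Noise-free 8-reach session: the simplest end-to-end input."""
    cfg = synth.SessionConfig(n_valid_reaches=8, noise_sigma=0.0, seed=11)
    return synth.gen_session(cfg)


@pytest.fixture(scope="session")
def noisy_session():
    """Default-noise session with distractor movements and ground truth."""
    cfg = synth.SessionConfig(
        n_valid_reaches=12, n_invalid_movements=12, invalid_kind="orthogonal", seed=5
    )
    return synth.gen_session(cfg)


@pytest.fixture(scope="session")
def noisy_segments(noisy_session):
    return segmentation.segment_trajectory(noisy_session.observed)


def make_segment(t, x, y, vx, vy, start=0):
    """Segment helper with the peak at the maximum speed sample."""
    eps = np.hypot(np.asarray(vx, float), np.asarray(vy, float))
    peak = start + int(np.argmax(eps))
    end = start + len(t) - 1
    peak = min(max(peak, start + 1), end - 1)
    return segmentation.Segment(
        start=start, peak=peak, end=end,
        t=np.asarray(t, float), x=np.asarray(x, float), y=np.asarray(y, float),
        vx=np.asarray(vx, float), vy=np.asarray(vy, float),
    )


@pytest.fixture
def toy_left_right_hmm():
    """Well-separated 4-state left-right Gaussian HMM used as a data generator."""
    return hmm.GaussianHmm(
        startprob=np.array([1.0, 0, 0, 0]),
        transmat=np.array(
            [[0.85, 0.15, 0, 0], [0, 0.85, 0.15, 0], [0, 0, 0.85, 0.15], [0, 0, 0, 1.0]]
        ),
        means=np.array([[0.0, 0.0], [40.0, 8.0], [80.0, -8.0], [120.0, 0.0]]),
        covars=np.array([np.eye(2) * 4.0] * 4),
    )
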