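import numpy as np
import pytest

from vabtrack import SimParams, simulate_session, tracks_from_arrays
from vabtrack.trackio import MARKERS


def make_tracks(positions, fps=20.0, pixels_per_cm=1.0, likelihoods=None):
    """TrackSet from explicit per-marker pixel positions.

    ``positions`` maps marker role -> (n, 2) array; missing markers default
    to the head-center trajectory (rod defaults to the origin).
    """
    hc = np.asarray(positions["head_center"], float)
    n = len(hc)
    full = {}
    for m in MARKERS:
        if m in positions:
            full[m] = np.asarray(positions[m], float)
        elif m == "rod":
            full[m] = np.zeros((n, 2))
        else:
            full[m] = hc.copy()
    lik = likelihoods or {}
    lik_full = {m: np.asarray(lik.get(m, np.ones(n)), float) for m in MARKERS}
    return tracks_from_arrays(full, lik_full, fps=fps,
                              pixels_per_cm=pixels_per_cm)


@pytest.fixture(scope="session")
def clean_session():
    """One noise-free, dropout-free simulated session with its ground truth."""
    params = SimParams(seed=11, noise_sd_px=0.0, dropout_rate=0.0)
    return simulate_session(params)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
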