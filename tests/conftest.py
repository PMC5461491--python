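import numpy as np
import pandas as pd
import pytest

import antsigns as A


@pytest.fixture(scope="session")
def square_geometry():
    """Symmetric four-chamber nest split into quadrants, entrance at centre."""
    return A.data_io.square_nest()


@pytest.fixture(scope="session")
def short_tracks(square_geometry):
    """A small seeded tracking table (20 ants, 5 min at 8 Hz) plus homes."""
    tracks, homes = A.simulate_tracks(
        square_geometry, n_ants=20, fidelity=0.71, duration=300.0, rate=8.0,
        seed=1, return_homes=True,
    )
    return tracks, homes


@pytest.fixture(scope="session")
def default_features():
    """Features from 19 default-parameter synthetic experiments (seed 3)."""
    peaks, labels = A.simulate_chromatograms(19, seed=3)
    return A.make_features(peaks, labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_peaks():
    """The four-peak hand example: C17:5, C19:3, C21:2, C25:10 in one chamber."""
    frame = pd.DataFrame(
        {
            "experiment_id": "e1",
            "chamber_id": "c1",
            "compound_id": ["C17", "C19", "C21", "C25"],
            "retention_min": [17.0, 19.0, 21.0, 25.0],
            "area": [5.0, 3.0, 2.0, 10.0],
        }
    )
    return A.PeakTable(frame=frame)
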