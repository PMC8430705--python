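import numpy as np
import pytest

from cellmotility import Track, TrackSet


def make_track(positions, dt=30.0, cell_id="c0", line_id="L0",
               group="control", substrate="TCP", concentration=0.0,
               frames=None):
    return Track(cell_id=cell_id, line_id=line_id, group=group,
                 substrate=substrate, concentration=concentration,
                 positions=np.asarray(positions, dtype=float), dt=dt,
                 frames=frames)


@pytest.fixture
def track_factory():
    return make_track


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture
def random_walk_track(rng):
    """A 48-frame uncorrelated random walk, unit step scale."""
    steps = rng.standard_normal((47, 2))
    pos = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
    return make_track(pos)


@pytest.fixture
def ballistic_track():
    """Constant-velocity trajectory: 48 frames at (3, 4)/5 µm per frame."""
    k = np.arange(48)[:, None]
    return make_track(k * np.array([0.6, 0.8]))


@pytest.fixture
def toy_trackset(track_factory):
    """Two complete lines x two cells plus one truncated cell, 48 frames."""
    tracks = []
    rng = np.random.default_rng(5)
    for line, group in (("pat01", "patient"), ("con01", "control")):
        for c in range(2):
            pos = np.cumsum(rng.standard_normal((48, 2)), axis=0)
            tracks.append(track_factory(pos, cell_id=f"{line}_c{c}",
                                        line_id=line, group=group))
    short = np.cumsum(rng.standard_normal((30, 2)), axis=0)
    tracks.append(track_factory(short, cell_id="pat01_short", line_id="pat01",
                                group="patient"))
    return TrackSet(tracks=tracks, dt=30.0, n_frames_expected=48)
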