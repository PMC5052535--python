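import numpy as np
import pytest

from tramqc import Track, TrackSet


def make_track(cell_id, T=10, x=None, y=None, times=None, **features):
    """Build a Track with sensible defaults for brevity in tests."""
    times = np.arange(T) if times is None else np.asarray(times)
    T = len(times)
    x = np.zeros(T) if x is None else np.asarray(x, dtype=float)
    y = np.zeros(T) if y is None else np.asarray(y, dtype=float)
    feats = {k: np.asarray(v, dtype=float) for k, v in features.items()}
    return Track(cell_id=cell_id, times=times, x=x, y=y, features=feats)


@pytest.fixture
def make_trackset():
    def _make(tracks, dt_minutes=1.0, t_expected=None, **metadata):
        if t_expected is None:
            t_expected = max(len(tr) for tr in tracks)
        return TrackSet(
            tracks=list(tracks),
            dt_minutes=dt_minutes,
            t_expected=t_expected,
            metadata=metadata,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
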