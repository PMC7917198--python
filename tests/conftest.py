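import numpy as np
import pytest

from woundtrack import Track, WoundFrame


@pytest.fixture
def vertical_wound() -> WoundFrame:
    """Vertical wound edge at x = 0; AP axis points woundward (−x)."""
    return WoundFrame(
        wound_edge=np.array([[0.0, -300.0], [0.0, 300.0]]),
        ap_axis=np.array([-1.0, 0.0]),
    )


def make_track(positions, track_id="t", frame_interval=1.0, frames=None, **kwargs) -> Track:
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Track(
        track_id=track_id,
        frames=np.asarray(frames),
        positions=positions,
        frame_interval=frame_interval,
        **kwargs,
    )


def random_track(rng, n_frames=12, step_scale=5.0, **kwargs) -> Track:
    steps = rng.normal(0.0, step_scale, size=(n_frames - 1, 2))
    pos = np.vstack([rng.uniform(-100, 400, size=2), np.cumsum(steps, axis=0)])
    pos[1:] += pos[0]
    return make_track(pos, **kwargs)
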