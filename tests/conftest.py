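import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from migrochip.geometry import PillarGeometry
from migrochip.tracks import Track

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_track(points, dt=3.0, track_id=0):
    """Track from a list of (x, y) positions at a fixed cadence."""
    pts = np.asarray(points, dtype=float)
    return Track(track_id=track_id, t=np.arange(len(pts)) * dt, xy=pts)


@pytest.fixture
def open_arena():
    """A pillar-free arena large enough that walls are never touched."""
    return PillarGeometry(pillar_diameter=0.0, arena_size=(1e6, 1e6))


@pytest.fixture
def pillar_forest():
    return PillarGeometry()  # 10 µm pillars, 30 µm pitch, 300x300 µm arena
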