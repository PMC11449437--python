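import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hydrataxis import ChamberGeometry, PoseTrack

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def geometry() -> ChamberGeometry:
    return ChamberGeometry()


def make_track(
    foot,
    *,
    animal_id: str = "a0",
    times=None,
    head_offset=(1.0, 0.0),
    group: str = "unknown",
    confidence=None,
) -> PoseTrack:
    """Build a minimal valid PoseTrack around a foot path."""
    foot = np.asarray(foot, dtype=float)
    n = foot.shape[0]
    if times is None:
        times = np.arange(n, dtype=float) * 20.0
    head = foot + np.asarray(head_offset, dtype=float)
    body = foot + 0.5 * np.asarray(head_offset, dtype=float)
    if confidence is None:
        confidence = np.full((n, 3), 0.99)
    return PoseTrack(
        animal_id=animal_id,
        times=np.asarray(times, dtype=float),
        foot=foot,
        body=body,
        head=head,
        confidence=confidence,
        group_label=group,
    )


@pytest.fixture
def track_factory():
    return make_track
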