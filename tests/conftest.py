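import hypothesis
import numpy as np
import pytest

from swimquant import PoseTrack, TankGeometry
from swimquant.pose_io import frames_from_arrays

hypothesis.settings.register_profile(
    "swimquant", deadline=None, max_examples=25, derandomize=True
)
hypothesis.settings.load_profile("swimquant")


@pytest.fixture
def geom() -> TankGeometry:
    return TankGeometry(surface_y=20.0, bottom_y=420.0, width_px=600.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_track(
    x,
    y,
    likelihood=None,
    bodyparts=("head", "tail"),
    fps=15.0,
    geometry=None,
    **kwargs,
) -> PoseTrack:
    """Build a PoseTrack from per-frame arrays.

    ``x``/``y`` may be 1-D (replicated across body parts) or
    (n_frames, n_bodyparts).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = np.repeat(x[:, None], len(bodyparts), axis=1)
        y = np.repeat(y[:, None], len(bodyparts), axis=1)
    if likelihood is None:
        likelihood = np.ones_like(x)
    else:
        likelihood = np.asarray(likelihood, dtype=float)
        if likelihood.ndim == 1:
            likelihood = np.repeat(likelihood[:, None], len(bodyparts), axis=1)
    if geometry is None:
        geometry = TankGeometry(surface_y=0.0, bottom_y=1000.0, width_px=1000.0)
    data = frames_from_arrays(bodyparts, x, y, likelihood)
    return PoseTrack(data=data, fps=fps, geometry=geometry, **kwargs)
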