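import numpy as np
import pytest

from radarbp.radar_params import RadarConfig, derive_params
from radarbp.synthetic import (
    DisplacementTrace,
    PulseModelParams,
    SceneParams,
    synth_displacement,
    synth_raw_frames,
)

SPS = 250.0


@pytest.fixture(scope="session")
def config():
    return RadarConfig()


@pytest.fixture(scope="session")
def derived(config):
    return derive_params(config)


@pytest.fixture(scope="session")
def pulse_trace():
    """30 s of the default 72 bpm, 50 um pulse, noise-free."""
    return synth_displacement(PulseModelParams(), duration=30.0, rate=SPS, seed=0)


def make_frames(
    config,
    doa_deg=0.0,
    displacement=None,
    noise_std=0.0,
    dc=0.4 + 0.2j,
    seed=0,
    n_chirps=None,
    **scene_kwargs,
):
    """Frames with a static clutter offset and optional displacement/noise."""
    if displacement is None:
        n = n_chirps or config.n_chirps_per_frame
        displacement = DisplacementTrace(samples=np.zeros(n), rate=1.0 / config.prt)
    scene = SceneParams(
        doa_deg=doa_deg, noise_std=noise_std, dc_offsets=(dc,) * 3, seed=seed,
        **scene_kwargs,
    )
    return synth_raw_frames(config, scene, displacement)


@pytest.fixture(scope="session")
def frames_factory(config):
    def _make(**kwargs):
        return make_frames(config, **kwargs)

    return _make
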