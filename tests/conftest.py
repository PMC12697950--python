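import numpy as np
import pytest

from seatag.aoa import default_l_array
from seatag.chain import AudioChainSpec


@pytest.fixture(scope="session")
def chain_spec() -> AudioChainSpec:
    """Deployed acquisition chain: -205 dB re FS/uPa, 16-bit, 96 kSPS, 3 ch."""
    return AudioChainSpec()


@pytest.fixture(scope="session")
def geometry():
    """Default 3-element L array, 0.125 m arms, 1491.2 m/s, 96 kSPS."""
    return default_l_array()


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One small synthetic deployment bundle shared across I/O and CLI tests."""
    from seatag.synth import DiveProfileSpec, synth_deployment_bundle

    outdir = tmp_path_factory.mktemp("bundle") / "deployment"
    synth_deployment_bundle(
        outdir,
        seed=11,
        dive_spec=DiveProfileSpec(
            n_dives=1, mean_duration_s=900.0, sd_duration_s=120.0,
            mean_max_depth_m=200.0, sd_max_depth_m=40.0, surface_interval_s=120.0,
            seed=11,
        ),
        audio_window_s=10.0,
        click_rate_per_min=60.0,
    )
    return outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
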