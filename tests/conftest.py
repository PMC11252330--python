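import numpy as np
import pytest

from sowpose import (
    GaitParams,
    InstancePose,
    MetricConfig,
    get_skeleton,
)


@pytest.fixture(scope="session")
def lateral_6():
    return get_skeleton("lateral_6")


@pytest.fixture(scope="session")
def lateral_13():
    return get_skeleton("lateral_13")


@pytest.fixture(scope="session")
def dorsal_10():
    return get_skeleton("dorsal_10")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fixed_cfg():
    """Fixed-scale config used by the closed-form oracles."""
    return MetricConfig(scale_mode="fixed", fixed_scale=10.0, k=0.5)


def make_pose(skeleton, coords, visibility=None):
    coords = np.asarray(coords, dtype=float)
    if visibility is None:
        visibility = np.ones(len(skeleton), dtype=bool)
    return InstancePose(skeleton=skeleton, coords=coords, visibility=visibility)


@pytest.fixture
def pose_factory():
    return make_pose


@pytest.fixture
def quiet_params():
    """Noise- and occlusion-free lame gait, convenient for exact checks."""
    def build(score=2, asymmetry=0.4, affected="hind_left", **kw):
        defaults = dict(
            score=score,
            asymmetry=asymmetry,
            affected_limb=affected,
            head_amp=5.0,
            arch_amp=5.0,
            noise_sd=0.0,
            occlusion_prob=0.0,
            view="lateral",
        )
        defaults.update(kw)
        return GaitParams(**defaults)

    return build
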