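import numpy as np
import pytest

from cryoab import (
    AbPose,
    GridGeometry,
    SyntheticSpec,
    UNet3D,
    make_pseudo_template,
    simulate_map,
)
from cryoab.model import ModelConfig
from cryoab.rotations import random_rotation


@pytest.fixture(scope="session")
def fab_template():
    return make_pseudo_template("fab")


@pytest.fixture(scope="session")
def vhh_template():
    return make_pseudo_template("vhh")


@pytest.fixture(scope="session")
def templates(fab_template, vhh_template):
    return {"fab": fab_template, "vhh": vhh_template}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_model():
    """A tiny untrained network (cheap forward passes for contract tests)."""
    return UNet3D(ModelConfig(base_channels=2, init_seed=7))


@pytest.fixture(scope="session")
def simulated_map():
    """One fixed synthetic map with its planted poses."""
    spec = SyntheticSpec(extent=64.0, border=12.0, n_antibodies=2)
    grid, poses = simulate_map(spec, seed=42)
    return spec, grid, poses


def sample_poses(rng, n, geometry: GridGeometry, min_separation=20.0, vhh_fraction=0.3):
    """Random well-separated poses inside a geometry's extent."""
    hi = np.array(geometry.shape) * geometry.cell_size
    poses = []
    while len(poses) < n:
        t = geometry.origin + rng.uniform(4.0, hi - 4.0)
        if all(np.linalg.norm(t - p.translation) >= min_separation for p in poses):
            poses.append(
                AbPose(
                    rotation=random_rotation(rng),
                    translation=t,
                    ab_class="vhh" if rng.random() < vhh_fraction else "fab",
                )
            )
    return poses
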