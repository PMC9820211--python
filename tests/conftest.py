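import numpy as np
import pytest

import knockon as kn


@pytest.fixture(scope="session")
def sitemap():
    return kn.default_sitemap()


@pytest.fixture(scope="session")
def landscape(sitemap):
    return kn.default_landscape(sitemap)


@pytest.fixture
def tiny_traj():
    """Two-frame, one-ion trajectory (dt = 2 fs)."""
    return kn.Trajectory(
        times=np.array([0.0, 0.002]),
        particles=[kn.Particle("K1", "K", np.array([0.5, 0.6]))])


def random_trajectory(rng, n_frames=5, n_particles=3, with_xy=False):
    species = rng.choice(["K", "W", "O", "CL"], size=n_particles)
    particles = []
    for i, sp in enumerate(species):
        kw = {}
        if with_xy:
            kw = {"x": rng.uniform(-2, 2, n_frames),
                  "y": rng.uniform(-2, 2, n_frames)}
        particles.append(kn.Particle(f"p{i}", str(sp),
                                     rng.uniform(-1, 3, n_frames), **kw))
    return kn.Trajectory(np.arange(n_frames) * 0.01, particles, box_z=4.0)
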