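import numpy as np
import pytest

from antsync import SimConfig, run_simulation


@pytest.fixture(scope="session")
def sim_r05():
    """Study-condition synchronous run: N=120, A=100, L=30, R=0.5, 4000 steps."""
    return run_simulation(SimConfig(r_target=0.5, n_steps=4000, seed=0))


@pytest.fixture(scope="session")
def sim_r0():
    """Study-condition asynchronous run: same but R=0."""
    return run_simulation(SimConfig(r_target=0.0, n_steps=4000, seed=0))


@pytest.fixture(scope="session")
def short_sim():
    """Small, fast run for invariant checks."""
    return run_simulation(
        SimConfig(n_agents=40, arena_side=18.0, r_target=0.5, n_steps=400, seed=3)
    )


@pytest.fixture(scope="session")
def rendered_colony():
    """Realistic-scale rendered clip of a synchronous run with ground truth."""
    from antsync.synthetic_data import RenderConfig, render_video

    sim = run_simulation(SimConfig(n_steps=400, seed=7))
    frames, gt = render_video(
        sim, RenderConfig.realistic(seed=7), start=150, stop=390
    )
    return sim, frames, gt


@pytest.fixture(scope="session")
def brood_scene():
    """A brood-pile crop with resting blobs and detouring movers."""
    from antsync.synthetic_data import make_brood_scene

    return make_brood_scene(n_resting=8, n_movers=6, n_frames=60, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
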