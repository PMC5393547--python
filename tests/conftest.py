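import logging

import numpy as np
import pytest
from hypothesis import settings

from planktonssm import synth
from planktonssm.inference import LakeData

logging.getLogger("planktonssm").setLevel(logging.ERROR)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def paper_dataset():
    """One survey-replica synthetic dataset (20 lakes, 4 visits)."""
    return synth.generate_dataset(synth.paper_preset(seed=7))


@pytest.fixture(scope="session")
def paper_frames(paper_dataset):
    return paper_dataset.to_frames()


def make_single_lake_data(rng=None, sigma=0.1, n_times=3):
    """A 1-lake LakeData with known truth, for conditional subproblems."""
    from planktonssm.dynamics import LakeParams, simulate_trajectory
    from planktonssm.params import HyperParams

    if rng is None:
        rng = np.random.default_rng(7)
    truth = HyperParams(
        alpha_c=0.1, beta_c=0.0, alpha_psi=np.log(0.3), beta_psi=0.0,
        m_fish=0.2, m_nofish=0.2, e=0.5, sigma_x=sigma, sigma_y=sigma,
        x1=np.array([1.0]), y1=np.array([0.5]),
    )
    traj = simulate_trajectory(1.0, 0.5, LakeParams(c=0.1, psi=0.3, m=0.2, e=0.5), n_times)
    data = LakeData(
        lake_ids=["A"], fish=np.array([False]), st=np.zeros(1), sp=np.zeros(1),
        obs_x=(traj.x + rng.normal(0, sigma, n_times))[None, :],
        obs_y=(traj.y + rng.normal(0, sigma, n_times))[None, :],
    )
    return data, truth
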