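import numpy as np
import pytest
from hypothesis import settings

from allonet.synth import (LigandSpec, PlantedHbond, SyntheticSpec,
                           generate_trajectory)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def two_state():
    """A 300-frame two-state trajectory: closed then open WPD, ordered then
    disordered α7, two planted bonds with asymmetric occupancies."""
    spec = SyntheticSpec(
        n_frames=300,
        state_schedule=["closed"] * 150 + ["open"] * 150,
        planted_hbonds=[PlantedHbond(28, 64, 0.1, 0.9),
                        PlantedHbond(39, 73, 0.95, 0.95)],
        helicity_schedule=[1.0] * 150 + [0.0] * 150,
        seed=11,
    )
    traj, truth = generate_trajectory(spec)
    return spec, traj, truth


@pytest.fixture(scope="session")
def ligand_run():
    """A ligand-bound trajectory: α site, brief flicker, β site, then
    dissociation at frame 200 (dt = 0.1 ns)."""
    schedule = (["alpha"] * 100 + ["unbound"] * 2 + ["alpha"] * 18
                + ["beta"] * 80 + ["other"] * 40 + ["unbound"] * 60)
    spec = SyntheticSpec(
        n_frames=300,
        state_schedule="open",
        helicity_schedule=0.0,
        ligand=LigandSpec(site_schedule=schedule, dissociation_frame=200),
        seed=23,
    )
    traj, truth = generate_trajectory(spec)
    return spec, traj, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
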