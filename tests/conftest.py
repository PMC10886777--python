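import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def pocket_all_kinds():
    """One pocket with every planted interaction kind always on."""
    import pocketfp as pf

    spec = pf.PocketSpec(
        planted=[
            pf.PlantedInteraction(k, p=1.0)
            for k in ("hbond", "hbond2", "ionic", "hydrophobic",
                      "pi_pi", "pi_cation", "water_bridge")
        ],
        n_frames=4,
        seed=11,
    )
    return pf.gen_pocket_trajectory(spec)
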