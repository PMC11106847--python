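import numpy as np
import pytest

from rtscr.model import RandomThinningSCR
from rtscr.simulate import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def study_scenario():
    """One synthetic survey at the study's conditions (13 otters, ~176 cells)."""
    return generate_scenario(ScenarioConfig(seed=5))


@pytest.fixture(scope="session")
def study_fit(study_scenario):
    """A moderate-length fit of the full model on the study-scale scenario."""
    design, enc, truth = study_scenario
    model = RandomThinningSCR.from_design(design, enc)
    res = model.fit(iterations=6000, burn_in=1500, thin=5, chains=2, seed=3)
    return model, res, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
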