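import numpy as np
import pytest

from kincal import FitProblem, ObservationMap, parse_model
from kincal import synthetic


DECAY_TEXT = """
model decay
  species A = 10
  species B = 0
  param k = 0.1
  deg: A -> B; k*A
end
"""


@pytest.fixture(scope="session")
def decay_model():
    return parse_model(DECAY_TEXT)


@pytest.fixture(scope="session")
def motif_models():
    return synthetic.motif_models()


@pytest.fixture(scope="session")
def smad_models():
    return synthetic.smad_demo_models()


@pytest.fixture(scope="session")
def nf_problem(motif_models):
    """Noise-free calibration problem on the negative-feedback motif."""
    nf = motif_models[0]
    table = synthetic.generate_data(nf, observables=("X", "F"), noise="none")
    obs_map = ObservationMap.uniform(["X", "F"], 100.0)
    return FitProblem(nf, table, obs_map, ["kx", "kdx", "kf"])


@pytest.fixture(scope="session")
def nf_truth(motif_models):
    nf = motif_models[0]
    return {name: nf.parameters[name] for name in ("kx", "kdx", "kf")}


@pytest.fixture
def rng():
    return np.random.default_rng(42)
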