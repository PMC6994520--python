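import warnings

import numpy as np
import pytest

from ebg.headmodel import ElectrodeMontage, build_head_model, fibonacci_sphere
from ebg.montage import default_ebg_montage
from ebg.preproc import preprocess
from ebg.simulate import ScenarioConfig, generate_recording

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*Montage name.*")


@pytest.fixture(scope="session")
def head_model():
    return build_head_model()


@pytest.fixture(scope="session")
def sphere_montage():
    """40-electrode quasi-uniform scalp sampling (no labels semantics)."""
    pts = fibonacci_sphere(40) * 92.0
    return ElectrodeMontage(tuple(f"E{i}" for i in range(40)), pts)


@pytest.fixture(scope="session")
def montage64(head_model):
    return default_ebg_montage(64, head_model)


@pytest.fixture(scope="session")
def montage32(head_model):
    return default_ebg_montage(32, head_model)


@pytest.fixture(scope="session")
def default_session(montage64, head_model):
    """One default Odor/Air session (20 trials per condition)."""
    cfg = ScenarioConfig(n_trials=20, seed=1)
    rec, gt = generate_recording(cfg, montage=montage64, head_model=head_model)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def default_epochs(default_session, montage64):
    _, rec, _ = default_session
    return preprocess(rec, reject=False)
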