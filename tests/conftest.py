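import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom_split():
    """A modest phantom cohort shared by training-dependent tests."""
    from neurotwin import synthgen
    phantoms = synthgen.generate_phantom_dataset(160, tumor_fraction=0.5,
                                                 seed=42)
    return phantoms[:110], phantoms[110:]


@pytest.fixture(scope="session")
def trained_vit(small_phantom_split):
    """A desk-profile patch transformer trained once per session."""
    from neurotwin import vitpp
    train, _ = small_phantom_split
    cfg = vitpp.ViTConfig.profile("desk", epochs=80, seed=3)
    model, history = vitpp.train_vitpp(train, cfg)
    return model, history


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-state FHV cohort built through the full EEG chain."""
    from neurotwin.pipeline import build_state_cohort
    return build_state_cohort(n_per_class=6, windows_per_seq=30, seed=21)
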