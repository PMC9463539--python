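import numpy as np
import pytest

import readernet as rn
from readernet.panel_sim import ReaderProfile, ReaderRole


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_profile():
    def make(reader_id="R", role=ReaderRole.INITIAL):
        return ReaderProfile(reader_id, role, np.eye(5), age_noise_slope=0.0)

    return make


@pytest.fixture
def small_panel():
    """A small but complete simulated panel dataset (deterministic)."""
    return rn.build_panel_dataset(
        n_patients=60,
        images_per_patient_dist={1: 0.9, 2: 0.1},
        n_initial_readers=6,
        n_arbitrators=2,
        seed=11,
        image_size=32,
    )


@pytest.fixture
def tiny_model_spec():
    return rn.ModelSpec(
        backbone="TOY_CNN",
        n_readers=8,
        reader_emb_dim=8,
        toy_channels=(4, 6, 8),
        dropout=0.0,
        use_reader_embeddings=True,
    )
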