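"""Shared fixtures.

The heavy session-scoped fixtures (trained GAN variants, style-transfer
runs) back several end-to-end behavioural tests; they run the package's
standard reduced-scale study conditions from :mod:`emgaug.experiments`.
"""

from __future__ import annotations

import numpy as np
import pytest

from emgaug import experiments
from emgaug.signal import EmgSignal

STUDY_SEED = 0
GENERATE_SEED = 7


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tremor_1s():
    from emgaug.synthdata import TremorParams, synth_tremor
    return synth_tremor(TremorParams(duration=1.0, seed=3))


@pytest.fixture(scope="session")
def tremor_records():
    return experiments.make_tremor_records(seed=1)


@pytest.fixture(scope="session")
def bundle_mbd_ma(tremor_records):
    """4CNN-MBD-MA trained at the reduced study scale (slow)."""
    return experiments.train_variant(tremor_records, "4CNN-MBD-MA",
                                     seed=STUDY_SEED)


@pytest.fixture(scope="session")
def bundle_4cnn(tremor_records):
    return experiments.train_variant(tremor_records, "4CNN", seed=STUDY_SEED)


@pytest.fixture(scope="session")
def bundle_4cnn_mbd(tremor_records):
    return experiments.train_variant(tremor_records, "4CNN-MBD",
                                     seed=STUDY_SEED)


@pytest.fixture(scope="session")
def style_runs(bundle_mbd_ma, tremor_records):
    """Balanced and content-dominant style-transfer runs (slow)."""
    return experiments.style_descent(bundle_mbd_ma, tremor_records,
                                     seed=STUDY_SEED)


@pytest.fixture(scope="session")
def fast_style_run(bundle_mbd_ma, style_runs):
    return experiments.fast_style_study(bundle_mbd_ma, style_runs,
                                        seed=STUDY_SEED)


@pytest.fixture
def tiny_extractor():
    """Small untrained discriminator feature extractor for unit tests."""
    from emgaug import gan
    spec = gan.DiscriminatorSpec(filters=4, final_filters=4, input_len=2000)
    disc = gan.build_discriminator(spec, seed=9)
    return disc.extractor("style")
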