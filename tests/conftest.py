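import numpy as np
import pytest

import nativefc as nf


@pytest.fixture(scope="session")
def small_spec():
    """A desk-scale cohort: 4+4 subjects, 128 volumes."""
    return nf.default_dmn_spec(n_young=4, n_elder=4, n_timepoints=128, seed=7)


@pytest.fixture(scope="session")
def bundle(small_spec):
    """One rendered synthetic subject (young)."""
    return nf.render_subject(small_spec, "young", 3, subject_id="sub-test")


@pytest.fixture(scope="session")
def clean_spec():
    """A spec with every artifact source switched off."""
    return nf.default_dmn_spec(
        n_young=4,
        n_elder=4,
        n_timepoints=128,
        noise_sd=0.0,
        drift_amplitude=0.0,
        resp_band_amplitude=0.0,
        spike_rate=0.0,
        seed=13,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
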