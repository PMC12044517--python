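import numpy as np
import pytest

from rovingnet import meg_synth, rnn_core


@pytest.fixture(scope="session")
def control_templates():
    """Control-group S and D evoked templates on the 138-sample label grid."""
    aef_s = meg_synth.generate_group_aef(meg_synth.CONTROL_PARAMS, "S")
    aef_d = meg_synth.generate_group_aef(meg_synth.CONTROL_PARAMS, "D")
    return aef_s, aef_d


@pytest.fixture(scope="session")
def small_labels(control_templates):
    """A reduced label set (60 replicates per condition) for fast training."""
    aef_s, aef_d = control_templates
    return rnn_core.make_labels(aef_s, aef_d, n_per_condition=60, noise_sd=0.6, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_labels):
    return rnn_core.make_dataset(small_labels, seed=8)


@pytest.fixture(scope="session")
def noiseless_epochs():
    """Noise-free control epochs: every trial equals gain x template."""
    return meg_synth.generate_synthetic_epochs(
        meg_synth.CONTROL_PARAMS,
        n_trials_per_condition=4,
        n_channels=16,
        noise_sd=0.0,
        seed=0,
    )


def zero_model():
    """A model whose every parameter is zero (predicts zero everywhere)."""
    model = rnn_core.init_model(seed=0)
    for p in model.parameters().values():
        p[...] = 0.0
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
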