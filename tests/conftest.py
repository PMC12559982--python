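import numpy as np
import pytest

import calyxstp as cx


@pytest.fixture(scope="session")
def control_blocks():
    """Priming, transient and influx parameters of the control condition."""
    return cx.builtin_condition("control")


@pytest.fixture(scope="session")
def small_population():
    """A small synthetic cohort (6 synapses, low noise) shared across tests."""
    spec = cx.PopulationSpec(n_synapses=6, seed=11, noise_cv=0.05, n_repetitions=3)
    tensor, truth = cx.generate_population(spec)
    return tensor, truth


@pytest.fixture(scope="session")
def control_train_200hz(control_blocks):
    params, tp, idp = control_blocks
    return cx.simulate_train(params, tp, idp, cx.StimulusProtocol(f_stim=200.0))
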