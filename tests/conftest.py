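import numpy as np
import pytest

from grkbret.synth import AssayDesign, ConditionTruth, generate_bret_dataset


@pytest.fixture
def zero_noise_plate():
    """Single-condition noise-free plate: instant response, saturating top dose.

    log EC50 = −10 with a 0.1 M top dose keeps the Hill occupancy within
    1e-9 of 1, so the planted top fold change is recovered to round-off.
    """
    design = AssayDesign(
        conditions=("cond",),
        concentrations=(0.0, 1e-12, 1e-11, 1e-10, 1e-9, 0.1),
        n_replicates=3,
    )
    truth = ConditionTruth(
        top_fold=1.25, noise_cv=0.0, response_tau_s=0.0, log_ec50=-10.0
    )
    wells = generate_bret_dataset(design, {"cond": truth}, seed=0)
    return wells, design, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
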