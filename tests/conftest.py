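import numpy as np
import pytest

from quantpk import AssayTruth, PKTruth, make_batch


@pytest.fixture
def zero_noise_truth():
    """Assay truth with every stochastic element switched off."""
    return AssayTruth(
        analyte_noise_cv=0.0, is_noise_cv=0.0, matrix_lot_sigma=0.0,
        blank_baseline_sd=0.0, seed=7,
    )


@pytest.fixture
def noisy_truth():
    return AssayTruth(analyte_noise_cv=3.0, is_noise_cv=2.0, seed=42)


@pytest.fixture
def zero_noise_batch(zero_noise_truth):
    return make_batch(zero_noise_truth, batch_id="b1")


@pytest.fixture
def noisy_batch(noisy_truth):
    return make_batch(noisy_truth, batch_id="b1")


@pytest.fixture
def iv_truth():
    """One-compartment IV truth: t1/2 ~ 2.3 h, V = 9 l/kg."""
    return PKTruth(residual_cv=0.0, dose=5.0, ke=0.005, v=9.0, seed=3)
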