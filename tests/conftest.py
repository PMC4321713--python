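import numpy as np
import pytest

from nanospring import synth


@pytest.fixture(scope="session")
def afm_cohort():
    """Mid-sized seeded AFM cohort shared by detector and population tests."""
    traces, truth = synth.gen_fd_traces(n_traces=100, seed=11)
    return traces, truth


@pytest.fixture(scope="session")
def quadratic_umbrella():
    """Umbrella windows sampled on a known quadratic PMF (a = 10 kJ/mol/nm^2)."""
    windows, truth = synth.gen_umbrella_samples(
        synth.harmonic_potential(10.0, 3.0), n_samples_per_window=5000, seed=1
    )
    return windows, truth


@pytest.fixture(scope="session")
def amide_plate():
    """Synthetic 3-component amide-I plate at signal-to-noise 100."""
    spectra, truth = synth.gen_amide1_spectra(seed=5, noise_sd=0.073 / 100)
    return spectra, truth
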