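import numpy as np
import pytest

from ftirchemo.synthetic_data import (
    ExperimentDesign,
    generate_concentrations,
    generate_spectra,
)


@pytest.fixture(scope="session")
def default_design():
    return ExperimentDesign()


@pytest.fixture(scope="session")
def default_spectra(default_design):
    return generate_spectra(default_design)


@pytest.fixture(scope="session")
def small_design():
    """Cheap 3-class design for unit tests."""
    return ExperimentDesign(
        class_labels=("A", "B", "C"),
        samples_per_class=(8, 8, 8),
        grid_start=2000.0,
        grid_end=1000.0,
        grid_step=10.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_spectra(small_design):
    from ftirchemo.synthetic_data import PeakDef

    peaks = [
        PeakDef(1800.0, 30.0, 0.5, (0.10, 0.00, 0.01)),
        PeakDef(1500.0, 30.0, 0.4, (0.00, 0.10, 0.01)),
        PeakDef(1200.0, 30.0, 0.3, (0.01, 0.00, 0.10)),
    ]
    return generate_spectra(small_design, peaks)


@pytest.fixture(scope="session")
def quant_spectra():
    design = ExperimentDesign(samples_per_class=(6, 6, 6, 6, 6), seed=3)
    return generate_spectra(design)


@pytest.fixture(scope="session")
def quant_table(quant_spectra):
    table, log = generate_concentrations(quant_spectra, noise_sd=0.01, seed=4)
    return table, log


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
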