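import numpy as np
import pytest
from hypothesis import settings

import spectrodx as sx

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def strong_cohort():
    """Well-separated cohort: 10% band shift, low noise, 200 patients.

    Session-scoped because several classifier tests reuse it.
    """
    cfg = sx.SimConfig(
        n_patients=200,
        prevalence=0.5,
        effect_size=0.10,
        noise_additive_sd=0.01,
        well_effect_sd=0.01,
        seed=42,
    )
    records, spectra = sx.simulate_cohort(cfg)
    return cfg, records, spectra


@pytest.fixture(scope="session")
def strong_features(strong_cohort):
    """Preprocessed features + labels for the strong cohort."""
    _, records, spectra = strong_cohort
    X, grid, index = sx.preprocess_pipeline(spectra, sx.PreprocessConfig())
    truth = {r.patient_id: r.true_class for r in records}
    labels = index["patient_id"].map(truth).to_numpy()
    return X, grid, index, labels, records, truth


@pytest.fixture()
def flat_spectrum():
    grid = sx.make_grid(1800, 900, 101)
    return sx.Spectrum("P1", 1, 1, grid, np.full(grid.size, 0.5))
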