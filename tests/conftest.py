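import numpy as np
import pytest
from hypothesis import settings

from epibind import spectra, synth

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_recipe():
    """Noise-free wild-type-like breakdown series recipe."""
    return synth.SimulationRecipe(noise_sd=0.0, na_adduct_fraction=0.0, seed=0)


@pytest.fixture(scope="session")
def clean_series(clean_recipe):
    return synth.simulate_series(clean_recipe)


@pytest.fixture(scope="session")
def clean_processed(clean_recipe, clean_series):
    return spectra.process_series(
        clean_series, clean_recipe.antibody_mass, clean_recipe.peptide_mass
    )


@pytest.fixture(scope="session")
def cv_steps():
    return np.array([2, 4, 6, 8, 12, 16, 20, 30, 40, 50, 60, 70, 80], dtype=float)
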