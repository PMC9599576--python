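import numpy as np
import pytest

from wirespec.spectra_core import SpectrumSet, WavenumberGrid, default_grid
from wirespec.synthetic_data import (
    GeneratorConfig,
    merge_model_pair,
    simulate_line_scan,
    simulate_model_pair,
)


@pytest.fixture
def small_grid():
    return WavenumberGrid(np.linspace(700.0, 1900.0, 121))


@pytest.fixture
def small_set(small_grid):
    rng = np.random.default_rng(42)
    return SpectrumSet(
        grid=small_grid,
        intensities=rng.uniform(0.0, 2.0, (5, len(small_grid))),
        position_um=np.arange(5.0),
        model_label=np.array(["2D"] * 5, dtype=object),
        truth_region=np.array(
            ["nucleus", "nucleus", "cytoplasm", "cytoplasm", "ecm"], dtype=object
        ),
    )


@pytest.fixture(scope="session")
def default_scan():
    """One default synthetic line scan (98 positions)."""
    return simulate_line_scan(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def model_pair():
    """Labeled 2D/3D pair at default generator settings."""
    return simulate_model_pair(GeneratorConfig(seed=3), 200, 200)


@pytest.fixture(scope="session")
def merged_pair(model_pair):
    return merge_model_pair(*model_pair)


@pytest.fixture
def clean_config():
    """Generator config with every stochastic knob off."""
    return GeneratorConfig(
        seed=0,
        hotspot_cv=0.0,
        noise_sigma=0.0,
        baseline_scale=0.0,
        composition_sd=0.0,
        protein_shift=0.0,
    )
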