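import numpy as np
import pandas as pd
import pytest

from subtyper.io import CohortMatrix, PixelSpectrumGrid
from subtyper.synthetic import SynthConfig, generate_profile_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """40-patient, 40-metabolite profile cohort with 4 strong planted
    tumor subtypes (session-scoped: read-only)."""
    cfg = SynthConfig(n_patients=40, n_metabolites=40, effect_size=3.0, seed=7)
    return generate_profile_cohort(cfg, "tumor")


@pytest.fixture
def tiny_grid():
    """2x2-pixel, 3-channel grid with hand-set intensities."""
    return PixelSpectrumGrid(
        core_id="core0",
        pixel_coords=[(0, 0), (0, 1), (1, 0), (1, 1)],
        mz_channels=[100.0, 150.0, 200.0],
        intensities=[[1.0, 2.0, 3.0],
                     [4.0, 5.0, 6.0],
                     [0.5, 0.5, 0.5],
                     [7.0, 8.0, 9.0]],
    )


def two_group_cohort(n_per_group=4, sep=5.0, seed=0, n_features=6):
    """Two tight, well-separated sample groups as a CohortMatrix."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 0.05, size=(n_per_group, n_features)) + \
        np.linspace(1, 2, n_features)
    b = rng.normal(0.0, 0.05, size=(n_per_group, n_features)) + \
        np.linspace(2, 1, n_features) * sep
    X = np.vstack([a, b]) + 10.0
    df = pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per_group)],
                      columns=[f"m{i}" for i in range(n_features)])
    return CohortMatrix(data=df, compartment="tumor")
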