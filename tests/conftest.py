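"""Shared fixtures.

The heavy session fixtures (scaled six-phenotype growth runs, calibrated
acquisition settings) are computed once and reused by the module tests and
the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from tumorpet.growth import run_growth
from tumorpet.params import BioParams, PHENOTYPE_PRESETS, get_preset
from tumorpet.pet import AcquisitionSettings, calibrate_noise
from tumorpet.world import place_vessels, seed_tumor

#: Desk-scale study conditions used throughout the suite: a 320×320 grid
#: (6.4×6.4 mm at 20 µm) grown to 2.2 mm equivalent diameter.
SCALED_DIMS = (320, 320)
SCALED_STOP_MM = 2.2


@pytest.fixture(scope="session")
def bio() -> BioParams:
    return BioParams()


@pytest.fixture(scope="session")
def scaled_runs(bio):
    """One scaled growth run per phenotype preset (A–F), fixed seeds."""
    runs = {}
    for i, name in enumerate(sorted(PHENOTYPE_PRESETS)):
        runs[name] = run_growth(
            get_preset(name, seed=100 + i),
            bio,
            stop_diameter_mm=SCALED_STOP_MM,
            dims=SCALED_DIMS,
            max_hours=8000,
        )
    return runs


@pytest.fixture(scope="session")
def acq_noise_free():
    from tumorpet.pet import calibrate_recon_scale
    from dataclasses import replace

    acq = calibrate_recon_scale(AcquisitionSettings())
    return replace(acq, noise_free=True, target_nstd=0.0)


@pytest.fixture(scope="session")
def acq_10():
    """Acquisition settings calibrated to the 10% NSTD mid noise level."""
    rng = np.random.default_rng(2024)
    return calibrate_noise(0.10, rng)


@pytest.fixture()
def small_grid(bio):
    grid = place_vessels(get_preset("A", seed=3), bio, dims=(120, 120))
    return grid


@pytest.fixture()
def seeded_grid(small_grid):
    return seed_tumor(small_grid.copy())
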