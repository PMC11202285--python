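"""Canned quantitative experiments shared by the validation suite and the
acceptance script.

Each function runs the package end to end under the study conditions —
desk-scale grid sizes are the package's standard validation configuration —
and returns plain numbers.
"""

from __future__ import annotations

import numpy as np

from .cells import division_probability
from .growth import run_growth, measure_tissue_concentrations
from .params import BioParams, PHENOTYPE_PRESETS, PhenotypeConfig
from .pde import make_field, steady_state_solve
from .pet import calibrate_noise, measure_nstd, simulate_pet, uniform_phantom
from .world import CellState, place_vessels

#: Benchmark full-scale times (days) to reach 1 cm diameter per phenotype,
#: used to sanity-check growth rates of scaled configurations.
BENCHMARK_DAYS_TO_1CM = {
    "A": 96.0,
    "B": 158.0,
    "C": 180.0,
    "D": 258.0,
    "E": 108.0,
    "F": 196.0,
}

#: Desk-scale study conditions: grid side (pixels at 20 µm) and stop diameter.
SCALED_GRID = 320
SCALED_STOP_MM = 2.2


def mean_first_division_time(
    n_cells: int = 1000,
    o2_mmhg: float = 50.0,
    bio: BioParams | None = None,
    rng: np.random.Generator | None = None,
    max_hours: int = 1000,
) -> float:
    """Mean waiting time (hours) to first division of well-oxygenated cells.

    Simulates the hourly division Bernoulli trial for ``n_cells`` independent
    cells with unlimited free neighbors until first success.
    """
    bio = bio or BioParams()
    rng = rng or np.random.default_rng()
    p = division_probability(o2_mmhg, bio)
    draws = rng.uniform(size=(n_cells, max_hours)) < p
    waits = np.argmax(draws, axis=1) + 1
    waits[~draws.any(axis=1)] = max_hours
    return float(waits.mean())


def normal_tissue_steady_state(
    vessel_density_mm2: float,
    dims: tuple[int, int] = (500, 500),
    seed: int = 0,
    bio: BioParams | None = None,
) -> dict[str, float]:
    """Steady-state nutrient levels in vascularized normal tissue (no tumor).

    Returns mean O2 (mmHg) over non-vessel pixels and mean glucose (mM) over
    normal-tissue pixels.
    """
    bio = bio or BioParams()
    cfg = PhenotypeConfig(vessel_density_mm2=vessel_density_mm2, seed=seed)
    grid = place_vessels(cfg, bio, dims)
    normal = grid.states == int(CellState.NORMAL)
    out = {}
    for mol, key, to_units in (
        ("oxygen", "o2_mmhg", 1.0),
        ("glucose", "glucose_mM", 1e3),
    ):
        field = make_field(grid, bio, mol)
        steady_state_solve(field, grid, bio)
        out[key] = float(field.conc[normal].mean() * to_units)
    return out


def normal_tissue_across_densities(
    dims: tuple[int, int] = (500, 500),
    seed: int = 0,
    bio: BioParams | None = None,
) -> dict[str, float]:
    """Steady-state levels averaged over the six phenotype vessel densities."""
    o2, glu = [], []
    for i, cfg in enumerate(PHENOTYPE_PRESETS.values()):
        m = normal_tissue_steady_state(
            cfg.vessel_density_mm2, dims=dims, seed=seed + i, bio=bio
        )
        o2.append(m["o2_mmhg"])
        glu.append(m["glucose_mM"])
    return {"o2_mmhg": float(np.mean(o2)), "glucose_mM": float(np.mean(glu))}


def pooled_tumor_concentrations(
    dims: tuple[int, int] = (SCALED_GRID, SCALED_GRID),
    stop_diameter_mm: float = SCALED_STOP_MM,
    seed: int = 0,
    bio: BioParams | None = None,
    runs: dict | None = None,
) -> dict[str, float]:
    """End-of-growth tumor-tissue nutrient levels pooled over phenotypes A–F.

    Grows each phenotype on a scaled grid to the stop diameter (one
    realization per phenotype), measures the steady-state mean O2/glucose over
    tumor-state pixels, and averages across phenotypes.  Pre-computed runs may
    be supplied to avoid recomputation.
    """
    if runs is None:
        runs = {}
        for i, name in enumerate(sorted(PHENOTYPE_PRESETS)):
            runs[name] = run_growth(
                PHENOTYPE_PRESETS[name].with_seed(seed + i),
                bio,
                stop_diameter_mm=stop_diameter_mm,
                dims=dims,
                max_hours=10_000,
            )
    o2 = []
    glu = []
    per_phenotype = {}
    for name, run in runs.items():
        m = measure_tissue_concentrations(run)
        per_phenotype[name] = m
        o2.append(m["o2_tumor_mmhg"])
        glu.append(m["glucose_tumor_mM"])
    return {
        "o2_tumor_mmhg": float(np.mean(o2)),
        "glucose_tumor_mM": float(np.mean(glu)),
        "per_phenotype": per_phenotype,
    }


def mid_noise_nstd_percent(
    seed: int = 0,
    target: float = 0.10,
    n_measure: int = 20,
) -> float:
    """Calibrate the mid noise setting and measure phantom NSTD in percent."""
    rng = np.random.default_rng(seed)
    acq = calibrate_noise(target, rng)
    phantom = uniform_phantom(acq)
    vals = [
        measure_nstd(simulate_pet(phantom, acq, rng)) for _ in range(n_measure)
    ]
    return float(np.mean(vals) * 100.0)
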