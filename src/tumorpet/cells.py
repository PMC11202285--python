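"""Hourly per-cell decision rules: metabolism, necrosis, hypoxia, division.

Every biological hour, each viable tumor cell (visited in a fresh random
permutation) goes through the same sequence:

1. survival — two independent stochastic necrosis checks, one on local
   oxygen (exponent fixed at 1) and one on the ATP production rate (exponent
   is the phenotype parameter); death probability is 1 − R^x with R the
   local-to-threshold ratio,
2. oxygenation — reclassified normoxic/hypoxic from the local O2 band,
3. division — a Bernoulli draw at a rate proportional to local O2 (mean
   cycle 24 h at full oxygenation), with daughters placed on a uniformly
   chosen NORMAL Moore neighbor, falling back to a VESSEL neighbor with the
   phenotype's removal probability.

Normal cells and vessels are passive; necrotic pixels are skipped and never
revert.
"""

from __future__ import annotations

import numpy as np

from . import _kernels
from .params import BioParams, PhenotypeConfig
from .pde import NutrientField
from .world import AgentGrid, CellState


def atp_rate(f_G: float | np.ndarray, f_O: float | np.ndarray, bio: BioParams | None = None) -> float | np.ndarray:
    """ATP production rate from glucose and oxygen consumption magnitudes.

    f_ATP = 2·f_G + (27/5)·f_O: glycolysis yields 2 ATP per glucose, and the
    oxidative pathway ~27 ATP per glucose at 5 O2 per glucose.
    """
    bio = bio or BioParams()
    if np.any(np.asarray(f_G) < 0) or np.any(np.asarray(f_O) < 0):
        raise ValueError("consumption magnitudes must be non-negative")
    return bio.atp_per_glucose * f_G + bio.atp_per_o2 * f_O


def glucose_consumption_rate(state: CellState, glucose_M: float, bio: BioParams) -> float:
    """Michaelis–Menten glucose uptake (mol/min/cell) for a viable cell."""
    vmax = {
        CellState.TUMOR_NORMOXIC: bio.vmax_glucose_tumor_normoxic,
        CellState.TUMOR_HYPOXIC: bio.vmax_glucose_tumor_hypoxic,
        CellState.NORMAL: bio.vmax_glucose_normal,
    }[state]
    return vmax * glucose_M / (bio.km_glucose_M + glucose_M)


def oxygen_consumption_rate(state: CellState, bio: BioParams) -> float:
    """Zero-order oxygen uptake (mol/min/cell) for a viable cell."""
    return {
        CellState.TUMOR_NORMOXIC: bio.vmax_o2_tumor_normoxic,
        CellState.TUMOR_HYPOXIC: bio.vmax_o2_tumor_hypoxic,
        CellState.NORMAL: bio.vmax_o2_normal,
    }[state]


def death_probability(local_value: float, threshold_value: float, x: float) -> float:
    """Necrosis probability 1 − (local/threshold)^x, zero at/above threshold."""
    if threshold_value <= 0:
        raise ValueError("threshold_value must be positive")
    if x <= 0:
        raise ValueError("exponent x must be positive")
    if local_value >= threshold_value:
        return 0.0
    r = max(local_value, 0.0) / threshold_value
    return float(min(max(1.0 - r**x, 0.0), 1.0))


def survival_step(
    state: CellState,
    local_o2_mmhg: float,
    local_glucose_M: float,
    config: PhenotypeConfig,
    bio: BioParams,
    rng: np.random.Generator,
) -> CellState:
    """Evaluate both necrosis criteria for one viable cell.

    One uniform draw per criterion; either success turns the cell necrotic.
    """
    if state not in (CellState.TUMOR_NORMOXIC, CellState.TUMOR_HYPOXIC):
        raise ValueError("survival_step applies to viable tumor cells")
    p_o2 = death_probability(
        local_o2_mmhg, bio.death_o2_mmhg, config.necrosis_exponent_oxygen
    )
    if rng.uniform() < p_o2:
        return CellState.TUMOR_NECROTIC
    f_g = glucose_consumption_rate(state, local_glucose_M, bio)
    f_o = oxygen_consumption_rate(state, bio)
    f_atp = atp_rate(f_g, f_o, bio)
    p_atp = death_probability(f_atp, bio.death_atp_rate, config.necrosis_exponent_atp)
    if rng.uniform() < p_atp:
        return CellState.TUMOR_NECROTIC
    return state


def oxygenation_state(local_o2_mmhg: float, bio: BioParams | None = None) -> CellState:
    """Normoxic/hypoxic classification from the local O2 band (closed band)."""
    bio = bio or BioParams()
    lo, hi = bio.hypoxia_band_mmhg
    if lo <= local_o2_mmhg <= hi:
        return CellState.TUMOR_HYPOXIC
    return CellState.TUMOR_NORMOXIC


def division_probability(local_o2_mmhg: float, bio: BioParams | None = None) -> float:
    """Hourly division probability, linear in O2 and capped at 1/24.

    Any cell above the 0.5% O2 normoxia reference divides on average once per
    24 h; below it the probability scales proportionally with local O2.
    """
    bio = bio or BioParams()
    scale = min(1.0, max(local_o2_mmhg, 0.0) / bio.normoxia_ref_mmhg)
    return scale / bio.division_interval_h


def attempt_division(
    position: tuple[int, int],
    grid: AgentGrid,
    config: PhenotypeConfig,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Place a daughter cell for a successful division draw.

    Uniform choice among NORMAL Moore neighbors; if there are none, a VESSEL
    neighbor is replaced with probability ``vessel_removal_prob``.  Tumor
    cells of any state are never displaced.  Returns the daughter position or
    None if no site was available.
    """
    r, c = position
    rows, cols = grid.dims
    parent = CellState(grid.states[r, c])
    normals: list[tuple[int, int]] = []
    vessels: list[tuple[int, int]] = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nr, nc = (r + dr) % rows, (c + dc) % cols
            t = CellState(grid.states[nr, nc])
            if t == CellState.NORMAL:
                normals.append((nr, nc))
            elif t == CellState.VESSEL:
                vessels.append((nr, nc))
    if normals:
        site = normals[int(rng.uniform() * len(normals)) % len(normals)]
    elif vessels and rng.uniform() < config.vessel_removal_prob:
        site = vessels[int(rng.uniform() * len(vessels)) % len(vessels)]
    else:
        return None
    grid.states[site] = int(parent)
    return site


def update_agents(
    grid: AgentGrid,
    o2: NutrientField,
    glucose: NutrientField,
    config: PhenotypeConfig,
    bio: BioParams,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Apply one biological hour of cell decisions to every viable tumor cell.

    Cells are visited in a random permutation (re-drawn every hour) to avoid
    directional growth bias; daughters born this hour act from the next hour.
    The nutrient fields are read-only during the pass (they are at steady
    state on the cellular timescale).  Returns event counts.
    """
    viable = grid.mask(CellState.TUMOR_NORMOXIC, CellState.TUMOR_HYPOXIC)
    idx_r, idx_c = np.nonzero(viable)
    n = idx_r.size
    if n == 0:
        return {"necrosed": 0, "divided": 0, "visited": 0}
    order = rng.permutation(n)
    idx_r = np.ascontiguousarray(idx_r[order])
    idx_c = np.ascontiguousarray(idx_c[order])
    draws = rng.uniform(size=(5, n))
    n_necro, n_div = _kernels.update_agents_pass(
        grid.states,
        o2.conc,
        glucose.conc,
        idx_r,
        idx_c,
        draws[0],
        draws[1],
        draws[2],
        draws[3],
        draws[4],
        bio.death_o2_mmhg,
        bio.hypoxia_band_mmhg[0],
        bio.hypoxia_band_mmhg[1],
        bio.death_atp_rate,
        config.necrosis_exponent_atp,
        config.vessel_removal_prob,
        1.0 / bio.division_interval_h,
        bio.normoxia_ref_mmhg,
        bio.vmax_glucose_tumor_normoxic,
        bio.vmax_glucose_tumor_hypoxic,
        bio.km_glucose_M,
        bio.vmax_o2_tumor_normoxic,
        bio.vmax_o2_tumor_hypoxic,
        bio.atp_per_glucose,
        bio.atp_per_o2,
    )
    return {"necrosed": int(n_necro), "divided": int(n_div), "visited": int(n)}
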