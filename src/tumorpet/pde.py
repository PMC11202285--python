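"""Nutrient reaction–diffusion on periodic grids.

Each nutrient obeys Fick diffusion with a cellular consumption sink,
∂C/∂t = D ∇²C + f, discretized as an explicit FTCS scheme (5-point Laplacian,
periodic boundaries).  Blood-vessel pixels are Dirichlet sources clamped to
the vascular concentration; concentrations are floored at zero.  Between
agent steps the fields are relaxed until the per-step change is negligible,
so the cellular dynamics always see nutrient concentrations at steady state.

Oxygen is tracked as partial pressure (mmHg) with a concentration-independent
sink per cell class; glucose is tracked in mol/L with Michaelis–Menten
kinetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .params import BioParams
from .world import AgentGrid, CellState

#: FTCS diffusion-number target used when internally accelerating relaxation;
#: the steady state of the scheme is independent of dt, so relaxation may run
#: at a larger stable step than the physical 30 ms without changing the fixed
#: point.
_ACCEL_DIFFUSION_NUMBER = 0.24


@dataclass
class NutrientField:
    """Concentration lattice co-registered with an :class:`AgentGrid`."""

    conc: np.ndarray
    molecule: str                 # "oxygen" | "glucose"
    d_cm2_s: float
    dx_mm: float
    dt_s: float

    def __post_init__(self) -> None:
        if self.molecule not in ("oxygen", "glucose"):
            raise ValueError(f"unknown molecule {self.molecule!r}")
        self.conc = np.asarray(self.conc, dtype=np.float64)

    @property
    def diffusion_number(self) -> float:
        return (self.d_cm2_s * 100.0) * self.dt_s / self.dx_mm**2

    def check_stability(self) -> None:
        nu = self.diffusion_number
        if nu > 0.25:
            raise ValueError(
                f"{self.molecule}: diffusion number {nu:.4g} violates the "
                f"explicit stability bound 0.25"
            )

    def copy(self) -> "NutrientField":
        return NutrientField(
            self.conc.copy(), self.molecule, self.d_cm2_s, self.dx_mm, self.dt_s
        )


def make_field(
    grid: AgentGrid,
    bio: BioParams,
    molecule: str,
    init: float | np.ndarray | None = None,
) -> NutrientField:
    """Create a field for ``molecule`` initialized at the vascular level."""
    d = {"oxygen": bio.d_oxygen_cm2_s, "glucose": bio.d_glucose_cm2_s}[molecule]
    c0 = vascular_concentration(bio, molecule) if init is None else init
    conc = np.full(grid.dims, c0, dtype=np.float64) if np.isscalar(c0) else np.array(c0, dtype=np.float64)
    return NutrientField(conc, molecule, d, grid.pixel_mm, bio.dt_diffusion_s)


def vascular_concentration(bio: BioParams, molecule: str) -> float:
    return bio.c_vessel_o2_mmhg if molecule == "oxygen" else bio.c_vessel_glucose_M


def sink_vmax_lattice(grid: AgentGrid, bio: BioParams, molecule: str) -> np.ndarray:
    """Per-pixel maximum sink rate (concentration units / s).

    Vessels and necrotic pixels consume nothing.  For oxygen this is the full
    (zero-order) sink; for glucose it is the Vmax entering the
    Michaelis–Menten law.
    """
    if molecule == "oxygen":
        rates = {
            CellState.NORMAL: bio.vmax_o2_normal,
            CellState.TUMOR_NORMOXIC: bio.vmax_o2_tumor_normoxic,
            CellState.TUMOR_HYPOXIC: bio.vmax_o2_tumor_hypoxic,
        }
    else:
        rates = {
            CellState.NORMAL: bio.vmax_glucose_normal,
            CellState.TUMOR_NORMOXIC: bio.vmax_glucose_tumor_normoxic,
            CellState.TUMOR_HYPOXIC: bio.vmax_glucose_tumor_hypoxic,
        }
    lut = np.zeros(len(CellState), dtype=np.float64)
    for state, rate in rates.items():
        lut[int(state)] = bio.molar_rate_to_sink(rate, molecule)
    return lut[grid.states]


def consumption_field(
    grid: AgentGrid, field: NutrientField, bio: BioParams
) -> np.ndarray:
    """Signed consumption rate f (concentration units per second) per pixel.

    Glucose follows −Vmax·[S]/(KM+[S]); oxygen uses the zero-order −Vmax.
    Vessel and necrotic pixels contribute zero.
    """
    if np.any(field.conc < 0):
        raise ValueError("negative concentrations in input field")
    vmax = sink_vmax_lattice(grid, bio, field.molecule)
    if field.molecule == "glucose":
        s = field.conc
        return -vmax * s / (bio.km_glucose_M + s)
    return -vmax


def diffusion_step(
    field: NutrientField,
    consumption: np.ndarray,
    vessel_mask: np.ndarray,
    c_vessel: float | None = None,
) -> NutrientField:
    """One explicit FTCS update (pure-numpy reference path).

    Periodic 5-point Laplacian, then the consumption term, floor at zero,
    then vessel pixels clamped to the vascular concentration.
    """
    field.check_stability()
    c = field.conc
    alpha = field.diffusion_number
    lap = (
        np.roll(c, 1, 0) + np.roll(c, -1, 0) + np.roll(c, 1, 1) + np.roll(c, -1, 1)
        - 4.0 * c
    )
    new = c + alpha * lap + field.dt_s * consumption
    np.maximum(new, 0.0, out=new)
    if c_vessel is not None and vessel_mask is not None:
        new[vessel_mask] = c_vessel
    out = field.copy()
    out.conc = new
    return out


def relax_to_steady_state(
    field: NutrientField,
    grid: AgentGrid,
    bio: BioParams,
    tol: float = 1e-5,
    max_iter: int = 200_000,
    accelerate: bool = True,
    check_every: int = 25,
) -> tuple[NutrientField, int]:
    """Iterate diffusion steps until the field stops changing.

    Stops when the max per-step change, relative to the vascular
    concentration, falls below ``tol``.  ``accelerate`` runs the relaxation at
    the largest stable time step instead of the physical one — the FTCS fixed
    point D∇²C + f(C) = 0 does not depend on dt — which matters for glucose,
    whose physical diffusion number is ~0.02.

    Returns the relaxed field (in place) and the number of iterations taken.
    Non-convergence within ``max_iter`` warns rather than raises.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    field.check_stability()
    c_vessel = vascular_concentration(bio, field.molecule)
    vmax = sink_vmax_lattice(grid, bio, field.molecule)
    km = bio.km_glucose_M if field.molecule == "glucose" else -1.0
    vessel = (grid.states == int(CellState.VESSEL)).astype(np.uint8)

    dt = field.dt_s
    alpha = field.diffusion_number
    if accelerate and alpha < _ACCEL_DIFFUSION_NUMBER:
        dt = dt * _ACCEL_DIFFUSION_NUMBER / alpha
        alpha = _ACCEL_DIFFUSION_NUMBER

    conc = np.ascontiguousarray(field.conc)
    n_done = 0
    threshold = tol * c_vessel
    maxdiff = np.inf
    while n_done < max_iter:
        n = min(check_every, max_iter - n_done)
        maxdiff = _kernels.ftcs_relax(conc, alpha, dt, vmax, km, vessel, c_vessel, n)
        n_done += n
        if maxdiff < threshold:
            break
    if maxdiff >= threshold:
        warnings.warn(
            f"{field.molecule} relaxation did not converge in {max_iter} steps "
            f"(last change {maxdiff:.3g})"
        )
    field.conc = conc
    return field, n_done


def steady_state_solve(
    field: NutrientField,
    grid: AgentGrid,
    bio: BioParams,
    tol: float = 1e-5,
    max_sweeps: int = 50_000,
    omega: float = 1.85,
    check_every: int = 10,
) -> tuple[NutrientField, int]:
    """Solve the steady diffusion–consumption equation by red-black SOR.

    The fixed point — the 5-point discrete form of D∇²C + f(C) = 0 with
    vessels clamped to the vascular concentration — is identical to the one
    :func:`relax_to_steady_state` converges to; SOR just reaches it in far
    fewer sweeps, which is what makes hourly re-equilibration affordable in
    growth runs.  Warm-starts from ``field.conc`` in place.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    c_vessel = vascular_concentration(bio, field.molecule)
    vmax = sink_vmax_lattice(grid, bio, field.molecule)
    km = bio.km_glucose_M if field.molecule == "glucose" else -1.0
    vessel = (grid.states == int(CellState.VESSEL)).astype(np.uint8)
    beta = field.dx_mm**2 / (field.d_cm2_s * 100.0)  # dx²/D, seconds

    conc = np.ascontiguousarray(field.conc)
    n_done = 0
    threshold = tol * c_vessel
    maxdiff = np.inf
    while n_done < max_sweeps:
        n = min(check_every, max_sweeps - n_done)
        maxdiff = _kernels.sor_sweep(conc, beta, vmax, km, vessel, c_vessel, omega, n)
        n_done += n
        if maxdiff < threshold:
            break
    if maxdiff >= threshold:
        warnings.warn(
            f"{field.molecule} SOR solve did not converge in {max_sweeps} sweeps "
            f"(last change {maxdiff:.3g})"
        )
    field.conc = conc
    return field, n_done
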