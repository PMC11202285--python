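"""Agent lattice: cell states, vessel placement, tumor geometry.

Each lattice pixel holds exactly one agent: a blood-vessel cross-section, a
normal (healthy) cell, or a tumor cell in one of three metabolic states
(normoxic, hypoxic, necrotic).  Vessels are point sources of nutrients;
necrotic pixels are inert and never revert to a viable state.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .params import BioParams, PhenotypeConfig


class CellState(enum.IntEnum):
    VESSEL = 0
    NORMAL = 1
    TUMOR_NORMOXIC = 2
    TUMOR_HYPOXIC = 3
    TUMOR_NECROTIC = 4


TUMOR_STATES = (
    CellState.TUMOR_NORMOXIC,
    CellState.TUMOR_HYPOXIC,
    CellState.TUMOR_NECROTIC,
)
VIABLE_TUMOR_STATES = (CellState.TUMOR_NORMOXIC, CellState.TUMOR_HYPOXIC)


@dataclass
class AgentGrid:
    """2D lattice of agent states at a fixed physical pitch.

    ``states`` is a uint8 array of :class:`CellState` codes.  One agent per
    pixel; the default geometry is 2000×2000 pixels at 20 µm (a 4×4 cm
    tissue section), configurable for desk-scale runs.
    """

    states: np.ndarray
    pixel_um: float = 20.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.uint8)
        if self.states.ndim != 2:
            raise ValueError("AgentGrid states must be 2D")

    @property
    def dims(self) -> tuple[int, int]:
        return self.states.shape  # type: ignore[return-value]

    @property
    def pixel_mm(self) -> float:
        return self.pixel_um * 1e-3

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_mm**2

    @property
    def physical_extent_mm(self) -> tuple[float, float]:
        return (self.dims[0] * self.pixel_mm, self.dims[1] * self.pixel_mm)

    def mask(self, *states: CellState) -> np.ndarray:
        m = np.zeros(self.dims, dtype=bool)
        for s in states:
            m |= self.states == int(s)
        return m

    def tumor_mask(self) -> np.ndarray:
        return self.mask(*TUMOR_STATES)

    def counts(self) -> dict[str, int]:
        return {s.name: int(np.count_nonzero(self.states == int(s))) for s in CellState}

    def copy(self) -> "AgentGrid":
        return AgentGrid(self.states.copy(), self.pixel_um)


def place_vessels(
    config: PhenotypeConfig,
    bio: BioParams | None = None,
    dims: tuple[int, int] = (2000, 2000),
    rng: np.random.Generator | None = None,
) -> AgentGrid:
    """Fill a grid with normal cells and scatter vessel cross-sections.

    The expected vessel count is density × physical area.  ``random`` draws
    that many distinct uniform pixels; ``uniform`` lays vessels on a square
    lattice at spacing 1/√density with independent per-vessel jitter of ±25%
    of the spacing (collisions re-jittered), approximating a regular capillary
    bed with small deviations.
    """
    bio = bio or BioParams()
    config.validate()
    rows, cols = dims
    if rows <= 0 or cols <= 0:
        raise ValueError("grid dims must be positive")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    pixel_mm = bio.pixel_um * 1e-3
    area_mm2 = rows * cols * pixel_mm**2
    n_vessels = int(round(config.vessel_density_mm2 * area_mm2))
    if n_vessels >= rows * cols:
        raise ValueError(
            f"vessel density {config.vessel_density_mm2}/mm² implies "
            f"{n_vessels} vessels on a {rows}×{cols} grid — non-physical"
        )

    states = np.full(dims, int(CellState.NORMAL), dtype=np.uint8)
    if config.vessel_pattern == "random":
        flat = rng.choice(rows * cols, size=n_vessels, replace=False)
        states.flat[flat] = int(CellState.VESSEL)
    else:
        _place_uniform_jittered(states, config.vessel_density_mm2, pixel_mm, rng)
    return AgentGrid(states, pixel_um=bio.pixel_um)


def _place_uniform_jittered(
    states: np.ndarray, density_mm2: float, pixel_mm: float, rng: np.random.Generator
) -> None:
    rows, cols = states.shape
    spacing_px = (1.0 / np.sqrt(density_mm2)) / pixel_mm
    jitter = 0.25 * spacing_px
    # Lattice points offset by half a spacing so densities match at the edges.
    r_centers = np.arange(spacing_px / 2.0, rows, spacing_px)
    c_centers = np.arange(spacing_px / 2.0, cols, spacing_px)
    for r0 in r_centers:
        for c0 in c_centers:
            for _ in range(100):  # re-jitter on collision
                r = int(round(r0 + rng.uniform(-jitter, jitter))) % rows
                c = int(round(c0 + rng.uniform(-jitter, jitter))) % cols
                if states[r, c] != int(CellState.VESSEL):
                    states[r, c] = int(CellState.VESSEL)
                    break


def seed_tumor(grid: AgentGrid) -> AgentGrid:
    """Place a single normoxic tumor cell at the grid center (in place).

    Idempotent.  If the center pixel is a vessel it is replaced (the founding
    cell must exist) and a warning is emitted.
    """
    r, c = grid.dims[0] // 2, grid.dims[1] // 2
    current = CellState(grid.states[r, c])
    if current == CellState.VESSEL:
        warnings.warn("center pixel was a vessel; replaced by the founding tumor cell")
    grid.states[r, c] = int(CellState.TUMOR_NORMOXIC)
    return grid


def tumor_diameter(grid: AgentGrid) -> float:
    """Equivalent-circle tumor diameter in mm, 2·√(A/π).

    A is the physical area of all tumor-state pixels, necrotic core included.
    """
    n = int(np.count_nonzero(grid.tumor_mask()))
    area_mm2 = n * grid.pixel_area_mm2
    return float(2.0 * np.sqrt(area_mm2 / np.pi))
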