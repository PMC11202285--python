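"""Longitudinal tumor-growth runs: initialize, relax, update, snapshot.

A run starts from a grid fully occupied by normal cells and vessels, relaxes
both nutrient fields to steady state, seeds a single normoxic tumor cell at
the center, then alternates { relax fields → one hourly agent update } until
the tumor reaches the stop diameter (or goes extinct).  Agent-grid snapshots
are kept every ``snapshot_interval_h`` biological hours.

Runs are seedable and resumable: the simulation object owns its generator,
so continuing a run is bit-identical to having run it in one piece.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cells import update_agents
from .params import BioParams, PhenotypeConfig
from .pde import NutrientField, make_field, steady_state_solve
from .world import AgentGrid, CellState, place_vessels, seed_tumor, tumor_diameter

STATUS_RUNNING = "running"
STATUS_REACHED = "reached"
STATUS_EXTINCT = "extinct"
STATUS_MAX_HOURS = "max_hours"


@dataclass
class GrowthRun:
    """Result of a growth simulation."""

    config: PhenotypeConfig
    bio: BioParams
    grid: AgentGrid
    o2: NutrientField
    glucose: NutrientField
    snapshots: list[tuple[int, AgentGrid]] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)
    status: str = STATUS_RUNNING
    hours: int = 0

    @property
    def diameter_mm(self) -> float:
        return tumor_diameter(self.grid)


class GrowthSimulation:
    """Stepping engine behind :func:`run_growth`.

    Keeping the state (grid, fields, RNG, clock) on an object makes
    checkpoint/resume trivial: two objects advanced the same total number of
    hours from the same seed produce bit-identical grids.
    """

    def __init__(
        self,
        config: PhenotypeConfig,
        bio: BioParams | None = None,
        dims: tuple[int, int] = (2000, 2000),
        seed: int | None = None,
        tol: float = 1e-5,
        snapshot_interval_h: int = 10,
    ):
        self.config = config
        self.bio = bio or BioParams()
        self.bio.validate()
        config.validate()
        if seed is None:
            seed = config.seed
        self.rng = np.random.default_rng(seed)
        self.tol = tol
        self.snapshot_interval_h = snapshot_interval_h

        self.grid = place_vessels(config, self.bio, dims, rng=self.rng)
        self.o2 = make_field(self.grid, self.bio, "oxygen")
        self.glucose = make_field(self.grid, self.bio, "glucose")
        self._relax()
        seed_tumor(self.grid)
        self.hours = 0
        self.snapshots: list[tuple[int, AgentGrid]] = [(0, self.grid.copy())]
        self.log: list[dict] = [self._log_record()]
        self.status = STATUS_RUNNING

    def _relax(self) -> tuple[int, int]:
        _, n_o2 = steady_state_solve(self.o2, self.grid, self.bio, tol=self.tol)
        _, n_glu = steady_state_solve(self.glucose, self.grid, self.bio, tol=self.tol)
        return n_o2, n_glu

    def _log_record(self) -> dict:
        counts = self.grid.counts()
        return {
            "hours": self.hours,
            "diameter_mm": tumor_diameter(self.grid),
            "counts": counts,
            "o2_mean_mmhg": float(self.o2.conc.mean()),
            "glucose_mean_M": float(self.glucose.conc.mean()),
        }

    def step_hour(self) -> dict:
        """One biological hour: relax both fields, then update the agents."""
        self._relax()
        events = update_agents(
            self.grid, self.o2, self.glucose, self.config, self.bio, self.rng
        )
        self.hours += 1
        if self.hours % self.snapshot_interval_h == 0:
            self.snapshots.append((self.hours, self.grid.copy()))
        rec = self._log_record()
        rec.update(events)
        self.log.append(rec)
        return rec

    def viable_count(self) -> int:
        counts = self.grid.counts()
        return counts["TUMOR_NORMOXIC"] + counts["TUMOR_HYPOXIC"]

    def run(self, stop_diameter_mm: float, max_hours: int = 20_000) -> GrowthRun:
        extent = min(self.grid.physical_extent_mm)
        if stop_diameter_mm > extent:
            raise ValueError(
                f"stop diameter {stop_diameter_mm} mm exceeds the grid extent "
                f"{extent:.1f} mm"
            )
        while self.status == STATUS_RUNNING:
            if tumor_diameter(self.grid) >= stop_diameter_mm:
                self.status = STATUS_REACHED
                break
            if self.hours >= max_hours:
                self.status = STATUS_MAX_HOURS
                warnings.warn("growth run hit max_hours before the stop diameter")
                break
            self.step_hour()
            if self.viable_count() == 0:
                self.status = STATUS_EXTINCT
                break
        # final relaxation so end-of-run concentrations are at steady state
        self._relax()
        return GrowthRun(
            config=self.config,
            bio=self.bio,
            grid=self.grid,
            o2=self.o2,
            glucose=self.glucose,
            snapshots=self.snapshots,
            log=self.log,
            status=self.status,
            hours=self.hours,
        )


def run_growth(
    config: PhenotypeConfig,
    bio: BioParams | None = None,
    stop_diameter_mm: float = 10.0,
    dims: tuple[int, int] = (2000, 2000),
    seed: int | None = None,
    snapshot_interval_h: int = 10,
    max_hours: int = 20_000,
    tol: float = 1e-5,
) -> GrowthRun:
    """Run one longitudinal growth simulation (see module docstring)."""
    sim = GrowthSimulation(
        config,
        bio,
        dims,
        seed=seed,
        tol=tol,
        snapshot_interval_h=snapshot_interval_h,
    )
    return sim.run(stop_diameter_mm, max_hours=max_hours)


def measure_tissue_concentrations(run: GrowthRun) -> dict[str, float]:
    """Mean nutrient levels over normal vs tumor tissue at the end of a run.

    Oxygen in mmHg, glucose in mM.  Tumor tissue includes all three tumor
    states; normal tissue is NORMAL pixels only (vessels excluded from both).
    """
    normal = run.grid.mask(CellState.NORMAL)
    tumor = run.grid.tumor_mask()
    out: dict[str, float] = {}
    for name, mask in (("normal", normal), ("tumor", tumor)):
        if mask.any():
            out[f"o2_{name}_mmhg"] = float(run.o2.conc[mask].mean())
            out[f"glucose_{name}_mM"] = float(run.glucose.conc[mask].mean() * 1e3)
        else:
            out[f"o2_{name}_mmhg"] = float("nan")
            out[f"glucose_{name}_mM"] = float("nan")
    return out
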