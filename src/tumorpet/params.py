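"""Biological constants and phenotype configuration.

All defaults describe tumor growth in vascularized tissue on a 2D lattice of
20 µm pixels (one cell per pixel).  Two diffusible nutrients are modeled:
oxygen (tracked in mmHg) and glucose (tracked in mol/L).  Per-cell metabolic
rates are given in mol/min/cell and converted to concentration sinks using an
effective pixel volume (a unit-depth slab of the cell size) and, for oxygen,
a Henry-law solubility constant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

# Unit conversions -----------------------------------------------------------

#: mmHg of O2 partial pressure per 1% O2 at atmospheric pressure (760 mmHg).
MMHG_PER_PERCENT_O2 = 7.6

#: Henry-law solubility of oxygen in tissue, mol/(L·mmHg).  Used to convert
#: molar oxygen consumption into a partial-pressure sink.  ~1.3 µM/mmHg is the
#: standard value for warm tissue.
O2_SOLUBILITY = 1.3e-6

#: ATP stoichiometry: glycolysis yields 2 ATP per glucose; the oxidative term
#: contributes 27/5 ATP per O2 consumed (27 ATP per glucose at 5 O2/glucose).
ATP_PER_GLUCOSE = 2.0
ATP_PER_O2 = 27.0 / 5.0


@dataclass
class BioParams:
    """Biological parameters held constant across phenotypes.

    Units: diffusion coefficients cm²/s, concentrations mmHg (O2) and mol/L
    (glucose), per-cell rates mol/min/cell, times hours or seconds as named.
    """

    pixel_um: float = 20.0                       # cell/pixel size, µm
    d_oxygen_cm2_s: float = 1.65e-5              # O2 diffusion coeff in tissue
    d_glucose_cm2_s: float = 2.7e-6              # glucose diffusion coeff
    c_vessel_o2_mmhg: float = 50.0               # vascular O2
    c_vessel_glucose_M: float = 5e-3             # vascular glucose

    # Oxygen consumption is concentration-independent (Michaelis constant for
    # O2 in tissue is negligible next to tissue pO2), one rate per cell class.
    vmax_o2_tumor_normoxic: float = 4e-15        # mol/min/cell
    vmax_o2_tumor_hypoxic: float = 2e-15
    vmax_o2_normal: float = 2.5e-18

    # Glucose consumption is Michaelis–Menten with class-specific Vmax.
    vmax_glucose_tumor_normoxic: float = 5e-14   # mol/min/cell
    vmax_glucose_tumor_hypoxic: float = 1.02e-13
    vmax_glucose_normal: float = 5e-15
    #: Glucose half-saturation concentration, mol/L.  The source tables print
    #: this constant with rate units, which cannot be used as a concentration;
    #: 0.5 mmol/L is a standard hexokinase-level KM for tissue glucose.
    km_glucose_M: float = 5e-4

    #: ATP production rate below which necrosis becomes possible, mol/min/cell
    #: (equal to 42.82e-17 mol ATP/s/cell).
    death_atp_rate: float = 2.57e-14
    #: O2 below this fraction (percent O2) makes necrosis possible.
    death_o2_percent: float = 0.08
    #: Hypoxic classification band in percent O2, inclusive on both ends.
    hypoxia_band_percent: tuple[float, float] = (0.08, 0.5)

    division_interval_h: float = 24.0            # mean cycle of a normoxic cell
    dt_cell_h: float = 1.0                       # agent step, biological hours
    dt_diffusion_s: float = 0.03                 # PDE step, seconds

    o2_solubility: float = O2_SOLUBILITY
    mmhg_per_percent: float = MMHG_PER_PERCENT_O2
    atp_per_glucose: float = ATP_PER_GLUCOSE
    atp_per_o2: float = ATP_PER_O2

    # Derived quantities -----------------------------------------------------

    @property
    def pixel_mm(self) -> float:
        return self.pixel_um * 1e-3

    @property
    def pixel_volume_L(self) -> float:
        """Effective volume of one pixel: (pixel size)³ as a unit-depth slab."""
        side_dm = self.pixel_um * 1e-5           # µm -> dm; 1 L = 1 dm³
        return side_dm**3

    @property
    def death_o2_mmhg(self) -> float:
        return self.death_o2_percent * self.mmhg_per_percent

    @property
    def hypoxia_band_mmhg(self) -> tuple[float, float]:
        lo, hi = self.hypoxia_band_percent
        return (lo * self.mmhg_per_percent, hi * self.mmhg_per_percent)

    @property
    def normoxia_ref_mmhg(self) -> float:
        """O2 level at which the division probability saturates (0.5% O2)."""
        return self.hypoxia_band_percent[1] * self.mmhg_per_percent

    def diffusion_number(self, molecule: str) -> float:
        """Unitless FTCS coefficient D·dt/dx² for the given molecule."""
        d_mm2_s = {"oxygen": self.d_oxygen_cm2_s, "glucose": self.d_glucose_cm2_s}[
            molecule
        ] * 100.0  # cm²/s -> mm²/s
        return d_mm2_s * self.dt_diffusion_s / self.pixel_mm**2

    def molar_rate_to_sink(self, rate_mol_min_cell: float, molecule: str) -> float:
        """Convert a per-cell molar rate to a concentration sink per second.

        Oxygen sinks come back in mmHg/s, glucose sinks in mol/L/s.
        """
        per_liter_s = rate_mol_min_cell / self.pixel_volume_L / 60.0
        if molecule == "oxygen":
            return per_liter_s / self.o2_solubility
        return per_liter_s

    def validate(self) -> None:
        for mol in ("oxygen", "glucose"):
            nu = self.diffusion_number(mol)
            if nu > 0.25:
                raise ValueError(
                    f"diffusion number {nu:.3g} for {mol} exceeds the explicit-"
                    f"scheme stability bound 0.25; reduce dt_diffusion_s"
                )


VESSEL_DENSITY_RANGE = (20.0, 100.0)  # physiological range, vessels per mm²


@dataclass
class PhenotypeConfig:
    """The microparameters varied between tumor phenotypes.

    ``necrosis_exponent_atp`` is the power x in the death-probability law
    1 − R^x applied to the ATP-production ratio; the oxygen exponent is fixed
    at 1 for every phenotype.
    """

    name: str = "custom"
    vessel_density_mm2: float = 50.0
    vessel_removal_prob: float = 0.05
    vessel_pattern: str = "random"               # "random" | "uniform"
    necrosis_exponent_atp: float = 2.0
    necrosis_exponent_oxygen: float = 1.0
    seed: int | None = None

    def validate(self, strict_density: bool = False) -> None:
        if self.vessel_density_mm2 <= 0:
            raise ValueError("vessel_density_mm2 must be positive")
        if strict_density:
            lo, hi = VESSEL_DENSITY_RANGE
            if not lo <= self.vessel_density_mm2 <= hi:
                raise ValueError(
                    f"vessel density {self.vessel_density_mm2} outside the "
                    f"physiological range {lo}-{hi} per mm²"
                )
        if not 0.0 <= self.vessel_removal_prob <= 1.0:
            raise ValueError("vessel_removal_prob must be in [0, 1]")
        if self.vessel_pattern not in ("random", "uniform"):
            raise ValueError(f"unknown vessel pattern {self.vessel_pattern!r}")
        if self.necrosis_exponent_atp <= 0 or self.necrosis_exponent_oxygen <= 0:
            raise ValueError("necrosis exponents must be positive")

    def with_seed(self, seed: int) -> "PhenotypeConfig":
        return replace(self, seed=seed)


#: The six shipped phenotype presets: (vessel density /mm², removal
#: probability, pattern, ATP necrosis exponent).
PHENOTYPE_PRESETS: dict[str, PhenotypeConfig] = {
    "A": PhenotypeConfig("A", 100.0, 0.05, "random", 2.0),
    "B": PhenotypeConfig("B", 50.0, 0.05, "uniform", 2.0),
    "C": PhenotypeConfig("C", 50.0, 0.50, "random", 1.0),
    "D": PhenotypeConfig("D", 20.0, 0.05, "uniform", 2.0),
    "E": PhenotypeConfig("E", 80.0, 0.02, "random", 1.0),
    "F": PhenotypeConfig("F", 50.0, 1.00, "random", 2.0),
}


def get_preset(name: str, seed: int | None = None) -> PhenotypeConfig:
    try:
        cfg = PHENOTYPE_PRESETS[name.upper()]
    except KeyError:
        raise KeyError(
            f"unknown phenotype preset {name!r}; available: "
            + ", ".join(sorted(PHENOTYPE_PRESETS))
        ) from None
    return cfg.with_seed(seed) if seed is not None else cfg
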