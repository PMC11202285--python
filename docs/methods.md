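# Methods

## Model overview

`tumorpet` simulates the growth of a 2D tumor cross-section in vascularized
normal tissue with a hybrid model: an **agent lattice** (one agent per 20 µm
pixel: blood-vessel cross-section, normal cell, or a tumor cell in the
normoxic, hypoxic, or necrotic state) coupled to two **reaction–diffusion
lattices** for oxygen (tracked as partial pressure, mmHg) and glucose
(mol/L).  Vessels are point-like Dirichlet sources clamped at 50 mmHg O2 and
5 mM glucose; cells are sinks.  Because molecular diffusion (milliseconds to
seconds) is vastly faster than cellular decisions (hours), the nutrient
fields are driven to steady state between hourly agent updates, so cells
always see equilibrated concentrations.

### Nutrient transport and metabolism

Each nutrient obeys ∂C/∂t = D∇²C + f on a periodic grid (periodicity
emulates a section of a larger tissue and avoids edge artifacts).  Glucose
consumption is Michaelis–Menten, f = −Vmax·[S]/(KM+[S]), with class-specific
Vmax (normal 5·10⁻¹⁵, normoxic tumor 5·10⁻¹⁴, hypoxic tumor 1.02·10⁻¹³
mol/min/cell).  Oxygen consumption is zero-order (its KM in tissue is
negligible next to tissue pO2): normal 2.5·10⁻¹⁸, normoxic tumor 4·10⁻¹⁵,
hypoxic tumor 2·10⁻¹⁵ mol/min/cell.  Necrotic cells and vessels consume
nothing.

ATP production combines glycolysis and oxidative phosphorylation,
f_ATP = 2·f_G + (27/5)·f_O (2 ATP per glucose via glycolysis; ~27 ATP per
glucose at 5 O2 per glucose oxidatively).  The 27/5 stoichiometry is a named
configuration constant.

### Unit conventions

Two conversions close the unit system; both are configurable fields of
`BioParams`:

* **Per-cell rates → concentration sinks.**  Molar rates (mol/min/cell) are
  divided by an effective pixel volume, a unit-depth slab of the cell size:
  V_pix = (20 µm)³ = 8·10⁻¹² L.  The 2D model leaves the depth implicit;
  a one-cell-thick slab is the natural reading.
* **Oxygen bookkeeping in mmHg.**  Percent-O2 thresholds convert at
  1% O2 = 7.6 mmHg (760 mmHg total pressure), giving a hypoxia band of
  0.608–3.8 mmHg and a necrosis threshold of 0.608 mmHg.  Molar O2
  consumption converts to a partial-pressure sink through a Henry-law
  solubility of 1.3·10⁻⁶ mol/(L·mmHg), the standard value for warm tissue.

The glucose KM is published with rate units, which cannot be used for a
concentration constant; we use 0.5 mmol/L, a standard hexokinase-level KM
for tissue glucose, exposed in the configuration.

### Cellular decision rules (one pass per biological hour)

Viable tumor cells are visited in a fresh random permutation (avoiding
directional growth bias; the update order within a step is otherwise
unspecified by the model).  Each cell, in order:

1. **Survival.**  Two independent stochastic necrosis checks with death
   probability 1 − R^x, where R is the local-value/threshold ratio.  Oxygen:
   threshold 0.08% O2, exponent fixed at 1.  ATP: threshold 2.57·10⁻¹⁴
   mol/min/cell, exponent the phenotype parameter (1 or 2).  One uniform
   draw per criterion; either success makes the cell necrotic, permanently.
   The hourly probabilistic draw is the model's realization of
   prolonged-exposure risk; there is no separate timer.
2. **Oxygenation.**  Hypoxic iff local O2 lies in the closed band
   0.08–0.5% O2; above the band the cell is (re)classified normoxic.
   Transitions are bidirectional.
3. **Division.**  Requires both O2 and ATP at or above the necrosis
   thresholds.  The hourly success probability is (1/24)·min(1, pO2/3.8 mmHg)
   — a fully oxygenated cell divides on average once per 24 h, and the rate
   scales linearly with O2 below the normoxia reference.  The daughter
   (same state and kinetic parameters as the parent) takes a uniformly
   chosen NORMAL pixel in the Moore neighborhood; if none exists, a VESSEL
   neighbor is replaced with the phenotype's removal probability; tumor
   cells are never displaced.  Daughters act from the next hourly pass and
   are reclassified from local O2 then.

Normal cells neither divide nor die in a run (the model defines no
proliferation rule for them); they serve as consuming, displaceable tissue.

### Phenotypes

Six presets (A–F) vary four microparameters: vessel density (20–100 mm⁻²),
vessel removal probability (0.02–1), vessel pattern (random, or uniform =
square lattice at spacing 1/√density with independent per-vessel jitter of
±25% of the spacing, re-jittered on collision), and the ATP necrosis
exponent (1 or 2).  Jitter law and magnitude are a package choice: small and
bounded, preserving near-uniform density.

### Numerical scheme

The PDE step is explicit FTCS with the 5-point periodic Laplacian; the
stability number D·dt/dx² must stay ≤ 0.25 (0.124 for O2 at the physical
30 ms step).  Concentrations are floored at 0; vessels re-clamped each step.
`relax_to_steady_state` iterates FTCS until the per-step change falls below
tol (default 10⁻⁵) of the vascular concentration; since the FTCS fixed point
is independent of dt, relaxation may run internally at the largest stable
step (diffusion number 0.24), which matters for glucose (physical number
0.02).  The growth loop instead solves the identical discrete steady-state
equation by red-black SOR (ω = 1.85, Michaelis–Menten sinks handled
semi-implicitly), which reaches the same fixed point one to two orders of
magnitude faster; the test suite asserts FTCS and SOR agree to ~10⁻⁵
relative.  Note the stopping rule bounds the *per-step* change; slowly
decaying modes amplify the residual distance to the fixed point by roughly
two orders of magnitude, so deep tolerances are used wherever two solutions
are compared.

A consequence of the discrete clamp: steady-state normal-tissue O2 averages
marginally below 50 mmHg (consumption is weak and vessels dense), and
glucose sits 2–15% below 5 mM depending on vessel density — emergent, not
prescribed.

## Synthetic PET

Agent maps convert to pseudo-SUV: necrotic 0, normal 1, normoxic tumor 8
(8× normal-tissue FDG uptake), hypoxic tumor 12 (1.5× the normoxic uptake).
Vessels map to 1 (blood pool ≈ background; the four-class mapping leaves
them unspecified).  The acquisition chain: center-crop (or pad with
background 1) to the 68×68 × 0.58 mm FOV with 29×29 block averaging from the
20 µm grid; Gaussian system PSF of 2.35 mm FWHM; parallel-beam forward
projection (180 angles over 180°, 0.58 mm bins); scaling by a global
count factor (the acquisition-time surrogate); Poisson sampling; OSEM with
8 subsets × 4 iterations and unfiltered backprojection as the adjoint;
division by the count factor returns pSUV units.  A one-time noise-free
round trip of the uniform reference phantom (pSUV 2.37, the average liver
uptake) fixes a residual global scale (<0.01% here).  The end-to-end
point-source FWHM measures 2.35 mm within 0.1%, so no extra
post-reconstruction blur is applied (the hook exists).

Noise is quantified as NSTD = std/mean over the central 40%×40% ROI of the
reconstructed uniform phantom.  `calibrate_noise` finds the count scale for
a target NSTD by secant iteration on the Poisson scaling law NSTD ∝
counts^(−1/2), averaging ≥10 phantom realizations per evaluation, stopping
within 2% relative.  Target 0 bypasses Poisson sampling entirely.

The 68×0.58 mm FOV (39.44 mm) is slightly smaller than the full-scale 40 mm
world; the world is center-cropped.  Projector and OSEM settings are the
minimal standard tomography setup, declared in `AcquisitionSettings`, not
inferred from any external reconstruction framework.

## Radiomics

Per image: fixed-bin-width quantization (bin 0.5 pSUV, anchored at the
masked minimum — consistent with "no normalization" and making all features
invariant to constant intensity shifts); symmetric GLCM at distance 1 pixel
merged over the four 2D directions (the 2.5D direction-merged form collapsed
to a single slice); 22 Haralick features with log base 2 and 0·log 0 = 0.
Features are computed on the native 0.58 mm grid within the lesion mask
(ground-truth tumor support block-averaged to the recon grid, pixel in mask
iff tumor fraction ≥ 0.5).  Degenerate single-level matrices return
correlation and both informational measures of correlation as 0, flagged in
the log.  The implementation is verified against a brute-force
pair-enumeration oracle and against `skimage.feature.graycomatrix` for the
matrix itself.

## Discrimination statistics

Welch's unequal-variance two-sample t (group variances differ between
phenotypes; a pooled-variance option exists), |t| reported per feature per
phenotype pair with a significance flag at p < 0.01 and no multiple-testing
correction.  Group samples pool the last two growth snapshots per
realization by default (configurable window).  Cluster separation in
feature space uses scikit-learn's silhouette score and Calinski–Harabasz
criterion.  Longitudinal curves report mean ± sd vs diameter per phenotype
and flag non-monotone ("N"-shaped) curves: successive differences of the
mean curve that exceed the local dispersion band must share a sign.

## Desk-scale validation conditions

Full-scale runs (2000² pixels grown to 1.7 cm, five realizations × six
phenotypes) are supported through the same API/CLI but take hours per run.
The package's standard validation configuration, used by the test suite and
`scripts/acceptance.py`, is a 320×320 grid (6.4×6.4 mm) grown to 2.2 mm
equivalent diameter, one realization per phenotype, plus 500×500 grids for
tumor-free steady states.  At this scale one phenotype takes one to two
minutes.  Validation quantities and their observed desk-scale values:

* mean first-division time of fully oxygenated cells ≈ 24 h,
* normal tissue: O2 ≈ 50 mmHg; glucose ≈ 4.6–4.7 mM averaged over the six
  vessel densities,
* tumor tissue (pooled A–F): O2 ≈ 6–9 mmHg, glucose ≈ 1.2–1.3 mM,
* growth linear in time (R² > 0.98 past the single-cell lag),
* calibrated mid noise level re-measures at 10% NSTD.

Growth *times* scale with the stop diameter and are not comparable to
full-scale benchmarks (`BENCHMARK_DAYS_TO_1CM` records those: 96–258 days,
mean 166); concentrations, band structure, and texture statistics transfer
because they are set by vessel spacing, not tumor size.  The tumor
equivalent-circle diameter 2√(A/π) includes the necrotic core.

## What the synthetic data does and does not capture

The generator produces morphologies (necrotic cores, hypoxic rims, tendril
structures, healthy-tissue pockets) governed by vessel geometry and
metabolism.  It does not model angiogenesis, vessel geometry beyond point
cross-sections, mechanical forces, cell migration, apoptosis, clearing of
necrotic debris, pH, genetic variability, 3D structure, or PET physics
beyond Poisson counting (no attenuation, scatter, randoms, decay).  Passing
tests therefore demonstrate internal consistency and agreement with the
model's reported emergent observables, not fidelity to any particular real
tumor.

## Known limitations

* The per-step-change stopping rule under-estimates the distance to the
  PDE fixed point (see above); tolerances are chosen conservatively.
* Uniform-jitter vessel placement slightly reduces nearest-neighbor
  distances below 1/√density (~20% at ±25% jitter).
* t-score magnitudes of the full-scale discrimination tables depend on the
  exact sample composition (realizations × noise draws × pooled snapshots),
  which is configurable; only their qualitative structure is asserted.
* OSEM at 8×4 is deliberately unconverged, as in clinical practice; feature
  values depend on these settings, which are recorded in output sidecars.
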