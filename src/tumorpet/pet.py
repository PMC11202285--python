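"""Synthetic PET: pSUV mapping, acquisition simulation, OSEM, noise calibration.

Agent maps are first converted to cell-scale pseudo-SUV images (necrotic 0,
normal 1, normoxic tumor 8, hypoxic tumor 12 — uptake ratios of FDG-avid
tissue classes; vessels are treated as blood pool at background level 1).
The acquisition chain is then:

  block-average to the 0.58 mm reconstruction grid (68×68 FOV)
  → Gaussian system PSF (end-to-end 2.35 mm FWHM)
  → parallel-beam forward projection (180 angles over 180°)
  → scaling to expected counts and Poisson sampling
  → OSEM reconstruction (8 subsets × 4 iterations)
  → rescale back to pSUV units.

Image noise is quantified as NSTD (std/mean over a central ROI of a uniform
reference phantom at pSUV 2.37) and the expected-count scale is calibrated by
a secant search to hit a target NSTD, mimicking the choice of acquisition
time on a scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import iradon, radon

from .world import AgentGrid, CellState

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: pSUV assignment per agent class.  Vessels (blood pool) sit at background.
PSUV_MAP: dict[CellState, float] = {
    CellState.TUMOR_NECROTIC: 0.0,
    CellState.NORMAL: 1.0,
    CellState.TUMOR_NORMOXIC: 8.0,
    CellState.TUMOR_HYPOXIC: 12.0,
    CellState.VESSEL: 1.0,
}

#: Uniform reference phantom level (average liver FDG uptake).
PHANTOM_PSUV = 2.37


@dataclass
class PSUVImage:
    """Pseudo-SUV lattice, either cell-scale or reconstruction-scale."""

    values: np.ndarray
    pixel_mm: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class AcquisitionSettings:
    """Geometry, resolution, and count-scale settings of the virtual scanner."""

    recon_pixels: int = 68
    recon_pixel_mm: float = 0.58
    fwhm_mm: float = 2.35           # end-to-end system resolution
    n_angles: int = 180
    n_subsets: int = 8
    n_iterations: int = 4
    count_scale: float = 0.0        # expected counts per unit of projected pSUV
    noise_free: bool = False
    recon_scale: float = 1.0        # global calibration factor (round-trip)
    target_nstd: float | None = None
    pad_value: float = 1.0          # background pSUV when padding small worlds

    @property
    def fov_mm(self) -> float:
        return self.recon_pixels * self.recon_pixel_mm


@dataclass
class ReconImage:
    """OSEM-reconstructed pSUV image with provenance annotations."""

    values: np.ndarray
    pixel_mm: float
    fwhm_mm: float
    noise_nstd: float | None = None
    lesion_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


def agent_to_psuv(grid: AgentGrid) -> PSUVImage:
    """Map agent states to the fixed per-class pSUV values."""
    lut = np.full(256, np.nan)
    for state, v in PSUV_MAP.items():
        lut[int(state)] = v
    values = lut[grid.states]
    if np.isnan(values).any():
        bad = np.unique(grid.states[np.isnan(values)])
        raise ValueError(f"unknown agent state codes {bad.tolist()}")
    return PSUVImage(values, pixel_mm=grid.pixel_mm)


def _to_recon_grid(
    values: np.ndarray, pixel_mm: float, acq: AcquisitionSettings, pad_value: float
) -> np.ndarray:
    """Center-crop/pad a cell-scale image to the FOV and block-average down."""
    n = acq.recon_pixels
    if values.shape == (n, n):
        return values.astype(np.float64)
    factor = acq.recon_pixel_mm / pixel_mm
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"recon pixel ({acq.recon_pixel_mm} mm) must be an integer multiple "
            f"of the cell pixel ({pixel_mm} mm); got ratio {factor:.4f}. "
            f"Resample the input or change the geometry."
        )
    factor = int(round(factor))
    target = n * factor
    out = np.full((target, target), pad_value, dtype=np.float64)
    rows, cols = values.shape
    # center-crop the source if larger, center-place if smaller
    src_r0 = max((rows - target) // 2, 0)
    src_c0 = max((cols - target) // 2, 0)
    take_r = min(rows, target)
    take_c = min(cols, target)
    dst_r0 = max((target - rows) // 2, 0)
    dst_c0 = max((target - cols) // 2, 0)
    out[dst_r0 : dst_r0 + take_r, dst_c0 : dst_c0 + take_c] = values[
        src_r0 : src_r0 + take_r, src_c0 : src_c0 + take_c
    ]
    return out.reshape(n, factor, n, factor).mean(axis=(1, 3))


def _subset_angles(acq: AcquisitionSettings) -> list[np.ndarray]:
    theta = np.linspace(0.0, 180.0, acq.n_angles, endpoint=False)
    return [theta[s :: acq.n_subsets] for s in range(acq.n_subsets)]


def _osem(sinogram_subsets, subset_thetas, n_pix, n_iter):
    """Classic OSEM with unfiltered backprojection as the adjoint."""
    x = np.ones((n_pix, n_pix), dtype=np.float64)
    eps = 1e-12
    sens = [
        np.maximum(
            iradon(
                np.ones((sinogram_subsets[s].shape[0], len(subset_thetas[s]))),
                theta=subset_thetas[s],
                filter_name=None,
                circle=False,
                output_size=n_pix,
            ),
            eps,
        )
        for s in range(len(subset_thetas))
    ]
    for _ in range(n_iter):
        for s, theta_s in enumerate(subset_thetas):
            fp = radon(x, theta=theta_s, circle=False)
            ratio = sinogram_subsets[s] / np.maximum(fp, eps)
            bp = iradon(
                ratio,
                theta=theta_s,
                filter_name=None,
                circle=False,
                output_size=n_pix,
            )
            x = x * bp / sens[s]
            np.maximum(x, 0.0, out=x)
    return x


def simulate_pet(
    psuv: PSUVImage,
    acq: AcquisitionSettings,
    rng: np.random.Generator | None = None,
) -> ReconImage:
    """Forward-project, add Poisson noise, and OSEM-reconstruct a pSUV image.

    With ``acq.noise_free`` the Poisson sampling is skipped and a fixed unit
    count scale is used (the EM fixed point is scale-equivariant, so the
    count scale only matters for noise).
    """
    if not acq.noise_free:
        if acq.count_scale <= 0:
            raise ValueError(
                "count_scale not set; run calibrate_noise() or use noise_free"
            )
        if rng is None:
            raise ValueError("rng required for noisy simulation")
    img = _to_recon_grid(psuv.values, psuv.pixel_mm, acq, acq.pad_value)
    sigma_px = acq.fwhm_mm * FWHM_TO_SIGMA / acq.recon_pixel_mm
    blurred = gaussian_filter(img, sigma_px, mode="constant", cval=acq.pad_value)

    scale = acq.count_scale if not acq.noise_free else 1.0
    subset_thetas = _subset_angles(acq)
    sino_subsets = []
    total = 0.0
    for theta_s in subset_thetas:
        expected = scale * np.maximum(radon(blurred, theta=theta_s, circle=False), 0.0)
        counts = expected if acq.noise_free else rng.poisson(expected).astype(np.float64)
        sino_subsets.append(counts)
        total += counts.sum()
    if total == 0.0:
        recon = np.zeros((acq.recon_pixels, acq.recon_pixels))
    else:
        recon = _osem(sino_subsets, subset_thetas, acq.recon_pixels, acq.n_iterations)
        recon = recon * (acq.recon_scale / scale)
    return ReconImage(
        values=recon,
        pixel_mm=acq.recon_pixel_mm,
        fwhm_mm=acq.fwhm_mm,
        noise_nstd=acq.target_nstd,
    )


def central_roi(n_pix: int, fraction: float = 0.4) -> tuple[slice, slice]:
    """Central ``fraction``×``fraction`` box, the default NSTD ROI."""
    half = int(round(n_pix * fraction / 2.0))
    lo, hi = n_pix // 2 - half, n_pix // 2 + half
    return (slice(lo, hi), slice(lo, hi))


def measure_nstd(recon: ReconImage, roi: tuple[slice, slice] | None = None) -> float:
    """Normalized standard deviation (std/mean) over an ROI."""
    roi = roi or central_roi(recon.values.shape[0])
    vals = recon.values[roi]
    if vals.size == 0:
        raise ValueError("empty ROI")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("zero-mean ROI; NSTD undefined")
    return float(vals.std() / mean)


def uniform_phantom(acq: AcquisitionSettings, psuv: float = PHANTOM_PSUV) -> PSUVImage:
    n = acq.recon_pixels
    return PSUVImage(np.full((n, n), psuv), pixel_mm=acq.recon_pixel_mm)


def _mean_nstd(acq, phantom, rng, n_real):
    vals = [measure_nstd(simulate_pet(phantom, acq, rng)) for _ in range(n_real)]
    return float(np.mean(vals))


def calibrate_recon_scale(acq: AcquisitionSettings) -> AcquisitionSettings:
    """Fix the global pSUV round-trip factor with a noise-free phantom."""
    base = replace(acq, noise_free=True, recon_scale=1.0)
    phantom = uniform_phantom(base)
    recon = simulate_pet(phantom, base)
    mean = recon.values[central_roi(base.recon_pixels)].mean()
    return replace(acq, recon_scale=float(PHANTOM_PSUV / mean))


def calibrate_noise(
    target_nstd: float,
    rng: np.random.Generator,
    acq: AcquisitionSettings | None = None,
    phantom_psuv: float = PHANTOM_PSUV,
    n_realizations: int = 10,
    rel_tol: float = 0.02,
    max_iter: int = 12,
) -> AcquisitionSettings:
    """Find the count scale whose phantom NSTD matches ``target_nstd``.

    Secant iteration on log(scale) using the Poisson scaling law
    NSTD ∝ 1/√counts as the initial model; each evaluation averages the NSTD
    of ``n_realizations`` fresh phantom noise realizations.  target 0 returns
    noise-free settings.
    """
    acq = acq or AcquisitionSettings()
    acq = calibrate_recon_scale(acq)
    if target_nstd == 0:
        return replace(acq, noise_free=True, target_nstd=0.0)
    if not 0 < target_nstd <= 0.5:
        raise ValueError("target NSTD must be in (0, 0.5]")
    phantom = uniform_phantom(acq, phantom_psuv)

    scale = 10.0  # counts per projected pSUV·mm — order-of-magnitude start
    trial = replace(acq, count_scale=scale, noise_free=False)
    nstd = _mean_nstd(trial, phantom, rng, n_realizations)
    for _ in range(max_iter):
        if abs(nstd - target_nstd) <= rel_tol * target_nstd:
            break
        scale = scale * (nstd / target_nstd) ** 2
        trial = replace(trial, count_scale=scale)
        nstd = _mean_nstd(trial, phantom, rng, n_realizations)
    else:
        raise RuntimeError(
            f"noise calibration failed to reach NSTD {target_nstd} "
            f"(last {nstd:.4f} at scale {scale:.3g})"
        )
    return replace(trial, target_nstd=target_nstd)


def lesion_mask_from_truth(grid: AgentGrid, acq: AcquisitionSettings) -> np.ndarray:
    """Ground-truth tumor support resampled to the recon grid.

    A recon pixel belongs to the lesion when at least half of its area is
    covered by tumor-state pixels (any of normoxic/hypoxic/necrotic).
    """
    support = grid.tumor_mask().astype(np.float64)
    frac = _to_recon_grid(support, grid.pixel_mm, acq, pad_value=0.0)
    return frac >= 0.5
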