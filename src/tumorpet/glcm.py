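"""GLCM construction and the 22 Haralick texture features (IBSI-style).

Protocol: intensities are quantized with a constant bin width of 0.5 pSUV
anchored at the masked minimum (no normalization, no resampling); the
co-occurrence matrix uses distance 1 and merges the four 2D directions
(0°, 45°, 90°, 135°) symmetrically before normalization, i.e. the
direction-merged form collapsed to 2D for single-slice images.  Only pixel
pairs with both members inside the lesion mask are counted.  Entropies use
log base 2 with the 0·log 0 ≡ 0 convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: 2D displacement vectors of the four merged directions at distance d.
DIRECTIONS = ((0, 1), (1, 1), (1, 0), (1, -1))

#: Canonical feature order; column names of every feature table.
FEATURE_NAMES = (
    "autocorrelation",
    "joint_average",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_average",
    "difference_entropy",
    "difference_variance",
    "joint_energy",
    "joint_entropy",
    "imc1",
    "imc2",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_variance",
    "maximum_probability",
    "sum_entropy",
    "sum_of_squares",
)


@dataclass
class GLCM:
    """Normalized symmetric gray-level co-occurrence matrix."""

    matrix: np.ndarray
    n_levels: int
    distance: int = 1
    merged: bool = True


def quantize_constant_bin(
    image: np.ndarray, mask: np.ndarray, bin_size: float = 0.5
) -> np.ndarray:
    """Fixed-bin-width quantization anchored at the masked minimum.

    level(v) = floor((v − min_masked)/bin_size) + 1; returns an int array
    with zeros outside the mask and contiguous levels from 1 inside.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    image = np.asarray(image, dtype=np.float64)
    lo = image[mask].min()
    labels = np.zeros(image.shape, dtype=np.int64)
    labels[mask] = np.floor((image[mask] - lo) / bin_size).astype(np.int64) + 1
    return labels


def glcm_merged(
    labels: np.ndarray, mask: np.ndarray, distance: int = 1
) -> GLCM:
    """Direction-merged symmetric GLCM restricted to in-mask pairs."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(labels)
    n_levels = int(labels[mask].max()) if mask.any() else 0
    if n_levels < 1:
        raise ValueError("no labeled pixels in mask")
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    rows, cols = labels.shape
    for dr, dc in DIRECTIONS:
        d_r, d_c = dr * distance, dc * distance
        r0, r1 = max(0, -d_r), min(rows, rows - d_r)
        c0, c1 = max(0, -d_c), min(cols, cols - d_c)
        a = labels[r0:r1, c0:c1]
        b = labels[r0 + d_r : r1 + d_r, c0 + d_c : c1 + d_c]
        valid = mask[r0:r1, c0:c1] & mask[r0 + d_r : r1 + d_r, c0 + d_c : c1 + d_c]
        if not valid.any():
            continue
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid in-mask pixel pairs at this distance")
    counts = counts + counts.T  # symmetrize (merges each direction with its opposite)
    return GLCM(counts / counts.sum(), n_levels=n_levels, distance=distance)


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_features(glcm: GLCM) -> dict[str, float]:
    """All 22 Haralick features of a normalized symmetric GLCM.

    Degenerate single-level matrices return correlation and the two
    informational measures of correlation as 0 by convention (flagged in the
    log); entropies are 0 and joint energy 1 there by construction.
    """
    p = glcm.matrix
    ng = glcm.n_levels
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)                     # == py by symmetry
    mu = float((ii * p).sum())             # joint average (μx = μy)
    sigma2 = float(((ii - mu) ** 2 * p).sum())
    sigma = np.sqrt(sigma2)

    # sum and difference distributions
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(np.int64).ravel() - 2, p.ravel())
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(np.int64).ravel(), p.ravel())

    diff_avg = float((k_diff * p_diff).sum())
    f: dict[str, float] = {}
    f["autocorrelation"] = float((ii * jj * p).sum())
    f["joint_average"] = mu
    f["cluster_prominence"] = float(((ii + jj - 2 * mu) ** 4 * p).sum())
    f["cluster_shade"] = float(((ii + jj - 2 * mu) ** 3 * p).sum())
    f["cluster_tendency"] = float(((ii + jj - 2 * mu) ** 2 * p).sum())
    f["contrast"] = float(((ii - jj) ** 2 * p).sum())
    if sigma2 > 0:
        f["correlation"] = float(((ii - mu) * (jj - mu) * p).sum() / sigma2)
    else:
        logger.debug("single-level GLCM: correlation set to 0 by convention")
        f["correlation"] = 0.0
    f["difference_average"] = diff_avg
    f["difference_entropy"] = float(-_xlog2(p_diff).sum())
    f["difference_variance"] = float(((k_diff - diff_avg) ** 2 * p_diff).sum())
    f["joint_energy"] = float((p**2).sum())
    hxy = float(-_xlog2(p).sum())
    f["joint_entropy"] = hxy

    # informational measures of correlation
    hx = float(-_xlog2(px).sum())
    px_py = np.outer(px, px)
    log_pxpy = np.zeros_like(px_py)
    np.log2(px_py, out=log_pxpy, where=px_py > 0)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(px_py * log_pxpy).sum())
    if hx > 0:
        f["imc1"] = (hxy - hxy1) / hx
        arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
        f["imc2"] = float(np.sqrt(max(arg, 0.0)))
    else:
        f["imc1"] = 0.0
        f["imc2"] = 0.0

    absdiff = np.abs(ii - jj)
    f["inverse_difference_moment"] = float((p / (1.0 + (ii - jj) ** 2)).sum())
    f["inverse_difference_moment_normalized"] = float(
        (p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()
    )
    f["inverse_difference"] = float((p / (1.0 + absdiff)).sum())
    f["inverse_difference_normalized"] = float((p / (1.0 + absdiff / ng)).sum())
    k_pos = k_diff[1:]
    f["inverse_variance"] = float((p_diff[1:] / k_pos**2).sum())
    f["maximum_probability"] = float(p.max())
    f["sum_entropy"] = float(-_xlog2(p_sum).sum())
    f["sum_of_squares"] = sigma2
    return f


def features_from_image(
    image: np.ndarray,
    mask: np.ndarray,
    bin_size: float = 0.5,
    distance: int = 1,
) -> dict[str, float]:
    """Quantize → GLCM → features, the full per-image protocol."""
    labels = quantize_constant_bin(image, mask, bin_size)
    return haralick_features(glcm_merged(labels, mask, distance))


def feature_time_series(
    run,
    noise_settings: dict[float, "AcquisitionSettings"],
    rng: np.random.Generator,
    n_noise_realizations: int = 1,
    bin_size: float = 0.5,
    min_mask_pixels: int = 4,
) -> pd.DataFrame:
    """Features for every (snapshot × noise level × realization) of a run.

    ``noise_settings`` maps NSTD level (0 for noise-free) to calibrated
    :class:`AcquisitionSettings`.  Snapshots whose lesion mask has fewer than
    ``min_mask_pixels`` recon pixels are skipped with a log entry.
    """
    from .pet import agent_to_psuv, lesion_mask_from_truth, simulate_pet
    from .world import tumor_diameter

    records = []
    for hours, grid in run.snapshots:
        diameter = tumor_diameter(grid)
        psuv = agent_to_psuv(grid)
        for level, acq in sorted(noise_settings.items()):
            mask = lesion_mask_from_truth(grid, acq)
            if mask.sum() < min_mask_pixels:
                logger.info(
                    "skipping snapshot t=%dh at noise %.2f: lesion mask too small",
                    hours,
                    level,
                )
                continue
            n_real = 1 if acq.noise_free else n_noise_realizations
            for real in range(n_real):
                recon = simulate_pet(psuv, acq, rng)
                feats = features_from_image(recon.values, mask, bin_size=bin_size)
                records.append(
                    {
                        "phenotype": run.config.name,
                        "hours": hours,
                        "diameter_mm": diameter,
                        "noise_nstd": level,
                        "realization": real,
                        **feats,
                    }
                )
    return pd.DataFrame.from_records(records)
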