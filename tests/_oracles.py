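"""Independent brute-force oracles used only by the tests.

These deliberately re-derive quantities with naive loops and textbook
formulas, sharing no code with the package implementation.
"""

from __future__ import annotations

import numpy as np

OFFSETS = ((0, 1), (1, 1), (1, 0), (1, -1))


def glcm_bruteforce(labels: np.ndarray, mask: np.ndarray, distance: int = 1) -> np.ndarray:
    """Direction-merged symmetric GLCM by exhaustive pair enumeration."""
    ng = int(labels[mask].max())
    counts = np.zeros((ng, ng), dtype=float)
    rows, cols = labels.shape
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            for dr, dc in OFFSETS:
                rr, cc = r + dr * distance, c + dc * distance
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                    counts[labels[r, c] - 1, labels[rr, cc] - 1] += 1.0
    counts = counts + counts.T
    return counts / counts.sum()


def haralick_bruteforce(P: np.ndarray) -> dict[str, float]:
    """All 22 Haralick features by explicit loops over the GLCM."""
    ng = P.shape[0]

    def log2(x):
        return np.log2(x) if x > 0 else 0.0

    px = [sum(P[i][j] for j in range(ng)) for i in range(ng)]
    mu = sum((i + 1) * P[i][j] for i in range(ng) for j in range(ng))
    var = sum((i + 1 - mu) ** 2 * P[i][j] for i in range(ng) for j in range(ng))

    p_sum = {}
    p_diff = {}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + P[i][j]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i][j]
    da = sum(k * v for k, v in p_diff.items())

    hxy = -sum(P[i][j] * log2(P[i][j]) for i in range(ng) for j in range(ng))
    hx = -sum(px[i] * log2(px[i]) for i in range(ng))
    hxy1 = -sum(
        P[i][j] * log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * px[j] * log2(px[i] * px[j]) for i in range(ng) for j in range(ng)
    )

    f = {}
    f["autocorrelation"] = sum(
        (i + 1) * (j + 1) * P[i][j] for i in range(ng) for j in range(ng)
    )
    f["joint_average"] = mu
    for name, power in (
        ("cluster_prominence", 4),
        ("cluster_shade", 3),
        ("cluster_tendency", 2),
    ):
        f[name] = sum(
            (i + j + 2 - 2 * mu) ** power * P[i][j]
            for i in range(ng)
            for j in range(ng)
        )
    f["contrast"] = sum((i - j) ** 2 * P[i][j] for i in range(ng) for j in range(ng))
    f["correlation"] = (
        sum(
            (i + 1 - mu) * (j + 1 - mu) * P[i][j]
            for i in range(ng)
            for j in range(ng)
        )
        / var
        if var > 0
        else 0.0
    )
    f["difference_average"] = da
    f["difference_entropy"] = -sum(v * log2(v) for v in p_diff.values())
    f["difference_variance"] = sum((k - da) ** 2 * v for k, v in p_diff.items())
    f["joint_energy"] = sum(P[i][j] ** 2 for i in range(ng) for j in range(ng))
    f["joint_entropy"] = hxy
    f["imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    f["imc2"] = (
        float(np.sqrt(max(1.0 - np.exp(-2.0 * (hxy2 - hxy)), 0.0))) if hx > 0 else 0.0
    )
    f["inverse_difference_moment"] = sum(
        P[i][j] / (1.0 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_moment_normalized"] = sum(
        P[i][j] / (1.0 + (i - j) ** 2 / ng**2) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference"] = sum(
        P[i][j] / (1.0 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    f["inverse_difference_normalized"] = sum(
        P[i][j] / (1.0 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    f["inverse_variance"] = sum(v / k**2 for k, v in p_diff.items() if k > 0)
    f["maximum_probability"] = max(
        P[i][j] for i in range(ng) for j in range(ng)
    )
    f["sum_entropy"] = -sum(v * log2(v) for v in p_sum.values())
    f["sum_of_squares"] = var
    return f


def welch_t(a, b):
    """Textbook Welch statistic."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return abs(a.mean() - b.mean()) / np.sqrt(va + vb)
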