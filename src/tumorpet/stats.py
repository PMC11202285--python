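"""Phenotype-discrimination statistics.

Given per-phenotype samples of texture-feature values (realizations ×
pooled adjacent growth snapshots at one noise level), this module computes:

* pairwise two-sample t-scores per feature (Welch by default — group
  variances differ between phenotypes; a pooled-variance option exists),
  with a significance flag at p < 0.01 and no multiple-testing correction,
* cluster-separation metrics in feature space: silhouette score (SS) and
  Calinski–Harabasz criterion (CHC), higher = better-formed clusters,
* longitudinal feature curves (mean ± sd vs tumor diameter) with a
  non-monotonicity flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .glcm import FEATURE_NAMES


@dataclass
class DiscriminationTable:
    """t-scores (features × phenotype pairs) at one noise level."""

    tscores: pd.DataFrame          # |t| values, rows=features, cols="A_vs_E"
    significant: pd.DataFrame      # boolean, p < 0.01
    noise_nstd: float
    n_per_group: dict[str, int] = field(default_factory=dict)
    test: str = "welch"


def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool) -> tuple[float, float]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 samples per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float("inf"), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(abs(t)), float(p)


def pairwise_tscores(
    features_by_phenotype: dict[str, pd.DataFrame],
    pairs: list[tuple[str, str]],
    noise_nstd: float = 0.0,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
    welch: bool = True,
    alpha: float = 0.01,
) -> DiscriminationTable:
    """|t| per feature per phenotype pair, flagged significant at p < alpha.

    Each value of ``features_by_phenotype`` is a DataFrame whose rows are
    independent samples (realizations, optionally pooled snapshots) and whose
    columns include the feature names.
    """
    cols = [f"{a}_vs_{b}" for a, b in pairs]
    tmat = pd.DataFrame(index=list(feature_names), columns=cols, dtype=float)
    sig = pd.DataFrame(False, index=list(feature_names), columns=cols)
    for (a, b), col in zip(pairs, cols):
        fa, fb = features_by_phenotype[a], features_by_phenotype[b]
        for feat in feature_names:
            t, p = _two_sample_t(fa[feat].to_numpy(), fb[feat].to_numpy(), not welch)
            tmat.loc[feat, col] = t
            sig.loc[feat, col] = p < alpha
    n = {k: len(v) for k, v in features_by_phenotype.items()}
    return DiscriminationTable(
        tscores=tmat,
        significant=sig,
        noise_nstd=noise_nstd,
        n_per_group=n,
        test="welch" if welch else "pooled",
    )


def cluster_separation(
    points: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Silhouette score and Calinski–Harabasz criterion of labeled points."""
    points = np.asarray(points, dtype=np.float64)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise ValueError("cluster separation requires at least 2 clusters")
    if (counts < 2).any():
        raise ValueError("each cluster needs at least 2 points")
    ss = float(silhouette_score(points, labels))
    chc = float(calinski_harabasz_score(points, labels))
    return ss, chc


def pool_snapshots(table: pd.DataFrame, window: int = 2) -> pd.DataFrame:
    """Keep the last ``window`` snapshots per (phenotype, noise, realization).

    Pooling adjacent growth steps enlarges the sample behind each t-test the
    same way plotting two sequential growth steps does.
    """
    keys = ["phenotype", "noise_nstd", "realization"]
    rank = table.groupby(keys)["hours"].rank(method="dense", ascending=False)
    return table[rank <= window].reset_index(drop=True)


def longitudinal_curves(
    feature_table: pd.DataFrame,
    feature_names: tuple[str, ...] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Mean ± sd of each feature vs tumor diameter, per phenotype and noise.

    Adds a per-(phenotype, noise, feature) ``monotone`` flag: False when the
    successive differences of the mean curve change sign by more than the
    local dispersion band (an "N"-shaped curve), True otherwise.
    """
    grouped = (
        feature_table.groupby(["phenotype", "noise_nstd", "hours"])
        .agg(
            diameter_mm=("diameter_mm", "mean"),
            **{f: (f, "mean") for f in feature_names},
            **{f + "_sd": (f, "std") for f in feature_names},
        )
        .reset_index()
        .sort_values(["phenotype", "noise_nstd", "hours"])
    )
    flags = []
    for (pheno, noise), g in grouped.groupby(["phenotype", "noise_nstd"]):
        for f in feature_names:
            flags.append(
                {
                    "phenotype": pheno,
                    "noise_nstd": noise,
                    "feature": f,
                    "monotone": _is_monotone(
                        g[f].to_numpy(), g[f + "_sd"].fillna(0.0).to_numpy()
                    ),
                }
            )
    grouped.attrs["monotonicity"] = pd.DataFrame(flags)
    return grouped


def _is_monotone(means: np.ndarray, sds: np.ndarray) -> bool:
    diffs = np.diff(means)
    band = 0.5 * (sds[:-1] + sds[1:])
    signif = diffs[np.abs(diffs) > band]
    if signif.size < 2:
        return True
    return bool(np.all(signif > 0) or np.all(signif < 0))
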