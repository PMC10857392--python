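"""Feature-distribution diagnostics.

Quantifies how a feature's distribution drifts across trials or sessions:
per-group moments (mean, std, skewness, excess kurtosis) with the
cross-group spread of skewness and kurtosis as a drift summary; Gaussian
kernel density curves; and a 3-component PCA projection of the
(standardized) feature matrix for visual inspection of session overlap.

Kurtosis is the Fisher convention (normal -> 0) by default; moments use
the biased (population) estimators.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.decomposition import PCA

from .evaluation import Standardizer

__all__ = ["DistributionStats", "PcaProjection", "distribution_stats",
           "density_curve", "pca_projection"]

logger = logging.getLogger(__name__)


@dataclass
class DistributionStats:
    per_group: pd.DataFrame      # index: group; columns mean/std/skewness/kurtosis
    skewness_std: float          # cross-group spread of skewness
    kurtosis_std: float


def distribution_stats(
    groups: Mapping, fisher: bool = True, min_size: int = 3
) -> DistributionStats:
    """Moments of a feature's values per group (trial or session).

    Groups with fewer than ``min_size`` values are excluded with a warning.
    Cross-group standard deviations of skewness and kurtosis (sample std,
    ddof=1) summarise how much the shape of the distribution drifts.
    """
    rows = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < min_size:
            logger.warning("group %r has %d < %d values; excluded", name, values.size, min_size)
            continue
        rows[name] = {
            "mean": float(values.mean()),
            "std": float(values.std(ddof=0)),
            "skewness": float(sstats.skew(values, bias=True)),
            "kurtosis": float(sstats.kurtosis(values, fisher=fisher, bias=True)),
        }
    if not rows:
        raise ValueError("no group has enough values")
    per_group = pd.DataFrame.from_dict(rows, orient="index")
    return DistributionStats(
        per_group=per_group,
        skewness_std=float(per_group["skewness"].std(ddof=1)) if len(per_group) > 1 else 0.0,
        kurtosis_std=float(per_group["kurtosis"].std(ddof=1)) if len(per_group) > 1 else 0.0,
    )


def density_curve(
    values: Sequence[float], grid: Optional[np.ndarray] = None, n_grid: int = 512
) -> Tuple[np.ndarray, np.ndarray]:
    """Gaussian-kernel probability density estimate (Silverman bandwidth).

    Returns (grid, density).  With no grid given, one spanning the data
    plus four bandwidths is built, so the density integrates to ~1.
    Degenerate (all-equal) samples produce a narrow spike with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ValueError("need at least 5 values")
    if np.ptp(values) == 0:
        logger.warning("degenerate sample (all values equal); returning a narrow spike")
        center = values[0]
        bw = max(abs(center), 1.0) * 1e-3
        if grid is None:
            grid = np.linspace(center - 6 * bw, center + 6 * bw, n_grid)
        dens = np.exp(-0.5 * ((grid - center) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
        return np.asarray(grid), dens
    kde = sstats.gaussian_kde(values, bw_method="silverman")
    if grid is None:
        bw = kde.factor * values.std(ddof=1)
        grid = np.linspace(values.min() - 4 * bw, values.max() + 4 * bw, n_grid)
    return np.asarray(grid), kde(np.asarray(grid))


@dataclass
class PcaProjection:
    components: np.ndarray                # (k, D) orthonormal loadings
    scores: np.ndarray                    # (n, k)
    explained_variance_ratio: np.ndarray  # (k,), nonincreasing


def pca_projection(
    X: np.ndarray, n_components: int = 3, standardize: bool = True
) -> PcaProjection:
    """Top-k principal components of the (optionally standardized) rows.

    Standardization is the default because the feature set mixes scales
    (counts, amplitudes, dimensionless coefficients).  If the data rank is
    below ``n_components``, fewer components are returned with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 4:
        raise ValueError("need a 2-D array with at least 4 rows")
    if standardize:
        X = Standardizer().fit_transform(X)
    k = min(n_components, X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    nonzero = int(np.sum(pca.explained_variance_ > 1e-12))
    if nonzero < n_components:
        logger.warning("data rank %d < %d requested components", nonzero, n_components)
    return PcaProjection(
        components=pca.components_,
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
    )
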